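"""Quantify the effect of single- vs mixed-reference alignment.

When reads from a two-species coculture are aligned once against the
species' own genome and once against a combined two-species reference,
most genes' expression estimates barely move, but genes with
cross-species sequence homology lose reads to the other genome. Per
gene, the two paired expression vectors are stacked (each sample
appears twice, labelled by alignment) and a two-way fixed-effect ANOVA
with samples as blocks partitions the variance; the fraction
SS(alignment) / SS(total) measures how alignment-sensitive the gene is.
Genes at or above a threshold (default 10% of inter-sample variance)
are flagged. Two accompanying tests characterize the global effect: a
paired t-test on per-sample total counts (ambiguous reads shrink the
mixed-reference libraries) and a Mann-Whitney test on gene length of
flagged vs unflagged genes (cross-mapping genes tend to be shorter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, GeneAnnotation
from .preprocess import NormalizedMatrix, log_cpm, tmm_norm_factors

__all__ = [
    "AlignmentQCReport", "PairedTestResult", "LengthBiasResult",
    "alignment_variance_fraction", "flag_alignment_sensitive",
    "paired_library_size_test", "length_bias_test", "alignment_qc_report",
]


@dataclass
class PairedTestResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    p: float
    degenerate: bool = False  # zero-variance nonzero difference: p reported as 0


@dataclass
class LengthBiasResult:
    mean_length_diff: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class AlignmentQCReport:
    fractions: pd.Series
    flagged_gene_ids: list[str]
    threshold: float
    library_size_test: PairedTestResult | None = None
    length_bias: LengthBiasResult | None = None

    def to_dict(self) -> dict:
        out = {
            "threshold": self.threshold,
            "n_genes": int(len(self.fractions)),
            "n_flagged": len(self.flagged_gene_ids),
            "flagged_gene_ids": self.flagged_gene_ids,
            "mean_fraction": float(self.fractions.mean()),
            "median_fraction": float(self.fractions.median()),
        }
        if self.library_size_test is not None:
            t = self.library_size_test
            out["library_size_test"] = {"mean_diff": t.mean_diff, "ci": [t.ci_low, t.ci_high],
                                        "p": t.p, "degenerate": t.degenerate}
        if self.length_bias is not None:
            b = self.length_bias
            out["length_bias"] = {"mean_length_diff": b.mean_length_diff,
                                  "ci": [b.ci_low, b.ci_high], "p": b.p}
        return out


def alignment_variance_fraction(norm_single: NormalizedMatrix,
                                norm_mixed: NormalizedMatrix) -> pd.Series:
    """Per-gene fraction of total variance attributable to alignment.

    Balanced two-way ANOVA with one observation per (sample, alignment)
    cell: SS(alignment) = (n/2) * (mean_single - mean_mixed)^2.
    """
    if list(norm_single.gene_ids) != list(norm_mixed.gene_ids):
        raise ValueError("gene ids differ between the two alignments")
    if list(norm_single.sample_ids) != list(norm_mixed.sample_ids):
        raise ValueError("sample ids differ between the two alignments")
    a, b = norm_single.values, norm_mixed.values
    n = a.shape[1]
    grand = (a.sum(axis=1) + b.sum(axis=1)) / (2 * n)
    ss_total = ((a - grand[:, None]) ** 2).sum(axis=1) + ((b - grand[:, None]) ** 2).sum(axis=1)
    ss_align = (n / 2.0) * (a.mean(axis=1) - b.mean(axis=1)) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ss_total > 0, ss_align / ss_total, 0.0)
    return pd.Series(np.clip(frac, 0.0, 1.0), index=norm_single.gene_ids,
                     name="alignment_variance_fraction")


def flag_alignment_sensitive(fractions: pd.Series, threshold: float = 0.10) -> list[str]:
    """Gene ids whose alignment variance fraction is >= threshold, sorted descending."""
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    hit = fractions[fractions >= threshold]
    return list(hit.sort_values(ascending=False).index)


def paired_library_size_test(totals_single, totals_mixed) -> PairedTestResult:
    """Paired t-test on per-sample total counts between the two alignments."""
    x = np.asarray(totals_single, dtype=float)
    y = np.asarray(totals_mixed, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 totals")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    n = d.size
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 0.0, 0.0, 1.0)
        return PairedTestResult(mean, mean, mean, 0.0, degenerate=True)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    res = stats.ttest_1samp(d, 0.0)
    return PairedTestResult(mean, mean - tcrit * se, mean + tcrit * se, float(res.pvalue))


def length_bias_test(flagged_ids, annotation: GeneAnnotation,
                     universe_ids=None) -> LengthBiasResult:
    """Mann-Whitney comparison of gene lengths, flagged vs the rest.

    ``universe_ids`` defaults to every annotated gene; the "rest" group
    is the universe minus the flagged set. Exact enumeration is used for
    small tie-free groups (both <= 50), the tie-corrected normal
    approximation otherwise.
    """
    flagged = list(flagged_ids)
    universe = list(universe_ids) if universe_ids is not None else list(annotation.frame.index)
    rest = [g for g in universe if g not in set(flagged)]
    if not flagged or not rest:
        raise ValueError("both the flagged and the remaining group must be nonempty")
    lf = annotation.lengths(flagged)
    lr = annotation.lengths(rest)
    mean_diff = float(lf.mean() - lr.mean())
    se = float(np.sqrt(lf.var(ddof=1) / lf.size + lr.var(ddof=1) / lr.size)) \
        if min(lf.size, lr.size) > 1 else 0.0
    if se > 0:
        df = lf.size + lr.size - 2
        tcrit = stats.t.ppf(0.975, df)
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    else:
        ci = (mean_diff, mean_diff)
    has_ties = len(np.unique(np.concatenate([lf, lr]))) < lf.size + lr.size
    method = "exact" if (max(lf.size, lr.size) <= 50 and not has_ties) else "asymptotic"
    mw = stats.mannwhitneyu(lf, lr, alternative="two-sided", method=method)
    return LengthBiasResult(mean_diff, ci[0], ci[1], float(mw.pvalue))


def alignment_qc_report(single: CountMatrix, mixed: CountMatrix,
                        annotation: GeneAnnotation | None = None,
                        threshold: float = 0.10) -> AlignmentQCReport:
    """Full QC comparison of a single- vs mixed-reference count matrix pair.

    Both matrices are TMM-normalized to log-CPM independently before
    variance partitioning (library-size differences are reported by the
    paired total-count test, not folded into the per-gene fractions).
    """
    common = [g for g in single.gene_ids if g in set(mixed.gene_ids)]
    s = single.subset_genes(common)
    m = mixed.subset_genes(common).subset_samples(s.sample_ids)
    ns = log_cpm(s, tmm_norm_factors(s))
    nm = log_cpm(m, tmm_norm_factors(m))
    fractions = alignment_variance_fraction(ns, nm)
    flagged = flag_alignment_sensitive(fractions, threshold)
    lib_test = paired_library_size_test(s.library_sizes(), m.library_sizes())
    length = None
    if annotation is not None and flagged and len(flagged) < len(common):
        length = length_bias_test(flagged, annotation, universe_ids=common)
    return AlignmentQCReport(fractions, flagged, threshold, lib_test, length)
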