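"""Count preprocessing: replicate summation, expression filtering, TMM
library normalization, log-CPM / log-TPKM transforms, mean-variance
precision weights, a location-scale batch adjustment, PCA and
method-of-moments dispersion summaries.

The TMM implementation follows the published trimmed-mean-of-M-values
procedure: per-sample log2 ratios against a reference sample (the one
whose 75th-percentile count fraction is closest to the mean), doubly
trimmed on M (30% per tail) and on average abundance A (5% per tail),
averaged with inverse delta-method-variance precision weights, and
rescaled so the factors have geometric mean one.

Precision weights follow the voom recipe: the square-root residual
standard deviation of each gene's linear-model fit is smoothed against
average log2 count with lowess, and each observation's weight is the
predicted square-root standard deviation at its fitted log-count raised
to the power -4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
import statsmodels.api as sm

from .io_formats import CountMatrix, GeneAnnotation, SampleTable

__all__ = [
    "NormalizedMatrix", "FilterReport", "WeightMatrix",
    "sum_replicates", "filter_low_expression", "tmm_norm_factors",
    "log_cpm", "log_tpkm", "precision_weights", "batch_adjust",
    "pca", "estimate_dispersions",
]


@dataclass
class NormalizedMatrix:
    """log2-scale expression values with their normalization provenance."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray           # genes x samples, log2 scale
    norm_factors: np.ndarray     # per-sample, geometric mean 1
    prior_count: float = 0.5
    lib_sizes: np.ndarray | None = None  # effective library sizes (libsize * factor)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite normalized value")
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)
        if (self.norm_factors <= 0).any():
            raise ValueError("non-positive norm factor")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids) -> "NormalizedMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return NormalizedMatrix(list(gene_ids), list(self.sample_ids),
                                self.values[rows, :], self.norm_factors,
                                self.prior_count, self.lib_sizes)

    def subset_samples(self, sample_ids) -> "NormalizedMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return NormalizedMatrix(list(self.gene_ids), list(sample_ids),
                                self.values[:, cols], self.norm_factors[cols],
                                self.prior_count,
                                None if self.lib_sizes is None else self.lib_sizes[cols])


@dataclass
class FilterReport:
    kept_gene_ids: list[str]
    removed_gene_ids: list[str]
    min_per_library: float
    min_total: float


@dataclass
class WeightMatrix:
    """Positive per-observation precision weights plus the fitted mean-variance trend."""

    weights: np.ndarray          # genes x samples
    trend: pd.DataFrame = field(default_factory=pd.DataFrame)  # columns: mean_logcount, sqrt_sd

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValueError("weights must be positive and finite")
        self.weights = w


# ---------------------------------------------------------------------------


def sum_replicates(counts: CountMatrix, table: SampleTable) -> tuple[CountMatrix, SampleTable]:
    """Sum experimental replicates into one library per replicate group."""
    table.check_covers(counts)
    meta = table.frame.loc[counts.sample_ids]
    if meta["replicate_group"].isna().any():
        raise ValueError("replicate_group undefined for some samples")
    groups = list(dict.fromkeys(meta["replicate_group"]))  # first-appearance order
    cols = []
    rows_meta = []
    for g in groups:
        members = meta.index[meta["replicate_group"] == g]
        if len(members) == 0:
            raise ValueError(f"replicate group {g!r} has zero members")
        member_idx = [counts.sample_ids.index(s) for s in members]
        cols.append(counts.counts[:, member_idx].sum(axis=1))
        rec = meta.loc[members[0]].copy()
        if "ngn2" in meta.columns:
            rec["ngn2"] = meta.loc[members, "ngn2"].mean()
        rec.name = g
        rows_meta.append(rec)
    summed = CountMatrix(list(counts.gene_ids), [str(g) for g in groups],
                         np.column_stack(cols), counts.species, counts.alignment_ref)
    out_meta = pd.DataFrame(rows_meta)
    out_meta.index.name = "sample_id"
    out_meta["replicate_group"] = out_meta.index
    return summed, SampleTable(out_meta)


def filter_low_expression(counts: CountMatrix, min_per_library: float = 10,
                          min_total: float = 15) -> tuple[CountMatrix, FilterReport]:
    """Remove weakly expressed genes.

    A gene is kept iff its maximum count over libraries exceeds
    ``min_per_library`` AND its total count exceeds ``min_total``.
    Idempotent by construction.
    """
    maxes = counts.counts.max(axis=1) if counts.n_samples else np.zeros(counts.n_genes)
    totals = counts.counts.sum(axis=1)
    keep = (maxes > min_per_library) & (totals > min_total)
    kept = [g for g, k in zip(counts.gene_ids, keep) if k]
    removed = [g for g, k in zip(counts.gene_ids, keep) if not k]
    report = FilterReport(kept, removed, min_per_library, min_total)
    return counts.subset_genes(kept), report


# ---------------------------------------------------------------------------
# TMM


def _quantile_fraction(counts: np.ndarray, libsizes: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts / libsizes[None, :], p, axis=0)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Scaling factor (log2) of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        raise ValueError("no gene positive in both test and reference sample")
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)  # delta-method var
    fin = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[fin], a[fin], v[fin]
    n = m.size
    if n == 0:
        return 0.0
    if np.abs(m).max() < 1e-6:
        return 0.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return f if np.isfinite(f) else 0.0


def tmm_norm_factors(counts: CountMatrix, trim_m: float = 0.30,
                     trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    ``trim_m`` and ``trim_a`` are the per-tail trim fractions on the
    log-ratios and on average abundance respectively.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM needs >= 2 samples")
    libsizes = counts.library_sizes().astype(float)
    if (libsizes == 0).any():
        bad = counts.sample_ids[int(np.argmin(libsizes))]
        raise ValueError(f"all-zero sample: {bad!r}")
    f75 = _quantile_fraction(counts.counts, libsizes)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = counts.counts[:, ref_idx]
    log_factors = np.array([
        _tmm_pair(counts.counts[:, k], ref, libsizes[k], libsizes[ref_idx], trim_m, trim_a)
        for k in range(counts.n_samples)
    ])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# transforms


def log_cpm(counts: CountMatrix, factors: np.ndarray | None = None,
            prior_count: float = 0.5) -> NormalizedMatrix:
    """log2 counts-per-million: ``log2((count + prior) / (libsize*factor + 1) * 1e6)``."""
    if factors is None:
        factors = np.ones(counts.n_samples)
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("norm factors must be positive")
    eff = counts.library_sizes().astype(float) * factors
    values = np.log2((counts.counts + prior_count) / (eff[None, :] + 1.0) * 1e6)
    return NormalizedMatrix(list(counts.gene_ids), list(counts.sample_ids), values,
                            factors, prior_count, lib_sizes=eff)


def log_tpkm(counts: CountMatrix, annotation: GeneAnnotation,
             prior_count: float = 0.5) -> NormalizedMatrix:
    """log2 transcripts-per-kilobase-per-million.

    Counts are divided by gene length in kb, each sample's rates are
    rescaled to sum to 1e6, and the prior is added before the log.
    """
    lengths_kb = annotation.lengths(counts.gene_ids) / 1000.0
    rates = counts.counts / lengths_kb[:, None]
    col = rates.sum(axis=0)
    if (col == 0).any():
        raise ValueError("all-zero sample in TPKM computation")
    scaled = rates / col[None, :] * 1e6
    values = np.log2(scaled + prior_count)
    return NormalizedMatrix(list(counts.gene_ids), list(counts.sample_ids), values,
                            np.ones(counts.n_samples), prior_count)


# ---------------------------------------------------------------------------
# precision weights (voom recipe)


def _fit_residual_sd(values: np.ndarray, design: np.ndarray,
                     weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene residual SD and fitted values under OLS with a shared design."""
    n, p = design.shape
    if n - p < 1:
        raise ValueError("fewer residual degrees of freedom than 1")
    beta, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    fitted = (design @ beta).T
    resid = values - fitted
    sd = np.sqrt((resid ** 2).sum(axis=1) / (n - p))
    return sd, fitted


def precision_weights(normmat: NormalizedMatrix, design: np.ndarray,
                      span: float = 0.5) -> WeightMatrix:
    """Mean-variance precision weights for log-CPM values.

    Requires ``normmat`` to carry effective library sizes (i.e. to come
    from :func:`log_cpm`).
    """
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    if design.shape[0] != len(normmat.sample_ids):
        raise ValueError("design rows != number of samples")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("fewer samples than design columns (no residual df)")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if normmat.lib_sizes is None:
        raise ValueError("normalized matrix lacks library sizes; use log_cpm output")
    lib = np.asarray(normmat.lib_sizes, dtype=float)

    sd, fitted = _fit_residual_sd(normmat.values, design)
    sy = np.sqrt(sd)  # quarter-root variance
    sx = normmat.values.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)

    lo = sm.nonparametric.lowess(sy, sx, frac=span, return_sorted=True)
    xs, ys = lo[:, 0], lo[:, 1]
    xs, uniq = np.unique(xs, return_index=True)
    ys = ys[uniq]

    fitted_logcount = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, xs, ys)  # constant extrapolation at ends
    pred = np.maximum(pred, 1e-6)
    weights = pred ** -4
    trend = pd.DataFrame({"mean_logcount": sx, "sqrt_sd": sy})
    return WeightMatrix(weights=weights, trend=trend)


# ---------------------------------------------------------------------------
# batch adjustment (location-scale)


def batch_adjust(normmat: NormalizedMatrix, batches) -> NormalizedMatrix:
    """Location-scale batch adjustment.

    Per gene, each batch is centered to the pooled gene mean and scaled
    to the pooled gene SD. This is a deliberately simple adjustment, not
    an empirical-Bayes batch model: no information is shared across
    genes, so it is best suited to batches with a handful of samples or
    more.
    """
    batches = np.asarray(batches)
    if len(batches) != len(normmat.sample_ids):
        raise ValueError("one batch label per sample required")
    levels = list(dict.fromkeys(batches))
    if len(levels) == 1:
        return NormalizedMatrix(list(normmat.gene_ids), list(normmat.sample_ids),
                                normmat.values.copy(), normmat.norm_factors,
                                normmat.prior_count, normmat.lib_sizes)
    for lev in levels:
        if (batches == lev).sum() < 2:
            raise ValueError(f"singleton batch {lev!r}: cannot estimate scale")
    x = normmat.values
    pooled_mean = x.mean(axis=1, keepdims=True)
    pooled_sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.empty_like(x)
    for lev in levels:
        cols = batches == lev
        bm = x[:, cols].mean(axis=1, keepdims=True)
        bs = x[:, cols].std(axis=1, ddof=1, keepdims=True)
        z = np.where(bs > 0, (x[:, cols] - bm) / np.where(bs > 0, bs, 1.0), 0.0)
        out[:, cols] = z * pooled_sd + pooled_mean
    return NormalizedMatrix(list(normmat.gene_ids), list(normmat.sample_ids), out,
                            normmat.norm_factors, normmat.prior_count, normmat.lib_sizes)


# ---------------------------------------------------------------------------
# PCA


def pca(normmat: NormalizedMatrix, n_components: int):
    """PCA of samples over genes by SVD of the gene-centered matrix.

    Returns ``(scores, loadings, variance_fractions)`` where scores is
    samples x k, loadings genes x k. Sign is fixed so the
    largest-magnitude loading of each component is positive.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    x = normmat.values.T  # samples x genes
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = (s ** 2).sum()
    k = n_components
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, loadings, frac


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersions(counts: CountMatrix) -> tuple[np.ndarray, dict]:
    """Method-of-moments negative-binomial dispersion per gene.

    Counts are rescaled to a common library size; for each gene,
    ``phi_hat = max(0, (s^2 - m) / m^2)``. Returns the per-gene
    estimates and a mean/median summary over genes with positive mean.
    """
    if counts.n_samples < 3:
        raise ValueError("dispersion estimation needs >= 3 samples")
    lib = counts.library_sizes().astype(float)
    if (lib == 0).any():
        raise ValueError("all-zero sample")
    scaled = counts.counts / lib[None, :] * lib.mean()
    m = scaled.mean(axis=1)
    s2 = scaled.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m > 0, np.maximum(0.0, (s2 - m) / m ** 2), 0.0)
    ok = m > 0
    summary = {"mean": float(phi[ok].mean()) if ok.any() else 0.0,
               "median": float(np.median(phi[ok])) if ok.any() else 0.0}
    return phi, summary
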