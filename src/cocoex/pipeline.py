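"""End-to-end orchestration of the coculture analyses.

Three entry points mirror the study's three experiments:

* :func:`run_discovery` — alignment QC, preprocessing, astrocyte
  eigengene (zero baselines for glia-free cultures), human-gene
  association (~ AstroE + ngn2), optional GO-style enrichment, neuron
  eigengene from the positively associated genes, mouse-gene
  association (~ NeuroE), and overlap statistics.
* :func:`run_contact_contrast` — coculture vs sandwich differential
  expression with donor adjustment, and the overlap of contact-induced
  genes with the eigengene-associated set.
* :func:`run_village` — meta-cell aggregation of a pooled single-cell
  village, condition differential expression with donor covariates, and
  the aggregate standardized shift of a supplied gene set.

Each run emits a machine-readable report (config hash, seed, stage
summaries) sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment_qc import alignment_qc_report
from .association import (AssociationTable, adjust_pvalues, aggregate_shift,
                          annotate_significance, bonferroni_threshold,
                          condition_contrast, fit_gene_models, make_design,
                          metacells, moderate_variances)
from .eigengene import (ASTROCYTE_PANEL, MarkerPanel, assign_baseline,
                        build_neuron_eigengene, compute_eigengene)
from .enrichment import ora_hypergeometric, overlap_binomial
from .io_formats import (CountMatrix, GeneSetCollection, SampleTable,
                         read_count_matrix, read_gene_annotation, read_gmt,
                         read_sample_table, write_json)
from .preprocess import (filter_low_expression, log_cpm, precision_weights,
                         sum_replicates, tmm_norm_factors)
from .synthetic_data import SimConfig, simulate_coculture, simulate_village

logger = logging.getLogger("cocoex")

__all__ = ["PipelineConfig", "RunReport", "run_discovery",
           "run_contact_contrast", "run_village"]


@dataclass
class PipelineConfig:
    """Validated configuration of a pipeline run.

    Input paths may be omitted when in-memory data (or a simulation
    config) is supplied instead. Thresholds default to the analysis'
    standard settings: FDR 5%, Bonferroni 5%, 10% alignment-variance
    flag, gene sets of 10-1000 members.
    """

    human_counts: str | None = None
    human_single_counts: str | None = None
    mouse_counts: str | None = None
    sample_table: str | None = None
    annotation: str | None = None
    gene_sets_gmt: str | None = None
    marker_panel: str = "astrocyte"
    min_per_library: float = 10
    min_total: float = 15
    trim_m: float = 0.30
    trim_a: float = 0.05
    prior_count: float = 0.5
    weight_span: float = 0.5
    use_weights: bool = True
    alpha_fdr: float = 0.05
    alpha_bonferroni: float = 0.05
    alignment_threshold: float = 0.10
    set_min_size: int = 10
    set_max_size: int = 1000
    quality_covariates: tuple[str, ...] = ()
    simulate: SimConfig | None = None
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for a in ("alpha_fdr", "alpha_bonferroni"):
            if not (0 < getattr(self, a) < 1):
                raise ValueError(f"{a} must lie in (0, 1)")
        if not (0 <= self.alignment_threshold <= 1):
            raise ValueError("alignment_threshold must lie in [0, 1]")
        if self.set_min_size > self.set_max_size:
            raise ValueError("set_min_size > set_max_size")
        if self.simulate is not None:
            self.simulate.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim:
            base = dataclasses.asdict(SimConfig())
            if "base_expression_log2cpm_range" in sim:
                sim["base_expression_log2cpm_range"] = tuple(sim["base_expression_log2cpm_range"])
            base.update(sim)
            base["base_expression_log2cpm_range"] = tuple(base["base_expression_log2cpm_range"])
            cfg.simulate = SimConfig(**base)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Tables plus a JSON-serializable summary of one pipeline run."""

    kind: str
    summary: dict
    tables: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_json(self.summary, outdir / f"{self.kind}_report.json")
        for name, df in self.tables.items():
            if isinstance(df, pd.Series):
                df = df.to_frame()
            df.to_csv(outdir / f"{self.kind}_{name}.tsv", sep="\t")


# ---------------------------------------------------------------------------
# shared helpers


def _provenance(config: PipelineConfig) -> dict:
    return {"config": config.to_dict(), "config_hash": config.config_hash(),
            "version": __version__, "seed": config.seed}


def _load_discovery_data(config: PipelineConfig, data: dict | None) -> dict:
    if data is None:
        data = {}
    else:
        data = dict(data)
    if "human" not in data:
        if config.simulate is not None:
            human, mouse, table, truth = simulate_coculture(config.simulate)
            data.update(human=human, mouse=mouse, table=table, truth=truth)
        else:
            if config.human_counts is None or config.mouse_counts is None \
                    or config.sample_table is None:
                raise ValueError("need human/mouse count paths and a sample table, "
                                 "or a simulation config, or in-memory data")
            data["human"] = read_count_matrix(config.human_counts, "human", "mixed")
            data["mouse"] = read_count_matrix(config.mouse_counts, "mouse", "mixed")
            data["table"] = read_sample_table(config.sample_table)
    if "human_single" not in data and config.human_single_counts:
        data["human_single"] = read_count_matrix(config.human_single_counts, "human", "single")
    if "annotation" not in data and config.annotation:
        data["annotation"] = read_gene_annotation(config.annotation)
    if "gene_sets" not in data and config.gene_sets_gmt:
        data["gene_sets"] = read_gmt(config.gene_sets_gmt)
    return data


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _preprocess(counts: CountMatrix, table: SampleTable, config: PipelineConfig):
    """Replicate summation, filtering, TMM and log-CPM for one species."""
    table.check_covers(counts)
    groups = table.frame.loc[counts.sample_ids, "replicate_group"]
    if groups.nunique() < len(groups):
        counts, table = sum_replicates(counts, table)
        logger.info("summed replicates: %d libraries", counts.n_samples)
    filtered, report = filter_low_expression(counts, config.min_per_library, config.min_total)
    logger.info("filter: kept %d / %d genes", len(report.kept_gene_ids), counts.n_genes)
    factors = tmm_norm_factors(filtered, config.trim_m, config.trim_a)
    norm = log_cpm(filtered, factors, config.prior_count)
    return filtered, norm, table, report


def _marker_panel(config: PipelineConfig) -> MarkerPanel:
    if config.marker_panel == "astrocyte":
        return ASTROCYTE_PANEL
    return MarkerPanel("custom", tuple(config.marker_panel.split(",")))


def _associate(norm, design: pd.DataFrame, coef: str, config: PipelineConfig,
               use_weights: bool = True) -> AssociationTable:
    weights = None
    if use_weights and config.use_weights:
        weights = precision_weights(norm, design.to_numpy(), config.weight_span)
    tab = fit_gene_models(norm, design, coef, weights)
    tab = moderate_variances(tab)
    return annotate_significance(tab, config.alpha_bonferroni)


def _truth_confusion(detected: set[str], truth_set: set[str], universe: set[str]) -> dict:
    tp = len(detected & truth_set)
    fp = len(detected - truth_set)
    sens = tp / len(truth_set & universe) if truth_set & universe else float("nan")
    fdr = fp / len(detected) if detected else 0.0
    return {"n_detected": len(detected), "sensitivity": sens, "empirical_fdr": fdr}


# ---------------------------------------------------------------------------
# discovery


def run_discovery(config: PipelineConfig, data: dict | None = None) -> RunReport:
    """Full bidirectional discovery analysis; see module docstring."""
    config.validate()
    data = _load_discovery_data(config, data)
    human, mouse, table = data["human"], data["mouse"], data["table"]
    truth = data.get("truth")
    summary = _provenance(config)
    tables: dict = {}

    # --- stage 1: alignment QC (when a single-reference matrix is present)
    if "human_single" in data:
        qc = alignment_qc_report(data["human_single"], human, data.get("annotation"),
                                 config.alignment_threshold)
        summary["alignment_qc"] = qc.to_dict()
        tables["alignment_fractions"] = qc.fractions
        logger.info("alignment QC: %d flagged of %d genes",
                    len(qc.flagged_gene_ids), len(qc.fractions))

    # --- stage 2: preprocessing
    try:
        _, norm_h, table, _ = _preprocess(human, table, config)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[preprocess:human] {err}") from err

    cond = table.frame.loc[norm_h.sample_ids, "condition"]
    cocultures = list(cond.index[cond == "coculture"])
    glia_free = list(cond.index[cond != "coculture"])
    if len(cocultures) < 2:
        raise RuntimeError("[eigengene] need >= 2 coculture samples")

    # --- stage 3: astrocyte eigengene on coculture glia, zero baselines
    try:
        mouse_co = mouse.subset_samples([s for s in mouse.sample_ids if s in set(cocultures)])
        mouse_f, fr = filter_low_expression(mouse_co, config.min_per_library, config.min_total)
        norm_m = log_cpm(mouse_f, tmm_norm_factors(mouse_f, config.trim_m, config.trim_a),
                         config.prior_count)
        astro = compute_eigengene(norm_m, _marker_panel(config))
        astro = assign_baseline(astro, [s for s in glia_free if s not in astro.scores.index], 0.0)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[eigengene:astrocyte] {err}") from err
    summary["astrocyte_eigengene"] = {
        "variance_explained": astro.variance_explained,
        "n_estimated": len(astro.estimated_samples),
        "n_baseline": len(astro.baseline_samples),
    }
    tables["astrocyte_eigengene"] = pd.DataFrame({
        "score": astro.scores,
        "is_baseline": [s in set(astro.baseline_samples) for s in astro.scores.index],
    })

    # --- stage 4: human-gene association ~ AstroE + ngn2
    try:
        astro_scores = astro.scores.loc[norm_h.sample_ids]
        ngn2 = table.ngn2()
        covs = {"AstroE": astro_scores.to_numpy()}
        if ngn2 is not None:
            covs["ngn2"] = _zscore(ngn2.loc[norm_h.sample_ids].to_numpy(dtype=float))
        design = make_design(pd.DataFrame(covs, index=norm_h.sample_ids))
        assoc_h = _associate(norm_h, design, "AstroE", config)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[association:human] {err}") from err

    m_h = len(assoc_h.frame)
    sig = assoc_h.frame["q"] < config.alpha_fdr
    pos = sig & (assoc_h.frame["beta"] > 0)
    neg = sig & (assoc_h.frame["beta"] < 0)
    summary["human_association"] = {
        "n_genes_tested": m_h,
        "n_fdr_significant": int(sig.sum()),
        "n_induced": int(pos.sum()),
        "n_reduced": int(neg.sum()),
        "n_bonferroni": int(assoc_h.frame["bonferroni_significant"].sum()),
        "bonferroni_threshold": bonferroni_threshold(m_h, config.alpha_bonferroni),
        "d0": assoc_h.d0, "s0_2": assoc_h.s0_2,
    }
    tables["human_association"] = assoc_h.frame
    logger.info("human association: %d/%d FDR-significant", int(sig.sum()), m_h)

    if truth is not None:
        detected = set(assoc_h.frame.index[pos])
        summary["human_association"]["truth"] = _truth_confusion(
            detected, set(truth.responsive_gene_ids), set(assoc_h.frame.index))

    # --- stage 5: enrichment of the induced set (optional)
    induced = list(assoc_h.frame.index[pos])
    if "gene_sets" in data and induced:
        coll = data["gene_sets"]
        coll = GeneSetCollection(coll.sets, set(assoc_h.frame.index))
        try:
            enr = ora_hypergeometric(induced, coll, config.set_min_size, config.set_max_size)
            tables["enrichment"] = enr
            summary["enrichment"] = {"n_sets_tested": len(enr),
                                     "n_sets_q_lt_05": int((enr["q"] < 0.05).sum())}
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"[enrichment] {err}") from err

    # --- stage 6: neuron eigengene and mouse-gene association ~ NeuroE
    summary["mouse_association"] = None
    if len(induced) >= 2:
        try:
            norm_h_co = norm_h.subset_samples(cocultures)
            neuro = build_neuron_eigengene(norm_h_co, induced)
            design_m = make_design(pd.DataFrame(
                {"NeuroE": neuro.scores.loc[norm_m.sample_ids].to_numpy()},
                index=norm_m.sample_ids))
            assoc_m = _associate(norm_m, design_m, "NeuroE", config)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"[association:mouse] {err}") from err
        m_m = len(assoc_m.frame)
        sig_m = assoc_m.frame["q"] < config.alpha_fdr
        pos_m = sig_m & (assoc_m.frame["beta"] > 0)
        summary["neuron_eigengene"] = {"variance_explained": neuro.variance_explained,
                                       "n_genes": len(neuro.loadings)}
        summary["mouse_association"] = {
            "n_genes_tested": m_m,
            "n_fdr_significant": int(sig_m.sum()),
            "n_positive": int(pos_m.sum()),
            "n_negative": int((sig_m & (assoc_m.frame["beta"] < 0)).sum()),
            "n_bonferroni": int(assoc_m.frame["bonferroni_significant"].sum()),
            "bonferroni_threshold": bonferroni_threshold(m_m, config.alpha_bonferroni),
        }
        tables["mouse_association"] = assoc_m.frame
        tables["neuron_eigengene"] = neuro.scores.to_frame()

        if truth is not None and len(truth.mouse_responsive_gene_ids):
            detected_m = set(assoc_m.frame.index[pos_m])
            truth_m = set(truth.mouse_responsive_gene_ids)
            summary["mouse_association"]["truth"] = _truth_confusion(
                detected_m, truth_m, set(assoc_m.frame.index))
            # overlap of the detected mouse set with the known responsive set
            k = len(detected_m & truth_m)
            n = len(detected_m)
            p0 = len(truth_m & set(assoc_m.frame.index)) / m_m
            if n and 0 < p0 < 1:
                ov = overlap_binomial(k, n, p0)
                summary["mouse_association"]["overlap_with_truth"] = {
                    "k": k, "n": n, "p0": p0, "fold": ov.fold, "p": ov.p}

    report = RunReport("discovery", summary, tables)
    if config.outdir:
        report.write(config.outdir)
    return report


# ---------------------------------------------------------------------------
# contact contrast


def run_contact_contrast(config: PipelineConfig, data: dict | None = None) -> RunReport:
    """Coculture vs sandwich contrast plus overlap with eigengene-associated genes."""
    config.validate()
    data = _load_discovery_data(config, data)
    human, table = data["human"], data["table"]
    summary = _provenance(config)
    tables: dict = {}

    _, norm_h, table, _ = _preprocess(human, table, config)
    cond = table.frame.loc[norm_h.sample_ids, "condition"]
    for lev in ("coculture", "sandwich"):
        if (cond == lev).sum() < 2:
            raise RuntimeError(f"[contact] need >= 2 {lev} samples")
    keep = cond.isin(["coculture", "sandwich"])
    sub = norm_h.subset_samples(list(cond.index[keep]))
    cond_sub = cond[keep]

    # donor adjustment as fixed indicators; optional quality covariates
    meta = table.frame.loc[sub.sample_ids]
    cov = pd.get_dummies(meta["donor"], prefix="donor", drop_first=True).astype(float)
    for qc_col in config.quality_covariates:
        if qc_col in meta.columns and meta[qc_col].std() > 0:
            cov[qc_col] = _zscore(meta[qc_col].to_numpy(dtype=float))
    cov = cov.loc[:, cov.std() > 0] if len(cov.columns) else cov
    try:
        contrast = condition_contrast(sub, cond_sub, cov if len(cov.columns) else None,
                                      levels=("sandwich", "coculture"))
        contrast = moderate_variances(contrast)
        contrast = annotate_significance(contrast, config.alpha_bonferroni)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[contact:contrast] {err}") from err
    tables["contact_contrast"] = contrast.frame

    induced_contact = set(contrast.frame.index[(contrast.frame["q"] < config.alpha_fdr)
                                               & (contrast.frame["beta"] > 0)])
    summary["contact_contrast"] = {
        "n_genes_tested": len(contrast.frame),
        "n_induced_coculture": len(induced_contact),
        "n_reduced_coculture": int(((contrast.frame["q"] < config.alpha_fdr)
                                    & (contrast.frame["beta"] < 0)).sum()),
    }

    associated = data.get("associated_gene_ids")
    if associated is None and data.get("truth") is not None:
        associated = data["truth"].responsive_gene_ids
    if associated:
        detected_assoc = set(associated) & set(contrast.frame.index)
        k = len(induced_contact & detected_assoc)
        n = len(detected_assoc)
        p0 = len(induced_contact) / len(contrast.frame)
        if n and 0 < p0 < 1:
            ov = overlap_binomial(k, n, p0)
            summary["contact_overlap"] = {"k": k, "n": n, "p0": p0,
                                          "fold": ov.fold, "p": ov.p}

    report = RunReport("contact", summary, tables)
    if config.outdir:
        report.write(config.outdir)
    return report


# ---------------------------------------------------------------------------
# village


def run_village(config: PipelineConfig, data: dict | None = None,
                gene_set=None) -> RunReport:
    """Meta-cell DE of a pooled village plus the aggregate shift of a gene set."""
    config.validate()
    if data is None:
        if config.simulate is None:
            raise ValueError("run_village needs in-memory data or a simulation config")
        cells, meta, truth = simulate_village(config.simulate)
        data = {"cells": cells, "meta": meta, "truth": truth}
    cells, meta = data["cells"], data["meta"]
    truth = data.get("truth")
    summary = _provenance(config)
    tables: dict = {}

    mc = metacells(cells, meta["donor"], meta["condition"],
                   meta["sex"] if "sex" in meta.columns else None)
    summary["metacells"] = {"n_metacells": mc.counts.n_samples,
                            "n_cells_total": int(mc.meta["n_cells"].sum())}

    filtered, _ = filter_low_expression(mc.counts, config.min_per_library, config.min_total)
    norm = log_cpm(filtered, tmm_norm_factors(filtered, config.trim_m, config.trim_a),
                   config.prior_count)
    cond = mc.meta.loc[norm.sample_ids, "condition"]

    cov = pd.get_dummies(mc.meta.loc[norm.sample_ids, "donor"],
                         prefix="donor", drop_first=True).astype(float)
    for extra in ("mean_umi", "n_cells"):
        v = mc.meta.loc[norm.sample_ids, extra].to_numpy(dtype=float)
        if v.std() > 0:
            cov[extra] = _zscore(v)
    try:
        de = condition_contrast(norm, cond, cov if len(cov.columns) else None,
                                levels=("monoculture", "coculture"))
        de = moderate_variances(de)
        de = annotate_significance(de, config.alpha_bonferroni)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[village:DE] {err}") from err
    tables["village_de"] = de.frame
    sig = de.frame["q"] < config.alpha_fdr
    summary["village_de"] = {"n_genes_tested": len(de.frame),
                             "n_fdr_significant": int(sig.sum()),
                             "n_induced": int((sig & (de.frame["beta"] > 0)).sum())}

    if gene_set is None and truth is not None:
        gene_set = truth.responsive_gene_ids
    if gene_set:
        shift = aggregate_shift(norm, gene_set, cond, levels=("monoculture", "coculture"))
        summary["aggregate_shift"] = {"estimate": shift.estimate,
                                      "ci": [shift.ci_low, shift.ci_high],
                                      "p": shift.p, "n_genes": shift.n}

    report = RunReport("village", summary, tables)
    if config.outdir:
        report.write(config.outdir)
    return report
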