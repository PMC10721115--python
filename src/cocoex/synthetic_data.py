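"""Synthetic two-species coculture data with known ground truth.

The generator emulates the statistical structure of a bulk RNA-seq
experiment in which human neurons are grown on a monolayer of mouse glia:

* each coculture sample carries a latent astrocyte-abundance factor
  ``a_s`` that loads on a small panel of astrocyte marker genes in the
  mouse fraction;
* a subset of human (neuronal) genes responds linearly, on the log2
  scale, to ``a_s`` and to a per-sample Ngn2 transgene covariate;
* a subset of mouse (glial) genes responds linearly to the same latent
  factor, standing in for glial genes whose expression tracks neuronal
  maturation;
* monoculture samples have the factor fixed at exactly zero and no
  mouse reads; sandwich (membrane-separated) samples receive an
  independent soluble-exposure factor and lack the contact bonus that
  coculture responsive genes get;
* counts are negative-binomial via a Gamma-Poisson mixture.

A paired "mixed-reference" matrix can be derived from any human matrix:
every library loses a small fraction of reads to cross-species
ambiguity (binomial thinning) and a designated set of cross-mapping
genes additionally loses a random per-sample fraction of its reads,
mimicking alignment-sensitive genes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SampleTable

__all__ = ["SimConfig", "SimTruth", "simulate_coculture", "simulate_dual_alignment",
           "simulate_village", "simulate_null", "ASTROCYTE_MARKERS"]

ASTROCYTE_MARKERS = ("Aldh1l1", "Slc1a3", "Slc1a2", "Gfap", "Notch1", "S100b")


@dataclass
class SimConfig:
    """Parameters of the synthetic coculture experiment.

    Defaults mirror the design of the study being emulated: 28 cocultures
    plus 4 glia-free monocultures, a 6-gene astrocyte marker panel, and
    bulk libraries of a few million reads. ``factor_sd`` is the standard
    deviation of the latent astrocyte-abundance factor across coculture
    samples (unit variance by default; the factor's absolute scale is not
    identifiable from an eigengene anyway). ``beta_mean``/``beta_sd``
    give the per-gene log2 slope of responsive human genes on the factor.
    ``nb_dispersion`` is the negative-binomial dispersion (var = mu +
    phi*mu^2); ``count_noise="none"`` switches counts to deterministic
    rounding of the expected values for exactness tests.
    """

    n_coculture: int = 28
    n_monoculture: int = 4
    n_sandwich: int = 0
    n_human_genes: int = 2000
    n_mouse_genes: int = 1500
    n_marker_genes: int = 6
    n_responsive_genes: int = 100
    n_mouse_responsive_genes: int = 50
    factor_mean: float = 2.0
    factor_sd: float = 1.0
    beta_mean: float = 1.0
    beta_sd: float = 0.3
    ngn2_effect_sd: float = 0.3
    nb_dispersion: float = 0.1
    base_expression_log2cpm_range: tuple[float, float] = (1.0, 8.0)
    marker_base_log2cpm: float = 8.0
    marker_loading_mean: float = 2.0
    marker_loading_sd: float = 0.2
    library_size_mean: int = 5_000_000
    library_size_cv: float = 0.1
    crossmap_fraction: float = 0.02
    crossmap_loss: float = 0.5
    library_shrink: float = 0.039
    contact_effect_log2: float = 0.5
    count_noise: str = "nb"  # "nb" (phi=0 -> Poisson) or "none" (round means)
    # cell-village parameters
    n_donors: int = 8
    cells_per_donor: int = 40
    umi_per_cell_mean: int = 2000
    village_effect_log2: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_coculture", "n_human_genes", "n_mouse_genes",
                     "n_marker_genes", "library_size_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_monoculture", "n_sandwich", "n_responsive_genes",
                     "n_mouse_responsive_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_responsive_genes > 0 and self.factor_sd <= 0 and self.count_noise != "none":
            raise ValueError("factor_sd must be > 0 when responsive genes are requested")
        if self.factor_sd < 0:
            raise ValueError("factor_sd must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not (0 <= self.crossmap_fraction < 1):
            raise ValueError("crossmap_fraction must be in [0, 1)")
        if not (0 <= self.crossmap_loss < 1):
            raise ValueError("crossmap_loss must be in [0, 1)")
        if not (0 <= self.library_shrink < 1):
            raise ValueError("library_shrink must be in [0, 1)")
        if self.n_responsive_genes > self.n_human_genes:
            raise ValueError("more responsive genes than human genes")
        if self.count_noise not in ("nb", "none"):
            raise ValueError("count_noise must be 'nb' or 'none'")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Ground-truth record accompanying a simulated dataset."""

    factor_values: pd.Series            # latent factor per sample (0 for monoculture)
    ngn2_values: pd.Series
    responsive_gene_ids: list[str]
    true_betas: pd.Series               # log2 slope on factor, responsive human genes
    marker_loadings: pd.Series
    crossmap_gene_ids: list[str] = field(default_factory=list)
    mouse_responsive_gene_ids: list[str] = field(default_factory=list)
    mouse_true_betas: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def to_json(self, path: str | Path) -> None:
        obj = {
            "factor_values": self.factor_values.to_dict(),
            "ngn2_values": self.ngn2_values.to_dict(),
            "responsive_gene_ids": list(self.responsive_gene_ids),
            "true_betas": self.true_betas.to_dict(),
            "marker_loadings": self.marker_loadings.to_dict(),
            "crossmap_gene_ids": list(self.crossmap_gene_ids),
            "mouse_responsive_gene_ids": list(self.mouse_responsive_gene_ids),
            "mouse_true_betas": self.mouse_true_betas.to_dict(),
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            factor_values=pd.Series(obj["factor_values"], dtype=float),
            ngn2_values=pd.Series(obj["ngn2_values"], dtype=float),
            responsive_gene_ids=obj["responsive_gene_ids"],
            true_betas=pd.Series(obj["true_betas"], dtype=float),
            marker_loadings=pd.Series(obj["marker_loadings"], dtype=float),
            crossmap_gene_ids=obj["crossmap_gene_ids"],
            mouse_responsive_gene_ids=obj["mouse_responsive_gene_ids"],
            mouse_true_betas=pd.Series(obj["mouse_true_betas"], dtype=float),
        )


# ---------------------------------------------------------------------------
# count sampling


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float,
                 noise: str) -> np.ndarray:
    """Negative-binomial counts via a Gamma-Poisson mixture.

    phi = 0 degenerates to Poisson; noise = "none" returns rounded means.
    """
    if noise == "none":
        return np.rint(mu).astype(np.int64)
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * np.maximum(mu, 1e-300))
    else:
        lam = mu
    return rng.poisson(lam).astype(np.int64)


def _library_sizes(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    if cfg.count_noise == "none" or cfg.library_size_cv == 0:
        return np.full(n, float(cfg.library_size_mean))
    sizes = rng.normal(cfg.library_size_mean, cfg.library_size_cv * cfg.library_size_mean, n)
    return np.maximum(sizes, 0.1 * cfg.library_size_mean)


def _expected_from_log2cpm(log2cpm: np.ndarray, libsizes: np.ndarray) -> np.ndarray:
    return (2.0 ** log2cpm) / 1e6 * libsizes[None, :]


# ---------------------------------------------------------------------------
# main generators


def simulate_coculture(config: SimConfig) -> tuple[CountMatrix, CountMatrix, SampleTable, SimTruth]:
    """Simulate paired human (neuron) and mouse (glia) count matrices.

    Returns the human matrix, the mouse matrix, the sample table and the
    ground-truth record. Sample order: cocultures, monocultures,
    sandwich cultures. The mouse matrix has zero counts for monoculture
    and sandwich samples (no glia in the sequenced fraction).
    """
    return _simulate_bulk(config, null=False)


def simulate_null(config: SimConfig) -> tuple[CountMatrix, CountMatrix, SampleTable, SimTruth]:
    """As :func:`simulate_coculture` but with every responsive slope set to zero.

    The truth record lists an empty responsive set; used for type-I
    error calibration of the association stage.
    """
    return _simulate_bulk(config, null=True)


def _simulate_bulk(config: SimConfig, null: bool):
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_co, n_mono, n_sand = config.n_coculture, config.n_monoculture, config.n_sandwich
    n_samples = n_co + n_mono + n_sand
    sample_ids = (
        [f"co{i+1:02d}" for i in range(n_co)]
        + [f"mono{i+1:02d}" for i in range(n_mono)]
        + [f"sand{i+1:02d}" for i in range(n_sand)]
    )
    conditions = ["coculture"] * n_co + ["monoculture"] * n_mono + ["sandwich"] * n_sand

    # latent factor: astrocyte abundance for cocultures, soluble exposure
    # for sandwich cultures, exactly zero for glia-free monocultures
    a = np.zeros(n_samples)
    a[:n_co] = rng.normal(config.factor_mean, config.factor_sd, n_co)
    if n_sand:
        a[n_co + n_mono:] = rng.normal(config.factor_mean, config.factor_sd, n_sand)
    # sandwich cultures see soluble factors but lack physical contact:
    # responsive genes run a contact_effect_log2 deficit there
    no_contact = np.zeros(n_samples)
    no_contact[n_co + n_mono:] = 1.0

    ngn2 = rng.normal(0.0, 1.0, n_samples)

    # --- human (neuronal) genes -------------------------------------------
    hgenes = [f"hs:G{i+1:05d}" for i in range(config.n_human_genes)]
    lo, hi = config.base_expression_log2cpm_range
    base_h = rng.uniform(lo, hi, config.n_human_genes)
    resp_idx = rng.choice(config.n_human_genes, config.n_responsive_genes, replace=False)
    resp_idx.sort()
    betas = rng.normal(config.beta_mean, config.beta_sd, config.n_responsive_genes)
    gammas = rng.normal(0.0, config.ngn2_effect_sd, config.n_responsive_genes)
    if null:
        betas = np.zeros_like(betas)
        gammas = np.zeros_like(gammas)

    log2cpm_h = np.tile(base_h[:, None], (1, n_samples))
    log2cpm_h[resp_idx, :] += (
        betas[:, None] * a[None, :]
        + gammas[:, None] * ngn2[None, :]
        - (0.0 if null else config.contact_effect_log2) * no_contact[None, :]
    )
    lib_h = _library_sizes(rng, n_samples, config)
    mu_h = _expected_from_log2cpm(log2cpm_h, lib_h)
    counts_h = _draw_counts(rng, mu_h, config.nb_dispersion, config.count_noise)
    human = CountMatrix(hgenes, sample_ids, counts_h, species="human", alignment_ref="mixed")

    # --- mouse (glial) genes ----------------------------------------------
    n_markers = config.n_marker_genes
    marker_ids = [f"mm:{ASTROCYTE_MARKERS[i]}" if i < len(ASTROCYTE_MARKERS)
                  else f"mm:Marker{i+1}" for i in range(n_markers)]
    other_ids = [f"mm:G{i+1:05d}" for i in range(config.n_mouse_genes - n_markers)]
    mgenes = marker_ids + other_ids
    loadings = rng.normal(config.marker_loading_mean, config.marker_loading_sd, n_markers)
    base_m = rng.uniform(lo, hi, len(other_ids))
    m_resp_n = min(config.n_mouse_responsive_genes, len(other_ids))
    m_resp_idx = rng.choice(len(other_ids), m_resp_n, replace=False)
    m_resp_idx.sort()
    m_betas = rng.normal(config.beta_mean, config.beta_sd, m_resp_n)
    if null:
        m_betas = np.zeros_like(m_betas)

    # intercept chosen so markers sit at marker_base_log2cpm at the mean factor
    log2cpm_m = np.empty((len(mgenes), n_samples))
    log2cpm_m[:n_markers, :] = (
        config.marker_base_log2cpm
        + loadings[:, None] * (a[None, :] - config.factor_mean)
    )
    log2cpm_m[n_markers:, :] = base_m[:, None]
    log2cpm_m[n_markers + m_resp_idx, :] += m_betas[:, None] * (a[None, :] - config.factor_mean)
    lib_m = _library_sizes(rng, n_samples, config)
    mu_m = _expected_from_log2cpm(log2cpm_m, lib_m)
    counts_m = _draw_counts(rng, mu_m, config.nb_dispersion, config.count_noise)
    # glia absent from monoculture and sandwich neuronal fractions
    glia_absent = np.array([c != "coculture" for c in conditions])
    counts_m[:, glia_absent] = 0
    mouse = CountMatrix(mgenes, sample_ids, counts_m, species="mouse", alignment_ref="mixed")

    donors = [f"donor{(i % 4) + 1}" for i in range(n_samples)]
    table = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "condition": conditions,
        "donor": donors,
        "replicate_group": sample_ids,  # one library per group by default
        "batch": ["b1"] * n_samples,
        "timepoint": ["day28"] * n_samples,
        "ngn2": ngn2,
    }))

    resp_ids = [hgenes[i] for i in resp_idx]
    truth = SimTruth(
        factor_values=pd.Series(a, index=sample_ids),
        ngn2_values=pd.Series(ngn2, index=sample_ids),
        responsive_gene_ids=[] if null else resp_ids,
        true_betas=pd.Series(betas, index=resp_ids),
        marker_loadings=pd.Series(loadings, index=marker_ids),
        mouse_responsive_gene_ids=[] if null else [other_ids[i] for i in m_resp_idx],
        mouse_true_betas=pd.Series(m_betas, index=[other_ids[i] for i in m_resp_idx]),
    )
    return human, mouse, table, truth


def simulate_dual_alignment(human: CountMatrix, config: SimConfig) -> CountMatrix:
    """Derive a "mixed-reference" matrix from a single-reference human matrix.

    All libraries are binomially thinned by ``library_shrink`` (reads
    lost to cross-species ambiguity); genes in the cross-mapping set are
    additionally thinned by a per-sample uniform loss up to
    ``crossmap_loss``. The cross-mapping gene set is chosen from the
    matrix's genes with a seed derived from ``config.seed``, and is
    recorded on the returned matrix as ``crossmap_gene_ids``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    counts = human.counts
    n_genes, n_samples = counts.shape
    n_cross = int(round(config.crossmap_fraction * n_genes))
    cross_idx = np.sort(rng.choice(n_genes, n_cross, replace=False)) if n_cross else np.array([], dtype=int)

    keep = np.full(counts.shape, 1.0 - config.library_shrink)
    if n_cross:
        loss = rng.uniform(0.0, config.crossmap_loss, size=(n_cross, n_samples))
        keep[cross_idx, :] *= 1.0 - loss
    if config.library_shrink == 0 and n_cross == 0:
        out = counts.copy()
    else:
        out = rng.binomial(counts, keep)
    mixed = CountMatrix(list(human.gene_ids), list(human.sample_ids), out,
                        species=human.species, alignment_ref="mixed")
    mixed.crossmap_gene_ids = [human.gene_ids[i] for i in cross_idx]  # type: ignore[attr-defined]
    return mixed


def simulate_village(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Simulate a pooled "cell village" single-cell UMI experiment.

    Every donor contributes ``cells_per_donor`` cells to each of two
    conditions (neuron monoculture and glia coculture); responsive genes
    carry a ``village_effect_log2`` shift in coculture. Returns a
    gene x cell UMI count matrix, a cell metadata table (cell_id, donor,
    condition, sex) and the truth record.
    """
    config.validate()
    if config.n_donors < 2:
        raise ValueError("village needs >= 2 donors")
    rng = np.random.default_rng(config.seed + 2_000_003)
    genes = [f"hs:G{i+1:05d}" for i in range(config.n_human_genes)]
    lo, hi = config.base_expression_log2cpm_range
    base = rng.uniform(lo, hi, config.n_human_genes)
    resp_idx = np.sort(rng.choice(config.n_human_genes, config.n_responsive_genes, replace=False))

    conditions = ("monoculture", "coculture")
    cell_ids, cell_donor, cell_cond = [], [], []
    for cond in conditions:
        for d in range(config.n_donors):
            for c in range(config.cells_per_donor):
                cell_ids.append(f"{cond[:4]}_d{d+1:02d}_c{c+1:03d}")
                cell_donor.append(f"donor{d+1:02d}")
                cell_cond.append(cond)
    n_cells = len(cell_ids)

    log2cpm = np.tile(base[:, None], (1, n_cells))
    in_co = np.array([c == "coculture" for c in cell_cond], dtype=float)
    log2cpm[resp_idx, :] += config.village_effect_log2 * in_co[None, :]

    umi_totals = np.maximum(
        rng.normal(config.umi_per_cell_mean, 0.2 * config.umi_per_cell_mean, n_cells),
        0.2 * config.umi_per_cell_mean,
    )
    mu = _expected_from_log2cpm(log2cpm, umi_totals)
    # renormalize so expected per-cell totals hit the drawn UMI depths
    mu *= umi_totals[None, :] / mu.sum(axis=0)
    counts = _draw_counts(rng, mu, config.nb_dispersion, config.count_noise)
    cm = CountMatrix(genes, cell_ids, counts, species="human", alignment_ref="mixed")

    sexes = {f"donor{d+1:02d}": ("F" if d % 2 else "M") for d in range(config.n_donors)}
    meta = pd.DataFrame({
        "cell_id": cell_ids,
        "donor": cell_donor,
        "condition": cell_cond,
        "sex": [sexes[d] for d in cell_donor],
    }).set_index("cell_id")

    resp_ids = [genes[i] for i in resp_idx]
    truth = SimTruth(
        factor_values=pd.Series(in_co, index=cell_ids),
        ngn2_values=pd.Series(np.zeros(n_cells), index=cell_ids),
        responsive_gene_ids=resp_ids if config.village_effect_log2 != 0 else [],
        true_betas=pd.Series(np.full(len(resp_ids), config.village_effect_log2), index=resp_ids),
        marker_loadings=pd.Series(dtype=float),
    )
    return cm, meta, truth
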