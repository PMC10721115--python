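"""Marker-panel eigengenes by singular value decomposition.

An eigengene condenses the coordinated expression of a gene panel into
one number per sample: the first right singular vector of the
(row-standardized) marker x sample expression submatrix. For the
astrocyte panel (Aldh1l1, Slc1a3, Slc1a2, Gfap, Notch1, S100b, measured
in the mouse glial fraction of each coculture) the eigengene serves as
a per-culture proxy for relative astrocyte abundance/state. Samples
without glia can be given an assigned baseline score (zero) or an
extrapolated score obtained by projecting their marker values onto the
fitted loadings. The same machinery builds a "neuron eigengene" over a
large set of astrocyte-responsive neuronal genes.

Orientation is fixed so the eigengene correlates positively with the
mean standardized expression of the panel (high score = high marker
expression); with this convention, higher astrocyte eigengene means
more astrocyte signal. When the leading singular values tie exactly the
component is not identifiable; the decomposition then simply returns
numpy's deterministic SVD output, sign-fixed as above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

__all__ = ["MarkerPanel", "Eigengene", "ASTROCYTE_PANEL", "compute_eigengene",
           "assign_baseline", "extrapolate_baseline", "build_neuron_eigengene"]


@dataclass(frozen=True)
class MarkerPanel:
    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.gene_ids) < 1:
            raise ValueError("marker panel needs at least one gene")


ASTROCYTE_PANEL = MarkerPanel(
    "astrocyte", ("Aldh1l1", "Slc1a3", "Slc1a2", "Gfap", "Notch1", "S100b"))


@dataclass
class Eigengene:
    """First-singular-vector summary of a marker panel.

    ``scores`` holds the per-sample eigengene values (unit L2 norm over
    the estimated samples, before any baseline assignment); ``loadings``
    the per-marker weights (first left singular vector);
    ``variance_explained`` is d1^2 / sum(d_k^2).
    """

    panel: MarkerPanel
    scores: pd.Series
    loadings: pd.Series
    singular_values: np.ndarray
    variance_explained: float
    sign_anchor: str
    standardize: str
    row_centers: pd.Series = field(repr=False, default=None)
    row_scales: pd.Series = field(repr=False, default=None)
    baseline_samples: list[str] = field(default_factory=list)

    @property
    def estimated_samples(self) -> list[str]:
        base = set(self.baseline_samples)
        return [s for s in self.scores.index if s not in base]


def _resolve_markers(gene_ids: list[str], panel_genes) -> tuple[list[str], list[str]]:
    """Match panel genes to matrix gene ids, tolerating species prefixes like ``mm:``."""
    index = set(gene_ids)
    suffix = {}
    for g in gene_ids:
        if ":" in g:
            suffix.setdefault(g.split(":", 1)[1], g)
    found, missing = [], []
    for m in panel_genes:
        if m in index:
            found.append(m)
        elif m in suffix:
            found.append(suffix[m])
        else:
            missing.append(m)
    return found, missing


def compute_eigengene(normmat: NormalizedMatrix, panel: MarkerPanel,
                      standardize: str = "center_scale") -> Eigengene:
    """SVD eigengene of a marker panel over the samples of ``normmat``.

    ``standardize`` is ``"center"`` (row-center marker log-expression) or
    ``"center_scale"`` (additionally scale rows to unit SD; the default,
    so every marker contributes on equal footing).
    """
    if standardize not in ("center", "center_scale"):
        raise ValueError("standardize must be 'center' or 'center_scale'")
    if len(normmat.sample_ids) < 2:
        raise ValueError("eigengene needs >= 2 samples")
    rows, missing = _resolve_markers(normmat.gene_ids, panel.gene_ids)
    if missing:
        raise KeyError(f"marker gene(s) missing from matrix: {missing}")
    sub = normmat.subset_genes(rows)
    x = sub.values.astype(float)
    centers = x.mean(axis=1)
    xs = x - centers[:, None]
    if standardize == "center_scale":
        scales = x.std(axis=1, ddof=1)
        zero = scales == 0
        if zero.any():
            bad = [rows[i] for i in np.flatnonzero(zero)]
            raise ValueError(f"zero-variance marker row(s) under center_scale: {bad}")
        xs = xs / scales[:, None]
    else:
        scales = np.ones_like(centers)

    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    scores = vt[0]
    loadings = u[:, 0]
    total = (s ** 2).sum()
    var_explained = float(s[0] ** 2 / total) if total > 0 else 0.0

    anchor = xs.mean(axis=0)  # column mean of the standardized marker block
    r = float(np.dot(scores - scores.mean(), anchor - anchor.mean()))
    if r < 0:
        scores = -scores
        loadings = -loadings

    return Eigengene(
        panel=panel,
        scores=pd.Series(scores, index=sub.sample_ids, name=f"{panel.name}_eigengene"),
        loadings=pd.Series(loadings, index=rows),
        singular_values=s,
        variance_explained=var_explained,
        sign_anchor="positive r with panel mean",
        standardize=standardize,
        row_centers=pd.Series(centers, index=rows),
        row_scales=pd.Series(scales, index=rows),
    )


def assign_baseline(eig: Eigengene, baseline_ids, value: float = 0.0) -> Eigengene:
    """Extend the eigengene with an assigned constant score for glia-free samples."""
    baseline_ids = list(baseline_ids)
    overlap = set(baseline_ids) & set(eig.scores.index)
    if overlap:
        raise ValueError(f"baseline samples already have estimated scores: {sorted(overlap)[:5]}")
    extra = pd.Series(value, index=baseline_ids, dtype=float)
    scores = pd.concat([eig.scores, extra])
    scores.name = eig.scores.name
    return replace(eig, scores=scores,
                   baseline_samples=list(eig.baseline_samples) + baseline_ids)


def extrapolate_baseline(eig: Eigengene, normmat: NormalizedMatrix,
                         baseline_ids) -> pd.Series:
    """Project glia-free samples' marker values onto the fitted loadings.

    score = u' @ ((x - row_centers) / row_scales) / d1, using centers,
    scales and loadings fitted on the estimated samples. For a column
    identical to an estimated sample's this reproduces that sample's
    score exactly; a column at the row centers scores 0.
    """
    baseline_ids = list(baseline_ids)
    rows = list(eig.loadings.index)
    sub = normmat.subset_genes(rows).subset_samples(baseline_ids)
    x = sub.values
    xs = (x - eig.row_centers.to_numpy()[:, None]) / eig.row_scales.to_numpy()[:, None]
    d1 = eig.singular_values[0]
    if d1 == 0:
        raise ValueError("degenerate eigengene (zero leading singular value)")
    scores = eig.loadings.to_numpy() @ xs / d1
    return pd.Series(scores, index=baseline_ids, name=f"{eig.panel.name}_extrapolated")


def build_neuron_eigengene(normmat_human: NormalizedMatrix,
                           gene_ids, standardize: str = "center_scale") -> Eigengene:
    """Eigengene over a (large) induced neuronal gene set.

    ``gene_ids`` is typically the set of human genes positively
    associated with the astrocyte eigengene; the resulting score is a
    per-sample neuronal maturation proxy.
    """
    present = [g for g in gene_ids if g in set(normmat_human.gene_ids)]
    if len(present) < 2:
        raise ValueError("need >= 2 induced genes present in the matrix")
    panel = MarkerPanel("neuron", tuple(present))
    return compute_eigengene(normmat_human, panel, standardize=standardize)
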