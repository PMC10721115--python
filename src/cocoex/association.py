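"""Per-gene linear-model inference and aggregate contrast statistics.

The workhorse is :func:`fit_gene_models`: every gene's normalized
expression is regressed on a shared design matrix (optionally with
per-observation precision weights), giving a coefficient, standard
error, ordinary t and p per gene. :func:`moderate_variances` then
shrinks the residual variances toward a pooled prior via the standard
empirical-Bayes closed forms — the prior degrees of freedom ``d0`` and
prior variance ``s0^2`` are obtained by moment matching on the log
residual variances using digamma/trigamma inversion, the moderated
variance is the ``d``-weighted average of gene and prior variance, and
the moderated t gains ``d0`` degrees of freedom.

Also here: BH / Bonferroni multiplicity control, per-covariate variance
fractions, condition contrasts, per-donor meta-cell aggregation of
single-cell UMIs, and the aggregate/marker-class shift statistics used
to compare expression of a gene class between culture conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import CountMatrix
from .preprocess import NormalizedMatrix, WeightMatrix

__all__ = [
    "AssociationTable", "MetaCellMatrix", "ShiftResult",
    "make_design", "fit_gene_models", "moderate_variances", "adjust_pvalues",
    "annotate_significance", "estimate_variance_prior",
    "bonferroni_threshold", "variance_fractions", "condition_contrast",
    "metacells", "aggregate_shift", "marker_class_shift", "marker_class_contrast",
]


@dataclass
class AssociationTable:
    """Per-gene association results for one coefficient of a shared design.

    ``frame`` has one row per gene: beta, se, t, df, p and, after
    moderation / adjustment, t_mod, df_mod, p_mod, q,
    bonferroni_significant. ``sigma2``/``stdev_unscaled`` carry what
    variance moderation needs; ``d0``/``s0_2`` are filled in by
    :func:`moderate_variances`.
    """

    frame: pd.DataFrame
    coef: str
    residual_df: float
    sigma2: pd.Series = field(repr=False, default=None)
    stdev_unscaled: pd.Series = field(repr=False, default=None)
    d0: float | None = None
    s0_2: float | None = None

    @property
    def p(self) -> pd.Series:
        return self.frame["p_mod"] if "p_mod" in self.frame.columns else self.frame["p"]


@dataclass
class MetaCellMatrix:
    """Per-(donor, condition) UMI sums with the covariates the DE design uses."""

    counts: CountMatrix          # genes x metacells
    meta: pd.DataFrame           # index metacell id; donor, condition, n_cells, mean_umi, sex


@dataclass
class ShiftResult:
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# design construction


def make_design(covariates: pd.DataFrame | dict, intercept: bool = True) -> pd.DataFrame:
    """Assemble a design matrix from named per-sample covariates."""
    df = pd.DataFrame(covariates).astype(float)
    if intercept:
        df.insert(0, "Intercept", 1.0)
    return df


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("more design columns than residual degrees of freedom allow")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = []
        for j, name in enumerate(design.columns):
            others = np.delete(x, j, axis=1)
            coef, res, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
            resid = x[:, j] - others @ coef
            if np.abs(resid).max() < 1e-10:
                bad.append(name)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# per-gene (weighted) least squares


def fit_gene_models(normmat: NormalizedMatrix, design: pd.DataFrame,
                    coef: str, weights: WeightMatrix | None = None) -> AssociationTable:
    """Gene-wise (weighted) least squares for one coefficient of interest.

    Parameters
    ----------
    design
        samples x covariates data frame; must include the column ``coef``.
    weights
        Optional precision weights (genes x samples), e.g. from
        :func:`cocoex.preprocess.precision_weights`.
    """
    if coef not in design.columns:
        raise KeyError(f"coefficient {coef!r} not in design columns {list(design.columns)}")
    if list(design.index) != list(normmat.sample_ids):
        if len(design) != len(normmat.sample_ids):
            raise ValueError("design rows do not match samples")
        design = design.set_axis(normmat.sample_ids)
    _check_full_rank(design)
    x = design.to_numpy(dtype=float)
    y = normmat.values
    n, p = x.shape
    g = y.shape[0]
    j = list(design.columns).index(coef)

    if weights is None:
        w = np.ones((g, n))
    else:
        w = weights.weights
        if w.shape != y.shape:
            raise ValueError("weight matrix shape does not match expression matrix")

    # batched weighted normal equations: A_g = X' W_g X, b_g = X' W_g y_g
    a = np.einsum("ni,gn,nj->gij", x, w, x, optimize=True)
    b = np.einsum("ni,gn,gn->gi", x, w, y, optimize=True)
    beta = np.linalg.solve(a, b[..., None])[..., 0]
    ainv = np.linalg.inv(a)
    fitted = beta @ x.T
    resid = y - fitted
    rdf = n - p
    sigma2 = (w * resid ** 2).sum(axis=1) / rdf
    c2 = ainv[:, j, j]                      # unscaled squared stdev of coef
    se = np.sqrt(np.maximum(sigma2 * c2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, j] / se, np.where(beta[:, j] == 0, 0.0, np.inf * np.sign(beta[:, j])))
    pval = 2.0 * stats.t.sf(np.abs(t), rdf)

    frame = pd.DataFrame({
        "beta": beta[:, j], "se": se, "t": t, "df": float(rdf), "p": pval,
    }, index=normmat.gene_ids)
    return AssociationTable(
        frame=frame, coef=coef, residual_df=float(rdf),
        sigma2=pd.Series(sigma2, index=normmat.gene_ids),
        stdev_unscaled=pd.Series(np.sqrt(c2), index=normmat.gene_ids),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


def estimate_variance_prior(sigma2: np.ndarray, df: float,
                            d0_cap: float = 1e6) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Works on log residual variances: with s^2 ~ s0^2 * F(df, d0), the
    mean and excess variance of ``log(s^2) - digamma(df/2) + log(df/2)``
    identify s0^2 and d0 through digamma/trigamma. When the observed
    variances show no excess spread, d0 is capped at ``d0_cap`` and the
    prior variance is the mean observed variance (no shrinkage needed).
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0)) if e.size > 1 else -1.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        d0 = min(d0, d0_cap)
    else:
        d0 = d0_cap
        s0_2 = float(s2[ok].mean())
    return d0, s0_2


def moderate_variances(table: AssociationTable, d0_cap: float = 1e6) -> AssociationTable:
    """Shrink residual variances toward the pooled prior; add moderated t/p.

    s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d); the moderated t uses
    s_tilde and d0 + d degrees of freedom.
    """
    if len(table.frame) < 10:
        raise ValueError("variance moderation needs >= 10 genes")
    if table.residual_df < 1:
        raise ValueError("residual df < 1")
    s2 = table.sigma2.to_numpy()
    d = table.residual_df
    d0, s0_2 = estimate_variance_prior(s2, d, d0_cap)
    s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
    c = table.stdev_unscaled.to_numpy()
    beta = table.frame["beta"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = beta / (np.sqrt(s2_tilde) * c)
    df_mod = d0 + d
    # t distribution with huge df is numerically normal
    p_mod = 2.0 * stats.t.sf(np.abs(t_mod), min(df_mod, 1e9))
    frame = table.frame.copy()
    frame["t_mod"] = t_mod
    frame["df_mod"] = df_mod
    frame["p_mod"] = p_mod
    return AssociationTable(frame=frame, coef=table.coef, residual_df=table.residual_df,
                            sigma2=table.sigma2, stdev_unscaled=table.stdev_unscaled,
                            d0=d0, s0_2=s0_2)


# ---------------------------------------------------------------------------
# multiplicity


def adjust_pvalues(p, method: str = "BH", alpha: float = 0.05):
    """BH step-up q-values, or Bonferroni significance flags at level alpha."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "BH":
        m = p.size
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q
    if method == "bonferroni":
        return p < alpha / p.size
    raise ValueError(f"unknown method {method!r}")


def bonferroni_threshold(m: int, alpha: float = 0.05, sig_figs: int = 2) -> float:
    """Transcriptome-wide significance threshold alpha/m, rounded to sig_figs."""
    if m <= 0:
        raise ValueError("m must be positive")
    x = alpha / m
    from math import floor, log10
    digits = sig_figs - 1 - floor(log10(abs(x)))
    return round(x, digits)


def annotate_significance(table: AssociationTable, alpha: float = 0.05) -> AssociationTable:
    """Add BH q-values and a Bonferroni flag based on the (moderated) p-values."""
    p = table.p.to_numpy()
    frame = table.frame.copy()
    frame["q"] = adjust_pvalues(p, "BH")
    frame["bonferroni_significant"] = adjust_pvalues(p, "bonferroni", alpha)
    return AssociationTable(frame=frame, coef=table.coef, residual_df=table.residual_df,
                            sigma2=table.sigma2, stdev_unscaled=table.stdev_unscaled,
                            d0=table.d0, s0_2=table.s0_2)


# ---------------------------------------------------------------------------
# variance fractions


def variance_fractions(normmat: NormalizedMatrix, covariates: pd.DataFrame) -> pd.DataFrame:
    """Percent of each gene's variance explained by each covariate.

    Covariates are centered and sequentially orthogonalized in the
    order given (type-I decomposition on the orthogonalized basis), so
    fractions plus the residual sum to 100%.
    """
    x = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    y = normmat.values - normmat.values.mean(axis=1, keepdims=True)
    xc = x - x.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(xc)
    proj = y @ q                       # genes x covariates
    tot = (y ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = np.where(tot[:, None] > 0, proj ** 2 / tot[:, None], 0.0)
    out = pd.DataFrame(fracs * 100.0, index=normmat.gene_ids, columns=names)
    out["residual"] = np.where(tot > 0, 100.0 - out.sum(axis=1), 100.0)
    return out


# ---------------------------------------------------------------------------
# condition contrasts


def condition_contrast(normmat: NormalizedMatrix, condition,
                       covariates: pd.DataFrame | None = None,
                       weights: WeightMatrix | None = None,
                       levels: tuple[str, str] | None = None) -> AssociationTable:
    """Per-gene log2 fold change of one condition level against another.

    ``levels = (reference, test)``; the returned coefficient is the
    test-minus-reference log2 fold change. Defaults to the two levels
    present, in sorted order.
    """
    cond = pd.Series(np.asarray(condition), index=normmat.sample_ids)
    if levels is None:
        uniq = sorted(cond.unique())
        if len(uniq) != 2:
            raise ValueError(f"need exactly 2 condition levels or explicit `levels`; got {uniq}")
        levels = (uniq[0], uniq[1])
    ref, test = levels
    keep = cond.isin(levels)
    sub = normmat.subset_samples(list(cond.index[keep]))
    cond = cond[keep]
    for lev in levels:
        if (cond == lev).sum() < 2:
            raise ValueError(f"condition level {lev!r} has < 2 samples")
    cov = {"lfc": (cond == test).astype(float)}
    if covariates is not None:
        cov.update({c: covariates.loc[cond.index, c].astype(float) for c in covariates.columns})
    design = make_design(pd.DataFrame(cov, index=cond.index))
    if weights is not None:
        mask = np.asarray(keep)
        weights = WeightMatrix(weights.weights[:, mask], weights.trend)
    return fit_gene_models(sub, design, "lfc", weights)


# ---------------------------------------------------------------------------
# meta-cells


def metacells(cell_umis: CountMatrix, donors, condition, sex=None) -> MetaCellMatrix:
    """Sum single-cell UMIs into one meta-cell per (donor, condition).

    Attaches the number of cells and mean UMI per meta-cell (and donor
    sex if given) for use as DE covariates.
    """
    donors = pd.Series(np.asarray(donors), index=cell_umis.sample_ids)
    cond = pd.Series(np.asarray(condition), index=cell_umis.sample_ids)
    if donors.isna().any() or cond.isna().any():
        raise ValueError("every cell must have a donor and condition label")
    sex_map = {}
    if sex is not None:
        sex_s = pd.Series(np.asarray(sex), index=cell_umis.sample_ids)
        sex_map = dict(zip(donors, sex_s))
    keys = list(dict.fromkeys(zip(donors, cond)))
    cols, meta_rows, ids = [], [], []
    totals = cell_umis.counts.sum(axis=0)
    for donor, cnd in keys:
        mask = ((donors == donor) & (cond == cnd)).to_numpy()
        cols.append(cell_umis.counts[:, mask].sum(axis=1))
        mid = f"{donor}|{cnd}"
        ids.append(mid)
        meta_rows.append({
            "metacell_id": mid, "donor": donor, "condition": cnd,
            "n_cells": int(mask.sum()), "mean_umi": float(totals[mask].mean()),
            "sex": sex_map.get(donor, "NA"),
        })
    cm = CountMatrix(list(cell_umis.gene_ids), ids, np.column_stack(cols),
                     cell_umis.species, cell_umis.alignment_ref)
    meta = pd.DataFrame(meta_rows).set_index("metacell_id")
    return MetaCellMatrix(cm, meta)


# ---------------------------------------------------------------------------
# aggregate shift statistics


def aggregate_shift(normmat: NormalizedMatrix, gene_set, condition,
                    levels: tuple[str, str] | None = None) -> ShiftResult:
    """Mean standardized expression difference of a gene set between conditions.

    Per gene, expression is z-standardized across all samples pooled
    over conditions; the per-gene statistic is mean(z | test) -
    mean(z | reference); the estimate is its mean over the set, with a
    t-interval and one-sample t-test across genes.
    """
    genes = [g for g in gene_set if g in set(normmat.gene_ids)]
    if not genes:
        raise ValueError("gene set does not intersect the expression matrix")
    cond = pd.Series(np.asarray(condition), index=normmat.sample_ids)
    if levels is None:
        uniq = sorted(cond.unique())
        if len(uniq) != 2:
            raise ValueError("need exactly 2 condition levels or explicit `levels`")
        levels = (uniq[0], uniq[1])
    ref, test = levels
    sub = normmat.subset_genes(genes)
    x = sub.values
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)
    in_test = (cond == test).to_numpy()
    in_ref = (cond == ref).to_numpy()
    diffs = z[:, in_test].mean(axis=1) - z[:, in_ref].mean(axis=1)
    est = float(diffs.mean())
    n = diffs.size
    if n > 1 and diffs.std(ddof=1) > 0:
        se = diffs.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        res = stats.ttest_1samp(diffs, 0.0)
        return ShiftResult(est, est - tcrit * se, est + tcrit * se, float(res.pvalue), n)
    return ShiftResult(est, est, est, 1.0 if est == 0 else 0.0, n)


def marker_class_shift(normmat: NormalizedMatrix, class_genes, group) -> tuple[float, float, float]:
    """Regression of the per-sample mean z-scored class-gene expression on a group indicator.

    Returns (beta, SE, two-sided p).
    """
    genes = [g for g in class_genes if g in set(normmat.gene_ids)]
    if not genes:
        raise ValueError("class genes not present in matrix")
    g = pd.Series(np.asarray(group), index=normmat.sample_ids)
    uniq = sorted(g.unique())
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    sub = normmat.subset_genes(genes)
    x = sub.values
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)
    y = z.mean(axis=0)
    ind = (g == uniq[-1]).to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(ind), ind])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rdf = len(y) - 2
    if rdf < 1:
        raise ValueError("not enough samples")
    s2 = (resid ** 2).sum() / rdf
    cov = s2 * np.linalg.inv(design.T @ design)
    se = float(np.sqrt(cov[1, 1]))
    t = beta[1] / se if se > 0 else (0.0 if beta[1] == 0 else np.inf)
    p = 2.0 * stats.t.sf(abs(t), rdf)
    return float(beta[1]), se, float(p)


def marker_class_contrast(normmat: NormalizedMatrix, classA_genes,
                          classB_genes) -> tuple[float, float]:
    """Welch t-test between the pooled gene-sample values of two marker classes.

    Returns (delta = mean(A) - mean(B), two-sided p).
    """
    ga = [g for g in classA_genes if g in set(normmat.gene_ids)]
    gb = [g for g in classB_genes if g in set(normmat.gene_ids)]
    if not ga or not gb:
        raise ValueError("both marker classes must be present in the matrix")
    va = normmat.subset_genes(ga).values.ravel()
    vb = normmat.subset_genes(gb).values.ravel()
    delta = float(va.mean() - vb.mean())
    if np.allclose(va.var(), 0) and np.allclose(vb.var(), 0):
        return delta, 1.0 if delta == 0 else 0.0
    res = stats.ttest_ind(va, vb, equal_var=False)
    return delta, float(res.pvalue)
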