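"""Gene-set statistics: over-representation, overlap tests, competitive
regression and cell-type specificity.

All tests are computed within an explicit gene universe — the genes
actually analyzed in the expression data, not the full annotation — so
background composition cannot inflate enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import adjust_pvalues
from .io_formats import GeneSetCollection

__all__ = ["OverlapTest", "ora_hypergeometric", "overlap_binomial",
           "fold_enrichment", "competitive_geneset_regression",
           "celltype_specificity"]


@dataclass
class OverlapTest:
    k: int
    n: int
    p0: float
    alternative: str
    p: float
    fold: float


def fold_enrichment(k: int, n_study: int, K_set: int, N_universe: int) -> float:
    """Observed over expected overlap: k / (n_study * K_set / N_universe)."""
    if min(n_study, K_set, N_universe) <= 0:
        raise ValueError("study, set and universe sizes must be positive")
    if k < 0 or k > min(n_study, K_set):
        raise ValueError("overlap k out of range")
    return k / (n_study * K_set / N_universe)


def ora_hypergeometric(study_ids, collection: GeneSetCollection,
                       min_size: int = 10, max_size: int = 1000,
                       namespaces: dict | None = None) -> pd.DataFrame:
    """Over-representation analysis against a gene-set collection.

    Sets are restricted to the collection's universe and tested only if
    their within-universe size lies in ``[min_size, max_size]``. Study
    genes outside the universe are dropped with a warning. The p-value
    is the upper-tail hypergeometric probability of an overlap at least
    as large as observed; BH correction is applied across the tested
    sets — within each namespace separately when ``namespaces`` maps set
    names to namespaces.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty gene universe")
    study = set(study_ids)
    outside = study - universe
    if outside:
        warnings.warn(f"{len(outside)} study gene(s) outside the universe dropped",
                      stacklevel=2)
        study &= universe
    N, n = len(universe), len(study)
    rows = []
    for name, members in collection.sets.items():
        m = members & universe
        K = len(m)
        if K < min_size or K > max_size:
            continue
        k = len(study & m)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        fold = fold_enrichment(k, n, K, N) if n else 0.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "fold": fold, "p": p,
                     "namespace": (namespaces or {}).get(name, "all")})
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "fold", "p", "namespace"])
    if len(result):
        q = np.empty(len(result))
        for ns in result["namespace"].unique():
            mask = (result["namespace"] == ns).to_numpy()
            q[mask] = adjust_pvalues(result.loc[mask, "p"].to_numpy(), "BH")
        result["q"] = q
    else:
        result["q"] = []
    return result.set_index("set")


def overlap_binomial(k: int, n: int, p0: float,
                     alternative: str = "two_sided") -> OverlapTest:
    """Exact binomial test of an observed overlap k/n against a null proportion p0.

    The two-sided p aggregates all outcomes whose probability does not
    exceed that of the observed count (minimum-likelihood convention).
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("null proportion must lie strictly in (0, 1)")
    alt = {"two_sided": "two-sided", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = stats.binomtest(k, n, p0, alternative=alt)
    fold = (k / n) / p0 if n else 0.0
    return OverlapTest(k=k, n=n, p0=p0, alternative=alternative,
                       p=float(res.pvalue), fold=fold)


def competitive_geneset_regression(gene_z: pd.Series, membership,
                                   covariates: pd.DataFrame | None = None
                                   ) -> tuple[float, float, float]:
    """Competitive gene-set test: regress gene-level Z on set membership.

    ``membership`` is a set of gene ids or a boolean series aligned to
    ``gene_z``. Returns (beta, SE, one-sided p for beta > 0): a positive
    beta means member genes carry larger association statistics than
    non-members.
    """
    z = pd.Series(gene_z).astype(float)
    if isinstance(membership, (set, frozenset, list, tuple)):
        ind = z.index.isin(set(membership)).astype(float)
    else:
        ind = pd.Series(membership).reindex(z.index).astype(float).to_numpy()
    n_in = int(ind.sum())
    if n_in < 2 or (len(z) - n_in) < 2:
        raise ValueError("need >= 2 member and >= 2 non-member genes with Z")
    cols = [np.ones(len(z)), ind]
    names = ["Intercept", "member"]
    if covariates is not None:
        cov = covariates.reindex(z.index)
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(c)
    x = np.column_stack(cols)
    y = z.to_numpy()
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rdf = len(y) - x.shape[1]
    s2 = (resid ** 2).sum() / rdf
    cov_b = s2 * np.linalg.inv(x.T @ x)
    se = float(np.sqrt(cov_b[1, 1]))
    t = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    p = float(stats.t.sf(t, rdf))
    return float(beta[1]), se, p


def celltype_specificity(profiles: pd.DataFrame, gene_set,
                         focal_type: str) -> tuple[float, float]:
    """Is a gene set specifically expressed in one cell type?

    ``profiles`` is a cell-type x gene expression matrix. Each gene's
    profile is z-standardized across cell types; the focal type's z of
    the set genes is compared with the pooled z of the same genes in
    all other types by Welch t-test. Returns (mean focal z, p).
    """
    if focal_type not in profiles.index:
        raise KeyError(f"focal type {focal_type!r} not in profiles")
    if len(profiles.index) < 2:
        raise ValueError("need >= 2 cell types")
    genes = [g for g in gene_set if g in profiles.columns]
    if not genes:
        raise ValueError("gene set does not intersect profile genes")
    x = profiles[genes].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    z = np.where(sd > 0, (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    focal_idx = list(profiles.index).index(focal_type)
    focal = z[focal_idx, :]
    others = np.delete(z, focal_idx, axis=0).ravel()
    mean_focal = float(focal.mean())
    if np.allclose(focal.var(), 0) and np.allclose(others.var(), 0):
        return mean_focal, 1.0
    res = stats.ttest_ind(focal, others, equal_var=False)
    return mean_focal, float(res.pvalue)
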