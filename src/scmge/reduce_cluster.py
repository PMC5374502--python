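"""Dimension reduction and sub-population structure.

The analysis reduces QC-passed cells with PCA on the top 500 most variable
genes (variance-stabilized counts), finds genes associated with each of the
first four principal components using a moderated linear model (log2(nRPKM+1)
regressed on the component scores, with empirical-Bayes variance shrinkage at
P <= 1e-4), and clusters cells on those genes with agglomerative hierarchical
clustering (1 - Pearson correlation, average linkage by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import special, stats

from .io_model import CountMatrix, ExpressionMatrix, ValidationError

__all__ = [
    "PCModel",
    "ClusterResult",
    "variance_stabilize",
    "select_variable_genes",
    "run_pca",
    "pc_gene_prefilter",
    "pc_association",
    "select_pc_genes",
    "hcluster",
]


# ---------------------------------------------------------------------------
# variance stabilization


def _size_factors(arr: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors; falls back to column-sum ratios when no
    gene is expressed in every cell."""
    all_nonzero = (arr > 0).all(axis=1)
    if all_nonzero.any():
        sub = arr[all_nonzero].astype(float)
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        return np.exp(np.median(ratios, axis=0))
    totals = arr.sum(axis=0).astype(float)
    mean_total = totals.mean()
    if mean_total == 0:
        raise ValidationError("all-zero count matrix")
    sf = totals / mean_total
    return np.where(sf > 0, sf, 1.0)


def _moment_dispersion(x: np.ndarray) -> float:
    """Single NB dispersion by method of moments on size-factor-scaled counts:
    var = mu + alpha * mu^2 per gene, aggregated as the median over genes."""
    mu = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    ok = mu > 0
    if not ok.any():
        return -1.0
    alpha_g = (v[ok] - mu[ok]) / mu[ok] ** 2
    return float(np.median(alpha_g))


def variance_stabilize(
    counts: CountMatrix, method: str = "nb_vst", dispersion: float | None = None
) -> ExpressionMatrix:
    """Variance-stabilize counts for PCA.

    method="log2p1" applies log2(x+1) to size-factor-scaled counts.
    method="nb_vst" applies the closed-form negative-binomial stabilizer
    y = (2/sqrt(a)) * asinh(sqrt(a*x)) with a single dispersion ``a`` fitted
    by method of moments (or supplied via ``dispersion``). A non-positive
    dispersion estimate falls back to log2p1 with a warning. In the small-a
    (Poisson) limit the stabilizer reduces to 2*sqrt(x).
    """
    arr = counts.values.to_numpy().astype(float)
    sf = _size_factors(arr)
    x = arr / sf[None, :]
    if method == "nb_vst":
        alpha = _moment_dispersion(x) if dispersion is None else float(dispersion)
        if alpha <= 0:
            warnings.warn(
                "non-positive dispersion estimate; falling back to log2p1", stacklevel=2
            )
            method = "log2p1"
        else:
            vals = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * x))
            return ExpressionMatrix(
                pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns),
                transform="vst",
                meta={"method": "nb_vst", "dispersion": alpha},
            )
    if method != "log2p1":
        raise ValueError(f"unknown stabilization method {method!r}")
    vals = np.log2(x + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns),
        transform="vst",
        meta={"method": "log2p1"},
    )


def select_variable_genes(stab: ExpressionMatrix, n: int = 500) -> list:
    """Top-n genes by across-cell variance of stabilized values.

    Ties at the cutoff are broken by lexicographic gene id, so the selection
    is deterministic.
    """
    if n > stab.n_genes:
        raise ValidationError(f"requested {n} variable genes but matrix has {stab.n_genes}")
    variances = stab.values.var(axis=1, ddof=1)
    order = sorted(zip(-variances.to_numpy(), stab.values.index))
    return [g for _, g in order[:n]]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCModel:
    """PCA of gene-centered stabilized expression restricted to a gene subset.

    scores : cells x components; loadings : genes x components (orthonormal
    columns); variance_explained : fraction of total variance per component.
    Sign convention: each loading vector's largest-magnitude entry is
    non-negative.
    """

    variable_genes: list
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    meta: dict = field(default_factory=dict)


def run_pca(stab: ExpressionMatrix, genes: list, k: int, scale: bool = False) -> PCModel:
    """Exact SVD-based PCA on the gene-centered matrix restricted to ``genes``.

    Genes are centered across cells; by default they are not scaled to unit
    variance (the stabilizer already equalized variances).
    """
    if k > min(stab.n_cells, len(genes)):
        raise ValidationError(f"k={k} exceeds min(n_cells, n_genes)={min(stab.n_cells, len(genes))}")
    sub = stab.values.loc[genes]
    X = sub.to_numpy().astype(float)
    X = X - X.mean(axis=1, keepdims=True)
    if scale:
        sd = X.std(axis=1, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)[:, None]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry per component made positive
    for j in range(len(S)):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    total_var = float((S**2).sum())
    var_explained = (S**2 / total_var) if total_var > 0 else np.zeros_like(S)
    if total_var == 0:
        warnings.warn("degenerate all-constant input: zero-variance components", stacklevel=2)
    scores = pd.DataFrame(
        (Vt.T * S)[:, :k],
        index=sub.columns,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    loadings = pd.DataFrame(
        U[:, :k], index=sub.index, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return PCModel(list(genes), scores, loadings, var_explained[:k], meta={"scaled": scale})


# ---------------------------------------------------------------------------
# PC-associated genes


def pc_gene_prefilter(
    nrpkm_expr: ExpressionMatrix, min_value: float = 0.5, min_fraction: float = 0.25
) -> list:
    """Genes with nRPKM >= 0.5 in at least 25% of cells (both bounds inclusive)."""
    frac = (nrpkm_expr.values.to_numpy() >= min_value).mean(axis=1)
    return nrpkm_expr.values.index[frac >= min_fraction].tolist()


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled F distribution,
    returning (d0, s0_squared); d0 = inf when variances show no excess spread."""
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) if len(z) > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def pc_association(
    logexpr: ExpressionMatrix,
    model: PCModel,
    component: int,
    alpha: float = 1e-4,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-gene linear association of log expression with one PC's scores.

    Each gene is regressed on the component scores (intercept + slope) by
    ordinary least squares. With ``moderate=True`` the residual variances are
    shrunk toward a common prior by empirical Bayes — the posterior variance
    is (d0*s0^2 + d*s^2)/(d0 + d) with the prior (d0, s0^2) fitted by method
    of moments on the log residual variances — and the t statistic uses the
    shrunk variance with d0 + d degrees of freedom.

    Returns a DataFrame indexed by gene with slope, t_statistic, p_value and
    the selected flag (p <= alpha).
    """
    x = model.scores[f"PC{component}"].to_numpy().astype(float)
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 cells for the slope test")
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    if sxx == 0:
        raise ValidationError("zero-variance PC scores")
    Y = logexpr.values.loc[:, model.scores.index].to_numpy().astype(float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    slope = Yc @ xc / sxx
    resid = Yc - np.outer(slope, xc)
    df_resid = n - 2
    s2 = (resid**2).sum(axis=1) / df_resid
    gene_var = Yc.var(axis=1)
    constant = gene_var <= 1e-300

    if moderate and (~constant).sum() > 1:
        d0, s0_sq = _fit_f_dist(s2[~constant], df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
    else:
        d0, s0_sq = 0.0, float("nan")
        s2_post = s2
        df_total = df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post / sxx)
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    p[constant] = 1.0
    t[constant] = 0.0
    slope = np.where(constant, 0.0, slope)
    out = pd.DataFrame(
        {
            "slope": slope,
            "t_statistic": t,
            "p_value": p,
            "selected": p <= alpha,
        },
        index=logexpr.values.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_squared"] = s0_sq
    out.attrs["component"] = component
    return out


def select_pc_genes(
    logexpr: ExpressionMatrix,
    model: PCModel,
    components: tuple = (1, 2, 3, 4),
    alpha: float = 1e-4,
    moderate: bool = True,
) -> tuple[list, dict]:
    """Genes significant (p <= alpha) for any of the given components.

    Returns (gene list in matrix order, {component: per-gene result table}).
    The cutoff is applied per component without cross-component correction.
    """
    results = {
        c: pc_association(logexpr, model, c, alpha=alpha, moderate=moderate)
        for c in components
    }
    any_selected = np.zeros(logexpr.n_genes, dtype=bool)
    for res in results.values():
        any_selected |= res["selected"].to_numpy()
    return logexpr.values.index[any_selected].tolist(), results


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterResult:
    """Agglomerative clustering of cells or genes.

    linkage : scipy linkage matrix (merge heights non-decreasing for
    average/complete/single linkage on a proper metric).
    leaf_order : item ids in dendrogram order.
    labels : item id -> flat cluster id (1..k) when a cut was requested.
    """

    linkage: np.ndarray
    leaf_order: list
    labels: pd.Series | None
    axis: str
    meta: dict = field(default_factory=dict)


def hcluster(
    matrix: ExpressionMatrix,
    axis: str = "cells",
    k: int | None = None,
    distance: str = "correlation",
    linkage_method: str = "average",
) -> ClusterResult:
    """Hierarchical clustering with 1 - Pearson correlation distance and
    average linkage by default; cut into k flat clusters when k is given.

    Constant items have undefined correlation; their pairwise distances are
    set to the maximum (1.0) with a warning.
    """
    if axis == "cells":
        data = matrix.values.to_numpy().T
        ids = list(matrix.values.columns)
    elif axis == "genes":
        data = matrix.values.to_numpy()
        ids = list(matrix.values.index)
    else:
        raise ValueError(f"axis must be 'cells' or 'genes', got {axis!r}")
    if len(ids) < 2:
        raise ValidationError("need at least 2 items to cluster")
    if distance == "correlation":
        with np.errstate(invalid="ignore", divide="ignore"):
            d = ssd.pdist(data.astype(float), metric="correlation")
        if np.isnan(d).any():
            warnings.warn(
                "constant item(s) under correlation distance; distance set to 1",
                stacklevel=2,
            )
            d = np.nan_to_num(d, nan=1.0)
    else:
        d = ssd.pdist(data.astype(float), metric=distance)
    Z = sch.linkage(d, method=linkage_method)
    leaf_order = [ids[i] for i in sch.leaves_list(Z)]
    labels = None
    if k is not None:
        flat = sch.fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=ids, name="cluster")
    return ClusterResult(
        Z, leaf_order, labels, axis, meta={"distance": distance, "linkage": linkage_method}
    )
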