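"""Two-group differential expression by Mann-Whitney rank test.

The procedure: prefilter to genes with at least 10 counts in at least 3 cells
(pooled over both groups), test each gene's nRPKM values with the two-sided
Mann-Whitney test, adjust the tested genes' p-values (Holm by default, BH
optional), and report a floored-median log2 fold-change: per-cell log2(nRPKM)
with values below -8 (including -inf from zeros) replaced by -8, the LFC
being the difference of group medians of those floored values. Genes failing
the prefilter are backfilled with p = 1 and LFC = 0 but are excluded from the
multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import CountMatrix, ExpressionMatrix, ValidationError

__all__ = [
    "DEResult",
    "de_prefilter",
    "mann_whitney",
    "median_lfc",
    "adjust_pvalues",
    "run_de",
    "top_de_genes",
]

EXACT_MAX_N = 20  # combined group size below which the exact null is used
LFC_FLOOR = -8.0


@dataclass
class DEResult:
    """Per-gene DE table: tested, p_value, p_adjusted, lfc, n_A, n_B."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def tested_genes(self) -> list:
        return self.table.index[self.table["tested"]].tolist()


def de_prefilter(counts: CountMatrix, group_a: list, group_b: list,
                 min_count: int = 10, min_cells: int = 3) -> list:
    """Genes with >= ``min_count`` counts in >= ``min_cells`` cells of either group."""
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    pooled = counts.values.loc[:, list(group_a) + list(group_b)].to_numpy()
    n_high = (pooled >= min_count).sum(axis=1)
    return counts.values.index[n_high >= min_cells].tolist()


def mann_whitney(values_a: np.ndarray, values_b: np.ndarray, method: str = "auto") -> float:
    """Two-sided Mann-Whitney p-value with midrank tie handling.

    With method="auto", uses the exact null distribution when the combined
    sample size is at most 20 and there are no ties, and the normal
    approximation with tie and continuity corrections otherwise; "exact" or
    "asymptotic" force a path.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("empty group in Mann-Whitney test")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if method == "auto":
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(pooled) <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def median_lfc(values_a: np.ndarray, values_b: np.ndarray,
               floor: float = LFC_FLOOR, mode: str = "floored_log") -> float:
    """Floored-median log2 fold-change of group A over group B.

    mode="floored_log" (default): per-cell log2 values below ``floor`` —
    including -inf from zeros — are replaced by the floor, and the LFC is the
    difference of group medians of the floored values. mode="raw" takes group
    medians of the raw values first and floors their log2 instead.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    with np.errstate(divide="ignore"):
        if mode == "floored_log":
            la = np.maximum(np.log2(a), floor)
            lb = np.maximum(np.log2(b), floor)
            return float(np.median(la) - np.median(lb))
        if mode == "raw":
            la = max(np.log2(np.median(a)) if np.median(a) > 0 else -np.inf, floor)
            lb = max(np.log2(np.median(b)) if np.median(b) > 0 else -np.inf, floor)
            return float(la - lb)
    raise ValueError(f"unknown LFC mode {mode!r}")


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment, input order preserved.

    method="holm" is the step-down familywise-error procedure (the default of
    the adjustment the analysis calls); method="bh" is Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    sm_method = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=sm_method)[1]


def run_de(counts: CountMatrix, nrpkm_expr: ExpressionMatrix, group_a: list,
           group_b: list, adjust: str = "holm", floor: float = LFC_FLOOR,
           lfc_mode: str = "floored_log") -> DEResult:
    """Full DE procedure: prefilter, rank test on nRPKM, adjust, backfill."""
    tested = de_prefilter(counts, group_a, group_b)
    tested_set = set(tested)
    genes = counts.values.index
    va = nrpkm_expr.values.loc[:, group_a].to_numpy()
    vb = nrpkm_expr.values.loc[:, group_b].to_numpy()
    gene_pos = {g: i for i, g in enumerate(nrpkm_expr.values.index)}

    p_raw = np.ones(len(genes))
    lfc = np.zeros(len(genes))
    tested_flag = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        if g not in tested_set:
            continue
        j = gene_pos[g]
        p_raw[i] = mann_whitney(va[j], vb[j])
        lfc[i] = median_lfc(va[j], vb[j], floor=floor, mode=lfc_mode)
        tested_flag[i] = True

    p_adj = np.ones(len(genes))
    p_adj[tested_flag] = adjust_pvalues(p_raw[tested_flag], method=adjust)
    table = pd.DataFrame(
        {
            "tested": tested_flag,
            "p_value": p_raw,
            "p_adjusted": p_adj,
            "lfc": lfc,
            "n_A": len(group_a),
            "n_B": len(group_b),
        },
        index=genes,
    )
    table.index.name = "gene_id"
    return DEResult(table, meta={"adjust": adjust, "floor": floor, "lfc_mode": lfc_mode})


def top_de_genes(de: DEResult, n: int = 100) -> pd.DataFrame:
    """Top-n tested genes by adjusted p (ties: larger |lfc| first, then gene id).

    Returns a table with p_adjusted, lfc and a direction label (up/down for
    the sign of the LFC of group A over group B).
    """
    tested = de.table[de.table["tested"]].copy()
    if n > len(tested):
        warnings.warn(
            f"requested {n} genes but only {len(tested)} were tested; returning all",
            stacklevel=2,
        )
        n = len(tested)
    tested["_abs_lfc"] = tested["lfc"].abs()
    tested["_gid"] = tested.index
    ordered = tested.sort_values(
        ["p_adjusted", "_abs_lfc", "_gid"], ascending=[True, False, True]
    ).head(n)
    out = ordered[["p_adjusted", "lfc"]].copy()
    out["direction"] = np.where(ordered["lfc"] > 0, "up", np.where(ordered["lfc"] < 0, "down", "flat"))
    return out
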