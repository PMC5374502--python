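"""Heatmap value preparation, cross-system concordance, and volcano tables.

Heatmaps encode per-gene z-scores of log2(nRPKM) with log values below -6
floored at -6. Cross-system concordance joins two DE results on their shared
genes and flags genes significant (raw p below the cut) in both systems with
agreeing fold-change direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import DEResult
from .io_model import ExpressionMatrix, ValidationError
from .qpcr import zscore_genes

__all__ = ["ConcordanceTable", "heatmap_values", "concordance", "volcano_table", "plot_volcano"]

HEATMAP_FLOOR = -6.0


@dataclass
class ConcordanceTable:
    """Per-gene joined fold changes and p-values from two DE systems."""

    table: pd.DataFrame
    quadrant_counts: dict
    n_dropped: int
    meta: dict = field(default_factory=dict)


def heatmap_values(nrpkm_expr: ExpressionMatrix, floor: float = HEATMAP_FLOOR) -> ExpressionMatrix:
    """log2(nRPKM) floored at -6, then per-gene z-score (population sd)."""
    arr = nrpkm_expr.values.to_numpy().astype(float)
    with np.errstate(divide="ignore"):
        logged = np.maximum(np.log2(arr), floor)
    floored = ExpressionMatrix(
        pd.DataFrame(logged, index=nrpkm_expr.values.index, columns=nrpkm_expr.values.columns),
        transform="log2p1",
        floor_applied=floor,
    )
    z = zscore_genes(floored)
    z.floor_applied = floor
    return z


def concordance(de1: DEResult, de2: DEResult, p_cut: float = 0.05,
                use_adjusted: bool = False) -> ConcordanceTable:
    """Join two DE results on shared genes and flag concordant significance.

    A gene is concordant_significant when its p-value (raw by default) is
    below ``p_cut`` in both systems and its fold changes share a sign.
    """
    pcol = "p_adjusted" if use_adjusted else "p_value"
    shared = de1.table.index.intersection(de2.table.index)
    if len(shared) == 0:
        raise ValidationError("no shared genes between the two DE results")
    n_dropped = (len(de1.table) - len(shared)) + (len(de2.table) - len(shared))
    t1 = de1.table.loc[shared]
    t2 = de2.table.loc[shared]
    out = pd.DataFrame(
        {
            "lfc_system1": t1["lfc"],
            "lfc_system2": t2["lfc"],
            "p1": t1[pcol],
            "p2": t2[pcol],
        },
        index=shared,
    )
    out["concordant_significant"] = (
        (out["p1"] < p_cut)
        & (out["p2"] < p_cut)
        & (np.sign(out["lfc_system1"]) == np.sign(out["lfc_system2"]))
        & (out["lfc_system1"] != 0)
    )
    sig = (out["p1"] < p_cut) & (out["p2"] < p_cut)
    quadrants = {
        "upper_right": int((sig & (out["lfc_system1"] > 0) & (out["lfc_system2"] > 0)).sum()),
        "lower_left": int((sig & (out["lfc_system1"] < 0) & (out["lfc_system2"] < 0)).sum()),
        "upper_left": int((sig & (out["lfc_system1"] < 0) & (out["lfc_system2"] > 0)).sum()),
        "lower_right": int((sig & (out["lfc_system1"] > 0) & (out["lfc_system2"] < 0)).sum()),
    }
    out.index.name = "gene_id"
    return ConcordanceTable(out, quadrants, n_dropped, meta={"p_cut": p_cut, "p_column": pcol})


def volcano_table(de: DEResult, p_cut: float = 0.05, use_adjusted: bool = False) -> pd.DataFrame:
    """Volcano-plot table (lfc, -log10 p, significant flag), sorted by p.

    Significance uses the strict inequality p < p_cut; backfilled genes with
    p = 1 get -log10 p = 0.
    """
    pcol = "p_adjusted" if use_adjusted else "p_value"
    out = pd.DataFrame(
        {
            "lfc": de.table["lfc"],
            "neg_log10_p": -np.log10(de.table[pcol]),
            "significant": de.table[pcol] < p_cut,
        },
        index=de.table.index,
    )
    out.index.name = "gene_id"
    return out.sort_values("neg_log10_p", ascending=False, kind="stable")


def plot_volcano(volcano: pd.DataFrame, path: str) -> None:
    """Optional rendering of a volcano table to PNG/SVG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano["significant"]
    ax.scatter(volcano.loc[~sig, "lfc"], volcano.loc[~sig, "neg_log10_p"], s=6, c="grey")
    ax.scatter(volcano.loc[sig, "lfc"], volcano.loc[sig, "neg_log10_p"], s=6, c="crimson")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
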