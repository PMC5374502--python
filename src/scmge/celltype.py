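"""Rule-based cell-type markers and classification.

A gene is a marker for a cell type when it is expressed at or above a
threshold (norm_mRNA_mol >= 1 for the labelled reference, nRPKM >= 1
within-dataset) in a high fraction of that type's cells (75% reference, 50%
within-dataset) while being detected (> 0) in fewer than 25% of the cells of
every other type. A cell expressing at least four markers of a type is
called as that putative type; cells reaching four markers of two types, or
hitting a configured exclusion pair, are excluded as conflicts; biologically
implausible calls (e.g. pyramidal neurons in the MGE) can be flagged via
exclusion rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .io_model import ExpressionMatrix, ValidationError

__all__ = [
    "MarkerRule",
    "MarkerSet",
    "CellTypeCall",
    "derive_markers",
    "classify_cells",
    "signature_classify",
    "proportion_trend",
]

UNASSIGNED = "unassigned"
EXCLUDED_CONFLICT = "excluded_conflict"
EXCLUDED_IMPLAUSIBLE = "excluded_implausible"


@dataclass(frozen=True)
class MarkerRule:
    """Thresholds defining a cell-type marker.

    expr_threshold/expr_prevalence: the gene must be at or above
    ``expr_threshold`` in at least ``expr_prevalence`` of the type's cells
    (0.75 for a labelled reference; 0.50 for within-dataset derivation).
    detect_threshold/detect_prevalence: the gene is disqualified if detected
    (strictly above ``detect_threshold``) in at least ``detect_prevalence``
    of another type's cells. ``scope`` controls whether "another type" means
    each other type separately or all other cells pooled.
    """

    expr_threshold: float = 1.0
    expr_prevalence: float = 0.75
    detect_threshold: float = 0.0
    detect_prevalence: float = 0.25
    scope: str = "each_other_type"

    def __post_init__(self) -> None:
        if not (0 < self.expr_prevalence <= 1 and 0 < self.detect_prevalence <= 1):
            raise ValidationError("prevalences must lie in (0, 1]")
        if self.expr_threshold <= self.detect_threshold:
            raise ValidationError("expr_threshold must exceed detect_threshold")
        if self.scope not in ("each_other_type", "pooled_other_types"):
            raise ValidationError(f"unknown scope {self.scope!r}")


WITHIN_DATASET_RULE = MarkerRule(expr_prevalence=0.50)


@dataclass
class MarkerSet:
    """Cell-type label -> derived marker gene ids, with the rule that produced them."""

    markers: dict
    rule: MarkerRule
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.rule.scope == "each_other_type":
            seen: dict = {}
            for t, gs in self.markers.items():
                for g in gs:
                    if g in seen:
                        raise ValidationError(
                            f"marker {g} claimed by both {seen[g]} and {t}"
                        )
                    seen[g] = t


@dataclass
class CellTypeCall:
    """Per-cell classification: hit counts per type plus the assignment.

    ``table`` is indexed by cell id with one hit-count column per type and an
    ``assigned`` column holding the type label, "unassigned",
    "excluded_conflict" or "excluded_implausible".
    """

    table: pd.DataFrame
    min_markers: int = 4
    meta: dict = field(default_factory=dict)


def derive_markers(
    norm: ExpressionMatrix, labels: pd.Series, rule: MarkerRule = MarkerRule(),
    provenance: str = "",
) -> MarkerSet:
    """Derive cell-type-specific markers from a labelled expression matrix.

    All prevalence comparisons are inclusive ("at least"): a gene detected in
    exactly 25% of another type's cells is disqualified, and a gene at the
    expression threshold in exactly 75% of the type's cells qualifies.
    """
    labels = labels.reindex(norm.values.columns)
    if labels.isna().any():
        raise ValidationError("every cell must carry a type label")
    types = sorted(labels.unique())
    if len(types) == 1:
        warnings.warn(
            "single labelled type: the cross-type exclusion clause is vacuous",
            stacklevel=2,
        )
    arr = norm.values.to_numpy()
    cols = {t: (labels == t).to_numpy() for t in types}
    for t in types:
        if cols[t].sum() == 0:
            raise ValidationError(f"type {t!r} has no cells")
    expr_frac = {t: (arr[:, cols[t]] >= rule.expr_threshold).mean(axis=1) for t in types}
    detect_frac = {t: (arr[:, cols[t]] > rule.detect_threshold).mean(axis=1) for t in types}

    markers: dict = {}
    for t in types:
        qualifies = expr_frac[t] >= rule.expr_prevalence
        others = [u for u in types if u != t]
        if rule.scope == "each_other_type":
            for u in others:
                qualifies &= detect_frac[u] < rule.detect_prevalence
        elif others:
            pooled = np.zeros(arr.shape[1], dtype=bool)
            for u in others:
                pooled |= cols[u]
            pooled_frac = (arr[:, pooled] > rule.detect_threshold).mean(axis=1)
            qualifies &= pooled_frac < rule.detect_prevalence
        markers[t] = norm.values.index[qualifies].tolist()
    return MarkerSet(markers, rule, provenance)


def classify_cells(
    expr: ExpressionMatrix,
    markers: MarkerSet,
    min_markers: int = 4,
    call_threshold: float = 0.0,
    exclusions: list | None = None,
) -> CellTypeCall:
    """Assign each cell the type whose markers it expresses at least
    ``min_markers`` of (expression strictly above ``call_threshold``).

    Cells reaching the threshold for two or more types are excluded as
    conflicts. ``exclusions`` is a list of (type_x, type_y, action) rules
    applied after counting: when a cell reaches ``min_markers`` for type_x
    and (type_y's markers fire, or type_y is "*"), the action ("exclude",
    "implausible", "suppress") overrides the assignment.
    """
    if not markers.markers or not any(markers.markers.values()):
        raise ValidationError("empty marker set")
    types = sorted(markers.markers)
    present = set(expr.values.index)
    hit_counts = {}
    for t in types:
        genes = [g for g in markers.markers[t] if g in present]
        dropped = len(markers.markers[t]) - len(genes)
        if dropped:
            warnings.warn(f"{dropped} markers of {t!r} absent from matrix; dropped",
                          stacklevel=2)
        if genes:
            hit_counts[t] = (expr.values.loc[genes].to_numpy() > call_threshold).sum(axis=0)
        else:
            hit_counts[t] = np.zeros(expr.n_cells, dtype=int)

    hits = pd.DataFrame(hit_counts, index=expr.values.columns)
    assigned = []
    for _, row in hits.iterrows():
        reached = [t for t in types if row[t] >= min_markers]
        if len(reached) == 0:
            call = UNASSIGNED
        elif len(reached) > 1:
            call = EXCLUDED_CONFLICT
        else:
            call = reached[0]
        if exclusions and call not in (UNASSIGNED,):
            for tx, ty, action in exclusions:
                fired_x = row.get(tx, 0) >= min_markers
                fired_y = ty == "*" or row.get(ty, 0) >= min_markers
                if fired_x and fired_y and (call == tx or call == EXCLUDED_CONFLICT):
                    if action == "exclude":
                        call = EXCLUDED_CONFLICT
                    elif action == "implausible":
                        call = EXCLUDED_IMPLAUSIBLE
                    elif action == "suppress":
                        call = UNASSIGNED
        assigned.append(call)
    table = hits.copy()
    table["assigned"] = assigned
    table.index.name = "cell_id"
    return CellTypeCall(table, min_markers, meta={"call_threshold": call_threshold})


def signature_classify(
    zexpr: ExpressionMatrix,
    sig_up: list,
    sig_down: list,
    margin: float = 0.0,
    class_names: tuple = ("classA", "classB"),
) -> pd.Series:
    """Supervised two-signature classification on per-gene z-scores.

    Each cell scores the mean z over each signature's genes and is assigned
    the higher-scoring class, or "ambiguous" when the score difference does
    not exceed ``margin``.
    """
    present = set(zexpr.values.index)
    up = [g for g in sig_up if g in present]
    down = [g for g in sig_down if g in present]
    for name, asked, got in (("up", sig_up, up), ("down", sig_down, down)):
        if len(got) < len(asked):
            warnings.warn(f"{len(asked) - len(got)} {name}-signature genes absent; dropped",
                          stacklevel=2)
    if not up or not down:
        raise ValidationError("a signature is empty after dropping absent genes")
    score_a = zexpr.values.loc[up].mean(axis=0)
    score_b = zexpr.values.loc[down].mean(axis=0)
    diff = score_a - score_b
    out = pd.Series(
        np.where(diff > margin, class_names[0],
                 np.where(diff < -margin, class_names[1], "ambiguous")),
        index=zexpr.values.columns,
        name="signature_class",
    )
    return out


def proportion_trend(
    counts: pd.DataFrame, baseline: str, test: str = "fisher"
) -> pd.Series:
    """One-sided test of increased class proportion vs a baseline condition.

    ``counts`` is indexed by condition with columns ``successes`` (cells of
    the class of interest) and ``total``. Returns a p-value per non-baseline
    condition; "fisher" uses the exact hypergeometric tail,
    "two_proportion_z" the normal approximation.
    """
    if baseline not in counts.index:
        raise ValidationError(f"baseline condition {baseline!r} missing")
    if (counts["total"] <= 0).any():
        raise ValidationError("every condition needs a positive total")
    k0, n0 = int(counts.loc[baseline, "successes"]), int(counts.loc[baseline, "total"])
    pvals = {}
    for cond in counts.index:
        if cond == baseline:
            continue
        k1, n1 = int(counts.loc[cond, "successes"]), int(counts.loc[cond, "total"])
        if test == "fisher":
            _, p = stats.fisher_exact([[k1, n1 - k1], [k0, n0 - k0]], alternative="greater")
        elif test == "two_proportion_z":
            _, p = proportions_ztest([k1, k0], [n1, n0], alternative="larger")
        else:
            raise ValueError(f"unknown test {test!r}")
        pvals[cond] = float(p)
    return pd.Series(pvals, name="p_value")
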