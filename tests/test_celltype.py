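import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from scmge import celltype as ct
from scmge import preprocess as pp
from scmge import qpcr as qp
from scmge import diffexp as de
from scmge import reduce_cluster as rc
from scmge.io_model import ExpressionMatrix, ValidationError


def _expr(values, transform="norm_mRNA_mol", gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=cell_ids), transform)


class TestDeriveMarkers:
    def test_inclusive_expression_boundary(self):
        """Expression at exactly the threshold in exactly 75% of the type's
        cells qualifies; zero elsewhere keeps the gene exclusive."""
        vals = np.zeros((1, 8))
        vals[0, :3] = 1.0  # 3 of 4 T cells = exactly 75%
        labels = pd.Series(["T"] * 4 + ["U"] * 4, index=[f"c{j}" for j in range(8)])
        ms = ct.derive_markers(_expr(vals), labels)
        assert ms.markers["T"] == ["g0"]

    def test_detection_in_exactly_25pct_disqualifies(self):
        vals = np.zeros((1, 8))
        vals[0, :4] = 2.0        # perfect in T
        vals[0, 4] = 0.1         # detected in exactly 1 of 4 U cells = 25%
        labels = pd.Series(["T"] * 4 + ["U"] * 4, index=[f"c{j}" for j in range(8)])
        ms = ct.derive_markers(_expr(vals), labels)
        assert ms.markers["T"] == []

    def test_single_type_vacuous_exclusion(self):
        vals = np.full((2, 4), 2.0)
        labels = pd.Series(["T"] * 4, index=[f"c{j}" for j in range(4)])
        with pytest.warns(UserWarning, match="vacuous"):
            ms = ct.derive_markers(_expr(vals), labels)
        assert set(ms.markers["T"]) == {"g0", "g1"}

    def test_cell_order_invariance(self, reference):
        ref, labels = reference
        norm = pp.norm_mrna_mol(ref)
        ms1 = ct.derive_markers(norm, labels)
        perm = list(np.random.default_rng(4).permutation(norm.values.columns))
        ms2 = ct.derive_markers(norm.subset_cells(perm), labels.loc[perm])
        assert ms1.markers == ms2.markers

    def test_planted_markers_recovered(self, reference, default_cohort):
        _, _, truth = default_cohort
        ref, labels = reference
        ms = ct.derive_markers(pp.norm_mrna_mol(ref), labels)
        for rtype, planted in truth.markers.items():
            assert sorted(ms.markers[rtype]) == sorted(planted)

    def test_within_dataset_rule_prevalence(self):
        # nRPKM >= 1 in 50% (not 75%) suffices for the within-dataset variant
        vals = np.zeros((1, 8))
        vals[0, :2] = 1.5  # 2 of 4 T cells = 50%
        labels = pd.Series(["T"] * 4 + ["U"] * 4, index=[f"c{j}" for j in range(8)])
        assert ct.derive_markers(_expr(vals, "nRPKM"), labels).markers["T"] == []
        assert ct.derive_markers(
            _expr(vals, "nRPKM"), labels, ct.WITHIN_DATASET_RULE
        ).markers["T"] == ["g0"]

    def test_empty_type_rejected(self):
        vals = np.ones((1, 2))
        labels = pd.Series(["T", None], index=["c0", "c1"])
        with pytest.raises(ValidationError):
            ct.derive_markers(_expr(vals), labels)


def _marker_set():
    return ct.MarkerSet(
        {"microglia": [f"m{i}" for i in range(5)], "oligo": [f"o{i}" for i in range(5)],
         "interneuron": [f"n{i}" for i in range(5)]},
        ct.MarkerRule(),
    )


def _cell_expr(hits_by_type, ms, cell_id="cell"):
    genes = [g for gs in ms.markers.values() for g in gs]
    vals = pd.DataFrame(0.0, index=genes, columns=[cell_id])
    for t, n in hits_by_type.items():
        for g in ms.markers[t][:n]:
            vals.loc[g, cell_id] = 5.0
    return ExpressionMatrix(vals, "nRPKM")


class TestClassifyCells:
    def test_four_of_five_markers_assigns(self):
        ms = _marker_set()
        call = ct.classify_cells(_cell_expr({"microglia": 4}, ms), ms)
        assert call.table["assigned"].iloc[0] == "microglia"

    def test_three_markers_unassigned(self):
        ms = _marker_set()
        call = ct.classify_cells(_cell_expr({"microglia": 3}, ms), ms)
        assert call.table["assigned"].iloc[0] == ct.UNASSIGNED

    def test_two_types_reaching_threshold_conflict(self):
        ms = _marker_set()
        call = ct.classify_cells(_cell_expr({"oligo": 4, "interneuron": 4}, ms), ms)
        assert call.table["assigned"].iloc[0] == ct.EXCLUDED_CONFLICT

    def test_exclusion_rule_actions(self):
        ms = _marker_set()
        # implausible: a pyramidal-like call suppressed regardless of partner
        call = ct.classify_cells(
            _cell_expr({"microglia": 5}, ms), ms,
            exclusions=[("microglia", "*", "implausible")],
        )
        assert call.table["assigned"].iloc[0] == ct.EXCLUDED_IMPLAUSIBLE
        # suppress: putative interneurons dropped back to unassigned
        call = ct.classify_cells(
            _cell_expr({"interneuron": 4}, ms), ms,
            exclusions=[("interneuron", "*", "suppress")],
        )
        assert call.table["assigned"].iloc[0] == ct.UNASSIGNED

    def test_idempotent_and_marker_order_independent(self):
        ms = _marker_set()
        expr = _cell_expr({"microglia": 4}, ms)
        shuffled = ct.MarkerSet(
            {t: list(reversed(gs)) for t, gs in ms.markers.items()}, ms.rule
        )
        c1 = ct.classify_cells(expr, ms)
        c2 = ct.classify_cells(expr, shuffled)
        c3 = ct.classify_cells(expr, ms)
        assert c1.table["assigned"].equals(c3.table["assigned"])
        assert c1.table["assigned"].iloc[0] == c2.table["assigned"].iloc[0]

    def test_missing_markers_dropped_with_warning(self):
        ms = _marker_set()
        expr = _cell_expr({"microglia": 4}, ms)
        expr = ExpressionMatrix(expr.values.drop(index="o0"), "nRPKM")
        with pytest.warns(UserWarning, match="absent"):
            call = ct.classify_cells(expr, ms)
        assert call.table["assigned"].iloc[0] == "microglia"

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValidationError):
            ct.classify_cells(_cell_expr({}, _marker_set()), ct.MarkerSet({}, ct.MarkerRule()))

    def test_planted_rare_types_on_default_cohort(self, default_cohort, reference):
        """Every planted rare cell gets its planted type; no population cell
        gets any rare label; the dual-signature cell is a conflict."""
        _, counts, truth = default_cohort
        ref, labels = reference
        ms = ct.derive_markers(pp.norm_mrna_mol(ref), labels)
        call = ct.classify_cells(pp.nrpkm(counts), ms)
        tab = call.table.join(truth.cells)
        rare = tab[tab["rare_type"].notna()]
        assert (rare["assigned"] == rare["rare_type"]).all()
        assert (tab.loc[tab["population"].notna(), "assigned"] == ct.UNASSIGNED).all()
        assert (tab.loc[tab["is_dual_signature"], "assigned"] == ct.EXCLUDED_CONFLICT).all()


class TestSignatureClassify:
    def test_clear_cells(self):
        vals = np.array([[1.0, -1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, 1.0]])
        z = _expr(vals, "zscore", gene_ids=["u0", "u1", "d0", "d1"], cell_ids=["a", "b"])
        out = ct.signature_classify(z, ["u0", "u1"], ["d0", "d1"])
        assert out.tolist() == ["classA", "classB"]

    def test_zero_cell_ambiguous_at_positive_margin(self):
        z = _expr(np.zeros((2, 1)), "zscore", gene_ids=["u", "d"])
        out = ct.signature_classify(z, ["u"], ["d"], margin=0.1)
        assert out.iloc[0] == "ambiguous"

    def test_absent_genes_dropped_and_empty_rejected(self):
        z = _expr(np.ones((2, 1)), "zscore", gene_ids=["u", "d"])
        with pytest.warns(UserWarning, match="absent"):
            ct.signature_classify(z, ["u", "ghost"], ["d"])
        with pytest.raises(ValidationError):
            ct.signature_classify(z, ["ghost"], ["d"])

    def test_top_de_signatures_classify_later_ages(self, default_cohort, qc_kept):
        """Top-100 DE genes from the earliest age classify the later-age
        cells' planted populations with accuracy >= 0.95."""
        _, counts, truth = default_cohort
        pop = truth.cells["population"]
        e11 = [c for c in qc_kept if truth.cells.loc[c, "condition"] == "E11.5"
               and pop[c] in ("progenitor", "neuron")]
        later = [c for c in qc_kept if truth.cells.loc[c, "condition"] != "E11.5"
                 and pop[c] in ("progenitor", "neuron")]
        a = [c for c in e11 if pop[c] == "neuron"]
        b = [c for c in e11 if pop[c] == "progenitor"]
        nr = pp.nrpkm(counts)
        res = de.run_de(counts, nr, a, b)
        top = de.top_de_genes(res, n=100)
        sig_up = top.index[top["direction"] == "up"].tolist()
        sig_down = top.index[top["direction"] == "down"].tolist()
        z = qp.zscore_genes(pp.log_stabilize(nr.subset_cells(later)))
        calls = ct.signature_classify(z, sig_up, sig_down,
                                      class_names=("neuron", "progenitor"))
        acc = (calls.loc[later] == pop.loc[later]).mean()
        assert acc >= 0.95


class TestProportionTrend:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["successes", "total"],
                            index=[f"cond{i}" for i in range(len(rows))])

    def test_identical_proportions_not_significant(self):
        counts = self._counts([[10, 20], [10, 20]])
        p = ct.proportion_trend(counts, baseline="cond0")
        assert p["cond1"] >= 0.5

    def test_extreme_fisher_tail(self):
        """0/20 baseline vs 20/20: one-sided Fisher p is 1/C(40,20)."""
        counts = self._counts([[0, 20], [20, 20]])
        p = ct.proportion_trend(counts, baseline="cond0")
        assert p["cond1"] == pytest.approx(1.0 / comb(40, 20, exact=True), rel=1e-9)
        # cross-check against the hypergeometric tail directly
        assert p["cond1"] == pytest.approx(stats.hypergeom.sf(19, 40, 20, 20), rel=1e-9)

    def test_monotone_in_condition_successes(self):
        prev = 1.1
        for k in range(0, 21, 4):
            counts = self._counts([[5, 20], [k, 20]])
            p = ct.proportion_trend(counts, baseline="cond0")["cond1"]
            assert p <= prev + 1e-12
            prev = p

    def test_z_test_agrees_at_moderate_n(self):
        counts = self._counts([[10, 40], [25, 40]])
        pf = ct.proportion_trend(counts, baseline="cond0", test="fisher")["cond1"]
        pz = ct.proportion_trend(counts, baseline="cond0", test="two_proportion_z")["cond1"]
        assert abs(pf - pz) < 0.02

    def test_increasing_neuron_share_detected_in_cohort(self, default_cohort, qc_kept):
        """The planted age trend (more immature neurons later) is significant
        vs the E11.5 baseline."""
        _, counts, truth = default_cohort
        cells = truth.cells.loc[[c for c in qc_kept if truth.cells.loc[c, "population"]
                                 in ("progenitor", "neuron")]]
        grp = cells.assign(is_neuron=cells["population"] == "neuron").groupby(
            "condition", observed=True
        )
        tab = pd.DataFrame({"successes": grp["is_neuron"].sum(), "total": grp.size()})
        p = ct.proportion_trend(tab, baseline="E11.5")
        assert p["E15.5"] < 0.05 and p["E17.5"] < 0.05
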