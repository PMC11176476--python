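import numpy as np
import pandas as pd
import pytest

from recurcor import (
    ClassMap,
    ClassPValueMatrix,
    ValidationError,
    build_class_pvalue_matrix,
    build_dcscad,
    fraction_correlated_matrix,
    hierarchical_order,
    prune_to_complete,
)
from recurcor.annotation import ClassPair
from recurcor.cluster import export_heatmap, linkage_to_newick
from recurcor.correlation import PairCorrelation
from recurcor.enrichment import STATUS_TESTED, EnrichmentRecord


def _rec(key, p_fdr):
    return EnrichmentRecord(
        class_pair=ClassPair(key=key, same_class=False, contains_misc=False),
        k=2, n=10, K=3, N=60, p_raw=p_fdr / 2, p_fdr=p_fdr, status=STATUS_TESTED,
    )


class TestBuildMatrix:
    def test_all_pairs_tested(self):
        records = [_rec("A-B", 0.01), _rec("A-C", 0.2), _rec("B-C", 0.6)]
        m = build_class_pvalue_matrix(records, {"A-B", "A-C", "B-C"})
        assert m.classes == ["A", "B", "C"]
        assert not m.missing_mask.any()
        assert np.allclose(np.diag(m.values), 1.0)
        assert m.values[0, 1] == m.values[1, 0] == 0.01

    def test_background_only_pair_is_one_not_missing(self):
        m = build_class_pvalue_matrix([_rec("A-B", 0.01)], {"A-B", "A-C", "B-C"})
        assert m.values[1, 2] == 1.0 and not m.missing_mask[1, 2]

    def test_untested_pair_is_masked(self):
        m = build_class_pvalue_matrix([_rec("A-B", 0.01)], {"A-B", "A-C"})
        assert m.missing_mask[1, 2] and m.missing_mask[2, 1]
        assert m.n_missing_cells == 1


class TestPrune:
    def test_complete_matrix_is_noop(self):
        m = build_class_pvalue_matrix([_rec("A-B", 0.01)], {"A-B"})
        out = prune_to_complete(m)
        assert out.classes == m.classes

    def test_unique_offender_removed(self):
        # D is missing against everyone; A,B,C complete among themselves
        bg = {"A-B", "A-C", "B-C"}
        m = build_class_pvalue_matrix([_rec(k, 0.1) for k in bg], bg | {"A-D"})
        out = prune_to_complete(m)
        assert out.classes == ["A", "B", "C"]

    def test_each_step_reduces_missing_and_mask_empties(self, sim_result):
        pruned = sim_result.pruned
        assert not pruned.missing_mask.any()
        m = len(pruned.classes)
        assert pruned.n_class_pairs == m * (m - 1) // 2

    def test_manual_override_applied_first(self):
        bg = {"A-B", "A-C", "B-C", "A-D"}
        m = build_class_pvalue_matrix([_rec("A-B", 0.1)], bg)
        out = prune_to_complete(m, drop_classes=["D"])
        assert "D" not in out.classes

    def test_pruning_below_two_classes_is_error(self):
        m = build_class_pvalue_matrix([], {"A-B"})
        m.missing_mask[0, 1] = m.missing_mask[1, 0] = True
        with pytest.raises(ValidationError):
            prune_to_complete(m)


class TestHierarchicalOrder:
    def _matrix(self, values, classes):
        v = np.asarray(values, dtype=float)
        return ClassPValueMatrix(
            classes=classes, values=v, missing_mask=np.zeros_like(v, dtype=bool)
        )

    def test_identical_rows_merge_first_at_zero(self):
        m = self._matrix(
            [[1.0, 0.1, 0.9], [0.1, 1.0, 0.9], [0.9, 0.9, 1.0]], ["A", "B", "C"]
        )
        # A and B rows are permutations but not identical; craft identical rows
        m.values[0] = m.values[1] = [0.5, 0.5, 0.9]
        _, Z = hierarchical_order(m)
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_three_row_complete_linkage_oracle(self):
        # hand agglomeration on pairwise distances d(A,B)=1, d(A,C)=2,
        # d(B,C)=3: merge (A,B) at 1, then C at max(2,3)=3
        m = self._matrix(np.eye(3), ["A", "B", "C"])
        from scipy.cluster.hierarchy import linkage

        Z = linkage(np.array([1.0, 2.0, 3.0]), method="complete")
        assert Z[:, 2].tolist() == [1.0, 3.0]

    def test_permutation_invariance_of_leaf_order(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 1, (6, 6))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 1.0)
        classes = ["C1", "C2", "C3", "C4", "C5", "C6"]
        order1, _ = hierarchical_order(self._matrix(base, classes))
        perm = rng.permutation(6)
        order2, _ = hierarchical_order(
            self._matrix(base[np.ix_(perm, perm)], [classes[i] for i in perm])
        )
        assert order1 == order2

    def test_merge_heights_nondecreasing(self, sim_result):
        _, Z = hierarchical_order(sim_result.pruned)
        heights = Z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_missing_cells_rejected(self):
        m = self._matrix(np.eye(2), ["A", "B"])
        m.missing_mask[0, 1] = True
        with pytest.raises(ValidationError):
            hierarchical_order(m)


class TestFractionCorrelated:
    def _summaries(self):
        cors = [
            PairCorrelation(("a1", "b1"), "d1", 0.5, 12),
            PairCorrelation(("a1", "b1"), "d2", 0.4, 12),
            PairCorrelation(("a1", "b1"), "d3", 0.1, 12),
            PairCorrelation(("a2", "b1"), "d1", 0.02, 12),
            PairCorrelation(("a2", "b1"), "d2", 0.01, 12),
        ]
        return build_dcscad(cors)

    cm = ClassMap(assignments={"a1": "X", "a2": "X", "b1": "Y"})

    def test_fraction_and_qualifying_flag(self):
        frac, qual = fraction_correlated_matrix(
            self._summaries(), ["a1", "a2", "b1"], self.cm
        )
        assert frac.loc["a1", "b1"] == pytest.approx(2 / 3)
        assert bool(qual.loc["a1", "b1"])  # 0.667 > 0.66 qualifies
        assert not bool(qual.loc["a2", "b1"])

    def test_untested_and_same_class_unavailable(self):
        frac, _ = fraction_correlated_matrix(
            self._summaries(), ["a1", "a2", "b1"], self.cm
        )
        assert np.isnan(frac.loc["a1", "a2"])  # same class
        assert np.isnan(frac.loc["a1", "a1"])  # diagonal


class TestExport:
    def test_tsv_round_trip_and_determinism(self, tmp_path):
        records = [_rec("A-B", 0.01), _rec("A-C", 0.2), _rec("B-C", 0.6)]
        m = build_class_pvalue_matrix(records, {"A-B", "A-C", "B-C"})
        order, Z = hierarchical_order(m)
        out1 = export_heatmap(m, order, tmp_path / "h1")
        out2 = export_heatmap(m, order, tmp_path / "h2")
        t1 = (tmp_path / "h1.tsv").read_bytes()
        t2 = (tmp_path / "h2.tsv").read_bytes()
        assert t1 == t2
        df = pd.read_csv(tmp_path / "h1.tsv", sep="\t", index_col=0)
        assert list(df.index) == order
        assert (tmp_path / "h1.png").exists()
        nwk = linkage_to_newick(Z, m.classes)
        assert nwk.endswith(";") and "A" in nwk

    def test_masked_cell_sentinel(self, tmp_path):
        m = build_class_pvalue_matrix([_rec("A-B", 0.01)], {"A-B", "A-C"})
        export_heatmap(m, m.classes, tmp_path / "h")
        text = (tmp_path / "h.tsv").read_text()
        assert "NA" in text
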