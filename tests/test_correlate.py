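import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subtelomics.correlate import (
    hierarchical_order,
    marker_expression,
    pearson_with_marker,
    select_top_k,
)
from subtelomics.io import EXPRESSION, OmicsMatrix, ValidationError


def _matrix(rows, samples=None):
    rows = {k: np.asarray(v, float) for k, v in rows.items()}
    n = len(next(iter(rows.values())))
    samples = samples or [f"S{i}" for i in range(n)]
    return OmicsMatrix(EXPRESSION, pd.DataFrame(rows, index=samples).T)


class TestPearsonWithMarker:
    def test_perfect_correlations(self):
        marker = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"S{i}" for i in range(4)])
        m = _matrix({"same": [1, 2, 3, 4], "anti": [-1, -2, -3, -4]})
        res = pearson_with_marker(m, marker)
        assert res.loc["same", "r"] == pytest.approx(1.0)
        assert res.loc["anti", "r"] == pytest.approx(-1.0)
        assert res.loc["same", "p"] == 0.0

    def test_hand_computed_r(self):
        # x=(1,2,3), y=(1,2,4): r = 9/sqrt(84)
        marker = pd.Series([1.0, 2.0, 3.0], index=["S0", "S1", "S2"])
        res = pearson_with_marker(_matrix({"y": [1, 2, 4]}), marker)
        assert res.loc["y", "r"] == pytest.approx(9 / np.sqrt(84))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        marker = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
        vals = rng.normal(size=n)
        vals[rng.choice(n, 5, replace=False)] = np.nan
        res = pearson_with_marker(_matrix({"probe": vals}), marker)
        keep = ~np.isnan(vals)
        r_ref, p_ref = stats.pearsonr(vals[keep], marker.to_numpy()[keep])
        assert res.loc["probe", "r"] == pytest.approx(r_ref)
        assert res.loc["probe", "p"] == pytest.approx(p_ref, rel=1e-6)
        assert res.loc["probe", "n"] == keep.sum()

    def test_zero_variance_flagged(self):
        marker = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"S{i}" for i in range(4)])
        res = pearson_with_marker(_matrix({"flat": [5, 5, 5, 5]}), marker)
        assert not res.loc["flat", "usable"]
        assert np.isnan(res.loc["flat", "r"])

    def test_too_few_pairs_excluded(self):
        marker = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"S{i}" for i in range(4)])
        res = pearson_with_marker(_matrix({"sparse": [1, 2, np.nan, np.nan]}), marker)
        assert not res.loc["sparse", "usable"]

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        n = 20
        marker = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
        vals = rng.normal(size=n)
        base = pearson_with_marker(_matrix({"p": vals}), marker).loc["p", "r"]
        scaled = pearson_with_marker(_matrix({"p": 3 * vals + 10}), marker).loc["p", "r"]
        shifted_marker = pearson_with_marker(_matrix({"p": vals}), 0.5 * marker + 2).loc["p", "r"]
        assert scaled == pytest.approx(base)
        assert shifted_marker == pytest.approx(base)


class TestSelectTopK:
    @staticmethod
    def _results(r_values, ids=None):
        ids = ids or [f"P{i}" for i in range(len(r_values))]
        return pd.DataFrame(
            {"r": r_values, "p": 0.01, "n": 10, "usable": True},
            index=pd.Index(ids, name="probe_id"),
        )

    def test_basic_selection_and_threshold(self):
        sel = select_top_k(self._results([0.9, 0.8, 0.7]), k_pos=2, k_neg=2)
        assert sel.positive == ["P0", "P1"]
        assert sel.positive_threshold == pytest.approx(0.8)
        assert sel.negative == []

    def test_k_exceeding_available_returns_all(self):
        sel = select_top_k(self._results([0.5, 0.2, -0.1]), k_pos=10, k_neg=10)
        assert len(sel.positive) == 2 and len(sel.negative) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_full_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-1, 1, size=50).round(2)  # rounding creates ties
        res = self._results(r)
        sel = select_top_k(res, k_pos=10, k_neg=10)
        ranked_pos = sorted(res[res.r > 0].itertuples(), key=lambda t: (-t.r, t.Index))
        ranked_neg = sorted(res[res.r < 0].itertuples(), key=lambda t: (t.r, t.Index))
        assert sel.positive == [t.Index for t in ranked_pos[:10]]
        assert sel.negative == [t.Index for t in ranked_neg[:10]]

    def test_sets_disjoint_and_thresholds_bound_unselected(self):
        rng = np.random.default_rng(4)
        res = self._results(rng.uniform(-1, 1, size=40))
        sel = select_top_k(res, k_pos=5, k_neg=5)
        assert not set(sel.positive) & set(sel.negative)
        unselected_pos = res.loc[~res.index.isin(sel.positive) & (res.r > 0), "r"]
        assert (unselected_pos <= sel.positive_threshold).all()
        unselected_neg = res.loc[~res.index.isin(sel.negative) & (res.r < 0), "r"]
        assert (unselected_neg >= sel.negative_threshold).all()


class TestHierarchicalOrder:
    def test_identical_pair_merges_first(self):
        m = _matrix({"A": [1, 2, 3, 4], "B": [2, 4, 6, 8], "C": [4, 3, 2, 1]})
        # A and B are perfectly correlated (distance 0); they merge first
        ordering = hierarchical_order(m, axis="probes")
        ia, ib = ordering.leaf_order.index("A"), ordering.leaf_order.index("B")
        assert abs(ia - ib) == 1
        assert ordering.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_close_pair_adjacent(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        m = _matrix(
            {
                "A": base + rng.normal(0, 0.05, 12),
                "B": base + rng.normal(0, 0.05, 12),
                "C": rng.normal(size=12),
            }
        )
        order = hierarchical_order(m, axis="probes").leaf_order
        assert abs(order.index("A") - order.index("B")) == 1

    def test_heights_non_decreasing(self, expr_matrix):
        ordering = hierarchical_order(expr_matrix, axis="probes")
        assert (np.diff(ordering.heights) >= -1e-12).all()
        assert sorted(ordering.leaf_order) == sorted(expr_matrix.probe_ids)

    def test_reversal_symmetry_of_dendrogram_shape(self):
        # reversing input order must not change the nested cluster structure;
        # the drawn leaf order may differ only by branch flips within it
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(5, 10))
        ids = [f"P{i}" for i in range(5)]
        m1 = OmicsMatrix(EXPRESSION, pd.DataFrame(vals, index=ids))
        m2 = OmicsMatrix(EXPRESSION, pd.DataFrame(vals[::-1], index=ids[::-1]))
        o1 = hierarchical_order(m1, axis="probes")
        o2 = hierarchical_order(m2, axis="probes")
        assert o1.cluster_sets() == o2.cluster_sets()
        assert o1.heights == pytest.approx(o2.heights)

    def test_zero_variance_item_tolerated(self):
        m = _matrix({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1], "flat": [2, 2, 2, 2]})
        ordering = hierarchical_order(m, axis="probes")
        assert sorted(ordering.leaf_order) == ["A", "B", "flat"]

    def test_single_item_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_order(_matrix({"A": [1, 2, 3]}), axis="probes")


class TestMarkerExpression:
    def test_mean_over_marker_probes(self, default_cohort):
        marker = marker_expression(
            default_cohort.expression, default_cohort.annotation, default_cohort.truth.marker_gene
        )
        ann = default_cohort.annotation.table
        probes = ann.loc[
            (ann["gene"] == default_cohort.truth.marker_gene) & (ann["platform"] == "expression"),
            "probe_id",
        ]
        expected = default_cohort.expression.values.loc[probes].mean(axis=0)
        pd.testing.assert_series_equal(marker, expected, check_names=False)

    def test_unknown_marker_rejected(self, default_cohort):
        with pytest.raises(ValidationError):
            marker_expression(default_cohort.expression, default_cohort.annotation, "NOPE")
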