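import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from subtelomics.differential import (
    aggregate_probes_to_genes,
    classify_quadrant,
    differential_test,
    enrichment,
    fold_change,
    integrate,
    quadrant_composition,
)
from subtelomics.io import (
    EXPRESSION,
    GeneSetCollection,
    OmicsMatrix,
    ProbeAnnotation,
    ValidationError,
)
from subtelomics.reference import load_integration_reference


def _matrix(rows):
    return OmicsMatrix(EXPRESSION, pd.DataFrame(rows).T.astype(float))


def _labels(n_low, n_high):
    idx = [f"S{i}" for i in range(n_low + n_high)]
    return pd.Series(["low"] * n_low + ["high"] * n_high, index=idx)


class TestDifferentialTest:
    def test_identical_groups_not_significant(self):
        vals = {"P0": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}
        m = OmicsMatrix(EXPRESSION, pd.DataFrame(vals, index=[f"S{i}" for i in range(6)]).T)
        res = differential_test(m, _labels(3, 3))
        assert res.loc["P0", "fold_change"] == pytest.approx(1.0)
        assert res.loc["P0", "p"] == pytest.approx(1.0)
        assert not res.loc["P0", "significant"]

    def test_constant_equal_values_give_p_one(self):
        m = OmicsMatrix(
            EXPRESSION, pd.DataFrame({"P0": [2.0] * 6}, index=[f"S{i}" for i in range(6)]).T
        )
        res = differential_test(m, _labels(3, 3))
        assert res.loc["P0", "t"] == 0.0
        assert res.loc["P0", "p"] == 1.0

    def test_hand_computed_t(self):
        # low (1,2,3,4) vs high (3,4,5,6): t = -2.1909 on 6 df, p ~ 0.0710
        m = OmicsMatrix(
            EXPRESSION,
            pd.DataFrame({"P0": [1, 2, 3, 4, 3, 4, 5, 6]},
                         index=[f"S{i}" for i in range(8)], dtype=float).T,
        )
        res = differential_test(m, _labels(4, 4))
        assert res.loc["P0", "t"] == pytest.approx(-2.1909, abs=1e-4)
        assert res.loc["P0", "p"] == pytest.approx(0.0710, abs=1e-4)
        assert res.loc["P0", "mean_low"] == pytest.approx(2.5)
        assert res.loc["P0", "fold_change"] == pytest.approx(2.5 / 4.5)

    def test_welch_variant_differs_under_unequal_variance(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(0.5, 3.0, 10)])
        m = OmicsMatrix(
            EXPRESSION, pd.DataFrame({"P0": vals}, index=[f"S{i}" for i in range(20)]).T
        )
        labels = _labels(10, 10)
        student = differential_test(m, labels, equal_var=True).loc["P0", "p"]
        welch = differential_test(m, labels, equal_var=False).loc["P0", "p"]
        assert student != pytest.approx(welch, rel=1e-3)

    def test_group_entirely_missing_excluded(self):
        vals = pd.DataFrame(
            {"P0": [np.nan, np.nan, np.nan, 1, 2, 3], "P1": [1, 2, 3, 4, 5, 6]},
            index=[f"S{i}" for i in range(6)], dtype=float,
        ).T
        res = differential_test(OmicsMatrix(EXPRESSION, vals), _labels(3, 3))
        assert "P0" not in res.index and "P1" in res.index

    def test_probe_subset_respected(self, default_cohort):
        subset = list(default_cohort.methylation.probe_ids[:50])
        res = differential_test(default_cohort.methylation, default_cohort.truth.group,
                                probe_subset=subset)
        assert set(res.index) <= set(subset)


class TestFoldChange:
    @pytest.mark.parametrize(
        "mean_low,mean_high,expected",
        [(1.8678, 2.5767, 0.7249), (0.8874, 1.3309, 0.6668), (2.0, 2.0, 1.0)],
    )
    def test_values(self, mean_low, mean_high, expected):
        assert fold_change(mean_low, mean_high) == pytest.approx(expected, abs=5e-5)

    def test_zero_denominator_flagged(self):
        assert math.isnan(fold_change(1.0, 0.0))

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reciprocal_product_is_one(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


def _annotation(mapping):
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": list(mapping),
                "chromosome": "chr1",
                "position": 100,
                "gene": [mapping[p] for p in mapping],
                "platform": EXPRESSION,
            }
        )
    )


def _records(rows):
    df = pd.DataFrame(rows, columns=["probe_id", "mean_low", "mean_high", "p"]).set_index("probe_id")
    df["fold_change"] = df["mean_low"] / df["mean_high"]
    df["significant"] = True
    return df


class TestAggregation:
    def test_single_probe_identity(self):
        rec = _records([("P1", 0.2, 0.1, 0.001)])
        genes = aggregate_probes_to_genes(rec, _annotation({"P1": "G1"}), EXPRESSION)
        assert genes.loc["G1", "mean_low"] == 0.2
        assert genes.loc["G1", "fold_change"] == pytest.approx(2.0)
        assert genes.loc["G1", "n_probes"] == 1

    def test_two_probe_average(self):
        rec = _records([("P1", 0.2, 0.1, 0.002), ("P2", 0.4, 0.1, 0.001)])
        genes = aggregate_probes_to_genes(rec, _annotation({"P1": "G1", "P2": "G1"}), EXPRESSION)
        assert genes.loc["G1", "mean_low"] == pytest.approx(0.3)
        assert genes.loc["G1", "mean_high"] == pytest.approx(0.1)
        assert genes.loc["G1", "fold_change"] == pytest.approx(3.0)
        assert genes.loc["G1", "p"] == 0.001  # min probe p, summary only

    def test_unannotated_probes_dropped(self):
        rec = _records([("P1", 0.2, 0.1, 0.001), ("PX", 0.5, 0.1, 0.001)])
        ann = _annotation({"P1": "G1", "PX": None})
        genes = aggregate_probes_to_genes(rec, ann, EXPRESSION)
        assert list(genes.index) == ["G1"]

    def test_many_to_one_reduces_counts(self, default_cohort):
        # several probes per gene: gene-level records never outnumber probes
        labels = default_cohort.truth.group
        probes = differential_test(default_cohort.methylation, labels)
        sig = probes.loc[probes["significant"]]
        genes = aggregate_probes_to_genes(sig, default_cohort.annotation, "methylation")
        assert 0 < len(genes) <= len(sig)


class TestIntegrate:
    def test_reference_quadrants_all_hyper_down(self):
        ref = load_integration_reference()
        meth = ref[["meth_mean_low", "meth_mean_high", "meth_p"]].rename(
            columns=lambda c: c.replace("meth_", "")
        )
        expr = ref[["expr_mean_low", "expr_mean_high", "expr_p"]].rename(
            columns=lambda c: c.replace("expr_", "")
        )
        for df in (meth, expr):
            df["fold_change"] = df["mean_low"] / df["mean_high"]
        result = integrate(meth, expr)
        assert (result["quadrant"] == "hyper_down").all()
        assert result.loc["MGMT", "quadrant"] == "hyper_down"

    def test_disjoint_gene_lists_empty(self):
        a = _records([("P1", 0.2, 0.1, 0.01)]).set_index(pd.Index(["G1"], name="gene"))
        b = _records([("P2", 0.2, 0.1, 0.01)]).set_index(pd.Index(["G2"], name="gene"))
        assert len(integrate(a, b)) == 0

    def test_fold_change_one_excluded(self):
        meth = pd.DataFrame(
            {"mean_low": [0.2], "mean_high": [0.2], "fold_change": [1.0], "p": [0.001]},
            index=pd.Index(["G1"], name="gene"),
        )
        expr = pd.DataFrame(
            {"mean_low": [1.0], "mean_high": [2.0], "fold_change": [0.5], "p": [0.001]},
            index=pd.Index(["G1"], name="gene"),
        )
        res = integrate(meth, expr)
        assert res.loc["G1", "excluded"]
        assert res.loc["G1", "quadrant"] is None

    @pytest.mark.parametrize(
        "expr_fc,meth_fc,expected",
        [
            (0.7, 1.6, "hyper_down"),
            (1.3, 1.6, "hyper_up"),
            (0.7, 0.6, "hypo_down"),
            (1.3, 0.6, "hypo_up"),
            (1.0, 1.6, None),
        ],
    )
    def test_classify_quadrant(self, expr_fc, meth_fc, expected):
        assert classify_quadrant(expr_fc, meth_fc) == expected

    def test_composition_summary(self):
        integ = pd.DataFrame(
            {
                "quadrant": ["hyper_down", "hyper_down", "hyper_up", "hypo_down", None],
                "excluded": [False, False, False, False, True],
            },
            index=pd.Index(list("ABCDE"), name="gene"),
        )
        comp = quadrant_composition(integ)
        assert comp["n_concurrent"] == 4
        assert comp["n_hypermethylated"] == 3
        assert comp["pct_hypermethylated"] == pytest.approx(75.0)
        assert comp["pct_hyper_downregulated"] == pytest.approx(100.0 * 2 / 3)


class TestEnrichment:
    BACKGROUND = {f"G{i}" for i in range(10)}

    def test_exact_combinatorial_p(self):
        # N=10, K=2, n=2, k=2: p = C(2,2) C(8,0) / C(10,2) = 1/45
        sets = GeneSetCollection({"term": {"G0", "G1"}})
        res = enrichment({"G0", "G1"}, sets, self.BACKGROUND)
        assert res.loc["term", "p"] == pytest.approx(1 / 45)

    def test_disjoint_term_p_one(self):
        sets = GeneSetCollection({"term": {"G8", "G9"}})
        res = enrichment({"G0", "G1"}, sets, self.BACKGROUND)
        assert res.loc["term", "k"] == 0
        assert res.loc["term", "p"] == pytest.approx(1.0)

    def test_query_equals_background_saturates(self):
        sets = GeneSetCollection({"t1": {"G0", "G1"}, "t2": {"G5"}})
        res = enrichment(set(self.BACKGROUND), sets, self.BACKGROUND)
        assert res["p"].tolist() == pytest.approx([1.0] * len(res))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exact_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        term = set(rng.choice(sorted(self.BACKGROUND), 4, replace=False))
        query = set(rng.choice(sorted(self.BACKGROUND), 5, replace=False))
        res = enrichment(query, GeneSetCollection({"t": term}), self.BACKGROUND)
        k, K, n, N = len(term & query), len(term), len(query), len(self.BACKGROUND)
        p_exact = sum(
            comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
            for j in range(k, min(K, n) + 1)
        ) / comb(N, n, exact=True)
        assert res.loc["t", "p"] == pytest.approx(p_exact)

    def test_bh_preserves_p_order(self):
        rng = np.random.default_rng(7)
        bg = {f"G{i}" for i in range(50)}
        sets = {
            f"t{j}": set(rng.choice(sorted(bg), rng.integers(3, 10), replace=False))
            for j in range(8)
        }
        query = set(rng.choice(sorted(bg), 12, replace=False))
        res = enrichment(query, GeneSetCollection(sets), bg)
        by_p = res.sort_values("p")
        assert (np.diff(by_p["p_adj"].to_numpy()) >= -1e-12).all()
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            enrichment({"NOPE"}, GeneSetCollection({"t": {"G0"}}), self.BACKGROUND)

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            enrichment(set(), GeneSetCollection({"t": {"G0"}}), self.BACKGROUND)
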