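"""NB testing, FDR, classification, leaky calls, overlap and correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recseq.differential import (
    bh_fdr,
    classify,
    filter_by_depth,
    leaky_scanning_calls,
    nb_test,
    overlap_test,
    ratio_change_test,
    reciprocal_uaug_calls,
    spearman,
)


def nb_counts(rng, mu, alpha, n_reps):
    size = 1 / alpha
    return np.column_stack(
        [rng.negative_binomial(size, size / (size + mu)) for _ in range(n_reps)]
    )


class TestDepthFilter:
    def test_strict_boundary(self):
        counts = pd.DataFrame({"s1": [45, 46], "s2": [45, 45]}, index=["a", "b"])
        assert list(filter_by_depth(counts, 90, ">")) == ["b"]

    def test_gte_boundary(self):
        counts = pd.DataFrame({"s1": [7, 8]}, index=["a", "b"])
        assert list(filter_by_depth(counts, 8, ">=")) == ["b"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 40, size=(200, 4)))
        kept = set(filter_by_depth(counts, 50, ">"))
        brute = {i for i in counts.index if counts.loc[i].sum() > 50}
        assert kept == brute


class TestNbTest:
    def test_identical_counts_null(self):
        counts = pd.DataFrame([[10, 12, 11], [100, 90, 110]])
        res = nb_test(counts, counts.copy())
        assert np.allclose(res["log2FoldChange"], 0.0)
        assert (res["pvalue"].dropna() >= 0.99).all()

    def test_planted_fourfold_change_recovered(self):
        rng = np.random.default_rng(21)
        mu = rng.lognormal(np.log(100), 1.0, 2000)
        alpha = np.full(2000, 0.05)
        A = nb_counts(rng, mu, alpha, 3)
        B = nb_counts(rng, mu * 4, alpha, 3)
        res = nb_test(A, B)
        assert 1.8 <= np.median(res["log2FoldChange"]) <= 2.2

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(22)
        mu = rng.lognormal(np.log(100), 1.0, 2000)
        alpha = rng.gamma(4, 0.05 / 4, 2000)
        res = nb_test(nb_counts(rng, mu, alpha, 3), nb_counts(rng, mu, alpha, 3))
        frac = (res["pvalue"].dropna() < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(23)
        A = nb_counts(rng, np.full(50, 80.0), np.full(50, 0.05), 3)
        B = nb_counts(rng, np.full(50, 160.0), np.full(50, 0.05), 3)
        fwd = nb_test(A, B)
        rev = nb_test(B, A)
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"])
        assert np.allclose(fwd["pvalue"].dropna(), rev["pvalue"].dropna())

    def test_all_zero_gene_gets_no_pvalue(self):
        counts = pd.DataFrame([[0, 0, 0], [5, 6, 7]])
        res = nb_test(counts, counts.copy())
        assert np.isnan(res.loc[0, "pvalue"])
        assert np.isfinite(res.loc[1, "pvalue"])

    def test_size_factors_absorb_depth_difference(self):
        rng = np.random.default_rng(24)
        mu = np.full(500, 100.0)
        alpha = np.full(500, 0.02)
        A = nb_counts(rng, mu, alpha, 3)
        B = nb_counts(rng, mu * 2, alpha, 3)  # doubled depth, no biology
        res = nb_test(A, B, size_factors_a=[1, 1, 1], size_factors_b=[2, 2, 2])
        assert abs(np.median(res["log2FoldChange"])) < 0.1
        assert (res["pvalue"] < 0.05).mean() < 0.08

    def test_agrees_with_pydeseq2_on_planted_effects(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(25)
        n = 300
        mu = rng.lognormal(np.log(120), 0.8, n)
        alpha = np.full(n, 0.05)
        fc = np.ones(n)
        fc[:100] = 4.0
        fc[100:150] = 0.25
        A = nb_counts(rng, mu, alpha, 3)
        B = nb_counts(rng, mu * fc, alpha, 3)
        mine = nb_test(A, B)

        counts = pd.DataFrame(
            np.hstack([A, B]).T, index=[f"s{i}" for i in range(6)],
            columns=[f"g{i}" for i in range(n)],
        )
        meta = pd.DataFrame(
            {"condition": ["A"] * 3 + ["B"] * 3}, index=counts.index
        )
        dds = DeseqDataSet(counts=counts, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        theirs = ds.results_df["log2FoldChange"].to_numpy()
        # same estimand: log2 fold changes agree tightly gene by gene
        assert np.corrcoef(mine["log2FoldChange"], theirs)[0, 1] > 0.98
        assert abs(np.median(mine["log2FoldChange"][:100]) - 2.0) < 0.25


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p).all()

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestClassify:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (1.5, 0.01, "up"),
            (1.5, 0.2, "ns"),
            (-1.01, 0.049, "down"),
            (0.5, 0.001, "ns"),   # significant but below 2-fold
            (-0.9, 0.01, "ns"),
            (3.0, 0.05, "ns"),    # FDR boundary is strict
        ],
    )
    def test_rule(self, lfc, fdr, expected):
        assert classify([lfc], [fdr])[0] == expected

    def test_invariant_classes_imply_fold_changes(self):
        rng = np.random.default_rng(2)
        lfc = rng.normal(0, 2, 500)
        fdr = rng.uniform(0, 0.2, 500)
        cls = classify(lfc, fdr)
        assert (lfc[cls == "up"] > 1).all()
        assert (lfc[cls == "down"] < -1).all()


class TestLeakyCalls:
    @staticmethod
    def _diff(classes):
        return pd.DataFrame({"class": classes})

    def test_reciprocity_boundary(self):
        diff_m = self._diff(pd.Series({"a": "down", "b": "down"}))
        diff_i = self._diff(pd.Series({"a": "up", "b": "up"}))
        delta_m = pd.Series({"a": -100.0, "b": -100.0})
        delta_i = pd.Series({"a": 60.0, "b": 49.0})
        calls = leaky_scanning_calls(diff_m, diff_i, delta_m, delta_i)
        assert bool(calls.loc["a", "leaky"]) is True
        assert bool(calls.loc["b", "leaky"]) is False

    def test_requires_both_significance_calls(self):
        diff_m = self._diff(pd.Series({"a": "down"}))
        diff_i = self._diff(pd.Series({"a": "ns"}))
        calls = leaky_scanning_calls(
            diff_m, diff_i, pd.Series({"a": -100.0}), pd.Series({"a": 80.0})
        )
        assert not calls["leaky"].any()

    def test_reciprocal_uaug_rule(self):
        diff_u = self._diff(pd.Series({"a": "down", "b": "down"}))
        diff_m = self._diff(pd.Series({"a": "up", "b": "up"}))
        delta_u = pd.Series({"a": -60.0, "b": -20.0})
        delta_m = pd.Series({"a": 100.0, "b": 100.0})
        calls = reciprocal_uaug_calls(diff_u, diff_m, delta_u, delta_m)
        assert bool(calls.loc["a", "reciprocal"]) is True
        assert bool(calls.loc["b", "reciprocal"]) is False


class TestOverlap:
    def test_exhaustive_enumeration_case(self):
        # universe 10, two sets of 5, complete overlap: p = 1/C(10,5) = 1/252
        res = overlap_test(set(range(5)), set(range(5)), 10)
        assert res.overlap == 5
        assert res.p_value == pytest.approx(1 / 252)
        # enumeration oracle: count 5-subsets containing all of set1
        total = math.comb(10, 5)
        hits = sum(
            1 for combo in itertools.combinations(range(10), 5)
            if len(set(combo) & set(range(5))) >= 5
        )
        assert res.p_value == pytest.approx(hits / total)

    def test_disjoint_sets(self):
        res = overlap_test({0, 1}, {2, 3}, 10)
        assert res.overlap == 0
        assert res.p_value == pytest.approx(1.0)

    def test_set2_equals_universe(self):
        res = overlap_test({0, 1, 2}, set(range(10)), 10)
        assert res.overlap == 3
        assert res.representation_factor == pytest.approx(1.0)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(set(range(11)), {0}, 10)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=20).astype(float)
        y = rng.integers(0, 5, size=20).astype(float)
        rho = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle)

    def test_constant_vector_absent(self):
        assert np.isnan(spearman([1, 1, 1, 1], [1, 2, 3, 4]))


class TestRatioChangeTest:
    def test_consistent_shift_is_significant(self):
        a = np.array([1.0, 1.1, 0.9] * 2)
        b = a * 4
        est, p = ratio_change_test(a, b, seed=0)
        assert est == pytest.approx(2.0, abs=0.01)
        assert p < 0.01

    def test_no_change_is_not_significant(self):
        rng = np.random.default_rng(5)
        a = rng.lognormal(0, 0.1, 6)
        b = a * rng.lognormal(0, 0.2, 6)  # symmetric noise, no shift
        _, p = ratio_change_test(a, b, seed=1)
        assert p > 0.1

    def test_insufficient_data_absent(self):
        est, p = ratio_change_test([1.0], [2.0], seed=0)
        assert np.isnan(p)
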