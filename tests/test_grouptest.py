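"""Rank-sum machinery, BH, category/module statistics, list overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailfrac import grouptest
from tailfrac.errors import ConfigError, DataValidationError
from tailfrac.formats import CategoryMap


class TestWilcoxonRankSum:
    def test_exact_enumeration_small_sample(self):
        # all C(4,2)=6 rank splits: only {1,2} attains W=3 and only {3,4}
        # attains W=7 -> two-sided p = 2/6
        res = grouptest.wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_identical_multisets_give_p_one(self):
        res = grouptest.wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_strong_separation_agrees_with_reference_implementation(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        res = grouptest.wilcoxon_rank_sum(x, y)
        assert res.p_value < 1e-10
        ref = mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic").pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(DataValidationError):
            grouptest.wilcoxon_rank_sum([], [1.0])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30),
           st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetric_in_groups(self, x, y):
        a = grouptest.wilcoxon_rank_sum(x, y).p_value
        b = grouptest.wilcoxon_rank_sum(y, x).p_value
        assert a == pytest.approx(b, rel=1e-12)

    def test_exact_and_approximate_agree_for_ten_vs_ten(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.3, 1, 10)
            approx = grouptest.wilcoxon_rank_sum(x, y)
            assert approx.method == "approx"
            exact = mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
            assert abs(approx.p_value - exact) < 0.02

    def test_sweep_path_equals_single_test(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=300)
        masks = np.zeros((3, 300), dtype=bool)
        for i in range(3):
            masks[i, rng.choice(300, 40, replace=False)] = True
        sweep_p = grouptest.rank_sum_sweep(values, masks)
        for i in range(3):
            single = grouptest.wilcoxon_rank_sum(values[masks[i]],
                                                 values[~masks[i]])
            assert sweep_p[i] == pytest.approx(single.p_value, rel=1e-12)


class TestBenjaminiHochberg:
    def test_direct_formula_with_cummin(self):
        out = grouptest.benjamini_hochberg([0.01, 0.02, 0.03])
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_single_and_constant_vectors_unchanged(self):
        assert grouptest.benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(grouptest.benjamini_hochberg([0.4] * 5),
                                   0.4)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        ours = grouptest.benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_nan_passthrough_excluded_from_m(self):
        p = [0.01, np.nan, 0.02]
        out = grouptest.benjamini_hochberg(p)
        assert np.isnan(out[1])
        np.testing.assert_allclose([out[0], out[2]],
                                   grouptest.benjamini_hochberg([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            grouptest.benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, p):
        out = grouptest.benjamini_hochberg(p)
        assert np.all(out <= 1.0) and np.all(out >= np.asarray(p))


def _random_categories(rng, genes, n_cats, size_range=(10, 60)):
    rows = []
    for c in range(n_cats):
        size = int(rng.integers(*size_range))
        for g in rng.choice(genes, size=size, replace=False):
            rows.append({"category": f"c{c}", "name": f"cat {c}", "gene": g})
    return CategoryMap(pd.DataFrame(rows))


class TestCategorySweep:
    def test_planted_category_detected_with_correct_median(self):
        rng = np.random.default_rng(4)
        genes = np.array([f"g{i}" for i in range(5050)])
        values = pd.Series(rng.normal(0, 0.5, 5050), index=genes)
        planted = genes[:50]
        values[planted] -= 1.0
        cm = CategoryMap(pd.DataFrame(
            [{"category": "hit", "name": "planted", "gene": g} for g in planted]
            + [{"category": "null", "name": "random", "gene": g}
               for g in rng.choice(genes[50:], 50, replace=False)]))
        res = grouptest.category_sweep(values, cm)
        hit = res[res.category == "hit"].iloc[0]
        assert hit.p_value < 1e-6
        assert hit.median_log2FC == pytest.approx(-1.0, abs=0.3)

    def test_small_categories_skipped(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(100)]
        values = pd.Series(rng.normal(size=100), index=genes)
        cm = CategoryMap(pd.DataFrame(
            [{"category": "tiny", "name": "four genes", "gene": g}
             for g in genes[:4]]
            + [{"category": "ok", "name": "ten genes", "gene": g}
               for g in genes[4:14]]))
        res = grouptest.category_sweep(values, cm, min_size=5)
        assert set(res.category) == {"ok"}

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(200)]
        values = pd.Series(rng.normal(size=200), index=genes)
        cm = _random_categories(rng, np.array(genes), 5)
        a = grouptest.category_sweep(values, cm)
        perm = values.sample(frac=1.0, random_state=1)
        b = grouptest.category_sweep(perm, cm)
        pd.testing.assert_frame_equal(a, b)


class TestModuleCompare:
    def test_planted_module_ranks_first_in_most_simulations(self):
        # one module shifted by -0.5 among 60 null modules of the same size
        rng = np.random.default_rng(7)
        n_hits = 0
        n_runs = 200
        for _ in range(n_runs):
            # per-gene noise SD 0.5 (typical log2FC estimate noise) and 100
            # genes per module keep the median's sampling error (~0.06) well
            # below the planted shift
            n_mod, size = 61, 100
            values = rng.normal(0, 0.5, n_mod * size + 1000)
            values[:size] -= 0.5
            genes = [f"g{i}" for i in range(len(values))]
            assign = pd.Series(
                {g: f"m{i // size}" for i, g in enumerate(genes[: n_mod * size])})
            table, _ = grouptest.module_cdf_compare(
                pd.Series(values, index=genes), assign)
            if table.iloc[0]["module"] == "m0":
                n_hits += 1
        assert n_hits / n_runs >= 0.95

    def test_background_copy_ranks_last(self):
        rng = np.random.default_rng(8)
        background = rng.normal(0, 1, 3000)
        module = rng.normal(0, 1, 300)       # same distribution
        shifted = rng.normal(2, 1, 300)
        values = pd.Series(np.concatenate([background, module, shifted]),
                           index=[f"g{i}" for i in range(3600)])
        assign = pd.Series(
            {f"g{3000 + i}": "copy" for i in range(300)}
            | {f"g{3300 + i}": "shifted" for i in range(300)})
        table, ecdfs = grouptest.module_cdf_compare(values, assign)
        assert table.iloc[-1]["module"] == "copy"
        assert abs(table[table.module == "copy"].iloc[0].median_difference) < 0.2

    def test_ecdfs_are_valid_distribution_functions(self):
        rng = np.random.default_rng(9)
        values = pd.Series(rng.normal(size=500),
                           index=[f"g{i}" for i in range(500)])
        assign = pd.Series({f"g{i}": "m" for i in range(100)})
        _, ecdfs = grouptest.module_cdf_compare(values, assign)
        for curves in ecdfs.values():
            for x, y in curves.values():
                assert np.all(np.diff(y) >= 0)
                assert y[0] > 0 and y[-1] == pytest.approx(1.0)

    def test_all_gene_module_rejected(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        assign = pd.Series({"a": "m", "b": "m"})
        with pytest.raises(DataValidationError):
            grouptest.module_cdf_compare(values, assign)


def _hypergeom_tail_enumeration(universe, n_query, n_ref, k):
    """P[X >= k] by direct combinatorial enumeration."""
    total = math.comb(universe, n_ref)
    acc = 0
    for j in range(k, min(n_query, n_ref) + 1):
        acc += math.comb(n_query, j) * math.comb(universe - n_query, n_ref - j)
    return acc / total


class TestListOverlap:
    def test_identity_overlap_is_maximal(self):
        query = [f"g{i}" for i in range(5)]
        res = grouptest.list_overlap(query, {"self": query}, universe_size=50)
        assert res.iloc[0].overlap == 5

    def test_disjoint_lists_overlap_zero(self):
        res = grouptest.list_overlap(["a", "b"], {"other": ["c", "d"]},
                                     universe_size=10)
        assert res.iloc[0].overlap == 0
        assert res.iloc[0].p_value == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration(self):
        universe = [f"u{i}" for i in range(20)]
        query = universe[:5]
        ref = universe[2:7]       # overlap 3
        res = grouptest.list_overlap(query, {"r": ref}, universe_size=20)
        assert res.iloc[0].overlap == 3
        expected = _hypergeom_tail_enumeration(20, 5, 5, 3)
        assert res.iloc[0].p_value == pytest.approx(expected, rel=1e-12)

    def test_hypergeometric_pmf_sums_to_one(self):
        from scipy.stats import hypergeom
        pmf = hypergeom.pmf(np.arange(0, 6), 20, 5, 5)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicates_rejected(self):
        with pytest.raises(DataValidationError):
            grouptest.list_overlap(["a", "a"], {"r": ["b"]}, universe_size=10)

    def test_top_fraction_rounds_up(self):
        df = pd.DataFrame({"reference": [f"r{i}" for i in range(10)],
                           "overlap": range(10, 0, -1),
                           "p_value": np.linspace(0, 1, 10)})
        assert len(grouptest.top_fraction(df, 0.25)) == 3  # ceil(2.5)
        with pytest.raises(ConfigError):
            grouptest.top_fraction(df, 0.0)
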