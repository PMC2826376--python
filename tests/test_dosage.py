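"""Per-copy summaries, KS comparisons, fixed-fold estimation and the
variance test, each against enumeration or brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dosekit as dk
from dosekit.dosage import (ks_compare, moving_average_trend, rnai_effect,
                            summarize_by_copy, variance_ratio_test)


def brute_force_ks(a, b):
    """Max |ECDF_a - ECDF_b| over every observed value (double loop)."""
    best = 0.0
    for v in list(a) + list(b):
        fa = sum(1 for x in a if x <= v) / len(a)
        fb = sum(1 for x in b if x <= v) / len(b)
        best = max(best, abs(fa - fb))
    return best


def expr_table(values, arms=None, is_x=None, expressed=True):
    n = len(values)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "arm": arms if arms is not None else ["2L"] * n,
        "is_x": is_x if is_x is not None else [False] * n,
        "mean_rpkm": values,
        "expressed": [expressed] * n,
    })


def copy_table(copies, excluded=None):
    n = len(copies)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "copy": pd.array(copies, dtype="Int64"),
        "excluded": excluded if excluded is not None else [False] * n,
    })


class TestSummarize:
    def test_toy_medians_match_hand_computation(self):
        # 6 genes: autosome copy 2 {10, 20, 30}, X copy 1 {8, 12}, X copy 2 {40}
        expr = expr_table([10, 20, 30, 8, 12, 40],
                          is_x=[False] * 3 + [True] * 3)
        copies = copy_table([2, 2, 2, 1, 1, 2])
        out = summarize_by_copy(expr, copies).set_index(["class", "copy"])
        assert out.loc[("autosome", 2), "median_rpkm"] == 20
        assert out.loc[("autosome", 2), "median_per_copy"] == 10
        assert out.loc[("X", 1), "median_rpkm"] == 10
        assert out.loc[("X", 2), "median_rpkm"] == 40
        assert out.loc[("X", 2), "n_genes"] == 1

    def test_excluded_and_nonexpressed_genes_dropped(self):
        expr = expr_table([10, 20, 30])
        expr.loc[2, "expressed"] = False
        copies = copy_table([2, 2, 2], excluded=[False, True, False])
        out = summarize_by_copy(expr, copies)
        assert out["n_genes"].sum() == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(3, 1, 50)
        copies_arr = rng.integers(1, 6, 50)
        expr = expr_table(values)
        copies = copy_table(copies_arr)
        out1 = summarize_by_copy(expr, copies)
        perm = rng.permutation(50)
        out2 = summarize_by_copy(expr.iloc[perm].reset_index(drop=True),
                                 copies)
        pd.testing.assert_frame_equal(out1, out2)

    def test_per_copy_expression_decreases_with_copy(self):
        cfg = dk.SimulationConfig(expression_noise_cv=0.0,
                                  baseline_expression_log_sd=0.0,
                                  spanning_gene_fraction=0.0)
        genome = dk.simulate_genome(cfg, seed=13)
        table = dk.simulate_expression(genome, cfg, "mock", seed=13)
        table["expressed"] = True
        copies = genome.genes[["gene_id"]].copy()
        copies["copy"] = genome.genes["true_copy"]
        copies["excluded"] = genome.genes["spanning"]
        out = summarize_by_copy(table, copies)
        for cls, grp in out.groupby("class"):
            grp = grp.sort_values("copy")
            assert grp["median_per_copy"].is_monotonic_decreasing


class TestKs:
    def test_identical_samples(self):
        d, p = ks_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        with pytest.warns(UserWarning):
            d, _ = ks_compare([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_toy_matches_brute_force(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        with pytest.warns(UserWarning):
            d, _ = ks_compare(a, b)
        assert d == pytest.approx(brute_force_ks(a, b))

    @given(st.lists(st.integers(0, 4), min_size=5, max_size=8),
           st.lists(st.integers(0, 4), min_size=5, max_size=8))
    def test_matches_brute_force_on_small_samples(self, a, b):
        d, _ = ks_compare(a, b)
        assert d == pytest.approx(brute_force_ks(a, b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestRnaiEffect:
    def _tables(self, multiplier, noise_cv, seed=17, n_x=600, n_a=600):
        cfg = dk.SimulationConfig(
            arm_specs=[dk.ArmSpec("2L", 300, n_genes=n_a),
                       dk.ArmSpec("X", 300, is_x=True, n_genes=n_x)],
            min_segment_kb=30, max_segment_kb=60,
            msl_multiplier=multiplier, expression_noise_cv=noise_cv)
        genome = dk.simulate_genome(cfg, seed=seed)
        mock = dk.simulate_expression(genome, cfg, "mock", seed=seed)
        rnai = dk.simulate_expression(genome, cfg, "msl2_rnai", seed=seed)
        mock["expressed"] = True
        copies = genome.genes[["gene_id"]].copy()
        copies["copy"] = genome.genes["true_copy"]
        copies["excluded"] = genome.genes["spanning"]
        return mock, rnai, copies

    def test_noise_free_ratio_is_exact_reciprocal(self):
        mock, rnai, copies = self._tables(1.35, 0.0)
        cmp_res = rnai_effect(rnai, mock, copies)
        assert cmp_res.median_ratio["X"] == pytest.approx(1 / 1.35)
        assert cmp_res.median_ratio["autosome"] == pytest.approx(1.0)
        assert cmp_res.msl_fold == pytest.approx(1.35)
        # Fixed fold: per-copy X medians identical (dose independence).
        x_medians = cmp_res.per_copy.query("`class` == 'X'")["median_ratio"]
        assert x_medians.max() - x_medians.min() < 1e-12

    def test_null_multiplier_gives_unit_ratios(self):
        mock, rnai, copies = self._tables(1.0, 0.3)
        cmp_res = rnai_effect(rnai, mock, copies)
        assert cmp_res.median_ratio["X"] == pytest.approx(1.0, abs=0.05)
        assert cmp_res.median_ratio["autosome"] == pytest.approx(1.0, abs=0.05)

    def test_per_copy_medians_agree_with_noise(self):
        mock, rnai, copies = self._tables(1.35, 0.3, n_x=3000)
        cmp_res = rnai_effect(rnai, mock, copies)
        x = cmp_res.per_copy.query("`class` == 'X'")["median_ratio"]
        assert x.max() - x.min() < 0.08

    def test_mock_expression_filter_enforced(self):
        mock, rnai, copies = self._tables(1.35, 0.0)
        mock.loc[0, "mean_rpkm"] = 0.0
        with pytest.raises(ValueError):
            rnai_effect(rnai, mock, copies)


class TestMovingAverage:
    def test_constant_ratios_give_constant_trend(self):
        out = moving_average_trend(np.full(30, 0.74), np.arange(30))
        np.testing.assert_allclose(out["mean_ratio"], 0.74)

    def test_enumeration_40_genes(self):
        rng = np.random.default_rng(0)
        ratios = rng.uniform(0.5, 1.5, 40)
        expr = np.arange(40, dtype=float)
        out = moving_average_trend(ratios, expr, window=20)
        assert len(out) == 21
        for i in range(21):
            assert out["mean_ratio"].iloc[i] == pytest.approx(
                ratios[i:i + 20].mean())
            assert out["median_expression"].iloc[i] == pytest.approx(
                np.median(expr[i:i + 20]))

    def test_fewer_genes_than_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average_trend(np.ones(10), np.arange(10), window=20)

    def test_fixed_fold_trend_is_flat_across_expression(self):
        rng = np.random.default_rng(3)
        mock = rng.lognormal(3.5, 1.0, 2000)
        ratios = (1 / 1.35) * rng.lognormal(0, 0.2, 2000)
        out = moving_average_trend(ratios, mock)
        # No expression-level dependence of the knockdown effect.
        lo = out["mean_ratio"].iloc[: len(out) // 4].mean()
        hi = out["mean_ratio"].iloc[-len(out) // 4:].mean()
        assert lo == pytest.approx(hi, rel=0.05)


class TestVarianceRatio:
    def test_identical_samples_give_unit_f(self):
        s = [0.5, 0.8, 1.1, 1.4]
        f, p = variance_ratio_test(s, s)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_toy_variances_on_natural_scale(self):
        a = [0.0, 2.0, 4.0]   # variance 4
        b = [0.0, 1.0, 2.0]   # variance 1
        f, _ = variance_ratio_test(a, b, log=False)
        assert f == pytest.approx(4.0)

    def test_log_f_invariant_to_group_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 0.4, 80)
        a = rng.lognormal(0, 0.2, 80)
        f1, _ = variance_ratio_test(x, a)
        f2, _ = variance_ratio_test(7.7 * x, a)
        assert f1 == pytest.approx(f2)

    def test_dose_responsive_jitter_raises_variance(self):
        rng = np.random.default_rng(6)
        a = rng.lognormal(0, 0.15, 500)                  # fixed-fold only
        x = rng.lognormal(0, 0.15, 500) * rng.uniform(0.8, 1.25, 500)
        f, p = variance_ratio_test(x, a)
        assert f > 1.0
        assert p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio_test([1.0, 1.0], [1.0, 2.0])
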