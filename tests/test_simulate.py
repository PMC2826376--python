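"""Generator tests: ground-truth structure, seeded determinism, and the
statistical calibrations every downstream stage relies on."""

import numpy as np
import pandas as pd
import pytest

import dosekit as dk
from dosekit.simulate import (aneuploid_fraction, effective_per_copy_unit,
                              saturating_response, simulate_intergenic)

from conftest import make_genome


class TestGenome:
    def test_euploid_when_fractions_zero(self, flat_config):
        genome = dk.simulate_genome(flat_config, seed=3)
        g = genome.genes
        assert (g.loc[~g["is_x"], "true_copy"] == 4).all()
        assert (g.loc[g["is_x"], "true_copy"] == 2).all()
        assert len(genome.segments) == 2  # one segment per arm

    def test_aneuploid_fraction_matches_config(self):
        cfg = dk.SimulationConfig()
        genome = dk.simulate_genome(cfg, seed=7)
        assert aneuploid_fraction(genome, cfg) == pytest.approx(0.42, abs=0.03)
        assert aneuploid_fraction(genome, cfg, x=True) == pytest.approx(
            0.17, abs=0.03)

    def test_segments_partition_each_arm(self):
        cfg = dk.SimulationConfig()
        genome = dk.simulate_genome(cfg, seed=5)
        for arm in cfg.arm_specs:
            seg = genome.segments[genome.segments["arm"] == arm.name] \
                .sort_values("start")
            assert seg["start"].iloc[0] == 0
            assert seg["end"].iloc[-1] == arm.length_kb
            assert (seg["end"].to_numpy()[:-1]
                    == seg["start"].to_numpy()[1:]).all()

    def test_every_permitted_copy_class_is_populated(self):
        cfg = dk.SimulationConfig()
        genome = dk.simulate_genome(cfg, seed=9)
        copies = set(genome.segments["copy"])
        assert {1, 2, 3, 4, 5} <= copies

    def test_seed_determinism(self):
        cfg = dk.SimulationConfig()
        a = dk.simulate_genome(cfg, seed=42)
        b = dk.simulate_genome(cfg, seed=42)
        pd.testing.assert_frame_equal(a.segments, b.segments)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        wa = dk.simulate_dna_windows(a, cfg, seed=42)
        wb = dk.simulate_dna_windows(b, cfg, seed=42)
        pd.testing.assert_frame_equal(wa.windows, wb.windows)
        ea = dk.simulate_expression(a, cfg, "mock", seed=42)
        eb = dk.simulate_expression(b, cfg, "mock", seed=42)
        pd.testing.assert_frame_equal(ea, eb)
        np.testing.assert_array_equal(simulate_intergenic(a, cfg, seed=42),
                                      simulate_intergenic(b, cfg, seed=42))

    def test_spanning_genes_are_injected(self):
        cfg = dk.SimulationConfig(spanning_gene_fraction=0.05)
        genome = dk.simulate_genome(cfg, seed=2)
        assert genome.genes["spanning"].mean() >= 0.04

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            dk.SimulationConfig(aneuploid_fraction_autosome=1.4)
        with pytest.raises(ValueError):
            dk.SimulationConfig(ec50=0.0)
        with pytest.raises(ValueError):
            dk.SimulationConfig(msl_multiplier=0.9)
        with pytest.raises(ValueError):
            dk.SimulationConfig(
                arm_specs=[dk.ArmSpec("tiny", 10)])  # shorter than a segment
        with pytest.raises(ValueError):
            dk.SimulationConfig(copy_range=(5, 3))


class TestDnaWindows:
    def test_expected_density_is_copy_times_unit(self):
        # 10,000 windows at copy 2: mean RPKM within 3 SE of 4.58.
        cfg = dk.SimulationConfig(
            arm_specs=[dk.ArmSpec("A", 10_000, n_genes=10)],
            baseline_copy_autosome=2, aneuploid_fraction_autosome=0.0)
        genome = dk.simulate_genome(cfg, seed=0)
        track = dk.simulate_dna_windows(genome, cfg, seed=0)
        rpkm = track.windows["rpkm"].to_numpy()
        assert len(rpkm) == 10_000
        se = rpkm.std() / np.sqrt(rpkm.size)
        assert abs(rpkm.mean() - 2 * 2.29) < 3 * se

    def test_copy_zero_segment_has_zero_counts(self):
        cfg = dk.SimulationConfig(arm_specs=[dk.ArmSpec("A", 100, n_genes=1)])
        genome = make_genome([("A", 0, 50, 0), ("A", 50, 100, 4)])
        track = dk.simulate_dna_windows(genome, cfg, seed=1)
        w = track.windows
        assert (w.loc[w["start"] < 50, "count"] == 0).all()
        assert (w.loc[w["start"] >= 50, "count"] > 0).all()

    def test_zero_total_reads_rejected(self, flat_config):
        genome = dk.simulate_genome(flat_config, seed=1)
        with pytest.raises(ValueError):
            dk.SimulationConfig(total_dna_reads=0)
        flat_config.total_dna_reads = -5
        with pytest.raises(ValueError):
            dk.simulate_dna_windows(genome, flat_config, seed=1)

    def test_read_conservation_with_derived_unit(self):
        # With the per-copy unit derived from the genome, the simulated arms
        # receive the whole library, up to Poisson sampling error.
        cfg = dk.SimulationConfig(per_copy_rpkm_unit=None,
                                  total_dna_reads=1_000_000)
        genome = dk.simulate_genome(cfg, seed=3)
        track = dk.simulate_dna_windows(genome, cfg, seed=3)
        total = track.windows["count"].sum()
        assert abs(total - cfg.total_dna_reads) < 5 * np.sqrt(
            cfg.total_dna_reads)
        unit = effective_per_copy_unit(genome, cfg)
        seg = genome.segments
        assert unit * ((seg["end"] - seg["start"]) * seg["copy"]).sum() \
            == pytest.approx(1e6)


class TestExpression:
    def test_baseline_autosomal_gene_is_baseline_exactly(self, flat_config):
        genome = dk.simulate_genome(flat_config, seed=4)
        table = dk.simulate_expression(genome, flat_config, "mock", seed=4)
        auto = table[~table["is_x"]]
        expected = genome.genes.loc[~genome.genes["is_x"],
                                    "baseline_expression"]
        np.testing.assert_allclose(auto["rpkm_rep1"], expected)

    def test_saturation_factor_at_half_dose(self):
        # EC50=2, autosomal gene at copy 2 (x=0.5): expression = 0.6*baseline.
        cfg = dk.SimulationConfig(arm_specs=[dk.ArmSpec("A", 100, n_genes=1)],
                                  expression_noise_cv=0.0, ec50=2.0)
        genome = make_genome(
            [("A", 0, 100, 2)],
            genes=[("g1", "A", 10, 12, 2, 7.0, False, False)])
        table = dk.simulate_expression(genome, cfg, "mock", seed=0)
        assert table["rpkm_rep1"].iloc[0] == pytest.approx(7.0 * 0.6)

    def test_msl_multiplier_recovered_from_knockdown(self):
        cfg = dk.SimulationConfig(
            arm_specs=[dk.ArmSpec("X", 500, is_x=True, n_genes=2000)],
            aneuploid_fraction_X=0.0, expression_noise_cv=0.3)
        genome = dk.simulate_genome(cfg, seed=8)
        mock = dk.simulate_expression(genome, cfg, "mock", seed=8)
        rnai = dk.simulate_expression(genome, cfg, "msl2_rnai", seed=8)
        ratio = mock["mean_rpkm"] / rnai["mean_rpkm"]
        assert np.median(ratio) == pytest.approx(1.35, abs=0.03)

    def test_fixed_fold_is_exact_without_noise(self):
        cfg = dk.SimulationConfig(
            arm_specs=[dk.ArmSpec("X", 400, is_x=True, n_genes=300)],
            aneuploid_fraction_X=0.4, expression_noise_cv=0.0,
            min_segment_kb=30, max_segment_kb=60)
        genome = dk.simulate_genome(cfg, seed=6)
        mock = dk.simulate_expression(genome, cfg, "mock", seed=6)
        rnai = dk.simulate_expression(genome, cfg, "mof_rnai", seed=6)
        ratio = mock["mean_rpkm"] / rnai["mean_rpkm"]
        # The feed-forward construction: mock/RNAi is 1.35 for every X gene,
        # independent of its copy number.
        np.testing.assert_allclose(ratio, 1.35)

    def test_knockdown_residual_scales_multiplier(self, flat_config):
        flat_config.knockdown_residual = 0.1
        genome = dk.simulate_genome(flat_config, seed=4)
        mock = dk.simulate_expression(genome, flat_config, "mock", seed=4)
        rnai = dk.simulate_expression(genome, flat_config, "msl2_rnai", seed=4)
        x = mock["is_x"]
        ratio = (mock.loc[x, "rpkm_rep1"] / rnai.loc[x, "rpkm_rep1"]).iloc[0]
        assert ratio == pytest.approx(1.35 / (1 + 0.1 * 0.35))

    def test_monotone_and_sublinear_in_copy(self):
        cfg = dk.SimulationConfig(expression_noise_cv=0.0,
                                  baseline_expression_log_sd=0.0,
                                  spanning_gene_fraction=0.0)
        genome = dk.simulate_genome(cfg, seed=10)
        table = dk.simulate_expression(genome, cfg, "mock", seed=10)
        for is_x, baseline in ((False, 4), (True, 2)):
            sub = table[(table["is_x"] == is_x) & ~table["spanning"]]
            by_copy = sub.groupby("true_copy")["mean_rpkm"].first()
            assert by_copy.is_monotonic_increasing
            for copy, value in by_copy.items():
                if copy > baseline:
                    assert value / by_copy[baseline] < copy / baseline

    def test_unknown_condition_rejected(self, flat_config):
        genome = dk.simulate_genome(flat_config, seed=1)
        with pytest.raises(ValueError, match="unknown condition"):
            dk.simulate_expression(genome, flat_config, "scrambled", seed=1)


class TestIntergenic:
    def test_five_percent_reach_the_ceiling(self):
        cfg = dk.SimulationConfig()
        values = simulate_intergenic(None, cfg, seed=0)
        assert len(values) == 10_000
        assert np.mean(values >= 4.0) == pytest.approx(0.05, abs=0.01)

    def test_zero_scale_is_degenerate(self):
        cfg = dk.SimulationConfig(intergenic_scale=0.0)
        assert (simulate_intergenic(None, cfg, seed=0) == 0).all()

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            dk.SimulationConfig(intergenic_scale=-1.0)


def test_saturating_response_normalisation():
    for ec50 in (0.1, 1.0, 2.0, 17.0):
        assert saturating_response(1.0, ec50) == pytest.approx(1.0)
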