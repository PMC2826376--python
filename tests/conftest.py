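import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dosekit as dk

settings.register_profile(
    "dosekit",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("dosekit")


@pytest.fixture
def flat_config():
    """Euploid genome (no aneuploidy), small arms, noise-free expression."""
    return dk.SimulationConfig(
        arm_specs=[dk.ArmSpec("2L", 120, n_genes=40),
                   dk.ArmSpec("X", 120, is_x=True, n_genes=40)],
        aneuploid_fraction_autosome=0.0,
        aneuploid_fraction_X=0.0,
        expression_noise_cv=0.0,
        spanning_gene_fraction=0.0,
        intergenic_count=200,
    )


@pytest.fixture
def small_config():
    """Small aneuploid genome for fast end-to-end unit tests."""
    return dk.SimulationConfig(
        arm_specs=[dk.ArmSpec("2L", 200, n_genes=200),
                   dk.ArmSpec("X", 200, is_x=True, n_genes=400)],
        min_segment_kb=30, max_segment_kb=60,
        intergenic_count=500,
    )


def make_genome(segments, genes=None, arms=None):
    """Hand-built GenomeModel from (arm, start, end, copy) tuples."""
    seg = pd.DataFrame(segments, columns=["arm", "start", "end", "copy"])
    if genes is None:
        gene_df = pd.DataFrame(columns=["gene_id", "arm", "start", "end",
                                        "true_copy", "baseline_expression",
                                        "spanning", "is_x"])
    else:
        gene_df = pd.DataFrame(genes, columns=["gene_id", "arm", "start",
                                               "end", "true_copy",
                                               "baseline_expression",
                                               "spanning", "is_x"])
    inter = pd.DataFrame(columns=["arm", "start", "end"])
    return dk.GenomeModel(segments=seg, genes=gene_df,
                          intergenic_regions=inter)


@pytest.fixture
def step_track():
    """Noise-free two-level track: 100 windows at 2.29 then 100 at 4.58."""
    n = 100
    rpkm = np.r_[np.full(n, 2.29), np.full(n, 4.58)]
    starts = np.arange(2 * n)
    windows = pd.DataFrame({"arm": "2L", "start": starts, "end": starts + 1,
                            "count": (rpkm * 50).astype(int), "rpkm": rpkm})
    return dk.WindowTrack(windows=windows, width_kb=1,
                          total_mapped_reads=50_000_000)
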