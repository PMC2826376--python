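"""End-to-end synthetic analysis: simulate, call copies, quantify,
decompose X compensation.

This is the composition of every stage the package provides, used by the
command-line interface and by the reproduction script. Sampler sweep counts
default to a few hundred — enough for the chunk sizes the default genome
produces — and are exposed for longer runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import copy_number as cn
from . import dosage, dose_response, expression, simulate
from .config import SimulationConfig
from .datatypes import CopySegmentMap, GenomeModel, WindowTrack


@dataclass
class PipelineResult:
    config: SimulationConfig = field(repr=False)
    genome: GenomeModel = field(repr=False)
    track: WindowTrack = field(repr=False)
    segment_map: CopySegmentMap = field(repr=False)
    gene_copies: pd.DataFrame = field(repr=False)
    expr: dict = field(repr=False)
    threshold: float = 0.0
    summaries: dict = field(repr=False, default=None)
    comparison: dosage.ConditionComparison = field(repr=False, default=None)
    points: pd.DataFrame = field(repr=False, default=None)
    fit: dose_response.DoseResponseFit = None
    decomposition: dict = None


def run_pipeline(config: SimulationConfig | None = None,
                 seed: int | None = None,
                 rnai_condition: str = "msl2_rnai",
                 n_burn: int = 200, n_keep: int = 800,
                 posterior_threshold: float = cn.DEFAULT_POSTERIOR,
                 min_rpkm: float = cn.DEFAULT_MIN_RPKM,
                 alpha: float = expression.DEFAULT_ALPHA) -> PipelineResult:
    """Run the whole synthetic study and decompose X compensation.

    Steps: genome -> DNA windows -> RPKM filter -> change-point segmentation
    -> copy banding -> gene annotation; expression tables (mock + one RNAi)
    -> intergenic threshold -> expressed calls; per-copy summaries -> scaled
    dose-response points -> joint EC50 fit; RNAi/mock fixed fold -> composite
    decomposition.
    """
    config = config or SimulationConfig()
    seed = config.seed if seed is None else seed

    genome = simulate.simulate_genome(config, seed=seed)
    track = simulate.simulate_dna_windows(genome, config, seed=seed)
    filtered = cn.filter_windows(track, min_rpkm=min_rpkm)
    segmap = cn.segment_track(filtered,
                              posterior_threshold=posterior_threshold,
                              n_burn=n_burn, n_keep=n_keep, seed=seed)
    unit = simulate.effective_per_copy_unit(genome, config)
    segmap = cn.assign_segment_copies(segmap, per_copy_unit=unit)
    gene_copies = cn.annotate_gene_copies(genome.genes, segmap)

    intergenic = simulate.simulate_intergenic(genome, config, seed=seed)
    threshold = expression.expression_threshold(intergenic, alpha=alpha)

    expr = {}
    for condition in ("mock", rnai_condition):
        table = simulate.simulate_expression(genome, config, condition,
                                             seed=seed)
        table = expression.average_replicates(table)
        # Threshold computed once on mock background and reused.
        table = expression.call_expressed(table, threshold)
        expr[condition] = table
    # Ratio analyses use the mock expressed set for every condition.
    mock_expressed = expr["mock"].set_index("gene_id")["expressed"]
    expr[rnai_condition]["expressed"] = (
        expr[rnai_condition]["gene_id"].map(mock_expressed).to_numpy())

    summaries = {cond: dosage.summarize_by_copy(tab, gene_copies)
                 for cond, tab in expr.items()}
    comparison = dosage.rnai_effect(expr[rnai_condition], expr["mock"],
                                    gene_copies)

    points = dose_response.scale_curves(summaries, mock_key="mock",
                                        rnai_key=rnai_condition)
    fit = dose_response.fit_ec50(points, joint=True)
    dose_fold = dose_response.project_fold(fit.ec50, 2.0)
    decomposition = dose_response.composite_fold(dose_fold,
                                                 comparison.msl_fold)

    return PipelineResult(config=config, genome=genome, track=track,
                          segment_map=segmap, gene_copies=gene_copies,
                          expr=expr, threshold=threshold,
                          summaries=summaries, comparison=comparison,
                          points=points, fit=fit,
                          decomposition=decomposition)
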