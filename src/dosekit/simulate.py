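"""Synthetic aneuploid genomes, windowed DNA counts, expression tables and
intergenic background.

The generator is the testbed for every downstream stage: it produces data
with exactly the statistical structure the analysis assumes, so each
estimator can be validated against generator truth without any download.

Seeding: every generator derives an independent stream from
``(seed, stream_id)`` so that, e.g., adding an expression condition never
perturbs the DNA windows. Identical config + seed gives bitwise-identical
output.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import ArmSpec, SimulationConfig
from .datatypes import GenomeModel, WindowTrack

CONDITIONS = ("mock", "msl2_rnai", "mof_rnai")
_STREAMS = {"genome": 1, "windows": 2, "intergenic": 4,
            "mock": 11, "msl2_rnai": 12, "mof_rnai": 13}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def saturating_response(x, ec50: float):
    """Scaled dose response y = x(EC50+1)/(EC50+x); y(1) = 1 by construction."""
    x = np.asarray(x, dtype=float)
    return x * (ec50 + 1.0) / (ec50 + x)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _allowed_copies(cfg: SimulationConfig, is_x: bool) -> list[int]:
    lo, hi = cfg.x_copy_range if is_x else cfg.copy_range
    baseline = cfg.baseline_copy(is_x)
    allowed = [c for c in range(lo, hi + 1) if c != baseline]
    if not allowed:
        raise ValueError("copy range leaves no aneuploid copy available")
    return allowed


def _arm_segments(rng: np.random.Generator, arm: ArmSpec,
                  cfg: SimulationConfig,
                  kb_acc: dict[int, int] | None = None,
                  ) -> list[tuple[int, int, int]]:
    """Alternating baseline/aneuploid segments covering [0, L) exactly.

    The summed aneuploid length equals round(fraction * L) by construction.
    Copies are assigned greedily to balance total kb across the permitted
    values (tracked genome-wide through ``kb_acc``), so every dose class is
    populated roughly equally — a testbed design choice, not an empirical
    copy-number spectrum.
    """
    L = arm.length_kb
    baseline = cfg.baseline_copy(arm.is_x)
    frac = cfg.aneuploid_fraction_X if arm.is_x else cfg.aneuploid_fraction_autosome
    target = int(round(frac * L))
    if target == 0:
        return [(0, L, baseline)]

    # Draw k segment lengths and rescale them to sum exactly to the target,
    # so the measured aneuploid fraction matches the configured one and no
    # sliver segments are produced.
    mean_seg = 0.5 * (cfg.min_segment_kb + cfg.max_segment_kb)
    k = max(1, int(round(target / mean_seg)))
    if k * cfg.min_segment_kb > target:
        k = max(1, target // cfg.min_segment_kb)
    raw = rng.integers(cfg.min_segment_kb, cfg.max_segment_kb + 1, size=k)
    lengths = np.maximum(np.floor(raw * target / raw.sum()).astype(int), 1)
    lengths[np.argmax(lengths)] += target - lengths.sum()
    lengths = lengths.tolist()
    spare = L - sum(lengths)
    if spare < k - 1:
        raise ValueError(
            f"aneuploid fraction too high for arm {arm.name}: "
            "segments do not fit with separating baseline gaps")

    # k+1 gaps (ends may be empty, interior gaps >= 1 kb so aneuploid
    # segments never touch).
    interior = k - 1
    weights = rng.dirichlet(np.ones(k + 1))
    free = spare - interior
    gaps = np.floor(weights * free).astype(int)
    gaps[int(rng.integers(0, k + 1))] += free - gaps.sum()
    gaps[1:-1] += 1 if k > 1 else 0

    allowed = _allowed_copies(cfg, arm.is_x)
    if kb_acc is None:
        kb_acc = {c: 0 for c in allowed}
    for c in allowed:
        kb_acc.setdefault(c, 0)
    # Longest segments first, each to the currently least-covered copy.
    copies_for_len = {}
    for j in sorted(range(k), key=lambda j: -lengths[j]):
        lo_kb = min(kb_acc[c] for c in allowed)
        pick = int(rng.choice([c for c in allowed if kb_acc[c] == lo_kb]))
        kb_acc[pick] += lengths[j]
        copies_for_len[j] = pick
    copies = [copies_for_len[j] for j in range(k)]

    segments: list[tuple[int, int, int]] = []
    pos = 0
    for i in range(k):
        if gaps[i] > 0:
            segments.append((pos, pos + int(gaps[i]), baseline))
            pos += int(gaps[i])
        segments.append((pos, pos + lengths[i], copies[i]))
        pos += lengths[i]
    if gaps[k] > 0:
        segments.append((pos, pos + int(gaps[k]), baseline))
        pos += int(gaps[k])
    assert pos == L
    return segments


def _arm_genes(rng: np.random.Generator, arm: ArmSpec,
               segments: list[tuple[int, int, int]],
               cfg: SimulationConfig) -> pd.DataFrame:
    n = cfg.genes_for(arm)
    lo, hi = cfg.gene_length_kb
    lengths = rng.integers(lo, hi + 1, size=n)
    starts = rng.integers(0, np.maximum(arm.length_kb - lengths, 1))
    ends = starts + lengths

    # Force a configurable fraction of genes onto internal segment
    # boundaries to exercise the spanning-gene exclusion rule.
    boundaries = np.array([s for s, _, _ in segments[1:]], dtype=int)
    n_span = int(round(cfg.spanning_gene_fraction * n))
    if len(boundaries) and n_span:
        idx = rng.choice(n, size=n_span, replace=False)
        bpos = rng.choice(boundaries, size=n_span)
        starts[idx] = np.maximum(bpos - np.maximum(lengths[idx] // 2, 1), 0)
        ends[idx] = np.minimum(starts[idx] + np.maximum(lengths[idx], 2),
                               arm.length_kb)

    seg_starts = np.array([s for s, _, _ in segments])
    seg_ends = np.array([e for _, e, _ in segments])
    seg_copies = np.array([c for _, _, c in segments])
    i_start = np.searchsorted(seg_starts, starts, side="right") - 1
    spanning = ends > seg_ends[i_start]
    # True copy: the segment holding the larger share of the gene.
    i_mid = np.searchsorted(seg_starts, (starts + ends) // 2, side="right") - 1
    true_copy = seg_copies[np.where(spanning, i_mid, i_start)]

    baselines = rng.lognormal(cfg.baseline_expression_log_mean,
                              cfg.baseline_expression_log_sd, size=n)
    order = np.argsort(starts, kind="stable")
    return pd.DataFrame({
        "gene_id": [f"{arm.name}:g{i:05d}" for i in range(n)],
        "arm": arm.name,
        "start": starts,
        "end": ends,
        "true_copy": true_copy,
        "baseline_expression": baselines,
        "spanning": spanning,
        "is_x": arm.is_x,
    }).iloc[order].reset_index(drop=True)


def _intergenic_intervals(genes: pd.DataFrame, arm: ArmSpec) -> pd.DataFrame:
    g = genes.sort_values("start")
    ends = np.maximum.accumulate(g["end"].to_numpy())
    gap_start = ends[:-1]
    gap_end = g["start"].to_numpy()[1:]
    keep = gap_end > gap_start
    return pd.DataFrame({"arm": arm.name,
                         "start": gap_start[keep], "end": gap_end[keep]})


def simulate_genome(config: SimulationConfig,
                    seed: int | None = None) -> GenomeModel:
    """Draw an aneuploid genome: segments, genes and intergenic gaps.

    The aneuploid kb fraction per arm class equals the configured fraction
    exactly (up to 1 kb rounding); gene positions are uniform within arms.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed, "genome")
    seg_rows, gene_frames, inter_frames = [], [], []
    kb_acc: dict[bool, dict[int, int]] = {True: {}, False: {}}
    for arm in config.arm_specs:
        segments = _arm_segments(rng, arm, config, kb_acc[arm.is_x])
        seg_rows += [(arm.name, s, e, c) for s, e, c in segments]
        genes = _arm_genes(rng, arm, segments, config)
        gene_frames.append(genes)
        inter_frames.append(_intergenic_intervals(genes, arm))
    return GenomeModel(
        segments=pd.DataFrame(seg_rows, columns=["arm", "start", "end", "copy"]),
        genes=pd.concat(gene_frames, ignore_index=True),
        intergenic_regions=pd.concat(inter_frames, ignore_index=True),
    )


def aneuploid_fraction(genome: GenomeModel, config: SimulationConfig,
                       x: bool = False) -> float:
    """Measured fraction of kb at non-baseline copy for one arm class."""
    x_arms = {a.name for a in config.arm_specs if a.is_x}
    seg = genome.segments
    sel = seg["arm"].isin(x_arms) if x else ~seg["arm"].isin(x_arms)
    seg = seg[sel]
    baseline = config.baseline_copy(x)
    kb = (seg["end"] - seg["start"]).to_numpy()
    return float(kb[seg["copy"].to_numpy() != baseline].sum() / kb.sum())


# ---------------------------------------------------------------------------
# DNA windows
# ---------------------------------------------------------------------------

def effective_per_copy_unit(genome: GenomeModel,
                            config: SimulationConfig) -> float:
    """Per-copy RPKM: configured value, or derived so the simulated arms
    receive the entire read library (1e6 / total copy-kb)."""
    if config.per_copy_rpkm_unit is not None:
        return float(config.per_copy_rpkm_unit)
    seg = genome.segments
    copy_kb = ((seg["end"] - seg["start"]) * seg["copy"]).sum()
    return 1e6 / float(copy_kb)


def simulate_dna_windows(genome: GenomeModel, config: SimulationConfig,
                         seed: int | None = None) -> WindowTrack:
    """Poisson (optionally gamma-Poisson) read counts in fixed 1 kb windows.

    The expected RPKM of a window equals true_copy * per_copy_unit exactly;
    segments are kb-aligned so no window straddles a breakpoint.
    """
    if config.total_dna_reads <= 0:
        raise ValueError("total_dna_reads must be positive")
    rng = _rng(config.seed if seed is None else seed, "windows")
    unit = effective_per_copy_unit(genome, config)
    per_million = config.total_dna_reads / 1e6
    frames = []
    for arm in config.arm_specs:
        copies = genome.copy_track(arm.name, config.window_kb)
        lam = copies * unit * config.window_kb * per_million
        if config.count_dispersion > 0:
            shape = 1.0 / config.count_dispersion
            lam = np.where(lam > 0, rng.gamma(shape, np.maximum(lam, 1e-300)
                                              / shape), 0.0)
        counts = rng.poisson(lam)
        starts = np.arange(copies.size) * config.window_kb
        frames.append(pd.DataFrame({
            "arm": arm.name, "start": starts,
            "end": starts + config.window_kb, "count": counts}))
    windows = pd.concat(frames, ignore_index=True)
    windows["rpkm"] = windows["count"] / (config.window_kb * per_million)
    return WindowTrack(windows=windows, width_kb=config.window_kb,
                       total_mapped_reads=config.total_dna_reads)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(genome: GenomeModel, config: SimulationConfig,
                        condition: str, seed: int | None = None,
                        n_replicates: int = 2) -> pd.DataFrame:
    """Gene expression RPKM for one condition, two replicates.

    expression = baseline * S(copy / baseline_copy) * M * noise, where
    S(x) = x(EC50+1)/(EC50+x), M is the MSL multiplier for X genes (reduced
    to 1 + residual*(M-1) under RNAi, 1 on autosomes) and noise is
    multiplicative log-normal with the configured CV (median 1).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {CONDITIONS}")
    rng = _rng(config.seed if seed is None else seed, condition)
    g = genome.genes
    baseline_copy = np.where(g["is_x"], config.baseline_copy_X,
                             config.baseline_copy_autosome)
    x = g["true_copy"].to_numpy() / baseline_copy
    s = saturating_response(x, config.ec50)
    m_full = config.msl_multiplier
    if condition == "mock":
        m_x = m_full
    else:
        m_x = 1.0 + config.knockdown_residual * (m_full - 1.0)
    m = np.where(g["is_x"], m_x, 1.0)
    mu = g["baseline_expression"].to_numpy() * s * m

    sigma = config.noise_log_sd()
    out = g[["gene_id", "arm", "is_x", "true_copy", "spanning"]].copy()
    out["condition"] = condition
    rep_cols = []
    for r in range(1, n_replicates + 1):
        noise = (np.exp(rng.normal(0.0, sigma, size=len(g)))
                 if sigma > 0 else 1.0)
        col = f"rpkm_rep{r}"
        out[col] = mu * noise
        rep_cols.append(col)
    out["mean_rpkm"] = out[rep_cols].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# intergenic background
# ---------------------------------------------------------------------------

def simulate_intergenic(genome: GenomeModel | None, config: SimulationConfig,
                        seed: int | None = None) -> np.ndarray:
    """Right-skewed intergenic background RPKM values.

    Exponential with scale calibrated so the (1 - background_alpha) quantile
    equals ``intergenic_scale`` (default: 5% of regions at or above 4 RPKM).
    """
    if config.intergenic_count <= 0:
        raise ValueError("intergenic_count must be positive")
    if config.intergenic_scale < 0:
        raise ValueError("intergenic scale must be non-negative")
    rng = _rng(config.seed if seed is None else seed, "intergenic")
    if config.intergenic_scale == 0:
        return np.zeros(config.intergenic_count)
    theta = config.intergenic_scale / (-math.log(config.background_alpha))
    return rng.exponential(theta, size=config.intergenic_count)
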