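"""In-memory containers shared across the pipeline.

All coordinates are 0-based, half-open intervals in kb (BED convention,
scaled to the 1 kb window grid). Tabular payloads are pandas DataFrames with
documented columns; the dataclasses are thin, validated wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEGMENT_COLUMNS = ["arm", "start", "end", "copy"]
GENE_COLUMNS = ["gene_id", "arm", "start", "end", "true_copy",
                "baseline_expression", "spanning", "is_x"]


@dataclass
class GenomeModel:
    """Ground-truth genome: copy-number segments, genes, intergenic gaps.

    segments: arm, start, end, copy          (contiguous per arm, cover it)
    genes:    gene_id, arm, start, end, true_copy, baseline_expression,
              spanning, is_x
    intergenic_regions: arm, start, end
    """

    segments: pd.DataFrame
    genes: pd.DataFrame
    intergenic_regions: pd.DataFrame

    def __post_init__(self) -> None:
        for arm, seg in self.segments.groupby("arm", sort=False):
            seg = seg.sort_values("start")
            if (seg["start"].to_numpy()[1:] != seg["end"].to_numpy()[:-1]).any():
                raise ValueError(f"segments on arm {arm} are not contiguous")

    def arm_length(self, arm: str) -> int:
        seg = self.segments[self.segments["arm"] == arm]
        return int(seg["end"].max())

    def copy_track(self, arm: str, window_kb: int = 1) -> np.ndarray:
        """Per-window true copy number along one arm (kb-aligned segments)."""
        seg = self.segments[self.segments["arm"] == arm].sort_values("start")
        n = self.arm_length(arm) // window_kb
        out = np.empty(n, dtype=np.int64)
        for s, e, c in zip(seg["start"], seg["end"], seg["copy"]):
            out[s // window_kb: e // window_kb] = c
        return out


@dataclass
class WindowTrack:
    """Fixed-width windowed read counts, optionally with RPKM.

    windows: arm, start, end, count[, rpkm] — sorted, non-overlapping.
    """

    windows: pd.DataFrame
    width_kb: int = 1
    total_mapped_reads: int | None = None

    def __post_init__(self) -> None:
        w = self.windows
        if not (w["end"] - w["start"] == self.width_kb).all():
            raise ValueError("all windows must have the configured width")
        for arm, grp in w.groupby("arm", sort=False):
            starts = grp["start"].to_numpy()
            if (np.diff(starts) <= 0).any():
                raise ValueError(f"windows on arm {arm} must be sorted")
        if "rpkm" in w.columns and (w["rpkm"].to_numpy() < 0).any():
            raise ValueError("rpkm must be non-negative")

    @property
    def has_rpkm(self) -> bool:
        return "rpkm" in self.windows.columns

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class CopySegmentMap:
    """Breakpoints with posteriors plus segments with copy calls.

    breakpoints: arm, position, posterior      (posterior > threshold)
    segments:    arm, start, end, n_windows, mean_rpkm[, copy, confidence]
    """

    breakpoints: pd.DataFrame
    segments: pd.DataFrame
    posterior_threshold: float = 0.95

    def __post_init__(self) -> None:
        p = self.breakpoints.get("posterior")
        if p is not None and len(p) and ((p < 0) | (p > 1)).any():
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if (self.segments["mean_rpkm"].to_numpy() < 0).any():
            raise ValueError("segment mean_rpkm must be non-negative")

    @property
    def has_copies(self) -> bool:
        return "copy" in self.segments.columns


# Exclusion reasons used by annotate_gene_copies.
SPANS_BREAKPOINT = "spans_breakpoint"
LOW_CONFIDENCE = "low_confidence_copy"
UNSEGMENTED = "unsegmented"


@dataclass
class DoseResponseFit:
    """One-parameter saturation fit y = x(EC50+1)/(EC50+x)."""

    ec50: float
    r2: float
    points: pd.DataFrame = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    per_curve: dict | None = None

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.r2 > 1:
            raise ValueError("r2 cannot exceed 1")
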