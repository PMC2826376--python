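"""Copy-number calling from windowed DNA read densities.

Pipeline: RPKM transform -> low-mappability filter (RPKM < 2 removed) ->
Bayesian change-point segmentation of the retained windows -> integer copy
assignment by banding around multiples of the per-copy density
(2.29 RPKM = 1 copy, 4.58 = 2 copies, ...) -> per-gene copy annotation with
exclusion of genes that span a breakpoint or sit in low-confidence segments.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .config import DEFAULT_PER_COPY_RPKM
from .datatypes import (LOW_CONFIDENCE, SPANS_BREAKPOINT, UNSEGMENTED,
                        CopySegmentMap, WindowTrack)
from .segmentation import BayesianChangePointSegmenter

logger = logging.getLogger(__name__)

DEFAULT_MIN_RPKM = 2.0
DEFAULT_POSTERIOR = 0.95
DEFAULT_MAX_CONFIDENT = 5
DEFAULT_GAP_LIMIT = 10  # windows; segments never bridge a longer gap


def compute_window_rpkm(track: WindowTrack,
                        total_mapped_reads: int | None = None) -> WindowTrack:
    """Attach RPKM = count / (width_kb * total_mapped/1e6) to every window."""
    total = (track.total_mapped_reads if total_mapped_reads is None
             else total_mapped_reads)
    if total is None or total <= 0:
        raise ValueError("total_mapped_reads must be a positive count")
    windows = track.windows.copy()
    windows["rpkm"] = windows["count"] / (track.width_kb * total / 1e6)
    return WindowTrack(windows=windows, width_kb=track.width_kb,
                       total_mapped_reads=total)


def filter_windows(track: WindowTrack,
                   min_rpkm: float = DEFAULT_MIN_RPKM) -> WindowTrack:
    """Drop windows with RPKM strictly below ``min_rpkm``.

    Coordinates of the retained windows are preserved, so the filtered track
    may contain gaps; segmentation never bridges long ones.
    """
    if not track.has_rpkm:
        raise ValueError("compute RPKM before filtering")
    keep = track.windows["rpkm"] >= min_rpkm
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_windows: removed %d of %d windows below %.3g RPKM",
                    removed, len(track), min_rpkm)
    return WindowTrack(windows=track.windows[keep].reset_index(drop=True),
                       width_kb=track.width_kb,
                       total_mapped_reads=track.total_mapped_reads)


def _chunks(starts: np.ndarray, width_kb: int, gap_limit: int):
    """Split sorted window starts into runs not separated by long gaps."""
    gaps = np.diff(starts) // width_kb - 1  # missing windows between neighbours
    cut = np.flatnonzero(gaps > gap_limit) + 1
    return np.split(np.arange(starts.size), cut)


def segment_track(track: WindowTrack,
                  posterior_threshold: float = DEFAULT_POSTERIOR,
                  p0: float = 0.2, w0: float = 0.2,
                  n_burn: int = 500, n_keep: int = 4500,
                  gap_limit: int = DEFAULT_GAP_LIMIT,
                  seed: int | None = None) -> CopySegmentMap:
    """Breakpoints and mean-RPKM segments from a filtered window track.

    Each arm is segmented independently; runs of windows separated by more
    than ``gap_limit`` missing windows are segmented as separate chunks, so
    no segment bridges a long gap. Breakpoint positions are the genomic
    start coordinates of the first window of the right-hand segment.
    """
    if not track.has_rpkm:
        raise ValueError("compute RPKM before segmenting")
    if len(track) < 2:
        raise ValueError("segmentation needs at least 2 windows")
    bp_rows, seg_rows = [], []
    chunk_idx = 0
    for arm, grp in track.windows.groupby("arm", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        rpkm = grp["rpkm"].to_numpy(dtype=float)
        for members in _chunks(starts, track.width_kb, gap_limit):
            chunk_idx += 1
            y = rpkm[members]
            if y.size >= 2:
                seg = BayesianChangePointSegmenter(
                    p0=p0, w0=w0, n_burn=n_burn, n_keep=n_keep,
                    random_state=(None if seed is None
                                  else np.random.default_rng([seed, chunk_idx])))
                seg.fit(y)
                cps = seg.changepoints(posterior_threshold)
                posts = seg.posterior_[cps]
            else:
                cps, posts = np.array([], dtype=int), np.array([])
            for cp, post in zip(cps, posts):
                bp_rows.append((arm, int(starts[members[cp]]), float(post)))
            bounds = [0, *cps.tolist(), y.size]
            for a, b in zip(bounds[:-1], bounds[1:]):
                seg_rows.append((arm, int(starts[members[a]]),
                                 int(ends[members[b - 1]]),
                                 b - a, float(y[a:b].mean())))
    return CopySegmentMap(
        breakpoints=pd.DataFrame(bp_rows,
                                 columns=["arm", "position", "posterior"]),
        segments=pd.DataFrame(seg_rows, columns=["arm", "start", "end",
                                                 "n_windows", "mean_rpkm"]),
        posterior_threshold=posterior_threshold,
    )


def assign_copy(mean_rpkm: float,
                per_copy_unit: float = DEFAULT_PER_COPY_RPKM,
                max_confident: int = DEFAULT_MAX_CONFIDENT) -> tuple[int, str]:
    """Integer copy from the banding rule k*unit +/- unit/2.

    A mean exactly on a band edge rounds to the LOWER copy (conservative
    against overcalling amplification). Copy 0 and copies above
    ``max_confident`` are flagged low-confidence.
    """
    if mean_rpkm < 0:
        raise ValueError("mean_rpkm must be non-negative")
    if per_copy_unit <= 0:
        raise ValueError("per_copy_unit must be positive")
    q = mean_rpkm / per_copy_unit
    copy = max(int(math.ceil(round(q - 0.5, 9))), 0)
    confidence = "confident" if 1 <= copy <= max_confident else "low"
    return copy, confidence


def assign_segment_copies(segmap: CopySegmentMap,
                          per_copy_unit: float = DEFAULT_PER_COPY_RPKM,
                          max_confident: int = DEFAULT_MAX_CONFIDENT,
                          ) -> CopySegmentMap:
    """Apply :func:`assign_copy` to every segment of a map."""
    seg = segmap.segments.copy()
    calls = [assign_copy(m, per_copy_unit, max_confident)
             for m in seg["mean_rpkm"]]
    seg["copy"] = [c for c, _ in calls]
    seg["confidence"] = [conf for _, conf in calls]
    return CopySegmentMap(breakpoints=segmap.breakpoints, segments=seg,
                          posterior_threshold=segmap.posterior_threshold)


def annotate_gene_copies(genes: pd.DataFrame,
                         segmap: CopySegmentMap) -> pd.DataFrame:
    """Per-gene copy annotation from a copy-assigned segment map.

    Every input gene appears exactly once. A gene overlapping a retained
    breakpoint is excluded (``spans_breakpoint``); a gene inside a
    low-confidence segment is excluded (``low_confidence_copy``); a gene not
    fully contained in any segment is excluded (``unsegmented``).
    """
    if not segmap.has_copies:
        raise ValueError("assign segment copies before annotating genes")
    bp_by_arm = {arm: np.sort(g["position"].to_numpy())
                 for arm, g in segmap.breakpoints.groupby("arm", sort=False)}
    frames = []
    for arm, grp in genes.groupby("arm", sort=False):
        gs = grp["start"].to_numpy(dtype=int)
        ge = grp["end"].to_numpy(dtype=int)
        n = len(grp)
        copy = np.full(n, -1, dtype=int)
        reason = np.full(n, "", dtype=object)

        bps = bp_by_arm.get(arm, np.empty(0))
        # breakpoint strictly inside the gene interval
        spans = (np.searchsorted(bps, ge - 1, side="right")
                 - np.searchsorted(bps, gs, side="right")) > 0

        seg = segmap.segments[segmap.segments["arm"] == arm] \
            .sort_values("start")
        if len(seg):
            s_start = seg["start"].to_numpy()
            s_end = seg["end"].to_numpy()
            s_copy = seg["copy"].to_numpy()
            s_conf = (seg["confidence"] == "confident").to_numpy()
            idx = np.searchsorted(s_start, gs, side="right") - 1
            valid = idx >= 0
            idx_c = np.clip(idx, 0, len(seg) - 1)
            contained = valid & (ge <= s_end[idx_c]) & (gs >= s_start[idx_c])
        else:
            contained = np.zeros(n, dtype=bool)

        reason[~contained] = UNSEGMENTED
        if len(seg):
            low = contained & ~s_conf[idx_c]
            reason[low] = LOW_CONFIDENCE
            good = contained & s_conf[idx_c]
            copy[good] = s_copy[idx_c][good]
            reason[good] = ""
        reason[spans] = SPANS_BREAKPOINT
        copy[spans] = -1
        frames.append(pd.DataFrame({
            "gene_id": grp["gene_id"].to_numpy(),
            "arm": arm,
            "copy": copy,
            "excluded": reason != "",
            "reason": reason,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["copy"] = out["copy"].astype("Int64").where(out["copy"] >= 0, pd.NA)
    return out


def estimate_per_copy_unit(rpkms, bin_width: float | None = None) -> float:
    """Peak-spacing estimate of the per-copy RPKM unit.

    Window densities from an aneuploid genome cluster in bands at integer
    multiples of the unit; the estimator smooths the density histogram,
    finds its peaks, and returns the median spacing between consecutive
    peaks (falling back to the first peak position when only one band is
    present). A utility for data where the unit is not known a priori.
    """
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    r = np.asarray(rpkms, dtype=float)
    r = r[r > 0]
    if r.size < 10:
        raise ValueError("need at least 10 positive window densities")
    if bin_width is None:
        bin_width = max(np.median(r) / 100.0, 1e-6)
    hist, edges = np.histogram(r, bins=np.arange(0, r.max() + 2 * bin_width,
                                                 bin_width))
    smooth = gaussian_filter1d(hist.astype(float), sigma=2.0)
    peaks, _ = find_peaks(smooth, height=smooth.max() * 0.05)
    centers = (edges[peaks] + edges[peaks + 1]) / 2.0
    if centers.size == 0:
        raise ValueError("no density bands found")
    if centers.size == 1:
        return float(centers[0])
    return float(np.median(np.diff(centers)))
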