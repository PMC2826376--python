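"""Gene-level RPKM quantification and expressed-gene calling.

Expression is quantified as reads in unique exons per kb of unique exon
length per million mapped reads, averaged over biological replicates. The
"expressed" cutoff is set from the empirical distribution of intergenic
background densities so that the type-I error of the call (the fraction of
background regions at or above the cutoff) is bounded by alpha.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
MIN_INTERGENIC = 20


def gene_rpkm(exon_read_count, unique_exon_kb, total_mapped) -> np.ndarray | float:
    """RPKM over unique exons: count / (exon_kb * total_mapped / 1e6).

    ``unique_exon_kb`` must be strictly positive — a zero-length exon model
    is an annotation error, not a silent zero.
    """
    count = np.asarray(exon_read_count, dtype=float)
    kb = np.asarray(unique_exon_kb, dtype=float)
    if np.any(kb <= 0):
        raise ValueError("unique exon length must be positive")
    total = float(total_mapped)
    if total <= 0:
        raise ValueError("total_mapped must be positive")
    out = count / (kb * total / 1e6)
    return float(out) if out.ndim == 0 else out


def average_replicates(table: pd.DataFrame,
                       rep_cols: list[str] | None = None) -> pd.DataFrame:
    """Arithmetic mean over replicate RPKM columns into ``mean_rpkm``.

    Replicate columns are retained for correlation diagnostics. Missing
    replicate values trigger a warning and the mean uses what is available.
    """
    out = table.copy()
    if rep_cols is None:
        rep_cols = [c for c in table.columns if c.startswith("rpkm_rep")]
    if not rep_cols:
        raise ValueError("no replicate RPKM columns found")
    if out[rep_cols].isna().any().any():
        warnings.warn("missing replicate values; averaging available ones",
                      stacklevel=2)
    out["mean_rpkm"] = out[rep_cols].mean(axis=1, skipna=True)
    return out


def replicate_correlation(table: pd.DataFrame,
                          rep_cols: list[str] | None = None) -> float:
    """Squared Pearson correlation between the first two replicates
    (diagnostic only; ~0.98 in well-behaved libraries)."""
    if rep_cols is None:
        rep_cols = [c for c in table.columns if c.startswith("rpkm_rep")]
    if len(rep_cols) < 2:
        raise ValueError("need at least two replicates")
    r = np.corrcoef(table[rep_cols[0]], table[rep_cols[1]])[0, 1]
    return float(r ** 2)


class IntergenicThreshold(BaseEstimator):
    """Expressed-gene cutoff from the intergenic background distribution.

    ``fit`` selects the smallest observed background value such that the
    fraction of background values at or above it does not exceed ``alpha``
    (a tight empirical quantile: the type-I bound is exact on the sample,
    with no interpolation). ``predict`` flags expression values at or above
    the threshold.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA):
        self.alpha = alpha

    def fit(self, intergenic_rpkms, y=None):
        v = np.sort(np.asarray(intergenic_rpkms, dtype=float).ravel())
        if v.size < MIN_INTERGENIC:
            raise ValueError(
                f"need at least {MIN_INTERGENIC} intergenic values, got {v.size}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        n = v.size
        k_max = int(np.floor(self.alpha * n))  # largest allowed exceedance count
        uniq = np.unique(v)
        counts_ge = n - np.searchsorted(v, uniq, side="left")
        ok = np.flatnonzero(counts_ge <= k_max)
        if ok.size:
            self.threshold_ = float(uniq[ok[0]])
            self.n_exceeding_ = int(counts_ge[ok[0]])
        elif uniq.size == 1:
            # Degenerate background (all values tied): the tie value itself.
            self.threshold_ = float(uniq[-1])
            self.n_exceeding_ = int(counts_ge[-1])
        else:
            # alpha below 1/n: no observed value satisfies the bound; take
            # the smallest value strictly above the maximum.
            self.threshold_ = float(np.nextafter(uniq[-1], np.inf))
            self.n_exceeding_ = 0
        self.n_background_ = n
        self.type_i_rate_ = self.n_exceeding_ / n
        return self

    def predict(self, mean_rpkm) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise AttributeError("fit the threshold first")
        return np.asarray(mean_rpkm, dtype=float) >= self.threshold_


def expression_threshold(intergenic_rpkms,
                         alpha: float = DEFAULT_ALPHA) -> float:
    """Functional wrapper around :class:`IntergenicThreshold`."""
    return IntergenicThreshold(alpha=alpha).fit(intergenic_rpkms).threshold_


def call_expressed(table: pd.DataFrame, threshold: float,
                   col: str = "mean_rpkm") -> pd.DataFrame:
    """Flag genes with ``col`` at or above the threshold ("no less than")."""
    out = table.copy()
    out["expressed"] = out[col] >= threshold
    logger.info("call_expressed: %d of %d genes at/above %.3g RPKM",
                int(out["expressed"].sum()), len(out), threshold)
    return out
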