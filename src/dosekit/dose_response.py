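"""Saturating dose-response fitting and the compensation decomposition.

The scaled dose-response model is y = x(EC50+1)/(EC50+x): x is gene dose
relative to the chromosome-class baseline (X baseline 2 copies, autosomes
4), y is median expression relative to the baseline median, and EC50 is the
scaled dose at half-maximal expression. The model passes through (1, 1) for
every EC50 and saturates at EC50+1.

The decomposition multiplies the dose-responsive fold (the fitted curve
evaluated at a 2-fold scaled dose) by the MSL fixed fold estimated from the
knockdown, giving the composite X-compensation fold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import DoseResponseFit
from .simulate import saturating_response

X_BASELINE_COPY = 2
A_BASELINE_COPY = 4
DEFAULT_MIN_GENES = 25


class SaturationDoseResponse(BaseEstimator, RegressorMixin):
    """One-parameter least-squares fit of y = x(EC50+1)/(EC50+x).

    The objective is unimodal in EC50; the optimum is located by a bounded
    1-D search (Brent) refined to ``xatol``.

    Attributes: ``ec50_``, ``r2_``, ``residuals_``.
    """

    def __init__(self, bounds: tuple[float, float] = (1e-4, 1e4),
                 xatol: float = 1e-8):
        self.bounds = bounds
        self.xatol = xatol

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("x and y must have the same length")
        if np.any(x <= 0):
            raise ValueError("scaled doses must be positive")
        if np.count_nonzero(~np.isclose(x, 1.0)) < 2:
            raise ValueError(
                "need at least 2 points away from x = 1; "
                "the model is unidentifiable at the normalization point")

        def sse(log_e: float) -> float:
            e = np.exp(log_e)
            r = y - saturating_response(x, e)
            return float(r @ r)

        lo, hi = self.bounds
        res = minimize_scalar(sse, bounds=(np.log(lo), np.log(hi)),
                              method="bounded",
                              options={"xatol": self.xatol})
        self.ec50_ = float(np.exp(res.x))
        self.residuals_ = y - saturating_response(x, self.ec50_)
        ss_res = float(self.residuals_ @ self.residuals_)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_points_ = x.size
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "ec50_"):
            raise AttributeError("fit the model first")
        return saturating_response(np.asarray(X, dtype=float).reshape(-1),
                                   self.ec50_)


def scale_curves(summaries: dict[str, pd.DataFrame],
                 mock_key: str = "mock", rnai_key: str | None = None,
                 x_baseline_copy: int = X_BASELINE_COPY,
                 a_baseline_copy: int = A_BASELINE_COPY,
                 min_genes: int = DEFAULT_MIN_GENES) -> pd.DataFrame:
    """Scale per-copy medians to relative dose/expression points.

    Emits three curves — ``autosome`` (mock), ``X-mock`` and ``X-rnai`` —
    each normalised so its baseline cell (X copy 2; autosome copy 4) maps
    exactly to (1, 1). Normalising each curve by its own baseline removes
    both absolute expression scale and the MSL multiplier, which is what
    lets a common saturation curve describe all three.
    """
    if rnai_key is None:
        rnai_key = next((k for k in summaries if k != mock_key), None)
    specs = [("autosome", mock_key, "autosome", a_baseline_copy),
             ("X-mock", mock_key, "X", x_baseline_copy)]
    if rnai_key is not None:
        specs.append(("X-rnai", rnai_key, "X", x_baseline_copy))
    rows = []
    for curve, cond_key, cls, baseline_copy in specs:
        summ = summaries[cond_key]
        if not (summ["class"] == cls).any():
            continue  # class absent from this dataset: no curve to scale
        cells = summ[(summ["class"] == cls) & (summ["n_genes"] >= min_genes)]
        base = cells[cells["copy"] == baseline_copy]
        if base.empty:
            raise ValueError(
                f"missing baseline cell (copy {baseline_copy}) for {curve}")
        base_median = float(base["median_rpkm"].iloc[0])
        for _, cell in cells.iterrows():
            rows.append((curve, int(cell["copy"]),
                         cell["copy"] / baseline_copy,
                         float(cell["median_rpkm"]),
                         float(cell["median_rpkm"]) / base_median,
                         int(cell["n_genes"])))
    return pd.DataFrame(rows, columns=["curve", "copy", "x", "median_rpkm",
                                       "y", "n_genes"])


def fit_ec50(points: pd.DataFrame, joint: bool = True) -> DoseResponseFit:
    """Fit the saturation model to scaled dose-response points.

    By default all curves are fit jointly with one shared EC50 (the scaled
    curves are expected to collapse onto a single dose response); per-curve
    fits are attached as a diagnostic when more than one curve is present.
    """
    model = SaturationDoseResponse().fit(points["x"], points["y"])
    per_curve = None
    if joint and points["curve"].nunique() > 1:
        per_curve = {}
        for curve, grp in points.groupby("curve", sort=False):
            if np.count_nonzero(~np.isclose(grp["x"], 1.0)) >= 2:
                m = SaturationDoseResponse().fit(grp["x"], grp["y"])
                per_curve[curve] = {"ec50": m.ec50_, "r2": m.r2_}
    return DoseResponseFit(ec50=model.ec50_, r2=model.r2_,
                           points=points.copy(),
                           residuals=model.residuals_, per_curve=per_curve)


def project_fold(ec50: float, x) -> np.ndarray | float:
    """Evaluate y = x(EC50+1)/(EC50+x) at scaled dose x."""
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("scaled dose must be non-negative")
    y = saturating_response(xa, ec50)
    return float(y) if y.ndim == 0 else y


def composite_fold(dose_fold: float, msl_fold: float,
                   observed_x_a_fold: float | None = None) -> dict:
    """Composite X-compensation fold: dose-responsive times feed-forward.

    Both components must be folds >= 1; the observed X:autosome expression
    fold, when available, is reported alongside for comparison (it is not
    part of the product).
    """
    if dose_fold < 1 or msl_fold < 1:
        raise ValueError("both folds must be >= 1")
    product = dose_fold * msl_fold
    out = {"dose_fold": float(dose_fold), "msl_fold": float(msl_fold),
           "composite_fold": round(float(product), 2)}
    if observed_x_a_fold is not None:
        out["observed_x_a_fold"] = float(observed_x_a_fold)
    return out
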