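"""Likelihood comparison of the two normalization hypotheses.

RPKM normalization cannot distinguish "X expression halved" from "autosomal
expression doubled" after MSL knockdown, because both change the sampled
transcript pool. Per-cell mRNA yield breaks the tie: with an X-encoded
expression fraction f, hypothesis H0 (X halves, autosomes unchanged)
predicts a total mRNA yield of (1 - f/2) of wild type, while H1 (autosomes
double, X unchanged) predicts f + 2(1 - f). With f = 0.2 these are 90% and
180% of wild type.

The observed knockdown yields are scored under each hypothesis with a
normal error model whose spread is pooled from the within-condition
replicate scatter; a positive log-likelihood difference LL(H0) - LL(H1)
favors X down-regulation. Only the sign and ordering of the difference are
meaningful — the magnitude depends on the assumed error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_X_FRACTION = 0.2

#: Measured S2-cell mRNA yields (pg/cell), duplicate RNA-Seq experiments.
S2_MRNA_YIELDS_PG = {
    "mock": (0.16, 0.17),
    "msl2_rnai": (0.15, 0.19),
    "mof_rnai": (0.14, 0.20),
}


@dataclass
class YieldData:
    """Per-condition replicate mRNA yields (pg/cell) and the X fraction."""

    yields: dict = field(default_factory=lambda: {k: list(v) for k, v in
                                                  S2_MRNA_YIELDS_PG.items()})
    x_fraction: float = DEFAULT_X_FRACTION

    def __post_init__(self) -> None:
        if not 0 < self.x_fraction < 1:
            raise ValueError("x_fraction must lie in (0, 1)")
        for cond, vals in self.yields.items():
            if any(v <= 0 for v in vals):
                raise ValueError(f"yields must be positive ({cond})")

    @property
    def mock(self) -> np.ndarray:
        return np.asarray(self.yields["mock"], dtype=float)

    def knockdowns(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v, dtype=float)
                for k, v in self.yields.items() if k != "mock"}


def expected_totals(x_fraction: float = DEFAULT_X_FRACTION) -> tuple[float, float]:
    """Expected knockdown mRNA total as a fraction of wild type.

    H0 (X halves, autosomes unchanged): x/2 + (1 - x) = 1 - x/2.
    H1 (autosomes double, X unchanged): x + 2(1 - x)  = 2 - x.
    """
    if not 0 < x_fraction < 1:
        raise ValueError("x_fraction must lie in (0, 1)")
    return 1.0 - x_fraction / 2.0, 2.0 - x_fraction


def _pooled_sd(yields: YieldData) -> float:
    ss = 0.0
    df = 0
    for vals in yields.yields.values():
        v = np.asarray(vals, dtype=float)
        if v.size >= 2:
            ss += float(np.sum((v - v.mean()) ** 2))
            df += v.size - 1
    if df == 0 or ss == 0:
        raise ValueError("cannot estimate replicate spread "
                         "(no replicate scatter available)")
    return float(np.sqrt(ss / df))


def delta_loglik(yields: YieldData | None = None,
                 x_fraction: float | None = None) -> dict:
    """LL(H0) - LL(H1) for the observed knockdown yields.

    Wild-type level is the mean mock yield; each hypothesis predicts the
    knockdown yield as expected_total * wild-type, and observed knockdown
    replicates are scored under Normal(prediction, pooled replicate SD).
    A positive difference favors H0 (X down-regulation).
    """
    if yields is None:
        yields = YieldData()
    if x_fraction is None:
        x_fraction = yields.x_fraction
    mock = yields.mock
    if mock.size < 2:
        raise ValueError("need at least 2 mock replicates")
    kd = yields.knockdowns()
    if not any(v.size for v in kd.values()):
        raise ValueError("need at least 1 knockdown replicate")
    wild_type = float(mock.mean())
    h0_frac, h1_frac = expected_totals(x_fraction)
    pred = {"H0": h0_frac * wild_type, "H1": h1_frac * wild_type}
    sd = _pooled_sd(yields)

    components = {}
    ll = {"H0": 0.0, "H1": 0.0}
    for cond, obs in kd.items():
        components[cond] = {}
        for hyp, mu in pred.items():
            v = float(np.sum(stats.norm.logpdf(obs, loc=mu, scale=sd)))
            components[cond][hyp] = v
            ll[hyp] += v
    return {
        "delta_loglik": ll["H0"] - ll["H1"],
        "loglik": ll,
        "components": components,
        "predictions_pg": pred,
        "wild_type_pg": wild_type,
        "pooled_sd_pg": sd,
        "x_fraction": x_fraction,
        "error_model": "normal, pooled within-condition replicate SD",
    }
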