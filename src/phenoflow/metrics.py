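"""Model-agreement statistics: normalised RMSE and Lin's concordance
correlation coefficient with the McBride interpretation categories.

Lin's CCC decomposes as ``rho_c = rho * Cb`` where ``rho`` is the Pearson
correlation and ``Cb = 2 / (v + 1/v + u^2)`` penalises scale
(``v = s1/s2``) and location (``u = (m1 - m2)/sqrt(s1*s2)``) departures
from the 45° line through the origin.  Moments are population
(divide-by-n) by default, matching Lin's original definition; a
sample-moment variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AgreementStats",
    "nrmse",
    "lins_ccc",
    "mcbride_category",
]

MCBRIDE_CUTS = (0.90, 0.95, 0.99)


@dataclass(frozen=True)
class AgreementStats:
    rho_c: float
    rho: float
    cb: float
    v: float
    u: float
    category: str

    def as_dict(self) -> dict:
        return {
            "rho_c": self.rho_c,
            "rho": self.rho,
            "cb": self.cb,
            "v": self.v,
            "u": self.u,
            "category": self.category,
        }


def nrmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error normalised by the mean observation."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    mean_obs = float(np.mean(obs))
    if mean_obs == 0.0:
        raise ValueError("mean of observed series is zero")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return rmse / mean_obs


def mcbride_category(rho_c: float) -> str:
    """Interpretation category for a concordance coefficient.

    <= 0.90 poor; (0.90, 0.95] moderate; (0.95, 0.99] substantial;
    > 0.99 almost perfect.
    """
    if not -1.0 <= rho_c <= 1.0:
        raise ValueError(f"rho_c {rho_c} outside [-1, 1]")
    if rho_c > MCBRIDE_CUTS[2]:
        return "almost perfect"
    if rho_c > MCBRIDE_CUTS[1]:
        return "substantial"
    if rho_c > MCBRIDE_CUTS[0]:
        return "moderate"
    return "poor"


def lins_ccc(
    observed: Sequence[float],
    predicted: Sequence[float],
    sample_moments: bool = False,
) -> AgreementStats:
    """Lin's concordance correlation coefficient and its decomposition.

    Parameters
    ----------
    observed, predicted : sequences of equal length >= 2
        Both must be non-constant.
    sample_moments : bool, optional
        Use ddof=1 standard deviations instead of population moments.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length series of length >= 2")
    ddof = 1 if sample_moments else 0
    s1 = float(np.std(obs, ddof=ddof))
    s2 = float(np.std(pred, ddof=ddof))
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("constant series: concordance undefined")
    m1 = float(np.mean(obs))
    m2 = float(np.mean(pred))
    rho = float(np.corrcoef(obs, pred)[0, 1])
    v = s1 / s2
    u = (m1 - m2) / np.sqrt(s1 * s2)
    cb = 2.0 / (v + 1.0 / v + u * u)
    rho_c = rho * cb
    return AgreementStats(
        rho_c=rho_c,
        rho=rho,
        cb=cb,
        v=v,
        u=float(u),
        category=mcbride_category(rho_c),
    )
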