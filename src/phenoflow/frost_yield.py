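"""Post-flowering frost counting and the per-event yield penalty.

A frost event is a day with minimum temperature at or below the threshold
(0 °C by default) falling strictly after flowering and up to the window
end.  Each event removes a fixed fraction (5% by default) of the
potential yield; the penalised yield is floored at zero.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .weather import WeatherSeries

__all__ = [
    "FrostAssessment",
    "count_post_flowering_frosts",
    "apply_frost_penalty",
    "assess_frost",
]


@dataclass(frozen=True)
class FrostAssessment:
    """Frost-event count and the resulting yield figures (kg/ha)."""

    n_events: int
    yield_potential: float  # YieldW, at 12% seed moisture
    yield_lost: float  # YieldL
    yield_gm: float  # YieldGM = max(YieldW - YieldL, 0)
    window: tuple[dt.date, dt.date] | None = None

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if not 0.0 <= self.yield_lost <= self.yield_potential:
            raise ValueError("yield_lost must lie in [0, yield_potential]")


def count_post_flowering_frosts(
    weather: WeatherSeries,
    flowering: dt.date,
    end: dt.date,
    threshold: float = 0.0,
) -> int:
    """Number of frost days strictly after ``flowering`` up to ``end``.

    A frost day has ``tmin <= threshold`` (boundary inclusive).
    """
    if flowering > end:
        raise ValueError("flowering date after window end")
    if flowering < weather.start or end > weather.end:
        raise ValueError("frost window outside weather series")
    n = 0
    d = flowering + dt.timedelta(days=1)
    while d <= end:
        if weather.day(d).tmin <= threshold:
            n += 1
        d += dt.timedelta(days=1)
    return n


def apply_frost_penalty(
    yield_w: float,
    n_events: int,
    loss_per_event: float = 0.05,
    window: tuple[dt.date, dt.date] | None = None,
) -> FrostAssessment:
    """Apply the per-event yield penalty.

    ``YieldL = YieldW * n * loss_per_event`` capped at ``YieldW``;
    ``YieldGM = YieldW - YieldL`` (never negative).
    """
    if yield_w < 0:
        raise ValueError("potential yield must be non-negative")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    if not 0.0 <= loss_per_event <= 1.0:
        raise ValueError("loss_per_event must lie in [0, 1]")
    yield_l = min(yield_w * n_events * loss_per_event, yield_w)
    return FrostAssessment(
        n_events=n_events,
        yield_potential=yield_w,
        yield_lost=yield_l,
        yield_gm=max(yield_w - yield_l, 0.0),
        window=window,
    )


def assess_frost(
    weather: WeatherSeries,
    flowering: dt.date,
    end: dt.date,
    yield_w: float,
    threshold: float = 0.0,
    loss_per_event: float = 0.05,
) -> FrostAssessment:
    """Count frosts in the window and apply the penalty in one call."""
    n = count_post_flowering_frosts(weather, flowering, end, threshold)
    return apply_frost_penalty(
        yield_w, n, loss_per_event, window=(flowering, end)
    )
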