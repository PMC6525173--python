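"""Chickpea flowering engine: staged thermal-time development with a
photoperiod-interpolated phase target and a soil-water modification of
daily thermal time.

Daily thermal time (TT) comes from a cardinal-temperature response of the
daily mean (base 0 °C, optimum 30 °C, ceiling 40 °C by default).  While the
crop is between emergence and flowering and the 0–60 cm fraction of
available soil water (FASW) is at or above a threshold, the day's TT is
replaced by

    TTm = TT * (constant - min(FASW, 1))

with ``constant = 1.65`` and threshold 0.65 by default, so wet topsoil
slows thermal-time accumulation (multiplier 1 at the threshold, down to
0.65 at field capacity) and delays flowering.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd

from .soil import (
    SoilProfile,
    SoilWaterState,
    compute_fasw,
    hargreaves_et0,
    initialize_state,
    step_water_balance,
)
from .weather import DEFAULT_TWILIGHT_ANGLE, WeatherSeries, daylength

__all__ = [
    "Stage",
    "CardinalTemps",
    "SWModificationParams",
    "ChickpeaCultivarParams",
    "PhenologyTrace",
    "daily_thermal_time",
    "phase_target",
    "modify_tt",
    "advance_stage",
    "simulate_chickpea",
    "get_chickpea_cultivar",
    "CHICKPEA_CULTIVARS",
    "DEFAULT_CARDINALS",
]


class Stage(IntEnum):
    """Development stage codes (emergence = 3, flowering = 6)."""

    SOWING = 1
    GERMINATION = 2
    EMERGENCE = 3
    END_JUVENILE = 4
    FLORAL_INIT = 5
    FLOWERING = 6
    START_GRAIN = 7
    END_GRAIN = 8
    MATURITY = 9
    HARVEST_RIPE = 10


@dataclass(frozen=True)
class CardinalTemps:
    """Base / optimum / ceiling temperatures of the TT response, °C."""

    base: float = 0.0
    optimum: float = 30.0
    ceiling: float = 40.0

    def __post_init__(self) -> None:
        if not self.base < self.optimum < self.ceiling:
            raise ValueError("require base < optimum < ceiling")


DEFAULT_CARDINALS = CardinalTemps()


@dataclass(frozen=True)
class SWModificationParams:
    """Parameters of the soil-water thermal-time modification.

    The multiplier ``constant - min(FASW, 1)`` is applied when the stage
    lies in ``[min_stage, max_stage)`` and FASW >= ``threshold``; with the
    defaults it equals 1 exactly at the threshold and bottoms out at
    ``constant - 1`` when the zone is at or above drained upper limit.
    """

    constant: float = 1.65
    threshold: float = 0.65
    min_stage: int = int(Stage.EMERGENCE)
    max_stage: int = int(Stage.FLOWERING)
    zone_depth: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        if self.constant <= self.threshold:
            raise ValueError("constant must exceed threshold")
        if self.zone_depth <= 0:
            raise ValueError("zone_depth must be positive")


@dataclass(frozen=True)
class ChickpeaCultivarParams:
    """Phase thermal-time targets and photoperiod response of a cultivar.

    ``pp_knots`` / ``tt_endjuv_to_init_at_knots`` define the piecewise-
    linear photoperiod response of the end-juvenile → floral-initiation
    target (flat beyond the end knots).  The emergence target is
    ``emergence_lag + emergence_rate * sowing depth (mm)``.
    """

    name: str
    pp_knots: tuple[float, ...]
    tt_endjuv_to_init_at_knots: tuple[float, ...]
    tt_emerg_to_endjuv: float
    tt_init_to_flower: float = 33.0
    tt_flower_to_start_grain: float = 450.0
    tt_start_to_end_grain: float = 690.0
    tt_end_grain_to_maturity: float = 60.0
    tt_maturity_to_ripe: float = 1.0
    emergence_lag: float = 40.0  # °Cd
    emergence_rate: float = 1.0  # °Cd per mm sowing depth

    def __post_init__(self) -> None:
        if len(self.pp_knots) != len(self.tt_endjuv_to_init_at_knots):
            raise ValueError("pp_knots and targets must have equal length")
        if len(self.pp_knots) < 2:
            raise ValueError("need at least two photoperiod knots")
        if any(b <= a for a, b in zip(self.pp_knots, self.pp_knots[1:])):
            raise ValueError("pp_knots must be strictly ascending")
        for f in (
            "tt_emerg_to_endjuv",
            "tt_init_to_flower",
            "tt_flower_to_start_grain",
            "tt_start_to_end_grain",
            "tt_end_grain_to_maturity",
            "tt_maturity_to_ripe",
            "emergence_lag",
            "emergence_rate",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if any(t < 0 for t in self.tt_endjuv_to_init_at_knots):
            raise ValueError("photoperiod targets must be non-negative")


# Cultivar library.  "original" carries the 10.7–17 h photoperiod range
# and the 515 °Cd juvenile phase; "soilwater" is the re-parameterisation
# used together with the FASW modification (upper knot 12 h, longer
# juvenile phase: 660 °Cd for PBA HatTrick/Boundary, 690 °Cd for Tyson).
CHICKPEA_CULTIVARS: dict[str, dict[str, ChickpeaCultivarParams]] = {
    "hattrick": {
        "original": ChickpeaCultivarParams(
            name="PBA HatTrick (original)",
            pp_knots=(10.7, 17.0),
            tt_endjuv_to_init_at_knots=(446.0, 0.0),
            tt_emerg_to_endjuv=515.0,
        ),
        "soilwater": ChickpeaCultivarParams(
            name="PBA HatTrick (soilwater)",
            pp_knots=(10.7, 12.0),
            tt_endjuv_to_init_at_knots=(446.0, 0.0),
            tt_emerg_to_endjuv=660.0,
        ),
    },
    "boundary": {
        "original": ChickpeaCultivarParams(
            name="PBA Boundary (original)",
            pp_knots=(10.7, 17.0),
            tt_endjuv_to_init_at_knots=(446.0, 0.0),
            tt_emerg_to_endjuv=515.0,
        ),
        "soilwater": ChickpeaCultivarParams(
            name="PBA Boundary (soilwater)",
            pp_knots=(10.7, 12.0),
            tt_endjuv_to_init_at_knots=(446.0, 0.0),
            tt_emerg_to_endjuv=660.0,
        ),
    },
    "tyson": {
        "original": ChickpeaCultivarParams(
            name="Tyson (original)",
            pp_knots=(10.1, 17.0),
            tt_endjuv_to_init_at_knots=(468.3, 0.0),
            tt_emerg_to_endjuv=515.0,
        ),
        "soilwater": ChickpeaCultivarParams(
            name="Tyson (soilwater)",
            pp_knots=(10.1, 12.0),
            tt_endjuv_to_init_at_knots=(468.3, 0.0),
            tt_emerg_to_endjuv=690.0,
        ),
    },
}


def get_chickpea_cultivar(
    name: str, variant: str = "soilwater"
) -> ChickpeaCultivarParams:
    """Look up a cultivar parameter set (variant: original | soilwater)."""
    key = name.lower().replace("pba ", "").strip()
    try:
        return CHICKPEA_CULTIVARS[key][variant]
    except KeyError as exc:
        raise KeyError(f"unknown cultivar/variant {name!r}/{variant!r}") from exc


# ---------------------------------------------------------------------------
# Core daily operations


def daily_thermal_time(
    tmax: float, tmin: float, cardinals: CardinalTemps = DEFAULT_CARDINALS
) -> float:
    """Daily thermal time (°Cd) from a cardinal response of the daily mean.

    Zero at or below base; ``mean - base`` up to the optimum; linear
    decline from ``optimum - base`` at the optimum down to zero at the
    ceiling; zero beyond.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    m = 0.5 * (tmax + tmin)
    if m <= cardinals.base or m >= cardinals.ceiling:
        return 0.0
    if m <= cardinals.optimum:
        return m - cardinals.base
    peak = cardinals.optimum - cardinals.base
    return peak * (cardinals.ceiling - m) / (cardinals.ceiling - cardinals.optimum)


def phase_target(
    pp: float, knots: Sequence[float], targets: Sequence[float]
) -> float:
    """Piecewise-linear photoperiod interpolation of a phase target (°Cd).

    Flat extrapolation beyond the end knots (``numpy.interp`` semantics).
    """
    if len(knots) != len(targets):
        raise ValueError("knots and targets must have equal length")
    return float(np.interp(pp, np.asarray(knots), np.asarray(targets)))


def modify_tt(
    tt: float,
    fasw: float,
    stage: int,
    params: SWModificationParams,
) -> float:
    """Soil-water-modified daily thermal time.

    When ``min_stage <= stage < max_stage`` and ``fasw >= threshold``:
    ``tt * (constant - min(fasw, 1))``; otherwise ``tt`` unchanged.  At
    the threshold the multiplier equals ``constant - threshold`` (exactly
    1 with the defaults), so the gate opens continuously.
    """
    if tt < 0:
        raise ValueError("tt must be non-negative")
    if params.min_stage <= stage < params.max_stage and fasw >= params.threshold:
        return tt * (params.constant - min(fasw, 1.0))
    return tt


def advance_stage(
    stage: int,
    cum_phase: float,
    ttm_today: float,
    target_fn,
    final_stage: int = int(Stage.HARVEST_RIPE),
) -> tuple[int, float]:
    """Accumulate today's (modified) thermal time and advance stages.

    ``target_fn(stage)`` returns the current phase's target; when the
    accumulated total meets it the surplus rolls into the next phase
    (zero-target phases pass through on the same day).
    """
    cum_phase += ttm_today
    while stage < final_stage:
        tgt = target_fn(stage)
        if cum_phase < tgt:
            break
        cum_phase -= tgt
        stage += 1
    return stage, cum_phase


# ---------------------------------------------------------------------------
# Trace and simulation


@dataclass
class PhenologyTrace:
    """Per-day development record plus run-level summary."""

    sowing_date: dt.date
    dates: list[dt.date] = field(default_factory=list)
    stages: list[int] = field(default_factory=list)
    tt: list[float] = field(default_factory=list)
    ttm: list[float] = field(default_factory=list)
    fasw: list[float] = field(default_factory=list)
    daylength_h: list[float] = field(default_factory=list)
    cum_phase: list[float] = field(default_factory=list)
    flowering_date: dt.date | None = None
    maturity_date: dt.date | None = None
    tt_cum_at_flowering: float | None = None

    @property
    def flowered(self) -> bool:
        return self.flowering_date is not None

    @property
    def days_to_flowering(self) -> int | None:
        if self.flowering_date is None:
            return None
        return (self.flowering_date - self.sowing_date).days

    @property
    def days_to_maturity(self) -> int | None:
        if self.maturity_date is None:
            return None
        return (self.maturity_date - self.sowing_date).days

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "stage": self.stages,
                "tt": self.tt,
                "ttm": self.ttm,
                "fasw": self.fasw,
                "daylength": self.daylength_h,
                "cum_phase": self.cum_phase,
            }
        )

    def summary(self) -> dict:
        return {
            "sowing_date": self.sowing_date.isoformat(),
            "flowered": self.flowered,
            "days_to_flowering": self.days_to_flowering,
            "days_to_maturity": self.days_to_maturity,
            "flowering_date": (
                self.flowering_date.isoformat() if self.flowering_date else None
            ),
            "maturity_date": (
                self.maturity_date.isoformat() if self.maturity_date else None
            ),
            "tt_cum_at_flowering": self.tt_cum_at_flowering,
        }


# crop coefficient by stage for the transpiration demand kc * ET0
DEFAULT_KC = {
    int(Stage.SOWING): 0.0,
    int(Stage.GERMINATION): 0.0,
    int(Stage.EMERGENCE): 0.4,
    int(Stage.END_JUVENILE): 0.7,
    int(Stage.FLORAL_INIT): 0.9,
    int(Stage.FLOWERING): 1.0,
    int(Stage.START_GRAIN): 1.0,
    int(Stage.END_GRAIN): 0.9,
    int(Stage.MATURITY): 0.5,
    int(Stage.HARVEST_RIPE): 0.2,
}


def simulate_chickpea(
    weather: WeatherSeries,
    profile: SoilProfile,
    cultivar: ChickpeaCultivarParams,
    sowing_date: dt.date,
    sowing_depth_mm: float = 50.0,
    sw_params: SWModificationParams | None = None,
    starting_water: float = 0.5,
    init_mode: str = "uniform",
    cardinals: CardinalTemps = DEFAULT_CARDINALS,
    twilight_angle: float = DEFAULT_TWILIGHT_ANGLE,
    root_rate_mm_per_cd: float = 0.7,
    soil_evap_coeff: float = 0.6,
    kc: dict[int, float] | None = None,
    stop_stage: int = int(Stage.MATURITY),
) -> PhenologyTrace:
    """Run the daily chickpea development loop from sowing.

    Per day: thermal time → daylength → photoperiod phase target → soil
    water balance step → FASW → soil-water modification → stage advance
    (modify-then-advance).  Passing ``sw_params=None`` disables the
    modification entirely, reproducing a temperature-and-photoperiod-only
    model.  If the weather series ends before flowering the trace reports
    ``flowered = False`` rather than raising.
    """
    if not weather.start <= sowing_date <= weather.end:
        raise ValueError("sowing date outside weather series")
    kc = kc if kc is not None else DEFAULT_KC

    state = initialize_state(profile, starting_water, init_mode)
    stage = int(Stage.SOWING)
    cum_phase = 0.0
    cum_tt_unadjusted = 0.0  # raw TT accumulated from germination onward
    cum_tt_for_roots = 0.0
    trace = PhenologyTrace(sowing_date=sowing_date)

    emergence_target = (
        cultivar.emergence_lag + cultivar.emergence_rate * sowing_depth_mm
    )
    phase_targets_static = {
        int(Stage.GERMINATION): emergence_target,
        int(Stage.EMERGENCE): cultivar.tt_emerg_to_endjuv,
        int(Stage.FLORAL_INIT): cultivar.tt_init_to_flower,
        int(Stage.FLOWERING): cultivar.tt_flower_to_start_grain,
        int(Stage.START_GRAIN): cultivar.tt_start_to_end_grain,
        int(Stage.END_GRAIN): cultivar.tt_end_grain_to_maturity,
        int(Stage.MATURITY): cultivar.tt_maturity_to_ripe,
    }

    for i, day in enumerate(weather.from_date(sowing_date)):
        doy = day.date.timetuple().tm_yday
        tt = daily_thermal_time(day.tmax, day.tmin, cardinals)
        dl = daylength(weather.latitude, doy, twilight_angle)

        def target_fn(s: int, _dl: float = dl) -> float:
            if s == int(Stage.END_JUVENILE):
                return phase_target(
                    _dl, cultivar.pp_knots, cultivar.tt_endjuv_to_init_at_knots
                )
            return phase_targets_static[s]

        # water balance first, then FASW for today's modification
        root_depth_cm = min(
            sowing_depth_mm / 10.0 + root_rate_mm_per_cd * cum_tt_for_roots / 10.0,
            profile.depth_cm,
        )
        et0 = hargreaves_et0(day.tmax, day.tmin, weather.latitude, doy)
        demand = kc.get(stage, 0.0) * et0
        state = step_water_balance(
            profile,
            state,
            day,
            transpiration_demand=demand,
            root_depth=root_depth_cm,
            pot_soil_evap=soil_evap_coeff * et0,
        )
        zone = sw_params.zone_depth if sw_params is not None else 60.0
        fasw = compute_fasw(profile, state, min(zone, profile.depth_cm))

        ttm = tt
        if stage == int(Stage.SOWING):
            # germination: minimal moisture trigger from the day after sowing
            ttm = 0.0
            if i > 0 and state.sw[0] > profile.layers[0].ll15:
                stage = int(Stage.GERMINATION)
        elif stage >= int(Stage.GERMINATION):
            if sw_params is not None:
                ttm = modify_tt(tt, fasw, stage, sw_params)
            cum_tt_unadjusted += tt
            cum_tt_for_roots += tt
            prev_stage = stage
            stage, cum_phase = advance_stage(
                stage, cum_phase, ttm, target_fn, final_stage=stop_stage
            )
            if (
                prev_stage < int(Stage.FLOWERING) <= stage
                and trace.flowering_date is None
            ):
                trace.flowering_date = day.date
                trace.tt_cum_at_flowering = cum_tt_unadjusted
            if (
                prev_stage < int(Stage.MATURITY) <= stage
                and trace.maturity_date is None
            ):
                trace.maturity_date = day.date

        trace.dates.append(day.date)
        trace.stages.append(stage)
        trace.tt.append(tt)
        trace.ttm.append(ttm)
        trace.fasw.append(fasw)
        trace.daylength_h.append(dl)
        trace.cum_phase.append(cum_phase)

        if stage >= stop_stage:
            break

    return trace
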