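"""Wheat flowering engine.

Wheat development runs on the same staged thermal-time chain as chickpea
but, between emergence and floral initiation, the day's thermal time is
first reduced by the more limiting of a photoperiod factor and a
vernalisation factor (``TT * min(f_p, f_v)``).  The soil-water
modification is then applied on top of the reduced value when its gate is
open.  The factor equations follow the usual wheat-model conventions:

    f_p = 1 - 0.002 * Rp * (20 - pp)^2          (clamped to [0, 1])
    f_v = 1 - (6/1100) * Rv * (50 - V)          (clamped to [0, 1])

with V the cumulative vernal days, accrued on cool days and partially
reversed on hot days while V < 10.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .phenology_chickpea import (
    DEFAULT_CARDINALS,
    DEFAULT_KC,
    CardinalTemps,
    PhenologyTrace,
    SWModificationParams,
    Stage,
    advance_stage,
    daily_thermal_time,
    modify_tt,
)
from .soil import (
    SoilProfile,
    compute_fasw,
    hargreaves_et0,
    initialize_state,
    step_water_balance,
)
from .weather import DEFAULT_TWILIGHT_ANGLE, WeatherSeries, daylength

__all__ = [
    "WheatCultivarParams",
    "VernalisationState",
    "photoperiod_factor",
    "vernalisation_step",
    "simulate_wheat",
    "WHEAT_VARIANTS",
    "get_wheat_variant",
]

VERN_COEFF = 0.0054545  # per vernal day per unit sensitivity
VERN_SATURATION = 50.0  # vernal days at which f_v saturates at 1


@dataclass(frozen=True)
class WheatCultivarParams:
    """Wheat development parameters.

    ``photoperiod_sensitivity`` (Rp) is on a 0–5 scale;
    ``vernalisation_sensitivity`` (Rv) likewise dimensionless.
    ``tt_to_floral_init`` is the emergence → floral initiation thermal
    target (the phase the factors act on); ``tt_init_to_flower`` the
    remaining plain-TT chain to flowering.
    """

    name: str
    photoperiod_sensitivity: float
    vernalisation_sensitivity: float
    tt_to_floral_init: float = 555.0
    tt_init_to_flower: float = 680.0
    emergence_lag: float = 40.0
    emergence_rate: float = 1.0  # °Cd per mm sowing depth

    def __post_init__(self) -> None:
        if self.photoperiod_sensitivity < 0:
            raise ValueError("photoperiod sensitivity must be >= 0")
        if self.vernalisation_sensitivity < 0:
            raise ValueError("vernalisation sensitivity must be >= 0")
        for f in ("tt_to_floral_init", "tt_init_to_flower"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class VernalisationState:
    """Cumulative vernal days and the devernalisation tally."""

    v: float = 0.0
    devernalised: float = 0.0

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("vernal days must be non-negative")


def photoperiod_factor(pp: float, rp: float) -> float:
    """Photoperiod development factor in [0, 1]; 1 at pp >= 20 h."""
    if not 0.0 <= pp <= 24.0:
        raise ValueError(f"photoperiod {pp} outside [0, 24]")
    if pp >= 20.0 or rp == 0.0:
        return 1.0
    f = 1.0 - 0.002 * rp * (20.0 - pp) ** 2
    return min(1.0, max(0.0, f))


def vernalisation_step(
    state: VernalisationState, tmax: float, tmin: float, rv: float
) -> tuple[VernalisationState, float]:
    """Accrue one day of vernalisation and return (new state, f_v).

    Cool days (tmax < 30 °C and tmin < 15 °C) add up to one vernal day;
    hot days (tmax > 30 °C) remove up to half a vernal day per degree
    above 30 while fewer than 10 have accumulated.  ``f_v`` is 1 once
    50 vernal days have accrued or for an insensitive cultivar.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    v = state.v
    dev = state.devernalised
    tmean = 0.5 * (tmax + tmin)
    if tmax < 30.0 and tmin < 15.0:
        dv = min(
            1.4 - 0.0778 * tmean,
            0.5 + 13.44 * tmean / (tmax - tmin + 3.0) ** 2,
        )
        v += min(1.0, max(0.0, dv))
    elif tmax > 30.0 and v < 10.0:
        loss = min(0.5 * (tmax - 30.0), v)
        v -= loss
        dev += loss
    if rv == 0.0 or v >= VERN_SATURATION:
        f_v = 1.0
    else:
        f_v = 1.0 - VERN_COEFF * rv * (VERN_SATURATION - v)
        f_v = min(1.0, max(0.0, f_v))
    return VernalisationState(v=v, devernalised=dev), f_v


# Named model configurations: the stock parameterisation, the gene-based
# re-estimate, and the reduced-sensitivity set without / with the
# soil-water modification.
WHEAT_VARIANTS: dict[str, tuple[WheatCultivarParams, SWModificationParams | None]] = {
    "original": (
        WheatCultivarParams(
            name="Gregory (original)",
            photoperiod_sensitivity=3.2,
            vernalisation_sensitivity=2.7,
            tt_to_floral_init=555.0,
        ),
        None,
    ),
    "zheng": (
        WheatCultivarParams(
            name="Gregory (gene-based)",
            photoperiod_sensitivity=2.6,
            vernalisation_sensitivity=0.9,
            tt_to_floral_init=715.0,
        ),
        None,
    ),
    "reduced": (
        WheatCultivarParams(
            name="Gregory (reduced)",
            photoperiod_sensitivity=2.6,
            vernalisation_sensitivity=1.98,
            tt_to_floral_init=555.0,
        ),
        None,
    ),
    "reduced_sw": (
        WheatCultivarParams(
            name="Gregory (reduced + soilwater)",
            photoperiod_sensitivity=2.6,
            vernalisation_sensitivity=1.98,
            tt_to_floral_init=555.0,
        ),
        SWModificationParams(),
    ),
}


def get_wheat_variant(
    name: str,
) -> tuple[WheatCultivarParams, SWModificationParams | None]:
    """Named model variant: original | zheng | reduced | reduced_sw."""
    key = name.lower().replace("+", "_").replace(" ", "").replace("sw", "sw")
    key = {"reduced_sw": "reduced_sw", "reducedsw": "reduced_sw"}.get(key, key)
    try:
        return WHEAT_VARIANTS[key]
    except KeyError as exc:
        raise KeyError(f"unknown wheat variant {name!r}") from exc


def simulate_wheat(
    weather: WeatherSeries,
    profile: SoilProfile,
    cultivar: WheatCultivarParams,
    sowing_date: dt.date,
    sowing_depth_mm: float = 50.0,
    sw_params: SWModificationParams | None = None,
    starting_water: float = 0.5,
    init_mode: str = "uniform",
    cardinals: CardinalTemps = DEFAULT_CARDINALS,
    twilight_angle: float = DEFAULT_TWILIGHT_ANGLE,
    root_rate_mm_per_cd: float = 0.7,
    soil_evap_coeff: float = 0.6,
    initial_vernal_days: float = 0.0,
) -> PhenologyTrace:
    """Run the daily wheat development loop from sowing to flowering.

    Identical orchestration to the chickpea engine; the photoperiod /
    vernalisation factors reduce thermal time between emergence and
    floral initiation, and the soil-water modification (when enabled)
    applies to the reduced value over its stage gate.
    """
    if not weather.start <= sowing_date <= weather.end:
        raise ValueError("sowing date outside weather series")

    state = initialize_state(profile, starting_water, init_mode)
    vern = VernalisationState(v=initial_vernal_days)
    stage = int(Stage.SOWING)
    cum_phase = 0.0
    cum_tt_unadjusted = 0.0
    cum_tt_for_roots = 0.0
    trace = PhenologyTrace(sowing_date=sowing_date)

    emergence_target = (
        cultivar.emergence_lag + cultivar.emergence_rate * sowing_depth_mm
    )
    # wheat chain: emergence accrues straight to floral initiation (the
    # end-juvenile code passes through with a zero target), then a plain
    # thermal chain to flowering
    targets = {
        int(Stage.GERMINATION): emergence_target,
        int(Stage.EMERGENCE): cultivar.tt_to_floral_init,
        int(Stage.END_JUVENILE): 0.0,
        int(Stage.FLORAL_INIT): cultivar.tt_init_to_flower,
    }

    for i, day in enumerate(weather.from_date(sowing_date)):
        doy = day.date.timetuple().tm_yday
        tt = daily_thermal_time(day.tmax, day.tmin, cardinals)
        dl = daylength(weather.latitude, doy, twilight_angle)

        vern, f_v = vernalisation_step(
            vern, day.tmax, day.tmin, cultivar.vernalisation_sensitivity
        )
        f_p = photoperiod_factor(
            min(dl, 24.0), cultivar.photoperiod_sensitivity
        )

        root_depth_cm = min(
            sowing_depth_mm / 10.0 + root_rate_mm_per_cd * cum_tt_for_roots / 10.0,
            profile.depth_cm,
        )
        et0 = hargreaves_et0(day.tmax, day.tmin, weather.latitude, doy)
        demand = DEFAULT_KC.get(stage, 0.0) * et0
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
            ttm = 0.0
            if i > 0 and state.sw[0] > profile.layers[0].ll15:
                stage = int(Stage.GERMINATION)
        elif stage >= int(Stage.GERMINATION):
            eff = tt
            if int(Stage.EMERGENCE) <= stage < int(Stage.FLORAL_INIT):
                eff = tt * min(f_p, f_v)
            ttm = eff
            if sw_params is not None:
                ttm = modify_tt(eff, fasw, stage, sw_params)
            cum_tt_unadjusted += tt
            cum_tt_for_roots += tt
            prev_stage = stage
            stage, cum_phase = advance_stage(
                stage,
                cum_phase,
                ttm,
                lambda s: targets[s],
                final_stage=int(Stage.FLOWERING),
            )
            if (
                prev_stage < int(Stage.FLOWERING) <= stage
                and trace.flowering_date is None
            ):
                trace.flowering_date = day.date
                trace.tt_cum_at_flowering = cum_tt_unadjusted

        trace.dates.append(day.date)
        trace.stages.append(stage)
        trace.tt.append(tt)
        trace.ttm.append(ttm)
        trace.fasw.append(fasw)
        trace.daylength_h.append(dl)
        trace.cum_phase.append(cum_phase)

        if stage >= int(Stage.FLOWERING):
            break

    return trace
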