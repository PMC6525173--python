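"""Layered tipping-bucket soil water balance.

A deliberately minimal cascading bucket: daily infiltration, saturated
overflow, per-layer gravitational drainage, two-stage soil evaporation
from the surface layer, and root uptake.  Its one observable contract for
the phenology engines is the daily fraction of available soil water
(FASW) over a root-zone depth:

    FASW = sum(sw - ll15) / sum(dul - ll15)    over layers in the zone,

with the layer straddling the zone boundary prorated by thickness.  FASW
is returned unclamped (it exceeds 1 between saturation and drained upper
limit); consumers clamp where their own rules require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .weather import DailyWeather

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SoilWaterState",
    "initialize_state",
    "step_water_balance",
    "compute_fasw",
    "hargreaves_et0",
    "load_profile",
]

MM_PER_CM = 10.0


@dataclass(frozen=True)
class SoilLayer:
    """One soil layer with its water-holding and rate parameters.

    Volumetric fractions: ``air_dry <= ll15 < dul <= sat``.  ``swcon`` is
    the fraction of water above ``dul`` drained per day; ``kl`` the
    fraction of plant-available water extractable per day by roots.
    """

    top_depth: float  # cm
    bottom_depth: float  # cm
    ll15: float
    dul: float
    sat: float
    air_dry: float
    swcon: float = 0.3
    kl: float = 0.06

    def __post_init__(self) -> None:
        if self.bottom_depth <= self.top_depth:
            raise ValueError("bottom_depth must exceed top_depth")
        if not (self.air_dry <= self.ll15 < self.dul <= self.sat):
            raise ValueError(
                f"layer {self.top_depth}-{self.bottom_depth} cm violates "
                f"air_dry <= ll15 < dul <= sat "
                f"({self.air_dry}, {self.ll15}, {self.dul}, {self.sat})"
            )
        for name in ("swcon", "kl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def thickness_cm(self) -> float:
        return self.bottom_depth - self.top_depth

    @property
    def thickness_mm(self) -> float:
        return self.thickness_cm * MM_PER_CM

    @property
    def pawc_mm(self) -> float:
        return (self.dul - self.ll15) * self.thickness_mm


@dataclass(frozen=True)
class SoilProfile:
    """Contiguous stack of layers plus surface-evaporation parameters.

    ``u`` is the stage-1 evaporation limit (mm since last rewetting) and
    ``cona`` the stage-2 coefficient (mm per root-day).
    """

    layers: tuple[SoilLayer, ...]
    u: float = 6.0
    cona: float = 3.5
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if self.layers[0].top_depth != 0.0:
            raise ValueError("first layer must start at the surface")
        for a, b in zip(self.layers, self.layers[1:]):
            if b.top_depth != a.bottom_depth:
                raise ValueError(
                    f"layers not contiguous at {a.bottom_depth} cm"
                )
        if self.pawc_mm <= 0:
            raise ValueError("profile PAWC must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def depth_cm(self) -> float:
        return self.layers[-1].bottom_depth

    @property
    def pawc_mm(self) -> float:
        """Plant available water holding capacity, mm."""
        return sum(l.pawc_mm for l in self.layers)

    # vectorised parameter views (mm of water per layer)
    def _param_mm(self, attr: str) -> np.ndarray:
        return np.array(
            [getattr(l, attr) * l.thickness_mm for l in self.layers]
        )

    @property
    def thickness_mm(self) -> np.ndarray:
        return np.array([l.thickness_mm for l in self.layers])


@dataclass
class SoilWaterState:
    """Mutable daily water state: per-layer volumetric content plus the
    evaporation trackers and the previous step's flux ledger (mm)."""

    sw: np.ndarray  # volumetric fraction per layer
    sumes: float = 0.0  # cumulative evaporation since last rewetting, mm
    t_stage2: float = 0.0  # days since stage-2 evaporation began
    fluxes: dict = field(default_factory=dict)

    def copy(self) -> "SoilWaterState":
        return SoilWaterState(
            sw=self.sw.copy(),
            sumes=self.sumes,
            t_stage2=self.t_stage2,
            fluxes=dict(self.fluxes),
        )

    def storage_mm(self, profile: SoilProfile) -> float:
        return float(np.sum(self.sw * profile.thickness_mm))


def initialize_state(
    profile: SoilProfile,
    starting_water: float,
    mode: Literal["uniform", "fill_from_top"] = "uniform",
) -> SoilWaterState:
    """Initial water state at a fraction of PAWC.

    ``uniform`` sets every layer to ``ll15 + f*(dul - ll15)``;
    ``fill_from_top`` fills layers to ``dul`` from the surface down until
    ``f * PAWC`` mm has been allocated.
    """
    if not 0.0 <= starting_water <= 1.0:
        raise ValueError(f"starting_water {starting_water} outside [0, 1]")
    if mode == "uniform":
        sw = np.array(
            [l.ll15 + starting_water * (l.dul - l.ll15) for l in profile.layers]
        )
    elif mode == "fill_from_top":
        target = starting_water * profile.pawc_mm
        sw = np.array([l.ll15 for l in profile.layers])
        for i, l in enumerate(profile.layers):
            if target <= 0:
                break
            add = min(target, l.pawc_mm)
            sw[i] = l.ll15 + add / l.thickness_mm
            target -= add
    else:
        raise ValueError(f"unknown initialization mode {mode!r}")
    return SoilWaterState(sw=sw)


def hargreaves_et0(
    tmax: float, tmin: float, latitude: float, day_of_year: int
) -> float:
    """Reference evapotranspiration (mm/day) from temperature extremes.

    Hargreaves-Samani with extraterrestrial radiation from latitude and
    day of year; avoids needing measured radiation.
    """
    j = float(day_of_year)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * j / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * j / 365.0 - 1.39)
    phi = math.radians(latitude)
    x = -math.tan(phi) * math.tan(decl)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (
        (24.0 * 60.0 / math.pi)
        * 0.0820
        * dr
        * (
            ws * math.sin(phi) * math.sin(decl)
            + math.cos(phi) * math.cos(decl) * math.sin(ws)
        )
    )
    tmean = 0.5 * (tmax + tmin)
    et0 = 0.0023 * (tmean + 17.8) * math.sqrt(max(tmax - tmin, 0.0)) * 0.408 * ra
    return max(et0, 0.0)


def _default_pot_soil_evap(day: DailyWeather) -> float:
    # temperature-only fallback when the caller supplies no demand signal;
    # fixed Ra of 22 MJ/m2/day (mid-latitude annual mean)
    tmean = day.tmean
    e = 0.0023 * (tmean + 17.8) * math.sqrt(max(day.tmax - day.tmin, 0.0))
    return max(0.6 * e * 0.408 * 22.0, 0.0)


def step_water_balance(
    profile: SoilProfile,
    state: SoilWaterState,
    weather_day: DailyWeather,
    transpiration_demand: float,
    root_depth: float,
    pot_soil_evap: float | None = None,
    runoff_fn=None,
) -> SoilWaterState:
    """Advance the water balance by one day; returns a new state.

    Daily process order: infiltration of rain + irrigation into the top
    layer (runoff via the optional hook, zero by default); instantaneous
    cascade of water above saturation; gravitational drainage ``swcon *
    (sw - dul)`` per layer passed downward (below the profile = deep
    drainage); two-stage soil evaporation from the surface layer; root
    uptake within ``root_depth`` (cm), per-layer supply ``kl * (sw -
    ll15) * thickness`` scaled so the total never exceeds the demand.

    All fluxes are clipped to physical bounds; the returned state's
    ``fluxes`` ledger closes the day's mass balance exactly.
    """
    if transpiration_demand < 0:
        raise ValueError("transpiration demand must be non-negative")
    if root_depth < 0:
        raise ValueError("root depth must be non-negative")

    thick = profile.thickness_mm
    sw_mm = state.sw * thick
    ll15_mm = profile._param_mm("ll15")
    dul_mm = profile._param_mm("dul")
    sat_mm = profile._param_mm("sat")
    ad_mm = profile._param_mm("air_dry")
    n = profile.n_layers

    # 1. infiltration (runoff hook defaults to zero)
    water_in = weather_day.water_in
    runoff = float(runoff_fn(weather_day, state)) if runoff_fn else 0.0
    runoff = min(max(runoff, 0.0), water_in)
    infiltration = water_in - runoff
    sw_mm[0] += infiltration

    # 2 + 3. saturated overflow then gravitational drainage, cascading down
    deep_drainage = 0.0
    flux_down = 0.0
    for i in range(n):
        sw_mm[i] += flux_down
        overflow = max(0.0, sw_mm[i] - sat_mm[i])
        sw_mm[i] -= overflow
        drain = profile.layers[i].swcon * max(0.0, sw_mm[i] - dul_mm[i])
        sw_mm[i] -= drain
        flux_down = overflow + drain
    deep_drainage = flux_down

    # 4. two-stage soil evaporation from the surface layer
    sumes = state.sumes
    t2 = state.t_stage2
    if infiltration > 0.0:
        sumes = max(0.0, sumes - infiltration)
        if sumes < profile.u:
            t2 = 0.0
    if pot_soil_evap is None:
        pot_soil_evap = _default_pot_soil_evap(weather_day)
    if sumes < profile.u:
        es = min(pot_soil_evap, profile.u - sumes)
    else:
        t2 += 1.0
        es = min(
            pot_soil_evap,
            profile.cona * (math.sqrt(t2) - math.sqrt(t2 - 1.0)),
        )
    es = min(es, max(0.0, sw_mm[0] - ad_mm[0]))
    sw_mm[0] -= es
    sumes += es

    # 5. root uptake, prorated over layers intersecting the root zone
    uptake = 0.0
    if transpiration_demand > 0.0 and root_depth > 0.0:
        supply = np.zeros(n)
        for i, layer in enumerate(profile.layers):
            if layer.top_depth >= root_depth:
                break
            frac = min(root_depth, layer.bottom_depth) - layer.top_depth
            frac /= layer.thickness_cm
            supply[i] = layer.kl * max(0.0, sw_mm[i] - ll15_mm[i]) * frac
        total = float(np.sum(supply))
        if total > 0.0:
            scale = min(1.0, transpiration_demand / total)
            sw_mm -= supply * scale
            uptake = total * scale

    new = SoilWaterState(
        sw=sw_mm / thick,
        sumes=sumes,
        t_stage2=t2,
        fluxes={
            "infiltration": infiltration,
            "runoff": runoff,
            "drainage": deep_drainage,
            "evaporation": es,
            "uptake": uptake,
        },
    )
    return new


def compute_fasw(
    profile: SoilProfile, state: SoilWaterState, zone_depth: float = 60.0
) -> float:
    """Fraction of available soil water over ``[0, zone_depth]`` cm.

    Sums ``(sw - ll15)`` over ``(dul - ll15)`` across layers intersecting
    the zone, prorating the straddling layer by thickness fraction.  The
    result is *not* clamped and may exceed 1 when any layer holds more
    than its drained upper limit.
    """
    if zone_depth <= 0:
        raise ValueError("zone_depth must be positive")
    if zone_depth > profile.depth_cm:
        raise ValueError(
            f"zone_depth {zone_depth} cm deeper than profile "
            f"({profile.depth_cm} cm)"
        )
    num = 0.0
    den = 0.0
    for i, layer in enumerate(profile.layers):
        if layer.top_depth >= zone_depth:
            break
        depth_in = min(zone_depth, layer.bottom_depth) - layer.top_depth
        mm = depth_in * MM_PER_CM
        num += (state.sw[i] - layer.ll15) * mm
        den += (layer.dul - layer.ll15) * mm
    return num / den


# ---------------------------------------------------------------------------
# Config loading


def _layer_from_dict(d: dict) -> SoilLayer:
    return SoilLayer(
        top_depth=float(d["top_depth"]),
        bottom_depth=float(d["bottom_depth"]),
        ll15=float(d["ll15"]),
        dul=float(d["dul"]),
        sat=float(d["sat"]),
        air_dry=float(d["air_dry"]),
        swcon=float(d.get("swcon", 0.3)),
        kl=float(d.get("kl", 0.06)),
    )


def profile_from_dict(d: dict) -> SoilProfile:
    return SoilProfile(
        layers=tuple(_layer_from_dict(x) for x in d["layers"]),
        u=float(d.get("u", 6.0)),
        cona=float(d.get("cona", 3.5)),
        name=str(d.get("name", "")),
    )


def load_profile(path: str | Path) -> SoilProfile:
    """Load a layered soil profile from a YAML (or JSON) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return profile_from_dict(data)
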