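"""Daily weather series: readers/writers, a synthetic generator, and daylength.

Weather drives every other module: thermal time from daily temperature
extremes, rainfall into the soil water balance, and frost detection from
daily minima.  Two on-disk dialects are supported — a plain CSV and a
whitespace-delimited ``.met`` text layout with a ``latitude =`` header
constant, a column-name line and a units line.
"""

from __future__ import annotations

import datetime as dt
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "ClimateParams",
    "WeatherParseError",
    "read_weather",
    "write_weather",
    "generate_synthetic_weather",
    "daylength",
    "DEFAULT_TWILIGHT_ANGLE",
]

#: Sun angle (degrees relative to the horizon) used for photoperiod.
#: Crop models conventionally extend daylength into civil twilight; the
#: default puts the sun centre 2.2 degrees below the horizon.
DEFAULT_TWILIGHT_ANGLE = -2.2


class WeatherParseError(ValueError):
    """Raised when a weather file is malformed or violates invariants."""


@dataclass(frozen=True)
class DailyWeather:
    """One day of site weather.

    Parameters
    ----------
    date : datetime.date
    tmax, tmin : float
        Daily extreme air temperatures, °C.  ``tmax >= tmin`` is enforced.
    rain : float
        Rainfall, mm (non-negative).
    irrigation : float, optional
        Applied irrigation, mm (non-negative), default 0.
    """

    date: dt.date
    tmax: float
    tmin: float
    rain: float
    irrigation: float = 0.0

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(
                f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.rain < 0:
            raise ValueError(f"{self.date}: negative rain ({self.rain})")
        if self.irrigation < 0:
            raise ValueError(
                f"{self.date}: negative irrigation ({self.irrigation})"
            )

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)

    @property
    def water_in(self) -> float:
        """Rain plus irrigation, mm."""
        return self.rain + self.irrigation


@dataclass(frozen=True)
class WeatherSeries:
    """An ordered, gap-free run of :class:`DailyWeather` at one site."""

    latitude: float
    records: tuple[DailyWeather, ...]

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not self.records:
            raise ValueError("empty weather series")
        object.__setattr__(self, "records", tuple(self.records))
        for prev, cur in zip(self.records, self.records[1:]):
            if (cur.date - prev.date).days != 1:
                raise WeatherParseError(
                    f"dates not consecutive: {prev.date} -> {cur.date}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DailyWeather]:
        return iter(self.records)

    def __getitem__(self, i: int) -> DailyWeather:
        return self.records[i]

    @property
    def start(self) -> dt.date:
        return self.records[0].date

    @property
    def end(self) -> dt.date:
        return self.records[-1].date

    def day(self, date: dt.date) -> DailyWeather:
        """Record for ``date``; O(1) via the gap-free invariant."""
        idx = (date - self.start).days
        if idx < 0 or idx >= len(self.records):
            raise KeyError(f"{date} outside series [{self.start}, {self.end}]")
        return self.records[idx]

    def from_date(self, date: dt.date) -> Iterator[DailyWeather]:
        """Iterate records from ``date`` to the end of the series."""
        idx = (date - self.start).days
        if idx < 0 or idx >= len(self.records):
            raise KeyError(f"{date} outside series [{self.start}, {self.end}]")
        return iter(self.records[idx:])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [r.date for r in self.records],
                "maxt": [r.tmax for r in self.records],
                "mint": [r.tmin for r in self.records],
                "rain": [r.rain for r in self.records],
                "irrigation": [r.irrigation for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, latitude: float) -> "WeatherSeries":
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                date = row.date
                if isinstance(date, pd.Timestamp):
                    date = date.date()
                elif isinstance(date, str):
                    date = dt.date.fromisoformat(date)
                records.append(
                    DailyWeather(
                        date=date,
                        tmax=float(row.maxt),
                        tmin=float(row.mint),
                        rain=float(row.rain),
                        irrigation=float(getattr(row, "irrigation", 0.0) or 0.0),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise WeatherParseError(f"row {i + 1}: {exc}") from exc
        return cls(latitude=latitude, records=tuple(records))


# ---------------------------------------------------------------------------
# File IO


def _infer_format(path: Path) -> str:
    return "met" if path.suffix.lower() == ".met" else "csv"


def read_weather(
    path: str | Path,
    format: str | None = None,
    latitude: float | None = None,
) -> WeatherSeries:
    """Read a weather file into a validated :class:`WeatherSeries`.

    Parameters
    ----------
    path : path-like
    format : {"csv", "met"}, optional
        Inferred from the suffix when omitted.
    latitude : float, optional
        Required for the CSV dialect (which does not carry it); overrides
        the header constant of a ``.met`` file when given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        if latitude is None:
            raise ValueError("latitude is required when reading CSV weather")
        df = pd.read_csv(path)
        required = {"date", "maxt", "mint", "rain"}
        missing = required - set(df.columns)
        if missing:
            raise WeatherParseError(f"{path}: missing columns {sorted(missing)}")
        if "irrigation" not in df.columns:
            df["irrigation"] = 0.0
        return WeatherSeries.from_dataframe(df, latitude=latitude)
    if fmt == "met":
        return _read_met(path, latitude=latitude)
    raise ValueError(f"unknown weather format {fmt!r}")


def _read_met(path: Path, latitude: float | None = None) -> WeatherSeries:
    lines = path.read_text().splitlines()
    lat = latitude
    header: list[str] | None = None
    records: list[DailyWeather] = []
    data_started = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("!", "[")):
            continue
        m = re.match(r"latitude\s*=\s*(-?\d+(\.\d+)?)", line, re.IGNORECASE)
        if m and not data_started:
            if lat is None:
                lat = float(m.group(1))
            continue
        if "=" in line and not data_started:
            continue  # other header constants
        if header is None:
            header = line.split()
            continue
        if line.startswith("(") or line.split()[0].startswith("("):
            continue  # units line
        data_started = True
        parts = line.split()
        if len(parts) < len(header):
            raise WeatherParseError(f"{path}:{lineno}: expected {len(header)} fields")
        row = dict(zip(header, parts))
        try:
            date = dt.date(int(row["year"]), 1, 1) + dt.timedelta(
                days=int(row["day"]) - 1
            )
            records.append(
                DailyWeather(
                    date=date,
                    tmax=float(row["maxt"]),
                    tmin=float(row["mint"]),
                    rain=float(row["rain"]),
                    irrigation=float(row.get("irrigation", 0.0)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise WeatherParseError(f"{path}:{lineno}: {exc}") from exc
    if lat is None:
        raise WeatherParseError(f"{path}: no 'latitude =' header constant")
    if header is None or not records:
        raise WeatherParseError(f"{path}: no data rows")
    return WeatherSeries(latitude=lat, records=tuple(records))


def write_weather(series: WeatherSeries, path: str | Path, format: str | None = None) -> None:
    """Write ``series`` in the csv or met dialect (inferred from suffix)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        df = series.to_dataframe()
        df["date"] = [d.isoformat() for d in df["date"]]
        df.to_csv(path, index=False)
        return
    if fmt == "met":
        with open(path, "w") as fh:
            fh.write("[weather.met.weather]\n")
            fh.write(f"latitude = {series.latitude:.4f} (DECIMAL DEGREES)\n")
            fh.write("year day maxt mint rain irrigation\n")
            fh.write("() () (oC) (oC) (mm) (mm)\n")
            for r in series:
                doy = r.date.timetuple().tm_yday
                fh.write(
                    f"{r.date.year} {doy} {r.tmax:.2f} {r.tmin:.2f} "
                    f"{r.rain:.2f} {r.irrigation:.2f}\n"
                )
        return
    raise ValueError(f"unknown weather format {fmt!r}")


# ---------------------------------------------------------------------------
# Synthetic generator


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the seasonal-sinusoid + Markov-rain weather generator.

    Temperatures follow ``tmean_annual + amplitude*cos(2*pi*(doy - peak_doy)
    / 365.25)`` plus Gaussian noise; ``peak_doy`` defaults to mid-January so
    that a southern-hemisphere site has its minimum in July.  Rain occurrence
    is a two-state Markov chain (wet given dry / wet given wet) with
    gamma-distributed wet-day amounts.
    """

    tmean_annual: float = 18.0
    amplitude: float = 7.0
    peak_doy: float = 15.0
    diurnal_range: float = 12.0
    temp_noise_sd: float = 1.5
    p_wet_dry: float = 0.25
    p_wet_wet: float = 0.55
    rain_mean: float = 8.0
    rain_shape: float = 0.75

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be non-negative")
        if self.temp_noise_sd < 0:
            raise ValueError("temp_noise_sd must be non-negative")
        for name in ("p_wet_dry", "p_wet_wet"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.rain_mean <= 0:
            raise ValueError("rain_mean must be positive")
        if self.rain_shape <= 0:
            raise ValueError("rain_shape must be positive")

    @property
    def stationary_wet_probability(self) -> float:
        """Long-run wet-day frequency of the occurrence chain."""
        denom = 1.0 + self.p_wet_dry - self.p_wet_wet
        if denom <= 0:
            return 1.0
        return self.p_wet_dry / denom


def generate_synthetic_weather(
    latitude: float,
    start: dt.date,
    n_days: int,
    seed: int,
    climate: ClimateParams | None = None,
) -> WeatherSeries:
    """Deterministic synthetic daily weather for a site.

    The daily mean temperature is a seasonal sinusoid plus Gaussian noise;
    ``tmax``/``tmin`` are placed half the diurnal range either side of the
    mean, so ``tmax >= tmin`` always holds.  Rainfall follows a two-state
    wet/dry Markov chain with gamma wet-day amounts.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    climate = climate or ClimateParams()
    rng = np.random.default_rng(seed)
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)

    mean_t = climate.tmean_annual + climate.amplitude * np.cos(
        2.0 * math.pi * (doy - climate.peak_doy) / 365.25
    )
    mean_t = mean_t + rng.normal(0.0, climate.temp_noise_sd, n_days)
    half_range = 0.5 * climate.diurnal_range
    tmax = mean_t + half_range
    tmin = mean_t - half_range

    rain = np.zeros(n_days)
    wet = False
    for i in range(n_days):
        p = climate.p_wet_wet if wet else climate.p_wet_dry
        wet = bool(rng.random() < p)
        if wet:
            scale = climate.rain_mean / climate.rain_shape
            rain[i] = rng.gamma(climate.rain_shape, scale)

    records = tuple(
        DailyWeather(
            date=dates[i],
            tmax=float(tmax[i]),
            tmin=float(tmin[i]),
            rain=float(rain[i]),
        )
        for i in range(n_days)
    )
    return WeatherSeries(latitude=latitude, records=records)


# ---------------------------------------------------------------------------
# Daylength


def daylength(
    latitude: float,
    day_of_year: float,
    twilight_angle: float = DEFAULT_TWILIGHT_ANGLE,
) -> float:
    """Astronomical daylength in hours, including a twilight extension.

    Standard solar geometry: declination from day of year, then the
    hour angle at which the sun centre sits ``twilight_angle`` degrees
    relative to the horizon (negative = below, lengthening the day).

    Parameters
    ----------
    latitude : float
        Decimal degrees, south negative; must lie in [-90, 90].
    day_of_year : float
        1–366 (fractional values are accepted).
    twilight_angle : float, optional
        Degrees of the sun centre relative to the horizon.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    phi = math.radians(latitude)
    decl = math.radians(
        -23.45 * math.cos(2.0 * math.pi * (day_of_year + 10.0) / 365.25)
    )
    alt = math.radians(twilight_angle)
    denom = math.cos(phi) * math.cos(decl)
    if denom == 0.0:
        return 12.0
    cos_ha = (math.sin(alt) - math.sin(phi) * math.sin(decl)) / denom
    cos_ha = min(1.0, max(-1.0, cos_ha))
    return 24.0 * math.acos(cos_ha) / math.pi
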