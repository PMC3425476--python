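"""Daily weather forcing, psychrometrics and reference evapotranspiration.

The growth engine is driven by daily meteorology from a standard station
record: air temperature (mean/max/min at 2 m), relative humidity, sunshine
duration, wind speed at 2 m, atmospheric pressure and precipitation.  This
module validates such records, derives the psychrometric quantities needed
by the reference-crop combination equation (slope of the saturation
vapour-pressure curve, psychrometric constant, vapour pressures, net
radiation estimated from sunshine hours), computes daily reference
evapotranspiration ET0, and locates the thermal growth season.

Net radiation is not measured at typical stations; it is estimated from
sunshine duration with the Angström relation (defaults a=0.25, b=0.50) and
extraterrestrial radiation from latitude and day of year, with a standard
net-longwave correction.  Daily soil heat flux is taken as zero.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "WeatherDay",
    "PsychroDerived",
    "SiteInfo",
    "WeatherError",
    "read_weather",
    "write_weather",
    "pressure_from_elevation",
    "psychro",
    "et0",
    "growth_season",
]

#: MJ m-2 min-1
SOLAR_CONSTANT = 0.0820
#: MJ K-4 m-2 day-1
STEFAN_BOLTZMANN_DAILY = 4.903e-9
#: reference-crop albedo
ALBEDO = 0.23

WEATHER_COLUMNS = (
    "date",
    "t_mean",
    "t_max",
    "t_min",
    "rh_mean",
    "sunshine",
    "wind",
    "pressure",
    "precip",
)


class WeatherError(ValueError):
    """Invalid weather input (bad value, bad file layout, no growth season)."""


def pressure_from_elevation(elevation_m: float) -> float:
    """Mean atmospheric pressure [kPa] at a given elevation [m]."""
    return 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26


@dataclass(frozen=True)
class WeatherDay:
    """One day of meteorological forcing.

    Units: temperatures °C at 2 m, relative humidity as a fraction in
    [0, 1], sunshine in hours, wind in m s-1 at 2 m, pressure in kPa,
    precipitation in mm.
    """

    date: datetime.date
    t_mean: float
    t_max: float
    t_min: float
    rh_mean: float
    sunshine: float
    wind: float
    pressure: float
    precip: float

    def __post_init__(self) -> None:
        if not (self.t_min <= self.t_mean <= self.t_max):
            raise WeatherError(
                f"{self.date}: need t_min <= t_mean <= t_max, got "
                f"{self.t_min}/{self.t_mean}/{self.t_max}"
            )
        if not 0.0 <= self.rh_mean <= 1.0:
            raise WeatherError(f"{self.date}: rh_mean {self.rh_mean} outside [0, 1]")
        if not 0.0 <= self.sunshine <= 24.0:
            raise WeatherError(f"{self.date}: sunshine {self.sunshine} outside [0, 24]")
        if self.wind < 0.0:
            raise WeatherError(f"{self.date}: negative wind {self.wind}")
        if self.precip < 0.0:
            raise WeatherError(f"{self.date}: negative precip {self.precip}")
        if self.pressure <= 0.0:
            raise WeatherError(f"{self.date}: non-positive pressure {self.pressure}")


@dataclass(frozen=True)
class PsychroDerived:
    """Psychrometric quantities for one day.

    delta and gamma in kPa °C-1, vapour pressures in kPa, net radiation in
    MJ m-2 d-1.
    """

    delta: float
    gamma: float
    e_s: float
    e_a: float
    r_net: float


@dataclass(frozen=True)
class SiteInfo:
    """Geographic and radiation-estimation constants of the stand.

    Defaults describe the semi-arid sandy-land plantation the model was
    built for (42.717°N, ~226 m a.s.l.) with conventional Angström
    coefficients.
    """

    latitude: float = 42.717
    elevation: float = 226.0
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise WeatherError(f"latitude {self.latitude} outside [-90, 90]")
        if self.angstrom_a <= 0 or self.angstrom_b <= 0:
            raise WeatherError("Angström coefficients must be positive")

    @property
    def pressure(self) -> float:
        return pressure_from_elevation(self.elevation)


def _saturation_vp(t_c: float) -> float:
    """Saturation vapour pressure [kPa] at air temperature t_c [°C] (Tetens)."""
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def read_weather(path: str | Path, pressure_kpa: float | None = None) -> list[WeatherDay]:
    """Read a delimited daily weather file into validated ``WeatherDay`` records.

    The file must have a header naming the columns ``date, t_mean, t_max,
    t_min, rh_mean, sunshine, wind, precip`` (ISO dates, one row per day,
    contiguous).  ``pressure`` is optional per day; if the column is absent
    ``pressure_kpa`` (e.g. a site constant from elevation) must be given.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    required = [c for c in WEATHER_COLUMNS if c != "pressure"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise WeatherError(f"{path}: missing column(s) {', '.join(missing)}")
    has_pressure = "pressure" in frame.columns
    if not has_pressure and pressure_kpa is None:
        raise WeatherError(
            f"{path}: no 'pressure' column and no site pressure supplied"
        )
    days: list[WeatherDay] = []
    prev_date: datetime.date | None = None
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            date = datetime.date.fromisoformat(str(row.date))
            day = WeatherDay(
                date=date,
                t_mean=float(row.t_mean),
                t_max=float(row.t_max),
                t_min=float(row.t_min),
                rh_mean=float(row.rh_mean),
                sunshine=float(row.sunshine),
                wind=float(row.wind),
                pressure=float(row.pressure) if has_pressure else float(pressure_kpa),
                precip=float(row.precip),
            )
        except (WeatherError, ValueError) as exc:
            raise WeatherError(f"{path}, row {row_no}: {exc}") from exc
        if prev_date is not None and (date - prev_date).days != 1:
            raise WeatherError(
                f"{path}, row {row_no}: non-contiguous date {date} after {prev_date}"
            )
        prev_date = date
        days.append(day)
    return days


def write_weather(days: Sequence[WeatherDay], path: str | Path) -> Path:
    """Write ``WeatherDay`` records to a CSV consumable by :func:`read_weather`."""
    frame = pd.DataFrame(
        {
            "date": [d.date.isoformat() for d in days],
            "t_mean": [d.t_mean for d in days],
            "t_max": [d.t_max for d in days],
            "t_min": [d.t_min for d in days],
            "rh_mean": [d.rh_mean for d in days],
            "sunshine": [d.sunshine for d in days],
            "wind": [d.wind for d in days],
            "pressure": [d.pressure for d in days],
            "precip": [d.precip for d in days],
        }
    )
    path = Path(path)
    # %.17g guarantees exact float round-trips through the text file
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def psychro(day: WeatherDay, site: SiteInfo) -> PsychroDerived:
    """Psychrometric quantities and estimated net radiation for one day.

    delta is the Tetens-form derivative of saturation vapour pressure at
    t_mean; e_s averages saturation pressures at t_max and t_min;
    e_a = rh_mean * e_s; gamma follows from the day's pressure.  Net
    radiation = Angström shortwave minus clear-sky-scaled net longwave.
    """
    t = day.t_mean
    es_mean = _saturation_vp(t)
    delta = 17.27 * 237.3 * es_mean / (t + 237.3) ** 2
    e_s = 0.5 * (_saturation_vp(day.t_max) + _saturation_vp(day.t_min))
    e_a = day.rh_mean * e_s
    gamma = 0.665e-3 * day.pressure

    doy = day.date.timetuple().tm_yday
    phi = math.radians(site.latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = max(-1.0, min(1.0, -math.tan(phi) * math.tan(decl)))
    omega_s = math.acos(x)
    ra = (
        24.0 * 60.0 / math.pi
        * SOLAR_CONSTANT
        * dr
        * (omega_s * math.sin(phi) * math.sin(decl)
           + math.cos(phi) * math.cos(decl) * math.sin(omega_s))
    )
    daylength = 24.0 / math.pi * omega_s
    if daylength > 0.0:
        rel_sun = min(day.sunshine / daylength, 1.0)
    else:
        rel_sun = 0.0
    rs = (site.angstrom_a + site.angstrom_b * rel_sun) * ra
    rso = (0.75 + 2e-5 * site.elevation) * ra
    rns = (1.0 - ALBEDO) * rs
    if rso > 0.0:
        cloud_term = 1.35 * min(rs / rso, 1.0) - 0.35
    else:
        cloud_term = 0.0
    rnl = (
        STEFAN_BOLTZMANN_DAILY
        * 0.5 * ((day.t_max + 273.16) ** 4 + (day.t_min + 273.16) ** 4)
        * (0.34 - 0.14 * math.sqrt(max(e_a, 0.0)))
        * cloud_term
    )
    r_net = rns - rnl
    return PsychroDerived(delta=delta, gamma=gamma, e_s=e_s, e_a=e_a, r_net=r_net)


def et0(day: WeatherDay, derived: PsychroDerived) -> float:
    """Daily reference evapotranspiration [mm d-1], clamped at zero.

    Standard daily reference-crop combination equation with zero soil heat
    flux: radiation term 0.408*delta*Rn and aerodynamic term
    gamma*900/(T+273)*u2*(es-ea), denominator delta + gamma*(1+0.34*u2).
    """
    num = (
        0.408 * derived.delta * derived.r_net
        + derived.gamma * 900.0 / (day.t_mean + 273.0) * day.wind
        * (derived.e_s - derived.e_a)
    )
    den = derived.delta + derived.gamma * (1.0 + 0.34 * day.wind)
    return max(num / den, 0.0)


def growth_season(days: Sequence[WeatherDay]) -> tuple[int, int]:
    """Locate the thermal growth season inside one calendar year of weather.

    Returns (start, end) indices: start is the first day of the first run of
    5 consecutive days with t_mean >= 0 °C, end is the last day of the last
    such run.  Raises :class:`WeatherError` if no qualifying run exists.
    """
    runs: list[tuple[int, int]] = []
    run_start: int | None = None
    for idx, day in enumerate(days):
        if day.t_mean >= 0.0:
            if run_start is None:
                run_start = idx
        else:
            if run_start is not None and idx - run_start >= 5:
                runs.append((run_start, idx - 1))
            run_start = None
    if run_start is not None and len(days) - run_start >= 5:
        runs.append((run_start, len(days) - 1))
    if not runs:
        raise WeatherError("no growth season: no 5-day run with t_mean >= 0 °C")
    return runs[0][0], runs[-1][1]
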