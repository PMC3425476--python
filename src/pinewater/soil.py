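"""Daily root-zone water balance and seasonal transpiration.

The root zone is treated as a single bucket characterised by its total
available water TAW = 1000*(theta_f - theta_w)*z_r [mm] and the readily
available fraction RAW = r_frac*TAW.  The state variable is the depletion
D_r [mm] at the end of each day.  Water stress enters through the
coefficient K_s, equal to 1 while depletion stays below RAW and declining
linearly to 0 at full depletion.  Actual evapotranspiration is
ET_a = K_s*K_c*ET0 and the plant-transpired share is its canopy-intercepted
fraction 1 - exp(-k*LAI) (Beer-Lambert).  Interception, runoff and
groundwater recharge are neglected: excess rain beyond refilling the root
zone is discarded (depletion clamped at 0), and depletion is capped at TAW.

The season starts with no water deficit (D_r = 0) on the first day of the
thermal growth season.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .weather import SiteInfo, WeatherDay, et0 as _et0, growth_season, psychro

__all__ = [
    "SoilParams",
    "SoilWaterState",
    "SeasonForcing",
    "SeasonWater",
    "taw_raw",
    "stress_coefficient",
    "step_day",
    "compute_forcing",
    "run_season",
]

#: Beer-Lambert extinction coefficient used to split ET_a into the
#: canopy-transpired share (field value for conifer canopies).
DEFAULT_K_EXT = 0.5


@dataclass(frozen=True)
class SoilParams:
    """Soil/root-zone parameters.

    z_r rooting depth [m]; theta_f/theta_w volumetric water content at field
    capacity and wilting point [m3 m-3]; r_frac the depletable fraction of
    TAW before stress; k_c the crop coefficient.
    """

    z_r: float = 1.0
    theta_f: float = 0.12
    theta_w: float = 0.07
    r_frac: float = 0.5
    k_c: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_w < self.theta_f <= 1.0):
            raise ValueError(
                f"need 0 <= theta_w < theta_f <= 1, got {self.theta_w}, {self.theta_f}"
            )
        if self.z_r <= 0.0:
            raise ValueError(f"z_r must be positive, got {self.z_r}")
        if not 0.0 < self.r_frac < 1.0:
            raise ValueError(f"r_frac must be in (0, 1), got {self.r_frac}")
        if self.k_c <= 0.0:
            raise ValueError(f"k_c must be positive, got {self.k_c}")

    @property
    def taw(self) -> float:
        return 1000.0 * (self.theta_f - self.theta_w) * self.z_r

    @property
    def raw(self) -> float:
        return self.r_frac * self.taw


def taw_raw(soil: SoilParams) -> tuple[float, float]:
    """Total and readily available water of the root zone [mm]."""
    return soil.taw, soil.raw


def stress_coefficient(d_r: float, soil: SoilParams) -> float:
    """Water-stress coefficient K_s in [0, 1] at depletion d_r [mm].

    K_s = 1 while d_r <= RAW, then declines linearly:
    K_s = (TAW - d_r) / ((1 - r_frac) * TAW).
    """
    taw = soil.taw
    if d_r < -1e-9 or d_r > taw + 1e-9:
        raise ValueError(f"depletion {d_r} outside [0, TAW={taw}]")
    if d_r <= soil.raw:
        return 1.0
    k_s = (taw - d_r) / ((1.0 - soil.r_frac) * taw)
    return min(max(k_s, 0.0), 1.0)


@dataclass(frozen=True)
class SoilWaterState:
    """Bookkeeping for one day of the water balance.

    d_r is the depletion at the end of the day [mm]; surplus is rain that
    could not be stored (clamp at zero depletion); overdraft is demand the
    bucket could not supply (clamp at TAW).  All fluxes in mm.
    """

    day: int
    precip: float
    et0: float
    k_s: float
    et_a: float
    t_a_day: float
    d_r: float
    surplus: float = 0.0
    overdraft: float = 0.0


def step_day(
    prev: SoilWaterState,
    precip: float,
    et0: float,
    lai: float,
    soil: SoilParams,
    k_ext: float = DEFAULT_K_EXT,
) -> SoilWaterState:
    """Advance the depletion bookkeeping by one day.

    K_s is evaluated at the previous day's depletion; ET_a = K_s*K_c*ET0;
    the transpired share is ET_a * (1 - exp(-k_ext*LAI)); the new depletion
    is prev.d_r - precip + ET_a clamped into [0, TAW], with the clamped
    amounts recorded as surplus/overdraft.
    """
    if precip < 0.0 or et0 < 0.0:
        raise ValueError(f"negative flux: precip={precip}, et0={et0}")
    if lai < 0.0:
        raise ValueError(f"negative LAI {lai}")
    k_s = stress_coefficient(prev.d_r, soil)
    et_a = k_s * soil.k_c * et0
    t_a_day = et_a * (1.0 - math.exp(-k_ext * lai))
    raw_depletion = prev.d_r - precip + et_a
    surplus = max(0.0, -raw_depletion)
    overdraft = max(0.0, raw_depletion - soil.taw)
    d_r = min(max(raw_depletion, 0.0), soil.taw)
    return SoilWaterState(
        day=prev.day + 1,
        precip=precip,
        et0=et0,
        k_s=k_s,
        et_a=et_a,
        t_a_day=t_a_day,
        d_r=d_r,
        surplus=surplus,
        overdraft=overdraft,
    )


@dataclass(frozen=True)
class SeasonForcing:
    """Precomputed growth-season window and daily ET0/precipitation.

    Weather-only quantities, independent of the plant state; computing them
    once per weather year makes repeated simulations (calibration, sweeps)
    cheap.
    """

    start: int
    end: int
    precip: np.ndarray
    et0: np.ndarray


def compute_forcing(weather: Sequence[WeatherDay], site: SiteInfo) -> SeasonForcing:
    """Growth-season window plus per-day ET0 and precipitation arrays."""
    start, end = growth_season(weather)
    window = weather[start : end + 1]
    et0_vals = np.array([_et0(d, psychro(d, site)) for d in window])
    precip = np.array([d.precip for d in window])
    return SeasonForcing(start=start, end=end, precip=precip, et0=et0_vals)


@dataclass
class SeasonWater:
    """Daily ledger and totals of one growth season."""

    states: list[SoilWaterState]
    start: int
    end: int
    precip_total: float = field(init=False)
    et_a_total: float = field(init=False)
    t_a_total: float = field(init=False)
    surplus_total: float = field(init=False)
    overdraft_total: float = field(init=False)

    def __post_init__(self) -> None:
        self.precip_total = sum(s.precip for s in self.states)
        self.et_a_total = sum(s.et_a for s in self.states)
        self.t_a_total = sum(s.t_a_day for s in self.states)
        self.surplus_total = sum(s.surplus for s in self.states)
        self.overdraft_total = sum(s.overdraft for s in self.states)

    @property
    def d_r_final(self) -> float:
        return self.states[-1].d_r if self.states else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": [s.day for s in self.states],
                "precip": [s.precip for s in self.states],
                "et0": [s.et0 for s in self.states],
                "k_s": [s.k_s for s in self.states],
                "et_a": [s.et_a for s in self.states],
                "t_a": [s.t_a_day for s in self.states],
                "d_r": [s.d_r for s in self.states],
                "surplus": [s.surplus for s in self.states],
                "overdraft": [s.overdraft for s in self.states],
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def run_season(
    weather: Sequence[WeatherDay] | None,
    soil: SoilParams,
    lai: float,
    site: SiteInfo | None = None,
    k_ext: float = DEFAULT_K_EXT,
    forcing: SeasonForcing | None = None,
) -> SeasonWater:
    """Run the daily water balance over one growth season.

    LAI is held fixed within the season (one growth cycle).  The depletion
    starts at zero (no deficit at the start of the cycle).  Either a weather
    year plus site, or a precomputed :class:`SeasonForcing`, must be given.
    """
    if forcing is None:
        if weather is None or site is None:
            raise ValueError("need either forcing or (weather, site)")
        forcing = compute_forcing(weather, site)
    state = SoilWaterState(
        day=forcing.start - 1, precip=0.0, et0=0.0, k_s=1.0,
        et_a=0.0, t_a_day=0.0, d_r=0.0,
    )
    states: list[SoilWaterState] = []
    for precip, day_et0 in zip(forcing.precip, forcing.et0):
        state = step_day(state, float(precip), float(day_et0), lai, soil, k_ext=k_ext)
        states.append(state)
    return SeasonWater(states=states, start=forcing.start, end=forcing.end)
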