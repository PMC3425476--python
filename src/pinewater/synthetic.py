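"""Synthetic daily weather and synthetic calibration targets.

No station record or field target file ships with the package, so every
other module is exercised against data generated here: a stochastic daily
weather year with controllable annual statistics (mean temperature,
precipitation total and its summer concentration), and calibration target
files produced by forward simulation plus multiplicative noise.

The weather generator aims at the statistical regime of the semi-arid
sandy-land site the model was built for — annual means around 8–9 °C,
precipitation 300–620 mm concentrated in July–August — not at daily
fidelity to any particular year.  Presets encode the 2001–2007 annual
statistics of that regime.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .weather import SiteInfo, WeatherDay, pressure_from_elevation

__all__ = [
    "WeatherSpec",
    "NoiseSpec",
    "YEAR_PRESETS",
    "weather_spec_for_year",
    "synth_weather",
    "synth_weather_years",
    "synth_targets",
]

#: annual (mean air temperature [°C], total precipitation [mm]) per year of
#: the reference record
YEAR_PRESETS: dict[int, tuple[float, float]] = {
    2001: (7.5, 309.0),
    2002: (8.4, 391.2),
    2003: (8.5, 508.2),
    2004: (8.7, 621.4),
    2005: (7.9, 586.9),
    2006: (8.2, 358.9),
    2007: (9.3, 412.6),
}


@dataclass(frozen=True)
class WeatherSpec:
    """Annual statistics a synthetic weather year must reproduce.

    ``t_amplitude`` is the half-range of the seasonal sine (a continental
    January/July contrast of ~36 °C gives 18).  ``summer_share`` is the
    fraction of annual precipitation falling in July–August.  The
    precipitation total is met exactly by rescaling.
    """

    year: int = 2007
    t_mean_annual: float = 9.3
    t_amplitude: float = 18.0
    t_jitter: float = 1.5
    t_range_daily: float = 10.0
    precip_total: float = 412.6
    wet_day_prob: float = 0.25
    summer_share: float = 0.45
    rh_mean: float = 0.55
    wind_mean: float = 2.5
    sunshine_mean: float = 8.0
    elevation: float = 226.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.precip_total < 0:
            raise ValueError("precip_total must be >= 0")
        for name in ("wet_day_prob", "summer_share", "rh_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def weather_spec_for_year(year: int, seed: int = 0) -> WeatherSpec:
    """Preset spec reproducing the annual statistics of a reference year."""
    t_mean, total = YEAR_PRESETS[year]
    return WeatherSpec(year=year, t_mean_annual=t_mean, precip_total=total, seed=seed)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal observation noise for synthetic targets.

    ``sigma`` may be a single float or a mapping observable-group -> float.
    """

    sigma: float | dict[str, float] = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        sigmas = (
            self.sigma.values() if isinstance(self.sigma, dict) else [self.sigma]
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("noise sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def sigma_for(self, group: str) -> float:
        if isinstance(self.sigma, dict):
            return self.sigma.get(group, 0.0)
        return self.sigma


def synth_weather(spec: WeatherSpec) -> list[WeatherDay]:
    """Generate one 365-day synthetic weather year, deterministic per seed.

    Daily mean temperature is a seasonal sine (minimum mid-January) plus
    Gaussian jitter; max/min straddle the mean by a jittered daily range.
    Wet days are Bernoulli draws; amounts are exponential, boosted in
    July–August to hit the requested summer share, then rescaled so the
    annual sum equals the requested total exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_days = 365
    doy = np.arange(1, n_days + 1)
    t_mean = (
        spec.t_mean_annual
        - spec.t_amplitude * np.cos(2.0 * math.pi * (doy - 15) / 365.0)
        + rng.normal(0.0, spec.t_jitter, n_days)
    )
    half_range = np.abs(rng.normal(spec.t_range_daily, 2.0, n_days)) / 2.0
    t_max = t_mean + half_range
    t_min = t_mean - half_range
    rh = np.clip(rng.normal(spec.rh_mean, 0.10, n_days), 0.05, 0.98)
    sunshine = np.clip(rng.normal(spec.sunshine_mean, 2.0, n_days), 0.0, 14.0)
    wind = np.abs(rng.normal(spec.wind_mean, 1.0, n_days))
    pressure = pressure_from_elevation(spec.elevation)

    wet = rng.random(n_days) < spec.wet_day_prob
    amounts = np.where(wet, rng.exponential(1.0, n_days), 0.0)
    # July-August boost: scale summer wet-day amounts so their expected
    # share of the annual total equals summer_share.
    summer = (doy >= 182) & (doy <= 243)
    s_sum = amounts[summer].sum()
    o_sum = amounts[~summer].sum()
    if s_sum > 0.0 and o_sum > 0.0 and 0.0 < spec.summer_share < 1.0:
        boost = (spec.summer_share / (1.0 - spec.summer_share)) * (o_sum / s_sum)
        amounts = np.where(summer, amounts * boost, amounts)
    total = amounts.sum()
    if total > 0.0 and spec.precip_total > 0.0:
        amounts *= spec.precip_total / total
    elif spec.precip_total == 0.0:
        amounts[:] = 0.0

    start = datetime.date(spec.year, 1, 1)
    days = []
    for i in range(n_days):
        days.append(
            WeatherDay(
                date=start + datetime.timedelta(days=i),
                t_mean=float(t_mean[i]),
                t_max=float(t_max[i]),
                t_min=float(t_min[i]),
                rh_mean=float(rh[i]),
                sunshine=float(sunshine[i]),
                wind=float(wind[i]),
                pressure=float(pressure),
                precip=float(amounts[i]),
            )
        )
    return days


def synth_weather_years(
    years: Sequence[int] = (2001, 2002, 2003, 2004, 2005, 2006),
    seed: int = 0,
) -> list[list[WeatherDay]]:
    """One synthetic weather year per reference year, with per-year sub-seeds."""
    return [
        synth_weather(weather_spec_for_year(y, seed=seed + k))
        for k, y in enumerate(years)
    ]


def synth_targets(theta_star, config, noise: NoiseSpec):
    """Forward-simulate with hidden parameters theta_star and emit noisy targets.

    The record layout mirrors field target files: organ-level internode
    biomass/length/diameter and needle biomass per (PA, rank) class for the
    oldest tree, plus internode/needle compartment totals for every younger
    age.  Multiplicative lognormal noise exp(sigma * Z) is applied per
    record, with ``noise.replicates`` replicate trees; sigma = 0 returns
    the simulated values exactly.  Deterministic per noise seed.

    Implemented in :mod:`pinewater.calibration` terms: see
    ``calibration.predict_records`` for the simulated quantities.
    """
    from . import calibration as cal

    clean = cal.predict_records(theta_star, config)
    rng = np.random.default_rng(noise.seed)
    frames = []
    for rep in range(1, noise.replicates + 1):
        noisy = clean.copy()
        factors = np.array(
            [
                math.exp(noise.sigma_for(obs) * rng.standard_normal())
                for obs in noisy["observable"]
            ]
        )
        noisy["value"] = noisy["value"] * factors
        noisy["replicate"] = rep
        frames.append(noisy)
    import pandas as pd

    frame = pd.concat(frames, ignore_index=True)
    return cal.TargetData(frame)
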