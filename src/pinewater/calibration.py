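"""Hidden-parameter estimation by grouped generalised least squares.

Thirteen parameters of the growth engine cannot be measured directly and
are estimated from target files: the water-use efficiency, the internode
sinks p_e (PA 1-4), the needle sinks p_a (PA 2-4; PA 1 is the reference,
fixed at 1), the ring sink p_c, the needle-influence coefficient lambda
and the secondary sinks Rp (PA 2-4; trunk reference 1).

Targets pair observed organ dimensions and biomasses with their simulated
counterparts.  Observables of different kinds live on very different
scales, so records are grouped by kind and the error variance of each
group is estimated from the data itself: a 2-stage Aitken scheme first
fits by ordinary nonlinear least squares, then re-fits with residuals
weighted by the inverse estimated group standard deviations, iterating
the two stages to convergence.  Goodness of fit is reported as per-group
RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .architecture import INTERNODE, NEEDLE, BranchingRules, TreeTopology
from .growth import CycleLedger, PlantParams, simulate
from .soil import SeasonForcing, SoilParams, compute_forcing
from .weather import SiteInfo, WeatherDay

__all__ = [
    "HIDDEN_PARAM_NAMES",
    "OBSERVABLES",
    "TargetData",
    "TargetError",
    "CalibrationConfig",
    "FitResult",
    "theta_to_params",
    "params_to_theta",
    "load_targets",
    "predict_records",
    "residuals",
    "fit_gls",
    "rmse_report",
]

HIDDEN_PARAM_NAMES = (
    "wue",
    "p_e1", "p_e2", "p_e3", "p_e4",
    "p_a2", "p_a3", "p_a4",
    "p_c",
    "lambda_ring",
    "r_p2", "r_p3", "r_p4",
)

OBSERVABLES = (
    "internode_biomass",
    "internode_length",
    "internode_diameter",
    "needle_biomass",
    "compartment_internode",
    "compartment_needle",
)

_ORGAN_OBSERVABLES = OBSERVABLES[:4]

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "wue": (0.5, 20.0),
    "p_e1": (1e-4, 10.0), "p_e2": (1e-4, 10.0),
    "p_e3": (1e-4, 10.0), "p_e4": (1e-4, 10.0),
    "p_a2": (1e-4, 10.0), "p_a3": (1e-4, 10.0), "p_a4": (1e-4, 10.0),
    "p_c": (1e-3, 100.0),
    "lambda_ring": (0.0, 1.0),
    "r_p2": (1e-6, 1.0), "r_p3": (1e-6, 1.0), "r_p4": (1e-6, 1.0),
}


class TargetError(ValueError):
    """Malformed target file or record."""


def theta_to_params(theta: Sequence[float], base: PlantParams) -> PlantParams:
    """Plant parameters with the 13 hidden entries replaced from theta."""
    t = dict(zip(HIDDEN_PARAM_NAMES, theta))
    return replace(
        base,
        wue=t["wue"],
        p_e=(t["p_e1"], t["p_e2"], t["p_e3"], t["p_e4"]),
        p_a=(1.0, t["p_a2"], t["p_a3"], t["p_a4"]),
        p_c=t["p_c"],
        lambda_ring=t["lambda_ring"],
        r_p=(1.0, t["r_p2"], t["r_p3"], t["r_p4"]),
    )


def params_to_theta(params: PlantParams) -> np.ndarray:
    """The 13 hidden parameters of a parameter set, in canonical order."""
    return np.array(
        [
            params.wue,
            *params.p_e,
            params.p_a[1], params.p_a[2], params.p_a[3],
            params.p_c,
            params.lambda_ring,
            params.r_p[1], params.r_p[2], params.r_p[3],
        ]
    )


@dataclass
class TargetData:
    """Calibration records: (observable, age, pa, rank, value, unit, replicate).

    ``rank`` is the growth cycle in which the organ class appeared (organ
    observables; 0 for compartment totals).  Grouping key is the
    observable kind.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"observable", "age", "pa", "rank", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise TargetError(f"missing target column(s): {', '.join(sorted(missing))}")
        if "replicate" not in self.frame.columns:
            self.frame = self.frame.assign(replicate=1)
        bad = ~self.frame["observable"].isin(OBSERVABLES)
        if bad.any():
            raise TargetError(
                f"unknown observable(s): {sorted(self.frame.loc[bad, 'observable'].unique())}"
            )
        if (self.frame["value"] <= 0).any():
            row = int(self.frame.index[self.frame["value"] <= 0][0])
            raise TargetError(f"non-positive target value at record {row}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def groups(self) -> np.ndarray:
        return self.frame["observable"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    def validate_against(self, n_cycles: int) -> None:
        if (self.frame["age"] > n_cycles).any():
            bad = int(self.frame["age"].max())
            raise TargetError(
                f"target age {bad} exceeds simulated max age {n_cycles}"
            )
        organ = self.frame["observable"].isin(_ORGAN_OBSERVABLES)
        if organ.any() and (self.frame.loc[organ, "age"] != n_cycles).any():
            raise TargetError(
                f"organ-level records must refer to the oldest tree (age {n_cycles})"
            )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path


def load_targets(path: str | Path) -> TargetData:
    """Read a delimited target file (columns observable, age, pa, rank, value)."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface file problems verbatim
        raise TargetError(f"cannot read target file {path}: {exc}") from exc
    return TargetData(frame)


@dataclass
class CalibrationConfig:
    """Everything fixed during estimation: forcing, structure, known parameters."""

    weather_years: Sequence[Sequence[WeatherDay]] | None = None
    soil: SoilParams = field(default_factory=SoilParams)
    site: SiteInfo = field(default_factory=SiteInfo)
    rules: BranchingRules = field(default_factory=BranchingRules)
    base_params: PlantParams = field(default_factory=PlantParams)
    n_cycles: int = 6
    seed: int = 0
    stage_tol: float = 1e-6
    max_stage_iter: int = 20
    forcings: Sequence[SeasonForcing] | None = None

    def get_forcings(self) -> Sequence[SeasonForcing]:
        if self.forcings is None:
            if self.weather_years is None:
                raise ValueError("CalibrationConfig needs weather_years or forcings")
            object.__setattr__(
                self,
                "forcings",
                [compute_forcing(y, self.site) for y in self.weather_years],
            )
        return self.forcings


def _simulate_theta(
    theta: Sequence[float], config: CalibrationConfig
) -> tuple[list[CycleLedger], TreeTopology]:
    params = theta_to_params(theta, config.base_params)
    return simulate(
        None,
        config.soil,
        config.site,
        config.rules,
        params,
        n_cycles=config.n_cycles,
        seed=config.seed,
        forcings=config.get_forcings(),
    )


def predict_records(theta: Sequence[float], config: CalibrationConfig) -> pd.DataFrame:
    """Simulated counterparts of a full target layout.

    Organ-level rows: class means over organs sharing (kind, pa,
    birth cycle) on the oldest tree; internode biomass includes rings and
    diameters include secondary growth.  Compartment rows: internode and
    needle totals of the tree at each younger age.
    """
    ledgers, topology = _simulate_theta(theta, config)
    n = config.n_cycles
    rows: list[dict] = []
    classes: dict[tuple[str, int, int], list[float]] = {}
    for u in topology.units:
        key = (INTERNODE, u.pa, u.birth_cycle)
        for obs, val in (
            ("internode_biomass", u.internode.total_biomass),
            ("internode_length", u.internode.length),
            ("internode_diameter", u.internode.diameter),
            ("needle_biomass", u.needle.fresh_biomass),
        ):
            classes.setdefault((obs, u.pa, u.birth_cycle), []).append(val)
    for (obs, pa, birth), vals in sorted(classes.items()):
        unit = "cm" if "length" in obs or "diameter" in obs else "g"
        rows.append(
            {
                "observable": obs, "age": n, "pa": pa, "rank": birth,
                "value": float(np.mean(vals)), "unit": unit,
            }
        )
    for led in ledgers[:-1]:
        rows.append(
            {
                "observable": "compartment_internode", "age": led.cycle,
                "pa": 0, "rank": 0, "value": led.internode_mass, "unit": "g",
            }
        )
        rows.append(
            {
                "observable": "compartment_needle", "age": led.cycle,
                "pa": 0, "rank": 0, "value": led.needle_mass, "unit": "g",
            }
        )
    return pd.DataFrame(rows)


def residuals(
    theta: Sequence[float], targets: TargetData, config: CalibrationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(observed - simulated, group labels) for every target record."""
    try:
        pred_frame = predict_records(theta, config)
    except Exception as exc:
        raise RuntimeError(f"simulation failed at theta={list(theta)}: {exc}") from exc
    lookup = {
        (r.observable, r.age, r.pa, r.rank): r.value
        for r in pred_frame.itertuples(index=False)
    }
    res = np.empty(len(targets))
    for i, rec in enumerate(targets.frame.itertuples(index=False)):
        key = (rec.observable, int(rec.age), int(rec.pa), int(rec.rank))
        if key not in lookup:
            raise TargetError(f"target record {key} has no simulated counterpart")
        res[i] = float(rec.value) - lookup[key]
    return res, targets.groups


@dataclass
class FitResult:
    """Outcome of the grouped GLS estimation."""

    theta: dict[str, float]
    group_variance: dict[str, float]
    rmse: dict[str, float]
    converged: bool
    n_stage_iter: int
    n_records: int
    objective: float

    @property
    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[name] for name in HIDDEN_PARAM_NAMES])

    def report(self) -> str:
        lines = ["Grouped GLS fit of the 13 hidden growth parameters", ""]
        lines.append(f"records: {self.n_records}   stage iterations: "
                     f"{self.n_stage_iter}   converged: {self.converged}")
        lines.append(f"weighted objective: {self.objective:.6g}")
        lines.append("")
        lines.append("parameter estimates:")
        for name in HIDDEN_PARAM_NAMES:
            lines.append(f"  {name:12s} {self.theta[name]:.6g}")
        lines.append("")
        lines.append("per-group RMSE / estimated error s.d.:")
        for grp in sorted(self.rmse):
            sd = self.group_variance[grp] ** 0.5
            lines.append(f"  {grp:22s} rmse={self.rmse[grp]:.4g}  sd={sd:.4g}")
        return "\n".join(lines)


def _group_stats(res: np.ndarray, groups: np.ndarray) -> tuple[dict, dict]:
    variance: dict[str, float] = {}
    rmse: dict[str, float] = {}
    for grp in np.unique(groups):
        r = res[groups == grp]
        ms = float(np.mean(r**2))
        rmse[grp] = ms**0.5
        variance[grp] = max(ms, 1e-12)
    return variance, rmse


def fit_gls(
    targets: TargetData,
    config: CalibrationConfig,
    init: Sequence[float] | dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Estimate the 13 hidden parameters by iterated 2-stage Aitken GLS.

    Stage 1 minimises the unweighted sum of squared residuals; stage 2
    estimates each group's error variance from the current residuals and
    re-fits the variance-weighted criterion; stages repeat until the
    parameter vector changes by less than ``config.stage_tol`` (relative)
    or ``config.max_stage_iter`` is hit, in which case the result is
    flagged unconverged rather than raising.  Deterministic given init.
    """
    targets.validate_against(config.n_cycles)
    if len(targets) < len(HIDDEN_PARAM_NAMES):
        raise TargetError(
            f"need at least {len(HIDDEN_PARAM_NAMES)} records, got {len(targets)}"
        )
    if init is None:
        theta0 = params_to_theta(config.base_params)
    elif isinstance(init, dict):
        theta0 = np.array([init[name] for name in HIDDEN_PARAM_NAMES])
    else:
        theta0 = np.asarray(init, dtype=float)
    bounds_map = dict(DEFAULT_BOUNDS)
    if bounds:
        bounds_map.update(bounds)
    lo = np.array([bounds_map[n][0] for n in HIDDEN_PARAM_NAMES])
    hi = np.array([bounds_map[n][1] for n in HIDDEN_PARAM_NAMES])
    theta0 = np.clip(theta0, lo, hi)

    groups = targets.groups
    weights = np.ones(len(targets))

    def weighted(theta: np.ndarray) -> np.ndarray:
        res, _ = residuals(theta, targets, config)
        return res * weights

    theta = theta0
    converged = False
    variance: dict[str, float] = {}
    n_iter = 0
    for n_iter in range(1, config.max_stage_iter + 1):
        sol = least_squares(
            weighted, theta, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, x_scale="jac",
        )
        new_theta = sol.x
        res, _ = residuals(new_theta, targets, config)
        variance, _ = _group_stats(res, groups)
        weights = np.array([variance[g] ** -0.5 for g in groups])
        rel_change = np.max(
            np.abs(new_theta - theta) / np.maximum(np.abs(theta), 1e-12)
        )
        theta = new_theta
        if rel_change < config.stage_tol:
            converged = True
            break
    res, _ = residuals(theta, targets, config)
    _, rmse = _group_stats(res, groups)
    objective = float(np.sum((res * weights) ** 2))
    return FitResult(
        theta=dict(zip(HIDDEN_PARAM_NAMES, theta)),
        group_variance=variance,
        rmse=rmse,
        converged=converged,
        n_stage_iter=n_iter,
        n_records=len(targets),
        objective=objective,
    )


def rmse_report(
    fit: FitResult, targets: TargetData, config: CalibrationConfig
) -> pd.DataFrame:
    """Per-observable RMSE table recomputed at the fitted parameters."""
    res, groups = residuals(fit.theta_vector, targets, config)
    rows = []
    for grp in sorted(np.unique(groups)):
        r = res[groups == grp]
        rows.append(
            {"observable": grp, "n": len(r), "rmse": float(np.sqrt(np.mean(r**2)))}
        )
    return pd.DataFrame(rows)
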