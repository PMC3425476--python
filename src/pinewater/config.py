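"""Structured run configuration (YAML) and provenance records.

One YAML file carries every science parameter; command-line flags are
reserved for paths and verbosity so that runs stay auditable.  Sections
(all optional — defaults reproduce the calibrated young-pine setup):

.. code-block:: yaml

    site:        {latitude, elevation, angstrom_a, angstrom_b}
    soil:        {z_r, theta_f, theta_w, r_frac, k_c}
    plant:       {wue, c_w, epsilon, k_ext, p_e, p_a, p_c, lambda_ring,
                  r_p, b, beta, density, q0, rho, needle_life}
    branching:   {laterals: {1: 3, 2: 2, 3: 1}, max_pa, insertion_angle}
    weather:     {files: [...]}            # or
                 {synthetic: {years: [2001, ...], seed: 0}}
    simulation:  {n_cycles, seed}
    calibration: {targets, init, bounds, stage_tol, max_stage_iter}
    sensitivity: {scales: [0.5, ..., 1.5]}
    output:      {directory}

Every run writes ``provenance.json`` (config SHA-256, seeds, package
version) next to its outputs, sufficient to reproduce them bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .architecture import BranchingRules
from .growth import PlantParams
from .sensitivity import DEFAULT_SCALES
from .soil import SoilParams
from .synthetic import synth_weather_years
from .weather import SiteInfo, read_weather

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration problem, naming the offending section/field."""


def _build(section: str, cls, data: dict[str, Any]):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"section '{section}': {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"section '{section}': {exc}") from exc


@dataclass
class RunConfig:
    """Validated configuration for a simulation/calibration/sensitivity run."""

    site: SiteInfo = field(default_factory=SiteInfo)
    soil: SoilParams = field(default_factory=SoilParams)
    plant: PlantParams = field(default_factory=PlantParams)
    branching: BranchingRules = field(default_factory=BranchingRules)
    weather_files: list[Path] = field(default_factory=list)
    synthetic_years: list[int] = field(
        default_factory=lambda: [2001, 2002, 2003, 2004, 2005, 2006]
    )
    weather_seed: int = 0
    n_cycles: int = 6
    seed: int = 0
    targets_path: Path | None = None
    calibration_init: dict[str, float] | None = None
    calibration_bounds: dict[str, tuple[float, float]] | None = None
    stage_tol: float = 1e-6
    max_stage_iter: int = 20
    scales: tuple[float, ...] = DEFAULT_SCALES
    output_dir: Path = Path("pinewater_out")
    raw: dict[str, Any] = field(default_factory=dict)

    def weather_years(self):
        """Load weather from files, or generate the synthetic presets."""
        if self.weather_files:
            years = []
            for f in self.weather_files:
                if not Path(f).exists():
                    raise ConfigError(f"section 'weather': file not found: {f}")
                years.append(read_weather(f, pressure_kpa=self.site.pressure))
            return years
        return synth_weather_years(self.synthetic_years, seed=self.weather_seed)

    def provenance(self) -> dict[str, Any]:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return {
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "weather_seed": self.weather_seed,
            "version": __version__,
        }

    def write_provenance(self, directory: Path) -> Path:
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "provenance.json"
        path.write_text(json.dumps(self.provenance(), indent=2, sort_keys=True) + "\n")
        return path


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration; None gives all defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded

    site = _build("site", SiteInfo, data.get("site", {}))
    soil = _build("soil", SoilParams, data.get("soil", {}))
    plant_data = dict(data.get("plant", {}))
    for key in ("p_e", "p_a", "r_p", "b", "beta"):
        if key in plant_data:
            plant_data[key] = tuple(plant_data[key])
    plant = _build("plant", PlantParams, plant_data)
    branching_data = dict(data.get("branching", {}))
    if "laterals" in branching_data:
        branching_data["laterals"] = {
            int(k): int(v) for k, v in branching_data["laterals"].items()
        }
    if "insertion_angle" in branching_data:
        branching_data["insertion_angle"] = tuple(branching_data["insertion_angle"])
    branching = _build("branching", BranchingRules, branching_data)

    weather = data.get("weather", {}) or {}
    weather_files = [Path(p) for p in weather.get("files", [])]
    synth = weather.get("synthetic", {}) or {}
    synthetic_years = list(synth.get("years", [2001, 2002, 2003, 2004, 2005, 2006]))
    weather_seed = int(synth.get("seed", 0))

    sim = data.get("simulation", {}) or {}
    cal = data.get("calibration", {}) or {}
    sens = data.get("sensitivity", {}) or {}
    out = data.get("output", {}) or {}

    bounds = cal.get("bounds")
    if bounds is not None:
        bounds = {k: (float(v[0]), float(v[1])) for k, v in bounds.items()}

    return RunConfig(
        site=site,
        soil=soil,
        plant=plant,
        branching=branching,
        weather_files=weather_files,
        synthetic_years=synthetic_years,
        weather_seed=weather_seed,
        n_cycles=int(sim.get("n_cycles", 6)),
        seed=int(sim.get("seed", 0)),
        targets_path=Path(cal["targets"]) if "targets" in cal else None,
        calibration_init=cal.get("init"),
        calibration_bounds=bounds,
        stage_tol=float(cal.get("stage_tol", 1e-6)),
        max_stage_iter=int(cal.get("max_stage_iter", 20)),
        scales=tuple(float(s) for s in sens.get("scales", DEFAULT_SCALES)),
        output_dir=Path(out.get("directory", "pinewater_out")),
        raw=data,
    )
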