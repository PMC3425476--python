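"""Yearly growth cycle: water-driven biomass production and source-sink allocation.

Each growth cycle (one year) runs five stages:

1. the topology develops (new growth units appear by the automaton rules);
2. the biomass produced in the previous cycle, Q(i-1), is shared among the
   new organs and the ring (secondary-growth) pool in proportion to their
   relative sink strengths: each new organ of kind o and physiological age
   k receives p_o(k) * Q(i-1) / D(i), where the demand D(i) sums the sinks
   of all appearing organs plus a single whole-tree ring sink p_c;
3. allometric rules turn organ biomass into dimensions, the ring pool is
   spread along the axes, and the functioning leaf area and LAI are updated;
4. the daily soil water balance runs over the growth season with that LAI,
   giving the cumulative plant transpiration T_a(i);
5. production closes the loop: dry matter = WUE * T_a(i) * S_p (1 mm of
   water over 1 m2 is 1 kg), converted to fresh mass with the plant water
   content C_w: fresh = dry / (1 - C_w).

Internodes are cylinders of fresh density rho whose slenderness (length /
diameter ratio) follows the power law s = b[pa] * q^beta[pa].  Ring biomass
is distributed over internodes with weights Rp[pa] * length * (lambda *
A_above + (1 - lambda)), where A_above is the fraction of living needle
area borne distal to the internode; the added mass thickens the internode
at constant length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .architecture import (
    INTERNODE,
    NEEDLE,
    BranchingRules,
    GrowthUnit,
    Organ,
    TreeTopology,
    develop_cycle,
    organ_census,
)
from .soil import SeasonForcing, SeasonWater, SoilParams, run_season
from .weather import SiteInfo, WeatherDay

__all__ = [
    "PlantParams",
    "CycleLedger",
    "AllocationError",
    "biomass_production",
    "demand",
    "allocate_primary",
    "allocate_rings",
    "internode_dimensions",
    "leaf_metrics",
    "simulate",
    "ledgers_to_frame",
]


class AllocationError(ValueError):
    """Degenerate allocation (zero demand or zero ring weights with supply)."""


@dataclass(frozen=True)
class PlantParams:
    """Plant parameters of the growth engine.

    Defaults are the calibrated values for young Mongolian Scots pine:
    water-use efficiency ``wue`` [g dry kg-1 water], plant water content
    ``c_w``, specific leaf weight ``epsilon`` [g dry cm-2], Beer-Lambert
    extinction ``k_ext``, relative sink strengths per physiological age for
    internodes ``p_e`` and needle entities ``p_a`` (p_a[1] = 1 is the
    reference), whole-tree ring sink ``p_c``, needle-influence coefficient
    ``lambda_ring``, secondary sinks ``r_p`` [cm-1] (PA 1 entry is the
    implicit trunk reference 1), allometric scale/shape ``b``/``beta`` per
    PA, stand density [trees m-2], initial seedling biomass ``q0`` [g
    fresh], internode fresh density ``rho`` [g cm-3] and needle functioning
    time [cycles].
    """

    wue: float = 4.5
    c_w: float = 0.60
    epsilon: float = 0.035
    k_ext: float = 0.5
    p_e: tuple[float, float, float, float] = (1.37, 0.12, 0.04, 0.01)
    p_a: tuple[float, float, float, float] = (1.0, 0.42, 0.17, 0.05)
    p_c: float = 11.09
    lambda_ring: float = 0.03
    r_p: tuple[float, float, float, float] = (1.0, 0.07, 0.01, 0.001)
    b: tuple[float, float, float, float] = (76.4, 163.3, 197.7, 358.0)
    beta: tuple[float, float, float, float] = (-0.24, -0.30, -0.20, 0.14)
    density: float = 1.0
    q0: float = 10.0
    rho: float = 1.0
    needle_life: int = 3

    def __post_init__(self) -> None:
        if self.wue <= 0:
            raise ValueError(f"wue must be positive, got {self.wue}")
        if not 0.0 <= self.c_w < 1.0:
            raise ValueError(f"c_w must be in [0, 1), got {self.c_w}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if any(p < 0 for p in self.p_e + self.p_a + self.r_p) or self.p_c < 0:
            raise ValueError("sink strengths must be >= 0")
        if abs(self.p_a[0] - 1.0) > 1e-12:
            raise ValueError("p_a[1] is the reference sink and must equal 1")
        if not 0.0 <= self.lambda_ring <= 1.0:
            raise ValueError(f"lambda_ring must be in [0, 1], got {self.lambda_ring}")
        if self.needle_life < 1:
            raise ValueError("needle_life must be >= 1 cycle")

    @property
    def s_p(self) -> float:
        """Available ground area per tree [m2]."""
        return 1.0 / self.density


def biomass_production(t_a: float, s_p: float, params: PlantParams) -> float:
    """Fresh biomass Q [g] produced from seasonal transpiration t_a [mm].

    Dry matter = wue * t_a * s_p; fresh = dry / (1 - c_w).
    """
    if t_a < 0 or s_p < 0:
        raise ValueError("t_a and s_p must be non-negative")
    dry = params.wue * t_a * s_p
    return dry / (1.0 - params.c_w)


def demand(census: dict[str, dict[int, int]], params: PlantParams) -> float:
    """Overall demand D(i): sinks of all appearing organs plus the ring sink."""
    total = 0.0
    for pa, n in census.get(INTERNODE, {}).items():
        total += params.p_e[pa - 1] * n
    for pa, n in census.get(NEEDLE, {}).items():
        total += params.p_a[pa - 1] * n
    return total + params.p_c


def allocate_primary(
    q_prev: float,
    d: float,
    census: dict[str, dict[int, int]],
    params: PlantParams,
) -> tuple[dict[tuple[str, int], float], float]:
    """Per-organ biomass increments and the ring pool from supply Q(i-1).

    Returns ({(kind, pa): per-organ share}, ring_pool); an organ of kind o
    and PA k receives p_o(k) * q_prev / d, the ring pool p_c * q_prev / d.
    The shares sum to q_prev exactly.
    """
    if d <= 0.0:
        if q_prev > 0.0:
            raise AllocationError(f"demand {d} <= 0 with supply {q_prev} > 0")
        return {}, 0.0
    ratio = q_prev / d
    shares: dict[tuple[str, int], float] = {}
    for pa in census.get(INTERNODE, {}):
        shares[(INTERNODE, pa)] = params.p_e[pa - 1] * ratio
    for pa in census.get(NEEDLE, {}):
        shares[(NEEDLE, pa)] = params.p_a[pa - 1] * ratio
    return shares, params.p_c * ratio


def _subtree_needle_area(unit: GrowthUnit, cache: dict[int, float]) -> float:
    if unit.uid in cache:
        return cache[unit.uid]
    area = unit.needle.leaf_area if unit.needle.alive else 0.0
    if unit.extension is not None:
        area += _subtree_needle_area(unit.extension, cache)
    for lat in unit.laterals:
        area += _subtree_needle_area(lat, cache)
    cache[unit.uid] = area
    return area


def allocate_rings(
    ring_pool: float, topology: TreeTopology, params: PlantParams
) -> dict[int, float]:
    """Distribute the ring pool over internodes and thicken them.

    Weight of internode j: r_p[pa_j] * l_j * (lambda * A_above_j +
    (1 - lambda)), A_above_j being the fraction of living needle area borne
    at or distal to j.  The increment raises the internode cross-section at
    constant length: d_area = increment / (rho * l).  Returns uid ->
    increment [g fresh].
    """
    if ring_pool < 0.0:
        raise ValueError(f"negative ring pool {ring_pool}")
    units = [u for u in topology.units if u.internode.length > 0.0]
    if not units:
        if ring_pool > 0.0:
            raise AllocationError("ring pool > 0 but no internode can receive it")
        return {}
    cache: dict[int, float] = {}
    total_area = _subtree_needle_area(topology.root, cache) if topology.root else 0.0
    weights: list[float] = []
    for u in units:
        a_above = cache.get(u.uid, 0.0) / total_area if total_area > 0.0 else 0.0
        w = (
            params.r_p[u.pa - 1]
            * u.internode.length
            * (params.lambda_ring * a_above + (1.0 - params.lambda_ring))
        )
        weights.append(w)
    w_sum = sum(weights)
    if w_sum <= 0.0:
        if ring_pool > 0.0:
            raise AllocationError("all ring weights are zero with ring pool > 0")
        return {}
    increments: dict[int, float] = {}
    for u, w in zip(units, weights):
        inc = ring_pool * w / w_sum
        increments[u.uid] = inc
        organ = u.internode
        organ.ring_biomass += inc
        area_old = math.pi / 4.0 * organ.diameter**2
        d_area = inc / (params.rho * organ.length)
        organ.diameter = math.sqrt(4.0 * (area_old + d_area) / math.pi)
    return increments


def internode_dimensions(q: float, pa: int, params: PlantParams) -> tuple[float, float]:
    """Length and diameter [cm] of a fresh internode of biomass q [g].

    Slenderness s = b[pa] * q^beta[pa]; the internode is a cylinder of
    density rho, so l = (4 s^2 q / (pi rho))^(1/3) and d = l / s, which
    inverts exactly to (pi/4) l d^2 rho = q.
    """
    if q <= 0.0:
        raise ValueError(f"internode biomass must be positive, got {q}")
    s = params.b[pa - 1] * q ** params.beta[pa - 1]
    length = (4.0 * s * s * q / (math.pi * params.rho)) ** (1.0 / 3.0)
    return length, length / s


def leaf_metrics(
    topology: TreeTopology, params: PlantParams, s_p: float
) -> tuple[float, float]:
    """Functioning leaf area S_a [m2] and LAI = S_a / S_p.

    Marks needle entities dead once their age exceeds the functioning time,
    then sums the areas of the living ones.
    """
    s_a_cm2 = 0.0
    for u in topology.units:
        needle = u.needle
        needle.alive = (topology.age - needle.birth_cycle) < params.needle_life
        if needle.alive:
            s_a_cm2 += needle.leaf_area
    s_a = s_a_cm2 / 1e4
    return s_a, (s_a / s_p if s_p > 0 else 0.0)


@dataclass(frozen=True)
class CycleLedger:
    """Per-cycle accounting of the growth engine.

    Masses in g fresh (internode masses include rings), lengths in cm,
    areas in m2, water fluxes in mm.  ``needle_mass`` keeps all needle
    biomass ever built (no abscission term in the model);
    ``needle_mass_living`` restricts to entities within functioning time.
    """

    cycle: int
    demand: float
    q_allocated: float
    q_produced: float
    t_a: float
    et_a: float
    precip: float
    s_a: float
    s_p: float
    lai: float
    height: float
    basal_diameter: float
    internode_mass: float
    needle_mass: float
    needle_mass_living: float
    trunk_mass: float
    mass_by_pa: dict[int, float]

    @property
    def aboveground(self) -> float:
        return self.internode_mass + self.needle_mass


def _collect_ledger_stats(topology: TreeTopology) -> dict:
    internode_mass = needle_mass = needle_living = trunk_mass = 0.0
    mass_by_pa: dict[int, float] = {}
    height = 0.0
    basal_diameter = 0.0
    for u in topology.units:
        m_int = u.internode.total_biomass
        m_ndl = u.needle.fresh_biomass
        internode_mass += m_int
        needle_mass += m_ndl
        if u.needle.alive:
            needle_living += m_ndl
        mass_by_pa[u.pa] = mass_by_pa.get(u.pa, 0.0) + m_int + m_ndl
        if u.pa == 1:
            trunk_mass += m_int + m_ndl
            height += u.internode.length
    if topology.root is not None:
        basal_diameter = topology.root.internode.diameter
    return {
        "internode_mass": internode_mass,
        "needle_mass": needle_mass,
        "needle_mass_living": needle_living,
        "trunk_mass": trunk_mass,
        "mass_by_pa": mass_by_pa,
        "height": height,
        "basal_diameter": basal_diameter,
    }


def simulate(
    weather_years: Sequence[Sequence[WeatherDay]] | None,
    soil: SoilParams,
    site: SiteInfo,
    rules: BranchingRules,
    params: PlantParams,
    n_cycles: int | None = None,
    seed: int = 0,
    forcings: Sequence[SeasonForcing] | None = None,
) -> tuple[list[CycleLedger], TreeTopology]:
    """Run the coupled yearly/daily model for ``n_cycles`` growth cycles.

    ``weather_years`` is one list of WeatherDay per calendar year, reused
    cyclically if shorter than the number of cycles.  Precomputed
    ``forcings`` (one per weather year) may be passed instead to skip the
    ET0 recomputation, which is independent of the plant parameters.
    Returns the per-cycle ledgers and the final topology.
    """
    if forcings is None:
        if weather_years is None:
            raise ValueError("need weather_years or forcings")
        from .soil import compute_forcing

        forcings = [compute_forcing(y, site) for y in weather_years]
    if not forcings:
        raise ValueError("need at least one year of weather")
    if n_cycles is None:
        n_cycles = len(forcings)
    topology = TreeTopology()
    ledgers: list[CycleLedger] = []
    q_prev = params.q0
    s_p = params.s_p
    for cycle in range(1, n_cycles + 1):
        develop_cycle(topology, rules, rng_seed=seed)
        census = organ_census(topology, cycle)
        d_i = demand(census, params)
        shares, ring_pool = allocate_primary(q_prev, d_i, census, params)
        for u in topology.new_units(cycle):
            q_int = shares.get((INTERNODE, u.pa), 0.0)
            u.internode.fresh_biomass = q_int
            if q_int > 0.0:
                length, diameter = internode_dimensions(q_int, u.pa, params)
                u.internode.length = length
                u.internode.diameter = diameter
            q_ndl = shares.get((NEEDLE, u.pa), 0.0)
            u.needle.fresh_biomass = q_ndl
            u.needle.leaf_area = q_ndl * (1.0 - params.c_w) / params.epsilon
        s_a, lai = leaf_metrics(topology, params, s_p)
        if ring_pool > 0.0:
            allocate_rings(ring_pool, topology, params)
        forcing = forcings[(cycle - 1) % len(forcings)]
        season: SeasonWater = run_season(
            None, soil, lai, None, k_ext=params.k_ext, forcing=forcing
        )
        q_i = biomass_production(season.t_a_total, s_p, params)
        stats = _collect_ledger_stats(topology)
        ledgers.append(
            CycleLedger(
                cycle=cycle,
                demand=d_i,
                q_allocated=q_prev,
                q_produced=q_i,
                t_a=season.t_a_total,
                et_a=season.et_a_total,
                precip=season.precip_total,
                s_a=s_a,
                s_p=s_p,
                lai=lai,
                **stats,
            )
        )
        q_prev = q_i
    return ledgers, topology


def ledgers_to_frame(ledgers: Sequence[CycleLedger]) -> pd.DataFrame:
    """Flatten cycle ledgers to a DataFrame (mass_by_pa expanded per PA)."""
    rows = []
    for led in ledgers:
        row = {
            "cycle": led.cycle,
            "demand": led.demand,
            "q_allocated": led.q_allocated,
            "q_produced": led.q_produced,
            "t_a": led.t_a,
            "et_a": led.et_a,
            "precip": led.precip,
            "s_a": led.s_a,
            "s_p": led.s_p,
            "lai": led.lai,
            "height": led.height,
            "basal_diameter": led.basal_diameter,
            "internode_mass": led.internode_mass,
            "needle_mass": led.needle_mass,
            "needle_mass_living": led.needle_mass_living,
            "trunk_mass": led.trunk_mass,
            "aboveground": led.aboveground,
        }
        for pa in range(1, 5):
            row[f"mass_pa{pa}"] = led.mass_by_pa.get(pa, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def save_ledgers(ledgers: Sequence[CycleLedger], path: str | Path) -> Path:
    path = Path(path)
    ledgers_to_frame(ledgers).to_csv(path, index=False)
    return path
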