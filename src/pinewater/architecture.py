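"""Physiological-age-structured tree topology and 3D geometry.

A young pine is described as growth units (GUs): the set of organs one bud
produces in one yearly growth cycle — one internode and one needle entity
(all needles of a GU pooled), plus the apical bud that extends the axis and
lateral buds that found branches.  Growth units are classified by
physiological age (PA), which for this species coincides with branching
order: 1 for the trunk up to M = 4 for third-order branches.

Topology develops by simple automaton rules: every terminal apical bud
extends its axis by one GU of the same PA each cycle, and every GU formed
in the previous cycle bears a configured number of lateral GUs of PA+1.
Branch counts are deterministic per PA; geometry (azimuth, insertion angle)
is the only seeded randomness and never feeds back into the census.
3D orientations serve visualisation only — they are not used by the growth
computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "Organ",
    "GrowthUnit",
    "BranchingRules",
    "TreeTopology",
    "ArchitectureError",
    "develop_cycle",
    "organ_census",
    "build_geometry",
    "export_geometry",
]

INTERNODE = "internode"
NEEDLE = "needle"


class ArchitectureError(ValueError):
    """Invalid topology operation or missing organ data."""


@dataclass
class Organ:
    """One organ: an internode or the pooled needle entity of a growth unit.

    Biomasses in g fresh; lengths/diameters in cm; leaf_area in cm2
    (needles only); ring_biomass accumulates secondary growth (internodes
    only).
    """

    kind: str
    pa: int
    birth_cycle: int
    fresh_biomass: float = 0.0
    ring_biomass: float = 0.0
    length: float = 0.0
    diameter: float = 0.0
    leaf_area: float = 0.0
    alive: bool = True

    @property
    def total_biomass(self) -> float:
        return self.fresh_biomass + self.ring_biomass


@dataclass
class GrowthUnit:
    uid: int
    pa: int
    birth_cycle: int
    internode: Organ
    needle: Organ
    parent: "GrowthUnit | None" = field(default=None, repr=False)
    extension: "GrowthUnit | None" = field(default=None, repr=False)
    laterals: list["GrowthUnit"] = field(default_factory=list, repr=False)


@dataclass(frozen=True)
class BranchingRules:
    """Branching counts and geometric ranges per physiological age.

    ``laterals`` maps bearer PA -> number of PA+1 lateral GUs it bears the
    cycle after its formation.  The default counts (3, 2, 1 for PA 1, 2, 3)
    are field-plausible placeholders for a six-year-old stand, not measured
    values.  Insertion angles in degrees, measured from the bearing axis.
    """

    laterals: dict[int, int] = field(default_factory=lambda: {1: 3, 2: 2, 3: 1})
    max_pa: int = 4
    insertion_angle: tuple[float, float] = (70.0, 90.0)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.laterals.values()):
            raise ArchitectureError("lateral counts must be >= 0")
        if self.max_pa < 1:
            raise ArchitectureError("max_pa must be >= 1")
        lo, hi = self.insertion_angle
        if not (0.0 <= lo <= hi <= 180.0):
            raise ArchitectureError(f"bad insertion angle range {self.insertion_angle}")


@dataclass
class TreeTopology:
    """The whole-tree index of growth units and organs."""

    root: GrowthUnit | None = None
    age: int = 0
    units: list[GrowthUnit] = field(default_factory=list)
    _next_uid: int = 0

    def iter_units(self) -> Iterator[GrowthUnit]:
        return iter(self.units)

    def organs(
        self,
        kind: str | None = None,
        pa: int | None = None,
        birth_cycle: int | None = None,
    ) -> list[Organ]:
        out: list[Organ] = []
        for u in self.units:
            for organ in (u.internode, u.needle):
                if kind is not None and organ.kind != kind:
                    continue
                if pa is not None and organ.pa != pa:
                    continue
                if birth_cycle is not None and organ.birth_cycle != birth_cycle:
                    continue
                out.append(organ)
        return out

    def new_units(self, cycle: int) -> list[GrowthUnit]:
        return [u for u in self.units if u.birth_cycle == cycle]

    def _make_unit(self, pa: int, cycle: int, parent: GrowthUnit | None) -> GrowthUnit:
        unit = GrowthUnit(
            uid=self._next_uid,
            pa=pa,
            birth_cycle=cycle,
            internode=Organ(kind=INTERNODE, pa=pa, birth_cycle=cycle),
            needle=Organ(kind=NEEDLE, pa=pa, birth_cycle=cycle),
            parent=parent,
        )
        self._next_uid += 1
        self.units.append(unit)
        return unit


def develop_cycle(
    topology: TreeTopology, rules: BranchingRules, rng_seed: int = 0
) -> TreeTopology:
    """Advance the topology by one growth cycle (in place; returns topology).

    Every terminal apical bud extends its axis by one GU of the same PA;
    every GU formed in the previous cycle bears ``rules.laterals[pa]``
    lateral GUs of PA+1 (none beyond max PA).  With fixed lateral counts
    the development is fully deterministic; the seed argument exists for
    interface symmetry with the geometric operations.
    """
    del rng_seed  # census is deterministic; randomness lives in geometry only
    cycle = topology.age + 1
    if topology.root is None:
        topology.root = topology._make_unit(pa=1, cycle=cycle, parent=None)
    else:
        terminals = [u for u in topology.units if u.extension is None]
        bearers = [u for u in topology.units if u.birth_cycle == topology.age]
        for unit in terminals:
            unit.extension = topology._make_unit(pa=unit.pa, cycle=cycle, parent=unit)
        for unit in bearers:
            child_pa = unit.pa + 1
            if child_pa > rules.max_pa:
                continue
            for _ in range(rules.laterals.get(unit.pa, 0)):
                lat = topology._make_unit(pa=child_pa, cycle=cycle, parent=unit)
                unit.laterals.append(lat)
    topology.age = cycle
    return topology


def organ_census(topology: TreeTopology, cycle: int) -> dict[str, dict[int, int]]:
    """Counts N_o(k, i) of organs appearing at the given cycle, by kind and PA."""
    if not 1 <= cycle <= topology.age:
        raise ArchitectureError(f"cycle {cycle} outside 1..{topology.age}")
    census: dict[str, dict[int, int]] = {INTERNODE: {}, NEEDLE: {}}
    for u in topology.units:
        if u.birth_cycle != cycle:
            continue
        for organ in (u.internode, u.needle):
            by_pa = census[organ.kind]
            by_pa[organ.pa] = by_pa.get(organ.pa, 0) + 1
    return census


def _perpendicular_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal pair spanning the plane normal to direction."""
    z = np.array([0.0, 0.0, 1.0])
    cross = np.cross(direction, z)
    if np.linalg.norm(cross) < 1e-9:
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = cross / np.linalg.norm(cross)
    v = np.cross(direction, u)
    v /= np.linalg.norm(v)
    return u, v


def build_geometry(
    topology: TreeTopology, rules: BranchingRules, rng_seed: int = 0
) -> pd.DataFrame:
    """Per-organ 3D frames: base point, axis direction, length, diameter.

    The trunk is vertical (+z); a lateral starts at its bearer's tip with
    azimuth uniform on the circle and insertion angle drawn uniformly from
    the configured range, both seeded; an axis keeps its founding direction.
    Needle entities appear as marker rows at their internode midpoint.
    """
    rng = np.random.default_rng(rng_seed)
    base: dict[int, np.ndarray] = {}
    direction: dict[int, np.ndarray] = {}
    rows: list[dict] = []
    for unit in topology.units:  # creation order: parents precede children
        organ = unit.internode
        if organ.length <= 0.0:
            raise ArchitectureError(
                f"internode of unit {unit.uid} (pa={unit.pa}, "
                f"cycle={unit.birth_cycle}) has no length; run the growth engine first"
            )
        if unit.parent is None:
            b = np.zeros(3)
            d = np.array([0.0, 0.0, 1.0])
        elif unit.parent.extension is unit:
            pb = base[unit.parent.uid]
            pd_ = direction[unit.parent.uid]
            b = pb + pd_ * unit.parent.internode.length
            d = pd_
        else:  # lateral: branch off at the bearer's tip
            pb = base[unit.parent.uid]
            pd_ = direction[unit.parent.uid]
            b = pb + pd_ * unit.parent.internode.length
            azimuth = rng.uniform(0.0, 2.0 * math.pi)
            lo, hi = rules.insertion_angle
            theta = math.radians(rng.uniform(lo, hi))
            u, v = _perpendicular_frame(pd_)
            d = (
                math.cos(theta) * pd_
                + math.sin(theta) * (math.cos(azimuth) * u + math.sin(azimuth) * v)
            )
            d /= np.linalg.norm(d)
        base[unit.uid] = b
        direction[unit.uid] = d
        rows.append(
            {
                "uid": unit.uid, "kind": INTERNODE, "pa": unit.pa,
                "birth_cycle": unit.birth_cycle,
                "x": b[0], "y": b[1], "z": b[2],
                "dx": d[0], "dy": d[1], "dz": d[2],
                "length": organ.length, "diameter": organ.diameter,
            }
        )
        mid = b + d * (0.5 * organ.length)
        rows.append(
            {
                "uid": unit.uid, "kind": NEEDLE, "pa": unit.pa,
                "birth_cycle": unit.birth_cycle,
                "x": mid[0], "y": mid[1], "z": mid[2],
                "dx": d[0], "dy": d[1], "dz": d[2],
                "length": 0.0, "diameter": 0.0,
            }
        )
    return pd.DataFrame(rows)


def _cylinder(
    base: np.ndarray, direction: np.ndarray, length: float, radius: float, sections: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vertices/faces of a closed cylinder: 2*sections + 2 vertices, 4*sections tris."""
    u, v = _perpendicular_frame(direction)
    angles = np.linspace(0.0, 2.0 * math.pi, sections, endpoint=False)
    ring = np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v)
    bottom = base + radius * ring
    top = bottom + direction * length
    verts = np.vstack([bottom, top, base, base + direction * length])
    b_center, t_center = 2 * sections, 2 * sections + 1
    faces = []
    for i in range(sections):
        j = (i + 1) % sections
        faces.append([i, j, sections + i])
        faces.append([j, sections + j, sections + i])
        faces.append([j, i, b_center])
        faces.append([sections + i, sections + j, t_center])
    return verts, np.array(faces)


#: triangle-mesh facet count per internode cylinder
MESH_SECTIONS = 12
#: half-edge of the triangular needle marker [cm]
MARKER_SIZE = 0.5


def export_geometry(
    frames: pd.DataFrame, path: str | Path, sections: int = MESH_SECTIONS
) -> Path:
    """Write the crown as an OBJ triangle mesh plus a flat CSV frame table.

    Internodes become closed cylinders with ``sections`` facets
    (2*sections + 2 vertices each); needle entities become small triangular
    markers (3 vertices each).  The frame table is written next to the mesh
    with a ``.csv`` suffix.
    """
    path = Path(path)
    all_verts: list[np.ndarray] = []
    all_faces: list[np.ndarray] = []
    offset = 0
    for row in frames.itertuples(index=False):
        pos = np.array([row.x, row.y, row.z])
        d = np.array([row.dx, row.dy, row.dz])
        if row.kind == INTERNODE:
            verts, faces = _cylinder(
                pos, d, float(row.length), max(float(row.diameter) / 2.0, 1e-4), sections
            )
        else:
            u, v = _perpendicular_frame(d)
            verts = np.vstack(
                [pos + MARKER_SIZE * u, pos - MARKER_SIZE * u, pos + MARKER_SIZE * v]
            )
            faces = np.array([[0, 1, 2]])
        all_verts.append(verts)
        all_faces.append(faces + offset)
        offset += len(verts)
    mesh = trimesh.Trimesh(
        vertices=np.vstack(all_verts), faces=np.vstack(all_faces), process=False
    )
    mesh.export(str(path))
    frames.to_csv(path.with_suffix(".csv"), index=False)
    return path
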