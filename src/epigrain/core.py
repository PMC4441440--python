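"""Domain types and global simulation state.

The simulator represents every cell as a set of solid spherical particles
("grains"): internal grains model the cytoplasm (stiff in compression only),
and an ordered ring of peripheral grains linked by tension-only "cable"
elements models the plasma membrane.  All grains are geometrically
constrained to a spherical support (each grain centre sits at support radius
plus its own radius, i.e. grains roll on the outside of the support sphere).

Unit convention
---------------
All parameters are dimensionless *model units* that keep the published
values and their ratios exactly (lengths on a micrometre-like scale, a
five-value grain radius sequence 2.5..3.5, stiffnesses 20 / 13 / 5e-3,
tension band [0.05, 0.30], time step 0.004).  No unit conversion is applied
anywhere; the parameter set is internally consistent as a dimensionless
system.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import yaml

#: Cyclic radius sequence for grains as they are added to a cell.
RADIUS_SEQUENCE: tuple[float, ...] = (2.5, 2.8, 3.0, 3.3, 3.5)

#: Grain (and cable) mass density in model units.
DENSITY: float = 0.9


def grain_mass(radius: float, density: float = DENSITY) -> float:
    """Mass of a solid spherical grain: density x (4/3) pi r^3."""
    return density * (4.0 / 3.0) * np.pi * radius**3


class CellState(str, Enum):
    ARRIVING = "arriving"
    GROWING = "growing"
    MATURE = "mature"
    DIVIDING = "dividing"
    APOPTOTIC = "apoptotic"


class GrainKind(str, Enum):
    INTERNAL = "internal"
    PERIPHERAL = "peripheral"


@dataclass
class SupportSphere:
    """The spherical support every grain is constrained to.

    A grain of radius ``r`` has its centre held at distance ``radius + r``
    from ``center``.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 100.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("support radius must be positive")

    def constraint_radius(self, grain_radius: float) -> float:
        return self.radius + grain_radius


@dataclass
class Grain:
    id: int
    position: np.ndarray
    velocity: np.ndarray
    radius: float
    mass: float
    kind: GrainKind

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


@dataclass
class CableElement:
    """Tension-only elastic link between two consecutive peripheral grains."""

    id: int
    endpoints: tuple[int, int]
    rest_length: float
    thickness: float = 3.0
    tension: float = 0.0


@dataclass
class Cell:
    id: int
    internal_grains: list[int] = field(default_factory=list)
    peripheral_ring: list[int] = field(default_factory=list)
    cables: list[int] = field(default_factory=list)
    state: CellState = CellState.ARRIVING
    birth_stage: int = 0
    adhesions: set[int] = field(default_factory=set)

    @property
    def grain_ids(self) -> list[int]:
        return list(self.internal_grains) + list(self.peripheral_ring)

    @property
    def grain_count(self) -> int:
        return len(self.internal_grains) + len(self.peripheral_ring)


@dataclass
class SimulationConfig:
    """Complete parameter record for one simulation scenario.

    Geometric, mechanical and biological parameters default to the published
    parameter table; loop-control values (organization rate, stage budget,
    coverage sampling) are numerical choices documented in the methods note.
    """

    scenario: str = "accretion"  # "accretion" | "proliferation"
    # --- geometry -----------------------------------------------------
    target_cell_count: int = 60         # mature cells the support is sized for
    support_radius: float | None = None  # derived from target_cell_count if None
    grain_radii: tuple[float, ...] = RADIUS_SEQUENCE
    density: float = DENSITY
    cable_thickness: float = 3.0
    l_min: float = 2.0
    l_max: float = 5.5
    adhesion_distance: float = 13.0
    adhesion_probability: float = 0.5
    adhesion_stiffness: float = 1.0   # cadherin-junction spring (model units)
    mature_grain_count: int = 41
    # --- mechanics ----------------------------------------------------
    e_gg: float = 20.0     # grain/grain compressive stiffness
    c_gg: float = 5.0      # grain/grain Kelvin-Voigt damping
    e_gc: float = 13.0     # grain/cable compressive stiffness
    c_gc: float = 5.0      # grain/cable Kelvin-Voigt damping
    e_c: float = 5e-3      # cable tensile stiffness
    t_min: float = 0.05
    t_max: float = 0.30
    # --- numerics -----------------------------------------------------
    dt: float = 0.004
    organization_rate: int = 500  # integration steps between stages
    growth_period: int = 2  # stages between growth events (growth rate)
    relax_speed_tol: float = 5e-4  # early equilibrium exit (max grain speed)
    global_damping: float = 0.1    # numerical viscosity (1/time) on velocities
    stage_velocity_quench: bool = True  # quasi-static settle between stages
    # --- accretion scenario -------------------------------------------
    max_new_cells_per_stage: int = 2
    accretion_n_seed: int = 15   # cells already contacting the support at t=0
    placement_trials: int = 100
    arrival_size_range: tuple[int, int] = (3, 15)
    cell_limit: int = 60
    # --- proliferation scenario ---------------------------------------
    n_seed: int = 15
    initial_grains: int = 6
    mitotic_fraction: float = 0.07
    apoptosis_mitosis_ratio: float = 1.0 / 3.0
    apoptosis_removal_rate: int = 1
    # --- loop control -------------------------------------------------
    coverage_stop: float = 0.99
    coverage_samples: int = 10000
    max_stages: int = 400
    settle_stages: int = 5  # event-free relaxation after the stop rule
    contact_tolerance: float | None = None  # default 0.5 * min grain radius
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grain_radii = tuple(float(r) for r in self.grain_radii)
        self.arrival_size_range = tuple(int(k) for k in self.arrival_size_range)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.scenario not in ("accretion", "proliferation"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("e_gg", "e_gc", "e_c", "t_min", "t_max", "l_min", "l_max",
                     "dt", "density", "cable_thickness", "adhesion_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.l_min < self.l_max:
            raise ValueError("l_min must be < l_max")
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")
        if not 0.0 <= self.mitotic_fraction <= 1.0:
            raise ValueError("mitotic_fraction must be in [0, 1]")
        if self.apoptosis_mitosis_ratio < 0:
            raise ValueError("apoptosis_mitosis_ratio must be >= 0")
        if any(r <= 0 for r in self.grain_radii):
            raise ValueError("grain radii must be positive")
        if self.organization_rate < 1:
            raise ValueError("organization_rate must be >= 1")

    @property
    def min_grain_radius(self) -> float:
        return min(self.grain_radii)

    @property
    def max_grain_radius(self) -> float:
        return max(self.grain_radii)

    @property
    def effective_contact_tolerance(self) -> float:
        if self.contact_tolerance is not None:
            return self.contact_tolerance
        return 0.5 * self.min_grain_radius

    def radius_for_index(self, index: int) -> float:
        """Radius of the ``index``-th grain added to a cell (cyclic sequence)."""
        return self.grain_radii[index % len(self.grain_radii)]

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grain_radii"] = list(self.grain_radii)
        d["arrival_size_range"] = list(self.arrival_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def preset(name: str, **overrides) -> SimulationConfig:
    """Named scenario presets.

    ``ciona-accretion``       accretion up to 60 cells (ascidian-egg scale);
    ``proliferation-1over3``  7% mitosis, one apoptosis per three mitoses;
    ``proliferation-1over5``  7% mitosis, one apoptosis per five mitoses;
    ``proliferation-noapop``  7% mitosis, no apoptosis.
    """
    # accretion runs quasi-statically (stage quench); proliferation runs
    # in an overdamped-flow regime so the colony front can spread under
    # division pressure
    prolif = dict(scenario="proliferation", target_cell_count=60,
                  stage_velocity_quench=False, global_damping=0.2,
                  settle_stages=8, max_stages=250)
    presets = {
        "ciona-accretion": dict(scenario="accretion", cell_limit=60,
                                target_cell_count=60),
        "proliferation-1over3": dict(apoptosis_mitosis_ratio=1.0 / 3.0,
                                     **prolif),
        "proliferation-1over5": dict(apoptosis_mitosis_ratio=1.0 / 5.0,
                                     **prolif),
        "proliferation-noapop": dict(apoptosis_mitosis_ratio=0.0, **prolif),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


PRESET_NAMES = ("ciona-accretion", "proliferation-1over3",
                "proliferation-1over5", "proliferation-noapop")


@dataclass
class SimulationState:
    """Id-indexed collections of grains, cables and cells plus the support.

    Owns the single seeded random generator used for every stochastic
    choice (placement, adhesion coin flips, event selection).
    """

    support: SupportSphere
    rng: np.random.Generator
    seed: int = 0
    stage: int = 0
    time: float = 0.0
    grains: dict[int, Grain] = field(default_factory=dict)
    cables: dict[int, CableElement] = field(default_factory=dict)
    cells: dict[int, Cell] = field(default_factory=dict)
    #: cadherin junction springs: (cell_a, cell_b) -> (grain_a, grain_b)
    junctions: dict[tuple[int, int], tuple[int, int]] = field(
        default_factory=dict)
    n_arrivals: int = 0
    _next_grain_id: int = 0
    _next_cable_id: int = 0
    _next_cell_id: int = 0

    @classmethod
    def empty(cls, support: SupportSphere, seed: int = 0) -> "SimulationState":
        return cls(support=support, rng=np.random.default_rng(seed), seed=seed)

    # -- id allocation -------------------------------------------------
    def new_grain(self, position, velocity, radius, kind: GrainKind,
                  density: float = DENSITY) -> Grain:
        gid = self._next_grain_id
        self._next_grain_id += 1
        g = Grain(gid, np.asarray(position, float), np.asarray(velocity, float),
                  float(radius), grain_mass(radius, density), kind)
        self.grains[gid] = g
        return g

    def new_cable(self, a: int, b: int, rest_length: float,
                  thickness: float = 3.0, tension: float = 0.0) -> CableElement:
        cid = self._next_cable_id
        self._next_cable_id += 1
        c = CableElement(cid, (a, b), rest_length, thickness, tension)
        self.cables[cid] = c
        return c

    def new_cell(self, **kwargs) -> Cell:
        cid = self._next_cell_id
        self._next_cell_id += 1
        c = Cell(id=cid, **kwargs)
        self.cells[cid] = c
        return c

    # -- geometry helpers ----------------------------------------------
    def grain_positions(self, ids: Iterable[int]) -> np.ndarray:
        return np.array([self.grains[i].position for i in ids], float)

    def cell_barycentre(self, cell: Cell) -> np.ndarray:
        return self.grain_positions(cell.grain_ids).mean(axis=0)

    def cable_length(self, cable: CableElement) -> float:
        a, b = cable.endpoints
        return float(np.linalg.norm(self.grains[a].position -
                                    self.grains[b].position))

    def cable_tension_now(self, cable: CableElement, e_c: float) -> float:
        return max(0.0, e_c * (self.cable_length(cable) - cable.rest_length))

    @property
    def n_grains(self) -> int:
        return len(self.grains)

    # -- snapshot io ----------------------------------------------------
    def to_snapshot(self) -> dict:
        return {
            "format": "epigrain-state-v1",
            "seed": self.seed,
            "stage": self.stage,
            "time": self.time,
            "n_arrivals": self.n_arrivals,
            "support": {"center": self.support.center.tolist(),
                        "radius": self.support.radius},
            "junctions": [[list(k), list(v)]
                          for k, v in sorted(self.junctions.items())],
            "grains": [
                {"id": g.id, "position": g.position.tolist(),
                 "velocity": g.velocity.tolist(), "radius": g.radius,
                 "mass": g.mass, "kind": g.kind.value}
                for g in self.grains.values()
            ],
            "cables": [
                {"id": c.id, "endpoints": list(c.endpoints),
                 "rest_length": c.rest_length, "thickness": c.thickness,
                 "tension": c.tension}
                for c in self.cables.values()
            ],
            "cells": [
                {"id": c.id, "internal_grains": list(c.internal_grains),
                 "peripheral_ring": list(c.peripheral_ring),
                 "cables": list(c.cables), "state": c.state.value,
                 "birth_stage": c.birth_stage,
                 "adhesions": sorted(c.adhesions)}
                for c in self.cells.values()
            ],
        }

    def save_snapshot(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_snapshot(), fh)

    @classmethod
    def from_snapshot(cls, d: dict) -> "SimulationState":
        if d.get("format") != "epigrain-state-v1":
            raise ValueError("not an epigrain state snapshot")
        support = SupportSphere(np.array(d["support"]["center"]),
                                d["support"]["radius"])
        st = cls(support=support, rng=np.random.default_rng(d["seed"]),
                 seed=d["seed"], stage=d["stage"], time=d["time"],
                 n_arrivals=d.get("n_arrivals", 0))
        for g in d["grains"]:
            st.grains[g["id"]] = Grain(g["id"], np.array(g["position"]),
                                       np.array(g["velocity"]), g["radius"],
                                       g["mass"], GrainKind(g["kind"]))
        for c in d["cables"]:
            st.cables[c["id"]] = CableElement(c["id"], tuple(c["endpoints"]),
                                              c["rest_length"], c["thickness"],
                                              c["tension"])
        for c in d["cells"]:
            st.cells[c["id"]] = Cell(c["id"], list(c["internal_grains"]),
                                     list(c["peripheral_ring"]),
                                     list(c["cables"]), CellState(c["state"]),
                                     c["birth_stage"], set(c["adhesions"]))
        for k, v in d.get("junctions", []):
            st.junctions[tuple(k)] = tuple(v)
        st._next_grain_id = max(st.grains, default=-1) + 1
        st._next_cable_id = max(st.cables, default=-1) + 1
        st._next_cell_id = max(st.cells, default=-1) + 1
        return st

    @classmethod
    def load_snapshot(cls, path) -> "SimulationState":
        with open(path) as fh:
            return cls.from_snapshot(json.load(fh))


def derive_support_radius(config: SimulationConfig,
                          calibration_seed: int = 0) -> float:
    """Support radius sized for ``config.target_cell_count`` mature cells
    (see :mod:`epigrain.calibration` for the procedure)."""
    from .calibration import derive_support_radius as _impl
    return _impl(config, calibration_seed)


# ---------------------------------------------------------------------------
# validation

def validate_state(state: SimulationState,
                   config: SimulationConfig | None = None,
                   projection_tol: float = 1e-6) -> list[str]:
    """Check all type invariants; return a list of violations (empty = valid)."""
    cfg = config or SimulationConfig()
    violations: list[str] = []
    allowed = set(cfg.grain_radii)
    center = state.support.center

    owner: dict[int, int] = {}
    for cell in state.cells.values():
        for gid in cell.grain_ids:
            if gid in owner:
                violations.append(
                    f"grain {gid} assigned to cells {owner[gid]} and {cell.id}")
            owner[gid] = cell.id
            if gid not in state.grains:
                violations.append(f"cell {cell.id} references missing grain {gid}")
    for gid in state.grains:
        if gid not in owner:
            violations.append(f"grain {gid} belongs to no cell")

    for g in state.grains.values():
        r_c = state.support.constraint_radius(g.radius)
        dist = np.linalg.norm(g.position - center)
        if abs(dist - r_c) > projection_tol * max(1.0, r_c):
            violations.append(
                f"grain {g.id} off the support: |x|={dist:.6g}, expected {r_c:.6g}")
        if g.radius not in allowed:
            violations.append(f"grain {g.id} radius {g.radius} not in sequence")
        if abs(g.mass - grain_mass(g.radius, cfg.density)) > 1e-9 * g.mass:
            violations.append(f"grain {g.id} mass inconsistent with density")

    for (ca_, cb_), (ga_, gb_) in state.junctions.items():
        if ca_ not in state.cells or cb_ not in state.cells:
            violations.append(f"junction ({ca_},{cb_}) references missing cell")
        if ga_ not in state.grains or gb_ not in state.grains:
            violations.append(f"junction ({ca_},{cb_}) references missing grain")

    for c in state.cables.values():
        if c.tension < 0:
            violations.append(f"cable {c.id} has negative tension {c.tension}")
        for gid in c.endpoints:
            if gid not in state.grains:
                violations.append(f"cable {c.id} references missing grain {gid}")

    for cell in state.cells.values():
        ring, cabs = cell.peripheral_ring, cell.cables
        if len(ring) >= 3:
            if len(cabs) != len(ring):
                violations.append(
                    f"cell {cell.id} ring of {len(ring)} grains has "
                    f"{len(cabs)} cables (expected closed loop)")
            else:
                edges = {frozenset(state.cables[cid].endpoints) for cid in cabs
                         if cid in state.cables}
                expect = {frozenset((ring[k], ring[(k + 1) % len(ring)]))
                          for k in range(len(ring))}
                if edges != expect:
                    violations.append(f"cell {cell.id} cables do not form its ring")
        elif cell.state != CellState.APOPTOTIC:
            violations.append(f"cell {cell.id} ring has fewer than 3 grains")
        n = cell.grain_count
        if cell.state in (CellState.ARRIVING, CellState.GROWING) and \
                n >= cfg.mature_grain_count:
            violations.append(
                f"cell {cell.id} has {n} grains but state {cell.state.value}")
        if cell.state == CellState.MATURE and n < cfg.mature_grain_count - 6:
            violations.append(
                f"cell {cell.id} mature but only {n} grains")
    return violations
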