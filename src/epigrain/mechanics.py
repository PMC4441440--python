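"""Forces and time integration.

Pairwise force laws (grain/grain unilateral contact with Kelvin-Voigt
damping, grain/cable compressive contact, tension-only cables) are exposed
both as simple per-pair functions operating on domain objects, and as
batched numba kernels used by :func:`relax` / :func:`rk4_step` for whole
states.  Both contact laws (grain/grain and grain/cable) carry
Kelvin-Voigt damping on the normal relative velocity; cables are purely
elastic in traction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import (CableElement, Cell, Grain, SimulationConfig,
                   SimulationState)

__all__ = [
    "ForceAccumulator", "ArrayView", "grain_grain_force", "grain_cable_force",
    "cable_tension_force", "regulate_rest_lengths", "total_forces",
    "rk4_step", "project_to_support", "relax", "kinetic_energy",
    "rk4_step_ode",
]


# ---------------------------------------------------------------------------
# pairwise laws on domain objects

def grain_grain_force(a: Grain, b: Grain, e_gg: float, c_gg: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Unilateral linear contact with Kelvin-Voigt damping.

    Returns equal and opposite forces ``(f_a, f_b)``.  The total normal
    force is clamped at zero so the contact is never attractive.
    """
    d = b.position - a.position
    dist = float(np.linalg.norm(d))
    if dist < 1e-12:
        raise ValueError("coincident grain centres: contact normal undefined")
    delta = a.radius + b.radius - dist
    if delta <= 0:
        return np.zeros(3), np.zeros(3)
    n = d / dist
    approach = float(np.dot(a.velocity - b.velocity, n))
    mag = max(0.0, e_gg * delta + c_gg * approach)
    return -mag * n, mag * n


def grain_cable_force(g: Grain, cable: CableElement, state: SimulationState,
                      e_gc: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compressive grain-against-cable contact.

    The cable is a thick segment (diameter ``cable.thickness``); penetration
    of the grain sphere into it produces a repulsive force ``e_gc x
    penetration`` normal to the segment, with the reaction distributed to
    the endpoint grains by barycentric weights.  Returns
    ``(f_grain, f_endpoint_a, f_endpoint_b)``.
    """
    a, b = (state.grains[i] for i in cable.endpoints)
    seg = b.position - a.position
    L2 = float(np.dot(seg, seg))
    if L2 < 1e-12:
        raise ValueError(f"degenerate cable {cable.id}: coincident endpoints")
    t = float(np.clip(np.dot(g.position - a.position, seg) / L2, 0.0, 1.0))
    closest = a.position + t * seg
    d = g.position - closest
    dist = float(np.linalg.norm(d))
    pen = g.radius + 0.5 * cable.thickness - dist
    if pen <= 0 or dist < 1e-12:
        return np.zeros(3), np.zeros(3), np.zeros(3)
    n = d / dist
    f = e_gc * pen * n
    return f, -(1.0 - t) * f, -t * f


def cable_tension_force(cable: CableElement, state: SimulationState,
                        e_c: float) -> tuple[np.ndarray, np.ndarray]:
    """Tension-only cable elasticity; records the tension on the cable.

    Returns forces on the two endpoint grains, pulling them together when
    the cable is elongated beyond its rest length, zero otherwise.
    """
    a, b = (state.grains[i] for i in cable.endpoints)
    d = b.position - a.position
    length = float(np.linalg.norm(d))
    if length < 1e-12:
        raise ValueError(f"degenerate cable {cable.id}: coincident endpoints")
    e = length - cable.rest_length
    if e <= 0:
        cable.tension = 0.0
        return np.zeros(3), np.zeros(3)
    T = e_c * e
    cable.tension = T
    n = d / length
    return T * n, -T * n


def regulate_rest_lengths(cell: Cell, state: SimulationState,
                          config: SimulationConfig) -> Cell:
    """Adjust cable rest lengths so every tension lies in [Tmin, Tmax].

    Rest lengths grow as the cell grows, keeping membrane tension
    quasi-constant.  Out-of-band cables are re-solved directly at the
    violated band edge (``rest = L - T_edge / Ec``); in-band cables are
    untouched, so the operation is idempotent at fixed geometry.
    """
    from .core import CellState
    if cell.state == CellState.APOPTOTIC:
        raise ValueError("rest lengths of apoptotic cells are not regulated")
    for cid in cell.cables:
        cable = state.cables[cid]
        L = state.cable_length(cable)
        T = max(0.0, config.e_c * (L - cable.rest_length))
        if T > config.t_max:
            cable.rest_length = L - config.t_max / config.e_c
            T = config.t_max
        elif T < config.t_min:
            cable.rest_length = L - config.t_min / config.e_c
            T = config.t_min
        cable.tension = T
    return cell


# ---------------------------------------------------------------------------
# array view of a state

@dataclass
class ArrayView:
    """Flat-array mirror of a state for the numba kernels."""

    grain_ids: list[int]
    cable_ids: list[int]
    pos: np.ndarray
    vel: np.ndarray
    rad: np.ndarray
    mass: np.ndarray
    shellr: np.ndarray
    cellid: np.ndarray
    peri: np.ndarray
    ca: np.ndarray
    cb: np.ndarray
    crest: np.ndarray
    ccell: np.ndarray
    tension: np.ndarray
    ja: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    jb: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    jrest: np.ndarray = field(default_factory=lambda: np.empty(0))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def from_state(cls, state: SimulationState) -> "ArrayView":
        from .core import GrainKind
        gids = sorted(state.grains)
        gidx = {g: i for i, g in enumerate(gids)}
        n = len(gids)
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        rad = np.empty(n)
        mass = np.empty(n)
        peri = np.zeros(n, np.uint8)
        center = state.support.center
        for i, gid in enumerate(gids):
            g = state.grains[gid]
            pos[i] = g.position - center
            vel[i] = g.velocity
            rad[i] = g.radius
            mass[i] = g.mass
            peri[i] = 1 if g.kind == GrainKind.PERIPHERAL else 0
        shellr = state.support.radius + rad
        cellid = np.full(n, -1, np.int64)
        cable_owner: dict[int, int] = {}
        for cell in state.cells.values():
            for gid in cell.grain_ids:
                cellid[gidx[gid]] = cell.id
            for cid in cell.cables:
                cable_owner[cid] = cell.id
        cids = sorted(state.cables)
        m = len(cids)
        ca = np.empty(m, np.int64)
        cb = np.empty(m, np.int64)
        crest = np.empty(m)
        ccell = np.empty(m, np.int64)
        for k, cid in enumerate(cids):
            c = state.cables[cid]
            ca[k] = gidx[c.endpoints[0]]
            cb[k] = gidx[c.endpoints[1]]
            crest[k] = c.rest_length
            ccell[k] = cable_owner.get(cid, -1)
        jpairs = [(gidx[ga], gidx[gb]) for (ga, gb) in
                  state.junctions.values()
                  if ga in gidx and gb in gidx]
        ja = np.array([p[0] for p in jpairs], np.int64)
        jb = np.array([p[1] for p in jpairs], np.int64)
        jrest = np.array([rad[a] + rad[b] for a, b in jpairs])
        return cls(gids, cids, pos, vel, rad, mass, shellr, cellid, peri,
                   ca, cb, crest, ccell, np.zeros(m), ja, jb, jrest,
                   center.copy())

    def writeback(self, state: SimulationState) -> None:
        for i, gid in enumerate(self.grain_ids):
            g = state.grains[gid]
            g.position = self.pos[i] + self.center
            g.velocity = self.vel[i].copy()
        for k, cid in enumerate(self.cable_ids):
            state.cables[cid].tension = float(self.tension[k])


@dataclass
class ForceAccumulator:
    """Per-grain force table (model force units)."""

    forces: dict[int, np.ndarray]

    def net(self) -> np.ndarray:
        if not self.forces:
            return np.zeros(3)
        return np.sum(list(self.forces.values()), axis=0)

    def max_norm(self) -> float:
        if not self.forces:
            return 0.0
        return max(float(np.linalg.norm(f)) for f in self.forces.values())


def total_forces(state: SimulationState, config: SimulationConfig
                 ) -> ForceAccumulator:
    """Sum all force contributions per grain (pre-constraint-projection).

    Covers intra-cell grain/grain contacts, internal-grain-vs-own-membrane
    and peripheral-vs-foreign-cable contacts, cable tensions, and
    inter-cell peripheral contacts.  Cable tensions are recorded on the
    cable elements.
    """
    view = ArrayView.from_state(state)
    n = len(view.grain_ids)
    F = np.zeros((n, 3))
    if n:
        nb1, nb2 = bonded_neighbors(view)
        pi, pj = _kernels.build_pairs(view.pos, view.rad, view.cellid,
                                      view.peri, nb1, nb2, 0.5)
        gg, gk = _kernels.build_gc_pairs(view.pos, view.rad, view.cellid,
                                         view.peri, view.ca, view.cb,
                                         view.ccell,
                                         state_thickness(state), 0.5)
        _kernels.compute_forces(view.pos, view.vel, view.rad, pi, pj, gg, gk,
                                view.ca, view.cb, view.crest,
                                view.ja, view.jb, view.jrest,
                                config.adhesion_stiffness, config.t_max,
                                config.e_gg, config.c_gg, config.e_gc,
                                config.c_gc, config.e_c,
                                state_thickness(state), F, view.tension)
        for k, cid in enumerate(view.cable_ids):
            state.cables[cid].tension = float(view.tension[k])
    return ForceAccumulator({gid: F[i].copy()
                             for i, gid in enumerate(view.grain_ids)})


def bonded_neighbors(view: "ArrayView") -> tuple[np.ndarray, np.ndarray]:
    """Per-grain ring-neighbour (cable endpoint) table for the bonded
    contact exclusion."""
    n = len(view.grain_ids)
    nb1 = np.full(n, -1, np.int64)
    nb2 = np.full(n, -1, np.int64)
    for a, b in zip(view.ca, view.cb):
        if nb1[a] == -1:
            nb1[a] = b
        else:
            nb2[a] = b
        if nb1[b] == -1:
            nb1[b] = a
        else:
            nb2[b] = a
    return nb1, nb2


def state_thickness(state: SimulationState) -> float:
    for c in state.cables.values():
        return c.thickness
    return 3.0


# ---------------------------------------------------------------------------
# integration

def rk4_step(state: SimulationState, dt: float,
             config: SimulationConfig) -> SimulationState:
    """Advance one RK4 step of the second-order system x'' = F/m, then
    apply the spherical constraint.  Mutates and returns ``state``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    acc = total_forces(state, config)
    for gid, f in acc.forces.items():
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"non-finite force on grain {gid}")
    view = ArrayView.from_state(state)
    _kernels.rk4_relax(view.pos, view.vel, view.rad, view.mass, view.shellr,
                       view.cellid, view.peri, view.ca, view.cb, view.crest,
                       view.ccell, view.ja, view.jb, view.jrest,
                       config.adhesion_stiffness, config.t_max,
                       config.e_gg, config.c_gg, config.e_gc,
                       config.c_gc, config.e_c, state_thickness(state),
                       config.global_damping, dt,
                       1, 1, 1.0, 0.0, view.tension)
    view.writeback(state)
    state.time += dt
    return state


def relax(state: SimulationState, config: SimulationConfig,
          n_steps: int | None = None, speed_tol: float | None = None,
          rebuild_every: int = 20) -> int:
    """Run a relaxation block of up to ``n_steps`` RK4 steps (default: one
    organization-rate block).  Stops early at mechanical equilibrium (max
    grain speed below ``speed_tol``).  Returns the number of steps taken."""
    if n_steps is None:
        n_steps = config.organization_rate
    if speed_tol is None:
        speed_tol = config.relax_speed_tol
    if not state.grains:
        return 0
    view = ArrayView.from_state(state)
    steps = _kernels.rk4_relax(
        view.pos, view.vel, view.rad, view.mass, view.shellr,
        view.cellid, view.peri, view.ca, view.cb, view.crest, view.ccell,
        view.ja, view.jb, view.jrest, config.adhesion_stiffness,
        config.t_max,
        config.e_gg, config.c_gg, config.e_gc, config.c_gc,
        config.e_c, state_thickness(state), config.global_damping,
        config.dt, n_steps, rebuild_every, 1.0, speed_tol, view.tension)
    view.writeback(state)
    state.time += steps * config.dt
    return int(steps)


def project_to_support(state: SimulationState) -> SimulationState:
    """Radially project every grain to its constraint radius and remove the
    radial velocity component.  Idempotent."""
    center = state.support.center
    for g in state.grains.values():
        rel = g.position - center
        r = float(np.linalg.norm(rel))
        if r < 1e-12:
            raise ValueError(f"grain {g.id} at the support centre")
        shell = state.support.constraint_radius(g.radius)
        u = rel / r
        g.position = center + shell * u
        g.velocity = g.velocity - float(np.dot(g.velocity, u)) * u
    return state


def kinetic_energy(state: SimulationState) -> float:
    return 0.5 * sum(g.mass * float(np.dot(g.velocity, g.velocity))
                     for g in state.grains.values())


# ---------------------------------------------------------------------------
# generic RK4 (used by convergence / geodesic test harnesses)

def rk4_step_ode(f, t: float, y: np.ndarray, dt: float) -> np.ndarray:
    """One classic RK4 step for dy/dt = f(t, y) on a flat array."""
    k1 = f(t, y)
    k2 = f(t + dt / 2, y + dt / 2 * k1)
    k3 = f(t + dt / 2, y + dt / 2 * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
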