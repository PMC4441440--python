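"""Stage-level biology and the full simulation loop.

A simulation alternates blocks of mechanical relaxation (``organization
rate`` RK4 steps) with discrete *stages* at which biological events occur:
all immature cells add one internal grain; in the accretion scenario up to
two new cells arrive at random collision-free positions; in the
proliferation scenario mature cells are selected for mitosis (a fixed
fraction) or apoptosis (a fixed ratio to mitoses); membranes are remodeled
(cables split above Lmax, removed below Lmin), cadherin-like adhesions are
created, and cable rest lengths are re-regulated into the tension band.
The loop stops once the cell footprints cover 99% of the support surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (CableElement, Cell, CellState, Grain, GrainKind,
                   SimulationConfig, SimulationState, SupportSphere,
                   derive_support_radius)
from .mechanics import regulate_rest_lengths, relax
from .topology import ShapeCensus, census_from_state, coverage_fraction

__all__ = [
    "StageEventLog", "SimulationResult", "build_cell", "grow_cell",
    "remodel_cables", "create_adhesions", "attempt_accretion",
    "spawn_proliferative_seed", "select_events", "divide_cell",
    "apoptose_step", "run_simulation", "arrival_grain_count",
    "event_log_to_csv",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class StageEventLog:
    stage: int
    arrivals: list[int] = field(default_factory=list)
    growth: list[tuple[int, float]] = field(default_factory=list)
    divisions: list[tuple[int, int, int]] = field(default_factory=list)
    apoptoses_started: list[int] = field(default_factory=list)
    cells_deleted: list[int] = field(default_factory=list)
    adhesions_created: list[tuple[int, int]] = field(default_factory=list)
    arrival_grains: int = 0
    closure_grains: int = 0
    cable_splits: int = 0
    cable_merges: int = 0
    apoptotic_grains_removed: int = 0
    coverage: float = 0.0
    n_cells: int = 0
    n_grains: int = 0

    def grain_delta(self) -> int:
        """Net grain-count change implied by the logged events."""
        return (len(self.growth) + self.arrival_grains + self.closure_grains
                + self.cable_splits - self.cable_merges
                - self.apoptotic_grains_removed)


@dataclass
class SimulationResult:
    state: SimulationState
    config: SimulationConfig
    event_log: list[StageEventLog]
    census: ShapeCensus
    coverage: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.state.cells)

    def hexagon_frequency(self) -> float:
        return self.census.frequencies().get(6, 0.0)


# ---------------------------------------------------------------------------
# geometry helpers

def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(u, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _project_point(state: SimulationState, p: np.ndarray,
                   grain_radius: float) -> np.ndarray:
    rel = p - state.support.center
    r = np.linalg.norm(rel)
    shell = state.support.constraint_radius(grain_radius)
    return state.support.center + rel * (shell / r)


def _mid_band_rest(length: float, config: SimulationConfig) -> float:
    t_mid = 0.5 * (config.t_min + config.t_max)
    return length - t_mid / config.e_c


def _template_layout(config: SimulationConfig, k: int
                     ) -> tuple[list[tuple[float, float, float]],
                                list[tuple[float, float, float]], float]:
    """In-plane (x, y, radius) layout for a fresh ``k``-grain cell:
    internal grains on a sunflower disk inside a peripheral ring."""
    radii = [config.radius_for_index(i) for i in range(k)]
    rbar = float(np.mean(config.grain_radii))
    c = 1.05 * rbar
    # arriving cells wedge into gaps as tightly as the cable band allows
    # and expand afterwards; ring spacing starts just above Lmin
    target_cable = 1.2 * config.l_min

    # choose the ring size whose cable length is closest to mid-band for a
    # ring snugly enclosing the remaining (internal) grains
    best_m, best_err = min(3, k), np.inf
    for m in range(3, k + 1):
        n_int = k - m
        rho_int = c * math.sqrt(n_int) if n_int else 0.0
        rho = max(rho_int + 1.7 * rbar,
                  target_cable * m / (2.0 * math.pi))
        cable = 2.0 * rho * math.sin(math.pi / m)
        err = abs(cable - target_cable)
        if err < best_err:
            best_m, best_err = m, err
    m_ring = best_m
    n_int = k - m_ring
    int_radii = radii[m_ring:]
    internal = []
    for i, r in enumerate(int_radii):
        rho = c * math.sqrt(i + 0.5)
        th = i * _GOLDEN_ANGLE
        internal.append((rho * math.cos(th), rho * math.sin(th), r))
    rho_int = c * math.sqrt(n_int) if n_int else 0.0
    rho_ring = max(rho_int + 1.7 * rbar,
                   target_cable * m_ring / (2.0 * math.pi))
    ring = []
    for i, r in enumerate(radii[:m_ring]):
        th = 2.0 * math.pi * i / m_ring
        ring.append((rho_ring * math.cos(th), rho_ring * math.sin(th), r))
    return ring, internal, rho_ring


def template_clearance(config: SimulationConfig, k: int) -> float:
    """Footprint radius a fresh k-grain cell needs at placement."""
    _, _, rho_ring = _template_layout(config, k)
    return rho_ring + config.max_grain_radius


def build_cell(state: SimulationState, config: SimulationConfig,
               center_dir: np.ndarray, k: int,
               cell_state: CellState = CellState.ARRIVING) -> Cell:
    """Instantiate a fresh ``k``-grain cell centred on ``center_dir``."""
    if k < 3:
        raise ValueError("a cell needs at least 3 grains (closed ring)")
    u = np.asarray(center_dir, float)
    u = u / np.linalg.norm(u)
    e1, e2 = _tangent_basis(u)
    R = state.support.radius
    ring_xy, int_xy, _ = _template_layout(config, k)

    def place(x, y, r):
        p = state.support.center + R * u + x * e1 + y * e2
        return _project_point(state, p, r)

    ring_ids = []
    for (x, y, r) in ring_xy:
        g = state.new_grain(place(x, y, r), np.zeros(3), r,
                            GrainKind.PERIPHERAL, config.density)
        ring_ids.append(g.id)
    int_ids = []
    for (x, y, r) in int_xy:
        g = state.new_grain(place(x, y, r), np.zeros(3), r,
                            GrainKind.INTERNAL, config.density)
        int_ids.append(g.id)

    cell = state.new_cell(internal_grains=int_ids, peripheral_ring=ring_ids,
                          cables=[], state=cell_state,
                          birth_stage=state.stage)
    n = len(ring_ids)
    for i in range(n):
        a, b = ring_ids[i], ring_ids[(i + 1) % n]
        L = float(np.linalg.norm(state.grains[a].position -
                                 state.grains[b].position))
        cab = state.new_cable(a, b, _mid_band_rest(L, config),
                              config.cable_thickness)
        cell.cables.append(cab.id)
    return cell


# ---------------------------------------------------------------------------
# growth

def grow_cell(cell: Cell, state: SimulationState, config: SimulationConfig,
              log: StageEventLog | None = None) -> SimulationState:
    """Add one internal grain near the cell barycentre; radius follows the
    cyclic sequence indexed by the current grain count.  Flags the cell
    mature exactly when the count reaches the mature size."""
    if cell.state not in (CellState.ARRIVING, CellState.GROWING):
        raise ValueError(f"cannot grow cell {cell.id} in state "
                         f"{cell.state.value}")
    count = cell.grain_count
    if count >= config.mature_grain_count:
        raise ValueError(f"cell {cell.id} already at mature size")
    radius = config.radius_for_index(count)
    bary = state.cell_barycentre(cell)
    u = bary - state.support.center
    u /= np.linalg.norm(u)
    e1, e2 = _tangent_basis(u)
    rbar = float(np.mean(config.grain_radii))
    # choose the least-crowded of a few jittered candidates near the
    # barycentre to limit the energy injected by growth
    others = state.grain_positions(cell.grain_ids)
    best_pos, best_gap = None, -np.inf
    for _ in range(6):
        dx, dy = state.rng.uniform(-0.9 * rbar, 0.9 * rbar, size=2)
        p = _project_point(state, bary + dx * e1 + dy * e2, radius)
        gap = float(np.min(np.linalg.norm(others - p, axis=1)))
        if gap > best_gap:
            best_gap, best_pos = gap, p
    g = state.new_grain(best_pos, np.zeros(3), radius, GrainKind.INTERNAL,
                        config.density)
    cell.internal_grains.append(g.id)
    if cell.state == CellState.ARRIVING:
        cell.state = CellState.GROWING
    if cell.grain_count >= config.mature_grain_count:
        cell.state = CellState.MATURE
    if log is not None:
        log.growth.append((cell.id, radius))
    return state


# ---------------------------------------------------------------------------
# membrane remodeling

def _rotate_ring(cell: Cell, k: int) -> None:
    cell.peripheral_ring = cell.peripheral_ring[k:] + cell.peripheral_ring[:k]
    cell.cables = cell.cables[k:] + cell.cables[:k]


def remodel_cables(cell: Cell, state: SimulationState,
                   config: SimulationConfig, log: StageEventLog | None = None,
                   allow_small: bool = False,
                   allow_split: bool = True) -> Cell:
    """Split cables longer than Lmax (inserting a midpoint grain), remove
    cables shorter than Lmin (merging the endpoints); the ring stays a
    single closed loop throughout.  Idempotent when all lengths lie in
    [Lmin, Lmax]."""
    for _ in range(200):
        ring = cell.peripheral_ring
        n = len(ring)
        if n < 3:
            break
        lengths = [float(np.linalg.norm(
            state.grains[ring[i]].position -
            state.grains[ring[(i + 1) % n]].position)) for i in range(n)]
        split_k = next((i for i, L in enumerate(lengths)
                        if L > config.l_max), None) if allow_split else None
        if split_k is not None:
            _rotate_ring(cell, split_k)
            a, b = cell.peripheral_ring[0], cell.peripheral_ring[1]
            old = state.cables[cell.cables[0]]
            T = state.cable_tension_now(old, config.e_c)
            r_new = config.radius_for_index(cell.grain_count)
            mid = 0.5 * (state.grains[a].position + state.grains[b].position)
            pos = _project_point(state, mid, r_new)
            vel = 0.5 * (state.grains[a].velocity + state.grains[b].velocity)
            g = state.new_grain(pos, vel, r_new, GrainKind.PERIPHERAL,
                                config.density)
            del state.cables[old.id]
            L1 = float(np.linalg.norm(state.grains[a].position - pos))
            L2 = float(np.linalg.norm(pos - state.grains[b].position))
            c1 = state.new_cable(a, g.id, L1 - T / config.e_c,
                                 config.cable_thickness, T)
            c2 = state.new_cable(g.id, b, L2 - T / config.e_c,
                                 config.cable_thickness, T)
            cell.peripheral_ring.insert(1, g.id)
            cell.cables[0:1] = [c1.id, c2.id]
            if log is not None:
                log.cable_splits += 1
            continue
        merge_k = next((i for i, L in enumerate(lengths)
                        if L < config.l_min), None)
        if merge_k is not None:
            if n <= 3:
                if allow_small:
                    break
                raise ValueError(f"remodeling cell {cell.id} would leave "
                                 "fewer than 3 peripheral grains")
            _rotate_ring(cell, merge_k)
            a, b, c = (cell.peripheral_ring[i] for i in range(3))
            cab_ab = state.cables[cell.cables[0]]
            cab_bc = state.cables[cell.cables[1]]
            T = state.cable_tension_now(cab_bc, config.e_c)
            mid = 0.5 * (state.grains[a].position + state.grains[b].position)
            ga = state.grains[a]
            ga.position = _project_point(state, mid, ga.radius)
            del state.cables[cab_ab.id]
            del state.cables[cab_bc.id]
            del state.grains[b]
            _replace_junction_grain(state, b, a)
            L = float(np.linalg.norm(ga.position - state.grains[c].position))
            c_new = state.new_cable(a, c, L - T / config.e_c,
                                    config.cable_thickness, T)
            del cell.peripheral_ring[1]
            cell.cables = [c_new.id] + cell.cables[2:]
            if log is not None:
                log.cable_merges += 1
            continue
        break
    return cell


def _replace_junction_grain(state: SimulationState, old: int,
                            new: int) -> None:
    for key, (ga, gb) in list(state.junctions.items()):
        if ga == old:
            state.junctions[key] = (new, gb)
        elif gb == old:
            state.junctions[key] = (ga, new)


def _drop_cell_junctions(state: SimulationState, cell_id: int) -> None:
    for key in [k for k in state.junctions if cell_id in k]:
        del state.junctions[key]


# ---------------------------------------------------------------------------
# adhesion

def _min_segment_distance(A1, A2, B1, B2) -> float:
    """Minimum distance between two families of segments (broadcast all
    pairs).  Classic clamped closest-point computation."""
    d1 = (A2 - A1)[:, None, :]
    d2 = (B2 - B1)[None, :, :]
    r = A1[:, None, :] - B1[None, :, :]
    a = np.einsum("ijk,ijk->ij", d1, d1)
    e = np.einsum("ijk,ijk->ij", d2, d2)
    f = np.einsum("ijk,ijk->ij", d2, r)
    c = np.einsum("ijk,ijk->ij", d1, r)
    b = np.einsum("ijk,ijk->ij", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, (b * f - c * e) / np.where(denom > 1e-12,
                                                           denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    s = np.where(a > 1e-12, (b * t - c) / np.where(a > 1e-12, a, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    closest1 = A1[:, None, :] + s[..., None] * d1
    closest2 = B1[None, :, :] + t[..., None] * d2
    return float(np.min(np.linalg.norm(closest1 - closest2, axis=2)))


def _corridor_blocked(state: SimulationState, a: int, b: int,
                      pa: np.ndarray, pb: np.ndarray) -> bool:
    """True if any third cell's peripheral grain overlaps the open
    corridor between prospective junction anchor points."""
    seg = pb - pa
    L2 = float(np.dot(seg, seg))
    if L2 < 1e-12:
        return False
    mid = 0.5 * (pa + pb)
    reach = 0.5 * np.sqrt(L2) + 8.0
    for cid in state.cells:
        if cid == a or cid == b:
            continue
        ring = state.cells[cid].peripheral_ring
        if not ring:
            continue
        P = state.grain_positions(ring)
        if np.min(np.linalg.norm(P - mid, axis=1)) > reach:
            continue
        Rg = np.array([state.grains[g].radius for g in ring])
        t = np.clip((P - pa) @ seg / L2, 0.0, 1.0)
        d = np.linalg.norm(P - (pa + t[:, None] * seg), axis=1)
        if np.any(d < Rg):
            return True
    return False


def create_adhesions(state: SimulationState, config: SimulationConfig,
                     log: StageEventLog | None = None) -> SimulationState:
    """Create permanent cadherin-like adhesion partnerships.

    Every unadhered cell pair whose membranes (cable segments) come within
    the adhesion distance is a candidate; each candidate is realised with
    probability one half.  Existing partnerships are never removed.
    """
    segs = {}
    bary = {}
    bound = {}
    for cid in sorted(state.cells):
        cell = state.cells[cid]
        ring = cell.peripheral_ring
        if len(ring) < 2:
            continue
        P = state.grain_positions(ring)
        segs[cid] = (P, np.roll(P, -1, axis=0))
        bary[cid] = P.mean(axis=0)
        bound[cid] = float(np.max(np.linalg.norm(P - bary[cid], axis=1)))
    ids = sorted(segs)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if b in state.cells[a].adhesions:
                continue
            if (np.linalg.norm(bary[a] - bary[b]) >
                    bound[a] + bound[b] + config.adhesion_distance):
                continue
            dmin = _min_segment_distance(segs[a][0], segs[a][1],
                                         segs[b][0], segs[b][1])
            if dmin < config.adhesion_distance:
                if state.rng.random() < config.adhesion_probability:
                    Pa, Pb = segs[a][0], segs[b][0]
                    D = np.linalg.norm(Pa[:, None, :] - Pb[None, :, :],
                                       axis=2)
                    ia, ib = np.unravel_index(np.argmin(D), D.shape)
                    pa, pb = Pa[ia], Pb[ib]
                    # junctions form only across open intercellular space:
                    # a third cell's membrane between the anchor points
                    # blocks the contact
                    if _corridor_blocked(state, a, b, pa, pb):
                        continue
                    state.cells[a].adhesions.add(b)
                    state.cells[b].adhesions.add(a)
                    # permanent cadherin junction: spring anchored at the
                    # closest peripheral grain pair
                    ga = state.cells[a].peripheral_ring[ia]
                    gb = state.cells[b].peripheral_ring[ib]
                    state.junctions[(a, b)] = (ga, gb)
                    if log is not None:
                        log.adhesions_created.append((a, b))
    return state


# ---------------------------------------------------------------------------
# accretion

def arrival_grain_count(config: SimulationConfig, arrival_index: int) -> int:
    """Initial grain count of the ``arrival_index``-th arriving cell:
    linear from the small end of the range (first arrival) to the large end
    (arrival at the cell limit) — the later the cell arrives, the bigger
    it is."""
    k_lo, k_hi = config.arrival_size_range
    if config.cell_limit <= 1:
        return k_hi
    frac = (arrival_index - 1) / (config.cell_limit - 1)
    return int(round(k_lo + (k_hi - k_lo) * min(1.0, frac)))


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _placement_gap(state: SimulationState, u: np.ndarray) -> float:
    """Clearance from a support point to the nearest grain surface."""
    if not state.grains:
        return np.inf
    c0 = state.support.center + state.support.radius * u
    ids = sorted(state.grains)
    pos = state.grain_positions(ids)
    rad = np.array([state.grains[g].radius for g in ids])
    return float(np.min(np.linalg.norm(pos - c0, axis=1) - rad))


def _placement_is_free(state: SimulationState, u: np.ndarray,
                       clearance: float, margin: float = 0.0) -> bool:
    return _placement_gap(state, u) > clearance + margin


def _best_placement(state: SimulationState, config: SimulationConfig,
                    clearance: float) -> np.ndarray | None:
    """Test ``placement_trials`` random support positions; among the
    collision-free ones return the best spread: the candidate farthest
    from existing cell barycentres (planning the eventual equal-area
    tiling), with the grain-surface clearance as the feasibility test."""
    ids = sorted(state.cells)
    if ids:
        B = np.array([state.cell_barycentre(state.cells[c]) for c in ids])
    best_u, best_score = None, -np.inf
    R = state.support.radius
    for _ in range(config.placement_trials):
        u = _random_direction(state.rng)
        if _placement_gap(state, u) <= clearance:
            continue
        if ids:
            c0 = state.support.center + R * u
            score = float(np.min(np.linalg.norm(B - c0, axis=1)))
        else:
            score = 1.0
        if score > best_score:
            best_u, best_score = u, score
    return best_u


def attempt_accretion(state: SimulationState, config: SimulationConfig,
                      log: StageEventLog | None = None) -> SimulationState:
    """Place up to the per-stage maximum of new cells at random
    collision-free support positions (up to ``placement_trials`` trials
    each); failure to place is a logged non-event."""
    if config.scenario != "accretion":
        raise ValueError("attempt_accretion requires the accretion scenario")
    placed = 0
    while placed < config.max_new_cells_per_stage and \
            len(state.cells) < config.cell_limit:
        idx = state.n_arrivals + 1
        k = arrival_grain_count(config, idx)
        clearance = template_clearance(config, k)
        pos_found = _best_placement(state, config, clearance)
        if pos_found is None:
            break
        cell = build_cell(state, config, pos_found, k, CellState.ARRIVING)
        state.n_arrivals += 1
        placed += 1
        if log is not None:
            log.arrivals.append(cell.id)
            log.arrival_grains += cell.grain_count
    return state


def spawn_proliferative_seed(state: SimulationState,
                             config: SimulationConfig) -> SimulationState:
    """Seed the proliferation scenario: ``n_seed`` small cells at random
    collision-free positions on an empty support."""
    if config.scenario != "proliferation":
        raise ValueError("seeding requires the proliferation scenario")
    if state.cells:
        raise ValueError("proliferative seeding requires an empty state")
    clearance = template_clearance(config, config.initial_grains)
    trials_left = 100 * config.n_seed
    for _ in range(config.n_seed):
        while True:
            if trials_left == 0:
                raise RuntimeError(
                    f"could not place {config.n_seed} non-overlapping seed "
                    f"cells in 100 x n_seed trials")
            trials_left -= 1
            u = _random_direction(state.rng)
            if _placement_is_free(state, u, clearance):
                break
        build_cell(state, config, u, config.initial_grains, CellState.GROWING)
    return state


# ---------------------------------------------------------------------------
# proliferation events

def select_events(state: SimulationState, config: SimulationConfig
                  ) -> tuple[set[int], set[int]]:
    """Draw this stage's mitosis and apoptosis sets from the mature cells:
    ``round(mitotic_fraction x n_mature)`` mitoses, then
    ``round(ratio x n_mitoses)`` further (disjoint) apoptoses."""
    if config.scenario != "proliferation":
        raise ValueError("event selection requires the proliferation scenario")
    mature = sorted(cid for cid, c in state.cells.items()
                    if c.state == CellState.MATURE
                    and len(c.peripheral_ring) >= 6)
    n_mit = int(round(config.mitotic_fraction * len(mature)))
    if n_mit == 0:
        return set(), set()
    mit = set(state.rng.choice(mature, size=n_mit, replace=False).tolist())
    remaining = sorted(set(mature) - mit)
    n_apo = min(int(round(config.apoptosis_mitosis_ratio * n_mit)),
                len(remaining))
    apo = set(state.rng.choice(remaining, size=n_apo,
                               replace=False).tolist()) if n_apo else set()
    return mit, apo


def _closure_chain(state: SimulationState, config: SimulationConfig,
                   p_from: np.ndarray, p_to: np.ndarray,
                   offset: np.ndarray, count_start: int,
                   min_new: int = 0) -> tuple[list[int], int]:
    """New peripheral grains along the division chord, offset to one side."""
    span = float(np.linalg.norm(p_to - p_from))
    n_new = max(min_new, int(math.ceil(span / 4.0)) - 1)
    ids = []
    counter = count_start
    for s in range(1, n_new + 1):
        t = s / (n_new + 1)
        r = config.radius_for_index(counter)
        counter += 1
        p = _project_point(state, p_from + t * (p_to - p_from) + offset, r)
        g = state.new_grain(p, np.zeros(3), r, GrainKind.PERIPHERAL,
                            config.density)
        ids.append(g.id)
    return ids, counter


def divide_cell(cell: Cell, state: SimulationState, config: SimulationConfig,
                log: StageEventLog | None = None) -> SimulationState:
    """Split a mature cell into two daughters along its shortest diameter.

    The division axis is the chord between the two peripheral grains whose
    connecting path through the barycentre is shortest (a contractile
    filament through the cell centre).  Internal grains are partitioned by
    side of the axis plane with counts balanced so the daughters differ by
    at most two grains; each daughter ring is closed along the chord with
    new peripheral grains (logged as closure grains)."""
    if cell.state != CellState.MATURE:
        raise ValueError(f"cell {cell.id} is not mature, cannot divide")
    ring = list(cell.peripheral_ring)
    n = len(ring)
    if n < 6:
        raise ValueError(f"cell {cell.id} ring too small to divide")
    P = state.grain_positions(ring)
    bary = state.cell_barycentre(cell)
    u_b = bary - state.support.center
    u_b /= np.linalg.norm(u_b)

    # shortest diameter through the barycentre
    best, besti, bestj = np.inf, 0, n // 2
    min_sep = max(2, n // 3)
    for i in range(n):
        for j in range(i + 1, n):
            sep = min(j - i, n - (j - i))
            if sep < min_sep:
                continue
            chord = float(np.linalg.norm(P[i] - P[j]))
            d = P[j] - P[i]
            L2 = float(np.dot(d, d))
            t = np.clip(np.dot(bary - P[i], d) / L2, 0.0, 1.0)
            dseg = float(np.linalg.norm(bary - (P[i] + t * d)))
            score = chord + 4.0 * dseg
            if score < best:
                best, besti, bestj = score, i, j
    i, j = besti, bestj
    axis = P[j] - P[i]
    normal = np.cross(axis, u_b)
    normal /= np.linalg.norm(normal)

    arc1 = ring[i:j]          # contains ring[i]
    arc2 = ring[j:] + ring[:i]  # contains ring[j]
    side1 = float(np.mean([np.dot(state.grains[g].position - bary, normal)
                           for g in arc1]))
    if side1 < 0:
        normal = -normal

    internal = sorted(cell.internal_grains)
    n_int = len(internal)
    svals = np.array([np.dot(state.grains[g].position - bary, normal)
                      for g in internal])
    order = np.argsort(-svals)  # most positive (daughter-1 side) first
    a_take = int(round((n_int + len(arc2) - len(arc1)) / 2.0))
    a_take = max(0, min(n_int, a_take))
    int1 = [internal[q] for q in order[:a_take]]
    int2 = [internal[q] for q in order[a_take:]]

    rbar = float(np.mean(config.grain_radii))
    counter = cell.grain_count
    old_rest = {}
    for cid in cell.cables:
        cab = state.cables[cid]
        old_rest[frozenset(cab.endpoints)] = cab.rest_length

    def make_daughter(arc, ints, sign):
        nonlocal counter
        p_from = state.grains[arc[-1]].position
        p_to = state.grains[arc[0]].position
        min_new = max(0, 3 - len(arc))
        closure, counter2 = _closure_chain(state, config, p_from, p_to,
                                           sign * 1.2 * rbar * normal,
                                           counter, min_new)
        counter = counter2
        d_ring = arc + closure
        d = state.new_cell(internal_grains=list(ints),
                           peripheral_ring=d_ring, cables=[],
                           state=CellState.GROWING, birth_stage=state.stage)
        for q in range(len(d_ring)):
            a, b = d_ring[q], d_ring[(q + 1) % len(d_ring)]
            L = float(np.linalg.norm(state.grains[a].position -
                                     state.grains[b].position))
            rest = old_rest.get(frozenset((a, b)),
                                _mid_band_rest(L, config))
            cab = state.new_cable(a, b, rest, config.cable_thickness)
            d.cables.append(cab.id)
        return d, len(closure)

    d1, nc1 = make_daughter(arc1, int1, +1.0)
    d2, nc2 = make_daughter(arc2, int2, -1.0)

    # adhesion partners follow the nearer daughter membrane
    for pid in sorted(cell.adhesions):
        if pid not in state.cells:
            continue
        partner = state.cells[pid]
        Pp = state.grain_positions(partner.peripheral_ring) \
            if partner.peripheral_ring else np.array([bary])
        dists = []
        for d in (d1, d2):
            Pd = state.grain_positions(d.peripheral_ring)
            dists.append(np.min(np.linalg.norm(
                Pp[:, None, :] - Pd[None, :, :], axis=2)))
        target = d1 if dists[0] <= dists[1] else d2
        target.adhesions.add(pid)
        partner.adhesions.discard(cell.id)
        partner.adhesions.add(target.id)
        old_key = tuple(sorted((cell.id, pid)))
        anchors = state.junctions.pop(old_key, None)
        if anchors is not None:
            ga, gb = anchors
            partner_ring = set(partner.peripheral_ring)
            g_partner = ga if ga in partner_ring else gb
            g_daughter = gb if g_partner == ga else ga
            if g_partner not in state.grains:
                continue  # stale anchor; the pair may re-adhere later
            if g_daughter not in set(target.peripheral_ring):
                Pd = state.grain_positions(target.peripheral_ring)
                ref = state.grains[g_partner].position
                g_daughter = target.peripheral_ring[int(np.argmin(
                    np.linalg.norm(Pd - ref, axis=1)))]
            new_key = tuple(sorted((target.id, pid)))
            state.junctions[new_key] = ((g_daughter, g_partner)
                                        if new_key[0] == target.id
                                        else (g_partner, g_daughter))

    for cid in cell.cables:
        state.cables.pop(cid, None)
    del state.cells[cell.id]
    if log is not None:
        log.divisions.append((cell.id, d1.id, d2.id))
        log.closure_grains += nc1 + nc2
    return state


def apoptose_step(cell: Cell, state: SimulationState,
                  config: SimulationConfig,
                  log: StageEventLog | None = None) -> SimulationState:
    """Remove grains from an apoptotic cell at the configured per-stage
    rate (internal grains first, then peripheral, keeping the ring closed);
    the cell is deleted once nothing meaningful remains."""
    if cell.state != CellState.APOPTOTIC:
        raise ValueError(f"cell {cell.id} is not apoptotic")
    for _ in range(config.apoptosis_removal_rate):
        if cell.internal_grains:
            gid = min(cell.internal_grains)
            cell.internal_grains.remove(gid)
            del state.grains[gid]
            if log is not None:
                log.apoptotic_grains_removed += 1
        elif len(cell.peripheral_ring) > 3:
            k = cell.peripheral_ring.index(min(cell.peripheral_ring))
            _rotate_ring(cell, (k - 1) % len(cell.peripheral_ring))
            a, b, c = (cell.peripheral_ring[q] for q in range(3))
            cab_ab = state.cables[cell.cables[0]]
            cab_bc = state.cables[cell.cables[1]]
            T = state.cable_tension_now(cab_bc, config.e_c)
            del state.cables[cab_ab.id]
            del state.cables[cab_bc.id]
            del state.grains[b]
            _replace_junction_grain(state, b, a)
            L = float(np.linalg.norm(state.grains[a].position -
                                     state.grains[c].position))
            c_new = state.new_cable(a, c, L - T / config.e_c,
                                    config.cable_thickness, T)
            del cell.peripheral_ring[1]
            cell.cables = [c_new.id] + cell.cables[2:]
            if log is not None:
                log.apoptotic_grains_removed += 1
        else:
            for gid in list(cell.peripheral_ring):
                del state.grains[gid]
                if log is not None:
                    log.apoptotic_grains_removed += 1
            for cid in cell.cables:
                state.cables.pop(cid, None)
            del state.cells[cell.id]
            _drop_cell_junctions(state, cell.id)
            if log is not None:
                log.cells_deleted.append(cell.id)
            break
    return state


# ---------------------------------------------------------------------------
# the simulation loop

def run_simulation(config: SimulationConfig, seed: int | None = None,
                   progress: bool = False) -> SimulationResult:
    """Run one complete simulation of the configured scenario.

    Alternates relaxation blocks with stage events (growth, then scenario
    events, then membrane remodeling, then adhesion creation, then tension
    regulation) until the coverage stop rule fires or the stage budget is
    exhausted (the latter yields a warning-tagged result, not an error).
    Fully reproducible from (config, seed).
    """
    if seed is None:
        seed = config.rng_seed
    R = (config.support_radius if config.support_radius is not None
         else derive_support_radius(config))
    state = SimulationState.empty(SupportSphere(np.zeros(3), R), seed)
    warnings: list[str] = []
    logs: list[StageEventLog] = []
    coverage = 0.0

    if config.scenario == "proliferation":
        spawn_proliferative_seed(state, config)
    else:
        # the accretion process begins with a cohort of small cells already
        # contacting the support, before successive arrivals top it up
        for _ in range(min(config.accretion_n_seed, config.cell_limit)):
            idx = state.n_arrivals + 1
            k = arrival_grain_count(config, idx)
            u = _best_placement(state, config, template_clearance(config, k))
            if u is not None:
                build_cell(state, config, u, k, CellState.ARRIVING)
                state.n_arrivals += 1

    for stage in range(1, config.max_stages + 1):
        relax(state, config)
        if config.stage_velocity_quench:
            for g in state.grains.values():
                g.velocity[:] = 0.0
        state.stage = stage
        log = StageEventLog(stage=stage)

        if stage % max(1, config.growth_period) == 0:
            for cid in sorted(state.cells):
                cell = state.cells[cid]
                if cell.state in (CellState.ARRIVING, CellState.GROWING):
                    if cell.grain_count >= config.mature_grain_count:
                        cell.state = CellState.MATURE
                    else:
                        grow_cell(cell, state, config, log)

        if config.scenario == "accretion":
            attempt_accretion(state, config, log)
        else:
            mit, apo = select_events(state, config)
            for cid in sorted(mit):
                divide_cell(state.cells[cid], state, config, log)
            for cid in sorted(apo):
                state.cells[cid].state = CellState.APOPTOTIC
                log.apoptoses_started.append(cid)
            for cid in sorted(state.cells):
                cell = state.cells.get(cid)
                if cell is not None and cell.state == CellState.APOPTOTIC:
                    apoptose_step(cell, state, config, log)

        for cid in sorted(state.cells):
            cell = state.cells[cid]
            # a mature membrane keeps its grain complement (41 grains at
            # the end); only growing and dying cells remodel their ring
            if cell.state == CellState.MATURE:
                continue
            remodel_cables(cell, state, config, log, allow_small=True)
        create_adhesions(state, config, log)
        for cid in sorted(state.cells):
            cell = state.cells[cid]
            if cell.state != CellState.APOPTOTIC:
                regulate_rest_lengths(cell, state, config)

        if state.grains:
            pos0 = next(iter(state.grains.values())).position
            if not np.all(np.isfinite(pos0)):
                raise RuntimeError(f"non-finite state at stage {stage}")

        coverage = coverage_fraction(state, config.coverage_samples,
                                     config.effective_contact_tolerance)
        log.coverage = coverage
        log.n_cells = len(state.cells)
        log.n_grains = state.n_grains
        logs.append(log)
        if progress:
            print(f"stage {stage:4d}  cells {log.n_cells:4d}  "
                  f"grains {log.n_grains:5d}  coverage {coverage:.4f}")
        if coverage >= config.coverage_stop:
            if config.scenario == "proliferation":
                break
            # an accretion epithelium is complete only when its cells have
            # finished growing
            if all(c.state == CellState.MATURE for c in state.cells.values()):
                break
    else:
        warnings.append(
            f"stage budget ({config.max_stages}) exhausted at coverage "
            f"{coverage:.4f} < {config.coverage_stop}")

    # event-free settling before the terminal census: membranes tighten
    # and late adhesions form, but no growth, arrivals or divisions occur
    for _ in range(config.settle_stages):
        relax(state, config)
        if config.stage_velocity_quench:
            for g in state.grains.values():
                g.velocity[:] = 0.0
        create_adhesions(state, config)
        for cid in sorted(state.cells):
            cell = state.cells[cid]
            if cell.state != CellState.APOPTOTIC:
                regulate_rest_lengths(cell, state, config)

    census = census_from_state(state, config,
                               condition=config.scenario,
                               replicate=str(seed))
    return SimulationResult(state, config, logs, census, coverage, warnings)


def event_log_to_csv(logs: list[StageEventLog], path) -> None:
    rows = []
    for lg in logs:
        rows.append({
            "stage": lg.stage, "n_cells": lg.n_cells,
            "n_grains": lg.n_grains, "coverage": lg.coverage,
            "arrivals": len(lg.arrivals), "growth_events": len(lg.growth),
            "divisions": len(lg.divisions),
            "apoptoses_started": len(lg.apoptoses_started),
            "cells_deleted": len(lg.cells_deleted),
            "adhesions_created": len(lg.adhesions_created),
            "cable_splits": lg.cable_splits, "cable_merges": lg.cable_merges,
            "closure_grains": lg.closure_grains,
            "apoptotic_grains_removed": lg.apoptotic_grains_removed,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
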