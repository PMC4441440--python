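"""Cell neighbour topology, polygon-class censuses, coverage and fixtures.

The polygon class ("shape") of a cell is the number of neighbouring cells
its membrane touches.  For a closed 3-valent polygonal tiling of a sphere
Euler's formula forces ``sum(6 - class) = 12`` over all cells, so a
complete tiling made only of pentagons and hexagons always carries exactly
12 pentagons — the analytic skeleton of the ~80% hexagon frequency of a
60-cell spherical epithelium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import CellState, SimulationConfig, SimulationState

__all__ = [
    "ShapeCensus", "neighbor_graph", "shape_census", "census_from_state",
    "coverage_fraction", "cap_restricted_census", "euler_balance",
    "goldberg_fixture", "pentagon_hexagon_partition", "fibonacci_sphere",
    "census_to_csv", "read_census_csv", "write_edge_list",
]


@dataclass
class ShapeCensus:
    """Counts of cells per polygon class (number of neighbours)."""

    counts: dict[int, int] = field(default_factory=dict)
    condition: str = ""
    replicate: str = ""
    boundary_count: int = 0  # degree<3 cells, excluded from `counts`

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def frequencies(self) -> dict[int, float]:
        t = self.total
        if t == 0:
            raise ValueError("empty census")
        return {k: v / t for k, v in sorted(self.counts.items())}

    def classes(self) -> set[int]:
        return {k for k, v in self.counts.items() if v > 0}


# ---------------------------------------------------------------------------
# neighbour graph from membrane/membrane contacts

def _cell_membrane_arrays(state: SimulationState, cell_ids):
    out = {}
    for cid in cell_ids:
        cell = state.cells[cid]
        ring = cell.peripheral_ring
        if not ring:
            continue
        P = state.grain_positions(ring)
        R = np.array([state.grains[g].radius for g in ring])
        bary = P.mean(axis=0)
        bound = float(np.max(np.linalg.norm(P - bary, axis=1) + R))
        out[cid] = (P, R, bary, bound)
    return out


def _membranes_touch(Pa, Ra, Pb, Rb, thick: float, tol: float) -> bool:
    # grain-vs-grain surface distance
    d = np.linalg.norm(Pa[:, None, :] - Pb[None, :, :], axis=2)
    surf = d - Ra[:, None] - Rb[None, :]
    if surf.min() < tol:
        return True
    # grain of one membrane vs cable segments of the other (both ways)
    for P1, R1, P2, R2 in ((Pa, Ra, Pb, Rb), (Pb, Rb, Pa, Ra)):
        seg_a = P2
        seg_b = np.roll(P2, -1, axis=0)
        s = seg_b - seg_a                                  # (m,3)
        L2 = np.einsum("ij,ij->i", s, s)
        L2 = np.where(L2 < 1e-12, 1.0, L2)
        w = P1[:, None, :] - seg_a[None, :, :]             # (n,m,3)
        t = np.clip(np.einsum("nmj,mj->nm", w, s) / L2[None, :], 0.0, 1.0)
        closest = seg_a[None, :, :] + t[..., None] * s[None, :, :]
        dist = np.linalg.norm(P1[:, None, :] - closest, axis=2)
        surf = dist - R1[:, None] - 0.5 * thick
        if surf.min() < tol:
            return True
    return False


def neighbor_graph(state: SimulationState,
                   contact_tolerance: float | None = None,
                   include_apoptotic: bool = True,
                   include_junctions: bool = False,
                   config: SimulationConfig | None = None) -> nx.Graph:
    """Undirected graph with one vertex per cell and an edge for every pair
    of cells whose membranes (peripheral grains or cables) come within
    ``contact_tolerance`` of touching.

    With ``include_junctions`` every cadherin-junction-bonded pair is also
    an edge: a junction is a physical membrane/membrane bridge even when
    the jammed packing holds the membranes slightly apart."""
    cfg = config or SimulationConfig()
    tol = (contact_tolerance if contact_tolerance is not None
           else cfg.effective_contact_tolerance)
    thick = cfg.cable_thickness
    cell_ids = [cid for cid, c in state.cells.items()
                if include_apoptotic or c.state != CellState.APOPTOTIC]
    G = nx.Graph()
    G.add_nodes_from(cell_ids)
    mem = _cell_membrane_arrays(state, cell_ids)
    ids = sorted(mem)
    for i, a in enumerate(ids):
        Pa, Ra, ba, ra = mem[a]
        for b in ids[i + 1:]:
            Pb, Rb, bb, rb = mem[b]
            if np.linalg.norm(ba - bb) > ra + rb + tol + thick:
                continue
            if _membranes_touch(Pa, Ra, Pb, Rb, thick, tol):
                G.add_edge(a, b)
    if include_junctions:
        for (a, b) in state.junctions:
            if G.has_node(a) and G.has_node(b):
                G.add_edge(a, b)
    return G


def shape_census(graph: nx.Graph, condition: str = "",
                 replicate: str = "") -> ShapeCensus:
    """Polygon-class census of a neighbour graph: class = vertex degree.

    Cells of degree < 3 (boundary or immature cells of an incomplete
    epithelium) are tallied separately and excluded from the class counts.
    """
    counts: dict[int, int] = {}
    boundary = 0
    for node in graph.nodes:
        deg = graph.degree[node]
        if deg < 3:
            boundary += 1
        else:
            counts[deg] = counts.get(deg, 0) + 1
    return ShapeCensus(counts, condition, replicate, boundary)


def census_from_state(state: SimulationState,
                      config: SimulationConfig | None = None,
                      contact_tolerance: float | None = None,
                      include_apoptotic: bool = False,
                      condition: str = "", replicate: str = "") -> ShapeCensus:
    """Whole-sphere census of a simulation state.

    Apoptotic (dying) cells are excluded by default: mid-removal remnants
    are not epithelium cells.  Neighbours are membrane contacts plus
    cadherin-junction bonds.
    """
    G = neighbor_graph(state, contact_tolerance,
                       include_apoptotic=include_apoptotic,
                       include_junctions=True, config=config)
    return shape_census(G, condition, replicate)


# ---------------------------------------------------------------------------
# coverage

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform lattice of ``n`` unit vectors."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def coverage_fraction(state: SimulationState, n_samples: int = 10000,
                      contact_tolerance: float | None = None) -> float:
    """Fraction of the support surface lying under the epithelium.

    Sampled on a fixed Fibonacci lattice so the 99%-coverage stop rule is
    reproducible.  The footprint of a cell is its peripheral-ring spherical
    polygon inflated by the local peripheral grain radius plus the
    membrane-contact tolerance: a seam whose membranes are within contact
    tolerance of touching is interior tissue surface and counts as
    covered.
    """
    if n_samples < 100:
        raise ValueError("n_samples too small for a stable estimate")
    if not state.cells:
        return 0.0
    if contact_tolerance is None:
        radii = [g.radius for g in state.grains.values()]
        contact_tolerance = 0.5 * min(radii) if radii else 0.0
    R = state.support.radius
    center = state.support.center
    pts = fibonacci_sphere(n_samples)
    covered = np.zeros(n_samples, dtype=bool)

    for cell in state.cells.values():
        ring = cell.peripheral_ring
        if len(ring) < 3:
            continue
        P = state.grain_positions(ring) - center
        Rg = np.array([state.grains[g].radius for g in ring])
        U = P / np.linalg.norm(P, axis=1, keepdims=True)
        b = U.mean(axis=0)
        b /= np.linalg.norm(b)
        cosmax = float(np.min(U @ b))
        ang_pad = (np.max(Rg) + 1.0) / R
        theta = math.acos(max(-1.0, min(1.0, cosmax))) + ang_pad
        if theta >= math.pi / 2 * 0.95:
            theta = math.pi / 2 * 0.95
        todo = np.nonzero(~covered & (pts @ b > math.cos(theta)))[0]
        if todo.size == 0:
            continue
        # gnomonic projection: great circles -> straight lines
        e1 = np.cross(b, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(b, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(b, e1)
        q = pts[todo]
        denom = q @ b
        X = np.column_stack([(q @ e1) / denom, (q @ e2) / denom]) * R
        rd = U @ b
        V = np.column_stack([(U @ e1) / rd, (U @ e2) / rd]) * R

        inside = _points_in_polygon(X, V)
        near = _points_near_ring(X, V, Rg, contact_tolerance)
        covered[todo[inside | near]] = True
    return float(covered.mean())


def _points_in_polygon(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Vectorised even-odd (crossing number) point-in-polygon test."""
    n = V.shape[0]
    x, y = X[:, 0], X[:, 1]
    inside = np.zeros(X.shape[0], dtype=bool)
    x1, y1 = V[:, 0], V[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for k in range(n):
        cond = (y1[k] > y) != (y2[k] > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1[k] + (y - y1[k]) * (x2[k] - x1[k]) / (y2[k] - y1[k])
        inside ^= cond & (x < xint)
    return inside


def _points_near_ring(X: np.ndarray, V: np.ndarray, Rg: np.ndarray,
                      tol: float = 0.0) -> np.ndarray:
    """Points within the membrane's footprint (distance to a ring segment
    below the local peripheral grain radius plus ``tol``)."""
    seg_a = V
    seg_b = np.roll(V, -1, axis=0)
    r_edge = 0.5 * (Rg + np.roll(Rg, -1)) + tol
    s = seg_b - seg_a
    L2 = np.einsum("ij,ij->i", s, s)
    L2 = np.where(L2 < 1e-12, 1.0, L2)
    w = X[:, None, :] - seg_a[None, :, :]
    t = np.clip(np.einsum("nmj,mj->nm", w, s) / L2[None, :], 0.0, 1.0)
    closest = seg_a[None, :, :] + t[..., None] * s[None, :, :]
    dist = np.linalg.norm(X[:, None, :] - closest, axis=2)
    return np.any(dist < r_edge[None, :], axis=1)


# ---------------------------------------------------------------------------
# cap-restricted census

def cap_restricted_census(state: SimulationState, pole=(0.0, 0.0, 1.0),
                          cap_area_fraction: float = 0.8,
                          contact_tolerance: float | None = None,
                          include_apoptotic: bool = False,
                          config: SimulationConfig | None = None,
                          condition: str = "", replicate: str = ""
                          ) -> ShapeCensus:
    """Census restricted to cells whose barycentre lies in the spherical cap
    of area ``cap_area_fraction x 2 pi R^2`` around ``pole`` (the published
    counting rule draws the circle holding 80% of the half-sphere surface).

    Neighbour classes are still computed from the full graph; only the
    counted population is restricted.  Cap area ``A = 2 pi R^2 (1 - cos
    theta)`` gives boundary colatitude ``theta = arccos(1 - fraction)``.
    """
    if not 0.0 < cap_area_fraction <= 1.0:
        raise ValueError("cap_area_fraction must be in (0, 1]")
    pole = np.asarray(pole, float)
    pole = pole / np.linalg.norm(pole)
    cos_theta = 1.0 - cap_area_fraction
    G = neighbor_graph(state, contact_tolerance,
                       include_apoptotic=include_apoptotic, config=config)
    counts: dict[int, int] = {}
    boundary = 0
    center = state.support.center
    for cid in G.nodes:
        cell = state.cells[cid]
        b = state.cell_barycentre(cell) - center
        u = b / np.linalg.norm(b)
        if float(u @ pole) < cos_theta:
            continue
        deg = G.degree[cid]
        if deg < 3:
            boundary += 1
        else:
            counts[deg] = counts.get(deg, 0) + 1
    return ShapeCensus(counts, condition, replicate, boundary)


# ---------------------------------------------------------------------------
# Euler balance and analytic tilings

def euler_balance(census: ShapeCensus) -> int:
    """``sum over cells of (6 - class)``; equals 12 for any closed 3-valent
    polygonal tiling of the sphere.

    Only meaningful for censuses of complete tilings; raises if the census
    is empty or contains boundary (degree<3) cells.
    """
    if census.total == 0:
        raise ValueError("Euler balance is not applicable to an empty census")
    if census.boundary_count > 0:
        raise ValueError("Euler balance is not applicable: census has "
                         f"{census.boundary_count} boundary/immature cells")
    return int(sum((6 - k) * v for k, v in census.counts.items()))


def pentagon_hexagon_partition(n_cells: int) -> tuple[int, int]:
    """Pentagon/hexagon counts of a complete closed 3-valent spherical
    tiling containing only 5- and 6-sided cells.

    Euler's formula fixes the pentagon count at exactly 12, independent of
    the number of cells; returns ``(12, n_cells - 12)``.
    """
    if n_cells < 12:
        raise ValueError("a closed pentagon/hexagon tiling needs >= 12 cells")
    return 12, n_cells - 12


_PHI = (1.0 + math.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array([
    (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
    (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
    (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
], dtype=float)
_ICO_FACES = [
    (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
    (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
    (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
    (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
]


def goldberg_fixture(subdivision: int) -> tuple[nx.Graph, dict[int, np.ndarray]]:
    """Adjacency and face barycentres of the Goldberg polyhedron GP(m, 0):
    the dual of the ``m``-fold subdivided icosahedron.

    Yields ``10 m^2 + 2`` cells: exactly 12 pentagons (at the icosahedral
    vertices), the rest hexagons — an analytic complete spherical tiling.
    """
    m = int(subdivision)
    if m < 1:
        raise ValueError("subdivision must be >= 1")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    key_to_id: dict[tuple, int] = {}
    positions: dict[int, np.ndarray] = {}
    G = nx.Graph()

    def node_for(p: np.ndarray) -> int:
        key = tuple(np.round(p, 8))
        if key not in key_to_id:
            nid = len(key_to_id)
            key_to_id[key] = nid
            positions[nid] = p
            G.add_node(nid)
        return key_to_id[key]

    for (ia, ib, ic) in _ICO_FACES:
        A, B, C = verts[ia], verts[ib], verts[ic]
        grid = {}
        for i in range(m + 1):
            for j in range(m + 1 - i):
                p = (A * (m - i - j) + B * i + C * j) / m
                p = p / np.linalg.norm(p)
                grid[(i, j)] = node_for(p)
        for i in range(m + 1):
            for j in range(m + 1 - i):
                if (i + 1, j) in grid:
                    G.add_edge(grid[(i, j)], grid[(i + 1, j)])
                if (i, j + 1) in grid:
                    G.add_edge(grid[(i, j)], grid[(i, j + 1)])
                if (i + 1, j) in grid and (i, j + 1) in grid:
                    G.add_edge(grid[(i + 1, j)], grid[(i, j + 1)])
    return G, positions


def write_edge_list(graph: nx.Graph, path) -> None:
    """Export a neighbour graph as a plain two-column edge list."""
    nx.write_edgelist(graph, path, data=False)


# ---------------------------------------------------------------------------
# census CSV dialect: condition, replicate, polygon_class, count

def census_to_csv(censuses, path) -> None:
    rows = []
    for c in (censuses if isinstance(censuses, (list, tuple)) else [censuses]):
        for k, v in sorted(c.counts.items()):
            rows.append({"condition": c.condition, "replicate": c.replicate,
                         "polygon_class": k, "count": v})
    pd.DataFrame(rows, columns=["condition", "replicate",
                                "polygon_class", "count"]).to_csv(path,
                                                                  index=False)


def read_census_csv(path) -> list[ShapeCensus]:
    df = pd.read_csv(path)
    need = {"condition", "replicate", "polygon_class", "count"}
    if not need.issubset(df.columns):
        raise ValueError(f"census CSV needs columns {sorted(need)}")
    out = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        counts = {int(k): int(v) for k, v in
                  zip(grp["polygon_class"], grp["count"])}
        out.append(ShapeCensus(counts, str(cond), str(rep)))
    return out
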