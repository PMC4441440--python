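"""Support-radius calibration.

The support sphere radius is never an input of the biology: it is derived
from the target number of mature cells N so that N relaxed mature-cell
footprints tile the sphere surface, ``N x A_cell ~ 4 pi R^2``.  ``A_cell``
is measured once by growing a single cell to maturity on a very large
(locally flat) support, relaxing it, and integrating its in-plane membrane
footprint (ring polygon inflated by the peripheral grain radius).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .core import (CellState, SimulationConfig, SimulationState,
                   SupportSphere)

__all__ = ["derive_support_radius", "mature_cell_area"]

_CALIBRATION_SUPPORT_RADIUS = 200.0


def _config_key(config: SimulationConfig, seed: int) -> tuple:
    return (config.grain_radii, config.density, config.cable_thickness,
            config.l_min, config.l_max, config.e_gg, config.c_gg,
            config.e_gc, config.e_c, config.t_min, config.t_max,
            config.dt, config.mature_grain_count, seed)


def relaxed_mature_cell(config: SimulationConfig, seed: int = 0,
                        support_radius: float = _CALIBRATION_SUPPORT_RADIUS
                        ) -> SimulationState:
    """Grow one isolated cell to maturity and relax it mechanically."""
    from .mechanics import regulate_rest_lengths, relax
    from .scenarios import build_cell, grow_cell, remodel_cables

    state = SimulationState.empty(SupportSphere(np.zeros(3), support_radius),
                                  seed)
    cell = build_cell(state, config, np.array([0.0, 0.0, 1.0]), 3,
                      CellState.GROWING)

    def quench():
        if config.stage_velocity_quench:
            for g in state.grains.values():
                g.velocity[:] = 0.0

    while cell.grain_count < config.mature_grain_count:
        quench()
        grow_cell(cell, state, config)
        relax(state, config, n_steps=300, speed_tol=0.0)
        remodel_cables(cell, state, config)
        regulate_rest_lengths(cell, state, config)
    for _ in range(4):
        quench()
        relax(state, config, n_steps=500, speed_tol=1e-4)
        remodel_cables(cell, state, config)
        regulate_rest_lengths(cell, state, config)
    cell.state = CellState.MATURE
    return state


def _footprint_area(state: SimulationState) -> float:
    """In-plane membrane footprint of the single cell in ``state``:
    ring polygon area plus the Minkowski margin of the membrane itself
    (perimeter x mean grain radius + pi x mean radius^2)."""
    cell = next(iter(state.cells.values()))
    ring = cell.peripheral_ring
    P = state.grain_positions(ring)
    R = np.array([state.grains[g].radius for g in ring])
    bary = P.mean(axis=0)
    u = bary - state.support.center
    u /= np.linalg.norm(u)
    e1 = np.cross(u, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(u, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    rel = P - bary
    x = rel @ e1
    y = rel @ e2
    area = 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    per = float(np.sum(np.hypot(np.diff(np.append(x, x[0])),
                                np.diff(np.append(y, y[0])))))
    rbar = float(R.mean())
    return area + per * rbar + np.pi * rbar**2


def _config_from_key(key: tuple) -> SimulationConfig:
    return SimulationConfig(
        grain_radii=key[0], density=key[1], cable_thickness=key[2],
        l_min=key[3], l_max=key[4], e_gg=key[5], c_gg=key[6], e_gc=key[7],
        e_c=key[8], t_min=key[9], t_max=key[10], dt=key[11],
        mature_grain_count=key[12])


@lru_cache(maxsize=8)
def _isolated_area(key: tuple) -> float:
    cfg = _config_from_key(key)
    return _footprint_area(relaxed_mature_cell(cfg, seed=key[13]))


@lru_cache(maxsize=8)
def _derived_radius(key: tuple, n_cells: int) -> float:
    area = _isolated_area(key)
    return float(np.sqrt(n_cells * area / (4.0 * np.pi)))


def mature_cell_area(config: SimulationConfig, seed: int = 0) -> float:
    """Relaxed in-plane area of one isolated mature cell (model units^2)."""
    return _footprint_area(relaxed_mature_cell(config, seed))


def derive_support_radius(config: SimulationConfig,
                          calibration_seed: int = 0) -> float:
    """Support radius R such that ``target_cell_count`` mature-cell areas
    match the sphere surface, ``N x A_cell ~ 4 pi R^2``.

    ``A_cell`` is the in-plane footprint of an isolated, mechanically
    relaxed mature cell.  Deterministic given the configuration and
    calibration seed (results are cached).  Requires N >= 12: no closed
    polygonal tiling of a sphere exists with fewer pentagon-capable cells.
    """
    n = config.target_cell_count
    if n < 12:
        raise ValueError("target_cell_count must be >= 12 (no closed "
                         "spherical tiling with fewer cells)")
    return _derived_radius(_config_key(config, calibration_seed), n)
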