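import numpy as np
import pytest

from epigrain import SimulationConfig, SimulationState, SupportSphere
from epigrain.core import CellState
from epigrain.scenarios import build_cell


@pytest.fixture
def config():
    return SimulationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_two_cell_state(config, gap=2.0, k=9, seed=0):
    """Two small cells on a support, their membranes ``gap`` apart
    (negative gap = overlapping footprints)."""
    state = SimulationState.empty(SupportSphere(np.zeros(3), 60.0), seed)
    from epigrain.scenarios import template_clearance
    half_sep = template_clearance(config, k) + gap / 2.0
    ang = half_sep / 60.0
    u1 = np.array([np.sin(ang), 0.0, np.cos(ang)])
    u2 = np.array([-np.sin(ang), 0.0, np.cos(ang)])
    build_cell(state, config, u1, k, CellState.GROWING)
    build_cell(state, config, u2, k, CellState.GROWING)
    return state


@pytest.fixture
def two_cell_state(config):
    return make_two_cell_state(config)


@pytest.fixture(scope="session")
def mature_cell_state():
    """One isolated mature cell, mechanically relaxed (session-cached)."""
    from epigrain.calibration import relaxed_mature_cell
    return relaxed_mature_cell(SimulationConfig(), seed=0)


@pytest.fixture(scope="session")
def micro_accretion_result():
    """A complete accretion run at reduced scale (14 cells)."""
    from epigrain import run_simulation
    cfg = SimulationConfig(scenario="accretion", target_cell_count=14,
                           cell_limit=14, accretion_n_seed=8,
                           max_stages=220, rng_seed=3)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def micro_proliferation_result():
    """A small proliferation run (reduced support, few seed cells)."""
    from epigrain import preset, run_simulation
    # 8 seed cells: enough mature cells for the 7% mitotic draw to fire
    cfg = preset("proliferation-1over3", target_cell_count=16, n_seed=8,
                 max_stages=250, rng_seed=3)
    return run_simulation(cfg)
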