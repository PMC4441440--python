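"""Stage-level biology: growth, remodeling, adhesion, accretion,
division, apoptosis, and whole-run invariants at reduced scale."""

import numpy as np
import pytest

from epigrain import (SimulationConfig, SimulationState, SupportSphere,
                      run_simulation, validate_state)
from epigrain.core import CellState, GrainKind
from epigrain.scenarios import (apoptose_step, arrival_grain_count,
                                build_cell, create_adhesions, divide_cell,
                                grow_cell, remodel_cables, select_events,
                                spawn_proliferative_seed)

from conftest import make_two_cell_state


class TestGrowth:
    def test_growth_follows_the_cyclic_radius_sequence(self, config):
        state = make_two_cell_state(config, k=5)
        cell = next(iter(state.cells.values()))
        assert cell.grain_count == 5
        grow_cell(cell, state, config)
        added = state.grains[cell.internal_grains[-1]]
        assert added.radius == 2.5  # index 5 wraps to the sequence start
        grow_cell(cell, state, config)
        assert state.grains[cell.internal_grains[-1]].radius == 2.8

    def test_reaching_the_mature_count_flags_maturity(self, config):
        state = make_two_cell_state(config, k=9)
        cell = next(iter(state.cells.values()))
        while cell.grain_count < config.mature_grain_count:
            grow_cell(cell, state, config)
        assert cell.state == CellState.MATURE
        assert cell.grain_count == config.mature_grain_count

    def test_growing_a_mature_cell_is_an_error(self, config):
        state = make_two_cell_state(config, k=9)
        cell = next(iter(state.cells.values()))
        cell.state = CellState.MATURE
        with pytest.raises(ValueError):
            grow_cell(cell, state, config)


class TestCableRemodeling:
    def _ring_cell(self, config, n=8, radius=6.0):
        state = SimulationState.empty(SupportSphere(np.zeros(3), 500.0))
        ring = []
        for i in range(n):
            th = 2 * np.pi * i / n
            p = np.array([radius * np.cos(th), radius * np.sin(th), 503.0])
            g = state.new_grain(p, np.zeros(3), 3.0, GrainKind.PERIPHERAL)
            ring.append(g.id)
        cell = state.new_cell(peripheral_ring=ring, cables=[],
                              state=CellState.GROWING)
        from epigrain.mechanics import project_to_support
        for i in range(n):
            a, b = ring[i], ring[(i + 1) % n]
            L = np.linalg.norm(state.grains[a].position -
                               state.grains[b].position)
            cab = state.new_cable(a, b, L - 0.175 / config.e_c)
            cell.cables.append(cab.id)
        project_to_support(state)
        return state, cell

    def test_long_cables_split_with_a_midpoint_grain(self, config):
        # octagon of radius 8 -> cable length ~6.1 > Lmax
        state, cell = self._ring_cell(config, n=8, radius=8.0)
        n_before = len(cell.peripheral_ring)
        remodel_cables(cell, state, config)
        assert len(cell.peripheral_ring) > n_before
        lengths = [state.cable_length(state.cables[c]) for c in cell.cables]
        assert max(lengths) <= config.l_max + 1e-9
        assert len(cell.cables) == len(cell.peripheral_ring)

    def test_short_cables_removed_and_ring_reconnected(self, config):
        # dense ring of radius 2.2 -> cable length ~1.7 < Lmin
        state, cell = self._ring_cell(config, n=8, radius=2.2)
        remodel_cables(cell, state, config)
        assert len(cell.peripheral_ring) < 8
        assert len(cell.peripheral_ring) >= 3
        lengths = [state.cable_length(state.cables[c]) for c in cell.cables]
        assert min(lengths) >= config.l_min - 1e-9

    def test_in_band_ring_is_left_unchanged(self, config):
        state, cell = self._ring_cell(config, n=8, radius=4.6)
        ring_before = list(cell.peripheral_ring)
        remodel_cables(cell, state, config)
        assert cell.peripheral_ring == ring_before

    def test_cannot_shrink_below_three_grains(self, config):
        state, cell = self._ring_cell(config, n=3, radius=1.0)
        with pytest.raises(ValueError):
            remodel_cables(cell, state, config)
        remodel_cables(cell, state, config, allow_small=True)  # skips


class TestAdhesion:
    def test_distant_membranes_are_never_candidates(self, config):
        state = make_two_cell_state(config, gap=config.adhesion_distance + 1)
        for _ in range(30):
            create_adhesions(state, config)
        assert all(not c.adhesions for c in state.cells.values())

    def test_candidates_created_with_probability_one_half(self, config):
        # same near pair, many independent RNG streams: the created
        # fraction must sit inside the binomial 99% CI of 1/2
        created = 0
        n = 800
        for seed in range(n):
            state = make_two_cell_state(config, gap=4.0, seed=seed)
            create_adhesions(state, config)
            created += bool(next(iter(state.cells.values())).adhesions)
        se = np.sqrt(0.25 / n)
        assert abs(created / n - 0.5) < 2.576 * se

    def test_partnerships_are_permanent_and_idempotent(self, config):
        state = make_two_cell_state(config, gap=2.0, seed=11)
        for _ in range(30):
            create_adhesions(state, config)
        a, b = sorted(state.cells)
        assert b in state.cells[a].adhesions
        assert (a, b) in state.junctions
        snapshot = dict(state.junctions)
        create_adhesions(state, config)
        assert state.junctions == snapshot


class TestAccretion:
    def test_arrival_size_schedule_is_linear_in_arrival_index(self, config):
        assert arrival_grain_count(config, 1) == 3
        assert arrival_grain_count(config, config.cell_limit) == 15
        mid = arrival_grain_count(config, 30)
        assert 8 <= mid <= 10
        sizes = [arrival_grain_count(config, i) for i in range(1, 61)]
        assert sizes == sorted(sizes)

    def test_accretion_requires_the_accretion_scenario(self):
        cfg = SimulationConfig(scenario="proliferation")
        state = SimulationState.empty(SupportSphere(np.zeros(3), 60.0))
        from epigrain.scenarios import attempt_accretion
        with pytest.raises(ValueError):
            attempt_accretion(state, cfg)


class TestProliferativeSeeding:
    def test_seeds_are_collision_free_six_grain_cells(self):
        cfg = SimulationConfig(scenario="proliferation", n_seed=5,
                               support_radius=40.0)
        state = SimulationState.empty(SupportSphere(np.zeros(3), 40.0), 1)
        spawn_proliferative_seed(state, cfg)
        assert len(state.cells) == 5
        assert all(c.grain_count == cfg.initial_grains
                   for c in state.cells.values())
        assert validate_state(state, cfg) == []

    def test_single_seed_has_no_contacts(self):
        cfg = SimulationConfig(scenario="proliferation", n_seed=1,
                               support_radius=40.0)
        state = SimulationState.empty(SupportSphere(np.zeros(3), 40.0), 1)
        spawn_proliferative_seed(state, cfg)
        from epigrain import neighbor_graph
        assert neighbor_graph(state, config=cfg).number_of_edges() == 0

    def test_impossible_seeding_raises(self):
        cfg = SimulationConfig(scenario="proliferation", n_seed=40,
                               support_radius=12.0)
        state = SimulationState.empty(SupportSphere(np.zeros(3), 12.0), 1)
        with pytest.raises(RuntimeError):
            spawn_proliferative_seed(state, cfg)

    def test_seeding_requires_empty_state(self, config):
        cfg = SimulationConfig(scenario="proliferation", support_radius=60.0)
        state = make_two_cell_state(config)
        with pytest.raises(ValueError):
            spawn_proliferative_seed(state, cfg)


class TestEventSelection:
    def _mature_population(self, n):
        cfg = SimulationConfig(scenario="proliferation", support_radius=500.0)
        state = SimulationState.empty(SupportSphere(np.zeros(3), 500.0), 0)
        rng = np.random.default_rng(0)
        for _ in range(n):
            u = rng.normal(size=3)
            cell = build_cell(state, cfg, u / np.linalg.norm(u), 9,
                              CellState.MATURE)
        return state, cfg

    def test_seven_percent_mitoses_and_ratio_rounded_apoptoses(self):
        state, cfg = self._mature_population(100)
        mit, apo = select_events(state, cfg)
        assert len(mit) == 7          # round(0.07 * 100)
        assert len(apo) == 2          # round(7 / 3)
        assert not mit & apo

    def test_zero_ratio_means_no_apoptosis(self):
        state, cfg = self._mature_population(100)
        cfg = SimulationConfig(**{**cfg.to_dict(),
                                  "apoptosis_mitosis_ratio": 0.0})
        mit, apo = select_events(state, cfg)
        assert len(mit) == 7 and apo == set()

    def test_no_mature_cells_no_events(self):
        state, cfg = self._mature_population(0)
        assert select_events(state, cfg) == (set(), set())


class TestDivision:
    def test_division_partitions_the_parent(self, config, mature_cell_state):
        state = SimulationState.from_snapshot(
            mature_cell_state.to_snapshot())
        parent = next(iter(state.cells.values()))
        parent_grains = set(parent.grain_ids)
        n_parent = parent.grain_count
        log_parent_bary = state.cell_barycentre(parent)
        from epigrain.scenarios import StageEventLog
        log = StageEventLog(stage=1)
        divide_cell(parent, state, config, log)
        assert parent.id not in state.cells
        d1, d2 = (state.cells[c] for c in sorted(state.cells))
        assert d1.state == d2.state == CellState.GROWING
        # grain ledger: parent grains all transferred, plus logged closures
        assert d1.grain_count + d2.grain_count == \
            n_parent + log.closure_grains
        assert abs(d1.grain_count - d2.grain_count) <= 2
        assert parent_grains <= set(d1.grain_ids) | set(d2.grain_ids)
        # the division interface passes near the parent barycentre
        shared_new = [g for g in d1.grain_ids if g not in parent_grains]
        closure_pos = state.grain_positions(shared_new)
        d = np.linalg.norm(closure_pos.mean(axis=0) - log_parent_bary)
        assert d < 8.0

    def test_daughters_inherit_partners_by_proximity(self, config,
                                                     mature_cell_state):
        state = SimulationState.from_snapshot(
            mature_cell_state.to_snapshot())
        parent = next(iter(state.cells.values()))
        # put a small partner cell next to the parent, adhered to it
        bary = state.cell_barycentre(parent)
        u = bary / np.linalg.norm(bary)
        e1 = np.cross(u, [1.0, 0, 0])
        e1 /= np.linalg.norm(e1)
        ring = state.grain_positions(parent.peripheral_ring)
        extent = np.max(np.linalg.norm(ring - bary, axis=1))
        udir = bary + (extent + 10.0) * e1
        partner = build_cell(state, config, udir / np.linalg.norm(udir), 6,
                             CellState.GROWING)
        parent.adhesions.add(partner.id)
        partner.adhesions.add(parent.id)
        state.junctions[tuple(sorted((parent.id, partner.id)))] = (
            parent.peripheral_ring[0], partner.peripheral_ring[0])
        divide_cell(parent, state, config)
        heirs = [c for c in state.cells.values()
                 if partner.id in c.adhesions]
        assert len(heirs) == 1
        assert heirs[0].id in partner.adhesions
        # the inheriting daughter is the nearer one
        other = [c for c in state.cells.values()
                 if c.id not in (heirs[0].id, partner.id)][0]
        pb = state.cell_barycentre(partner)
        d_heir = np.linalg.norm(state.cell_barycentre(heirs[0]) - pb)
        d_other = np.linalg.norm(state.cell_barycentre(other) - pb)
        assert d_heir <= d_other

    def test_dividing_an_immature_cell_is_an_error(self, config):
        state = make_two_cell_state(config, k=9)
        cell = next(iter(state.cells.values()))
        with pytest.raises(ValueError):
            divide_cell(cell, state, config)


class TestApoptosis:
    def test_grains_removed_one_per_stage_then_cell_deleted(self, config):
        state = make_two_cell_state(config, k=9)
        cell = next(iter(state.cells.values()))
        for _ in range(4):
            grow_cell(cell, state, config)
        cell.state = CellState.APOPTOTIC
        counts = [cell.grain_count]
        while cell.id in state.cells and counts[-1] > 3:
            apoptose_step(cell, state, config)
            counts.append(cell.grain_count)
        deltas = [a - b for a, b in zip(counts, counts[1:])]
        assert all(d == 1 for d in deltas)
        # final stage removes the residual ring and deletes the cell
        apoptose_step(cell, state, config)
        assert cell.id not in state.cells
        assert validate_state(state, config) == []

    def test_only_apoptotic_cells_can_shrink(self, config):
        state = make_two_cell_state(config, k=9)
        cell = next(iter(state.cells.values()))
        with pytest.raises(ValueError):
            apoptose_step(cell, state, config)


class TestMicroAccretionRun(object):
    def test_reaches_coverage_with_full_cell_complement(
            self, config, micro_accretion_result):
        res = micro_accretion_result
        assert res.coverage >= res.config.coverage_stop
        assert res.n_cells == res.config.cell_limit
        assert not res.warnings

    def test_scenario_purity_no_divisions_or_deaths(self,
                                                    micro_accretion_result):
        for log in micro_accretion_result.event_log:
            assert not log.divisions
            assert not log.apoptoses_started
            assert len(log.arrivals) <= 2

    def test_coverage_monotone_up_to_sampling_noise(self,
                                                    micro_accretion_result):
        covs = [l.coverage for l in micro_accretion_result.event_log]
        for a, b in zip(covs, covs[1:]):
            assert b >= a - 0.01

    def test_adhesion_network_is_monotone(self, micro_accretion_result):
        seen = set()
        for log in micro_accretion_result.event_log:
            for pair in log.adhesions_created:
                assert pair not in seen
                seen.add(pair)
        final = micro_accretion_result.state
        final_pairs = {tuple(sorted((a, b)))
                       for a in final.cells
                       for b in final.cells[a].adhesions if b in final.cells}
        assert final_pairs <= seen

    def test_final_state_satisfies_all_invariants(self, config,
                                                  micro_accretion_result):
        assert validate_state(micro_accretion_result.state,
                              micro_accretion_result.config) == []

    def test_determinism_same_seed_same_event_log(self):
        cfg = SimulationConfig(scenario="accretion", target_cell_count=14,
                               cell_limit=14, accretion_n_seed=8,
                               max_stages=12, rng_seed=9)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        for la, lb in zip(a.event_log, b.event_log):
            assert la == lb
        assert a.coverage == b.coverage


class TestMicroProliferationRun(object):
    def test_run_terminates_with_divisions_having_occurred(
            self, micro_proliferation_result):
        res = micro_proliferation_result
        assert sum(len(l.divisions) for l in res.event_log) > 0
        assert res.coverage >= res.config.coverage_stop or res.warnings

    def test_no_arrivals_in_proliferation_mode(self,
                                               micro_proliferation_result):
        for log in micro_proliferation_result.event_log:
            assert not log.arrivals

    def test_grain_ledger_balances_each_stage(self,
                                              micro_proliferation_result):
        logs = micro_proliferation_result.event_log
        for prev, cur in zip(logs, logs[1:]):
            assert cur.n_grains - prev.n_grains == cur.grain_delta()

    def test_census_broader_than_accretion(self, micro_proliferation_result,
                                           micro_accretion_result):
        broad = micro_proliferation_result.census.classes()
        narrow = micro_accretion_result.census.classes()
        assert len(broad) >= len(narrow)
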