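"""Behaviour of the lattice exclusion process: initial conditions, the
single-event law, crowding, tracking, and run-level reproducibility."""

import math

import numpy as np
import pytest

from fucciabc.hex_lattice import LatticeGeometry, neighbours, site_to_xy
from fucciabc.simulator import (
    ModelParams,
    Phase,
    SimConfig,
    SimState,
    gillespie_step,
    init_from_positions,
    init_random_strips,
    select_tracked_cells,
    simulate,
)


def params(r=(0.0, 0.0, 0.0), m=(0.0, 0.0, 0.0)) -> ModelParams:
    return ModelParams(r[0], r[1], r[2], m[0], m[1], m[2])


def single_agent_state(geom, ij=(5, 5), phase=Phase.RED) -> SimState:
    s = geom.site_index(*ij)
    return SimState(geom, np.array([s]), np.array([int(phase)]))


class TestInitFromPositions:
    def test_empty_list(self, small_geom):
        state = init_from_positions([], small_geom)
        assert state.n_agents == 0

    def test_duplicate_site_omitted(self, small_geom):
        p = site_to_xy((3, 3), small_geom)
        q = (p[0] + 1.0, p[1] - 1.0)  # snaps onto the same site
        state = init_from_positions([(p, Phase.RED), (q, Phase.GREEN)], small_geom)
        assert state.n_agents == 1
        assert state.n_omitted == 1
        assert state.agent_phase[0] == int(Phase.RED)  # first one kept

    def test_distinct_sites_preserve_phase_counts(self):
        geom = LatticeGeometry.from_extent(1309.09, 1745.35, 20.0)
        rng = np.random.default_rng(5)
        sites = rng.choice(geom.n_sites, size=275, replace=False)
        phases = [Phase.RED] * 119 + [Phase.YELLOW] * 35 + [Phase.GREEN] * 121
        cells = [
            (site_to_xy(geom.site_ij(int(s)), geom), ph)
            for s, ph in zip(sites, phases)
        ]
        state = init_from_positions(cells, geom)
        assert state.n_agents == 275
        assert state.phase_counts() == (119, 35, 121)
        state.validate()

    def test_all_outside_domain_raises(self, small_geom):
        with pytest.raises(ValueError):
            init_from_positions([((-500.0, -500.0), Phase.RED)], small_geom)


class TestInitRandomStrips:
    def test_experimental_setting(self):
        geom = LatticeGeometry.from_extent(1309.09, 1745.35, 20.0)
        state = init_random_strips((119, 35, 121), 200.0, geom, seed=3)
        assert state.n_agents == 275
        assert state.phase_counts() == (119, 35, 121)
        x, _ = state.positions_xy()
        assert np.all((x <= 200.0) | (x >= 1309.09 - 200.0))
        state.validate()

    def test_empty_counts(self, small_geom):
        state = init_random_strips((0, 0, 0), 40.0, small_geom, seed=0)
        assert state.n_agents == 0

    def test_same_seed_is_deterministic(self, small_geom):
        a = init_random_strips((5, 3, 2), 60.0, small_geom, seed=11)
        b = init_random_strips((5, 3, 2), 60.0, small_geom, seed=11)
        assert np.array_equal(a.agent_site, b.agent_site)
        assert np.array_equal(a.agent_phase, b.agent_phase)

    def test_overfull_strips_raise(self, small_geom):
        with pytest.raises(ValueError):
            init_random_strips((200, 0, 0), 20.0, small_geom, seed=0)


class TestGillespieStep:
    def test_no_events_when_rates_zero(self, small_geom, rng):
        state = single_agent_state(small_geom)
        event, dt = gillespie_step(state, params(), rng)
        assert event == "none" and math.isinf(dt)

    def test_transition_vs_move_probability(self, small_geom):
        """One red agent with M_r = R_r = 1: the next event is a transition
        with probability R_r/(M_r + R_r) = 1/2."""
        rng = np.random.default_rng(7)
        p = params(r=(1.0, 0.0, 0.0), m=(1.0, 0.0, 0.0))
        n, n_trans = 4000, 0
        for _ in range(n):
            state = single_agent_state(small_geom)
            event, _ = gillespie_step(state, p, rng)
            n_trans += event == "transition"
        # binomial(4000, 1/2): 3.5 sigma band
        assert abs(n_trans / n - 0.5) < 3.5 * 0.5 / math.sqrt(n)

    def test_surrounded_green_agent_never_divides(self, small_geom):
        """Crowding aborts division when all six neighbour sites are taken."""
        centre = (5, 5)
        ring = sorted(neighbours(centre, small_geom))
        sites = [small_geom.site_index(*centre)] + [
            small_geom.site_index(*n) for n in ring
        ]
        phases = [int(Phase.GREEN)] + [int(Phase.RED)] * len(ring)
        state = SimState(small_geom, np.array(sites), np.array(phases))
        rng = np.random.default_rng(13)
        p = params(r=(0.0, 0.0, 5.0))
        for _ in range(200):
            event, _ = gillespie_step(state, p, rng)
            assert event == "division_blocked"
        assert state.n_agents == 7

    def test_waiting_time_is_exponential_in_total_rate(self, small_geom):
        rng = np.random.default_rng(3)
        p = params(r=(2.0, 0.0, 0.0), m=(3.0, 0.0, 0.0))  # total rate 5/h
        dts = []
        for _ in range(3000):
            state = single_agent_state(small_geom)
            _, dt = gillespie_step(state, p, rng)
            dts.append(dt)
        assert np.mean(dts) == pytest.approx(1.0 / 5.0, rel=0.05)


class TestSimulate:
    def test_zero_rates_leave_state_unchanged(self, small_geom):
        state = init_random_strips((4, 2, 2), 60.0, small_geom, seed=2)
        res = simulate(state, params(), SimConfig(duration=48.0, seed=0))
        assert np.array_equal(res.state.agent_site, state.agent_site)
        assert np.array_equal(res.state.agent_phase, state.agent_phase)

    def test_same_seed_bit_reproducible(self, small_geom):
        state = init_random_strips((4, 2, 2), 60.0, small_geom, seed=2)
        p = params(r=(0.1, 0.2, 0.1), m=(2.0, 2.0, 2.0))
        r1 = simulate(state, p, SimConfig(duration=24.0, seed=42))
        r2 = simulate(state, p, SimConfig(duration=24.0, seed=42))
        assert np.array_equal(r1.state.agent_site, r2.state.agent_site)
        assert np.array_equal(r1.state.agent_phase, r2.state.agent_phase)
        assert r1.log == r2.log

    def test_free_agent_mean_move_count(self):
        """A lone walker at M = 1/h makes ≈ 48 successful moves in 48 h
        (every attempt succeeds on an empty lattice away from boundaries)."""
        geom = LatticeGeometry(n_rows=80, n_cols=80, delta=20.0)
        state = single_agent_state(geom, ij=(40, 40))
        p = params(m=(1.0, 0.0, 0.0))
        moves = [
            simulate(state, p, SimConfig(duration=48.0, seed=s)).log["move_successes"]
            for s in range(300)
        ]
        # Poisson(48) mean, 4-sigma Monte Carlo band
        assert abs(np.mean(moves) - 48.0) < 4 * math.sqrt(48.0 / 300)

    def test_exclusion_and_growth_bookkeeping(self):
        """After a crowded growth run the exclusion invariant still holds and
        the agent count grew by exactly the number of successful divisions."""
        geom = LatticeGeometry.from_extent(436.36, 581.78, 20.0)
        state = init_random_strips((13, 4, 13), 66.7, geom, seed=8)
        p = params(r=(0.2, 0.3, 0.25), m=(4.0, 4.0, 4.0))
        res = simulate(state, p, SimConfig(duration=48.0, seed=9))
        res.state.validate()
        assert res.state.n_agents == state.n_agents + res.log["division_successes"]
        assert res.state.n_agents >= state.n_agents

    def test_tracking_stops_at_division_and_times_increase(self):
        geom = LatticeGeometry(n_rows=30, n_cols=30, delta=20.0)
        state = init_random_strips((10, 0, 0), 100.0, geom, seed=4)
        p = params(r=(0.5, 0.5, 0.5), m=(1.0, 1.0, 1.0))
        tracked = select_tracked_cells(state, 5, geom)
        res = simulate(
            state, p, SimConfig(duration=48.0, seed=5, tracked_ids=tuple(tracked))
        )
        assert len(res.records) == len(tracked)
        for rec in res.records:
            assert rec.phases[0] == int(Phase.RED)
            assert np.all(np.diff(rec.times) > 0)
            assert rec.termination in ("divided", "simulation_end")
            if rec.termination == "divided":
                assert rec.phases[-1] == int(Phase.RED)  # back to the start phase

    def test_record_distances_match_kernel_accumulators(self):
        """Path lengths derived from the event records equal the distances
        accumulated inside the compiled event loop."""
        geom = LatticeGeometry(n_rows=30, n_cols=30, delta=20.0)
        state = init_random_strips((8, 0, 0), 100.0, geom, seed=6)
        p = params(r=(0.1, 0.2, 0.1), m=(3.0, 2.0, 1.0))
        tracked = select_tracked_cells(state, 8, geom)
        res = simulate(
            state, p, SimConfig(duration=48.0, seed=7, tracked_ids=tuple(tracked))
        )
        from_records = np.stack([r.phase_path_lengths() for r in res.records])
        np.testing.assert_allclose(from_records, res.phase_distances, atol=1e-9)


class TestSelectTrackedCells:
    def test_blocked_cell_is_not_leading_edge(self):
        """Of two reds in one row left of the midline, only the inner one
        has an unhindered path toward the scratch."""
        geom = LatticeGeometry(n_rows=5, n_cols=20, delta=20.0)
        sites = [geom.site_index(1, 3), geom.site_index(1, 7)]
        state = SimState(geom, np.array(sites), np.array([0, 0]))
        chosen = select_tracked_cells(state, 5, geom)
        assert list(chosen) == [1]  # the agent at column 7

    def test_full_column_next_to_gap_all_qualify(self):
        geom = LatticeGeometry(n_rows=6, n_cols=20, delta=20.0)
        sites = [geom.site_index(i, 4) for i in range(1, 7)]
        state = SimState(geom, np.array(sites), np.zeros(6, dtype=int))
        chosen = select_tracked_cells(state, 10, geom)
        assert sorted(chosen) == list(range(6))

    def test_no_red_agents_raises(self, small_geom):
        state = SimState(
            small_geom, np.array([small_geom.site_index(2, 2)]), np.array([2])
        )
        with pytest.raises(ValueError):
            select_tracked_cells(state, 3, small_geom)
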