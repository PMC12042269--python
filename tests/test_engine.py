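"""KMC engine: rates, move enumeration, selection, time, trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slmassembly import (
    ConfigurationError,
    InteractionParams,
    LatticeState,
    Simulation,
    enumerate_moves,
    make_targets,
    move_rate,
    random_initial_state,
    run_trajectory,
    select_move,
    total_energy,
    waiting_time,
)
from slmassembly.engine import BookkeepingError
from slmassembly.experiments import fixture_small_system

R0 = 2.5e6


class TestMoveRate:
    def test_translation_at_zero_delta_is_r0(self, params_default):
        assert move_rate("translate", 0.0, params_default, 2) == R0

    def test_switch_at_zero_delta_is_4r0_over_mtm1(self, params_default):
        assert move_rate("switch", 0.0, params_default, 2) == 4 * R0
        assert move_rate("switch", 0.0, params_default, 3) == 2 * R0

    @settings(derandomize=True, max_examples=60)
    @given(
        de=st.floats(-20, 20),
        law=st.sampled_from(["symmetric", "metropolis"]),
        kind=st.sampled_from(["translate", "switch"]),
    )
    def test_detailed_balance(self, de, law, kind):
        p = InteractionParams()
        fwd = move_rate(kind, de, p, 2, law)
        bwd = move_rate(kind, -de, p, 2, law)
        assert fwd / bwd == pytest.approx(math.exp(-de), rel=1e-12)

    def test_switch_requires_multiple_targets(self, params_default):
        with pytest.raises(ConfigurationError):
            move_rate("switch", 0.0, params_default, 1)


class TestEnumerateMoves:
    def test_candidate_count(self, targets25, params_default):
        st_ = random_initial_state(15, targets25, 0)
        ms = enumerate_moves(st_, params_default, targets25)
        assert len(ms) == (3 + 2) * 25 == 125

    def test_boxed_in_particle_has_zero_translation_rates(self):
        ts = make_targets(5, 1, shape_spec=(1, 5))
        # plus-shape: particle 0 centred, 1-4 on its four sides
        pos = np.array([[2, 2], [1, 2], [3, 2], [2, 1], [2, 3]])
        st_ = LatticeState(5, pos, np.ones(5, dtype=int))
        ms = enumerate_moves(st_, InteractionParams(), ts)
        assert np.all(ms.rates[0:4] == 0.0)

    def test_isolated_particle_translates_at_r0(self, targets25, params_default):
        pos = np.array([[3 * i, 3 * j] for i in range(5) for j in range(5)])
        st_ = LatticeState(15, pos, np.ones(25, dtype=int))
        # particle 6 sits at (3, 3): all four destinations free and isolated
        rates = enumerate_moves(st_, params_default, targets25).rates[24:28]
        assert np.allclose(rates, R0)


class TestSelectMove:
    def test_bracketing_example(self):
        # rates (1,2,3), u=0.5 -> uQ=3 -> second move (index 1, 0-based)
        cum = np.cumsum([1.0, 2.0, 3.0])
        assert select_move(cum, 0.5) == 1

    def test_zero_rate_moves_never_selected(self, rng):
        cum = np.cumsum([1.0, 0.0, 2.0, 0.0, 3.0])
        for u in np.concatenate([rng.random(2000), [1e-12, 1.0, 1 / 6, 0.5]]):
            if not 0 < u <= 1:
                continue
            assert select_move(cum, float(u)) in (0, 2, 4)

    def test_equal_rates_select_uniformly(self, rng):
        from scipy.stats import chisquare

        cum = np.cumsum(np.ones(8))
        picks = np.array([select_move(cum, float(u)) for u in rng.random(100_000)])
        res = chisquare(np.bincount(picks, minlength=8))
        assert res.pvalue > 1e-3

    def test_stalled_state_raises(self):
        with pytest.raises(RuntimeError):
            select_move(np.array([0.0, 0.0]), 0.5)


class TestWaitingTime:
    def test_uprime_one_gives_zero(self):
        assert waiting_time(100.0, 1.0) == 0.0

    def test_scaling_in_total_rate(self):
        assert waiting_time(2.0, 0.3) == pytest.approx(waiting_time(1.0, 0.3) / 2)

    def test_sample_mean_is_inverse_rate(self):
        from slmassembly import _kernel

        rng = _kernel.seed_state(99)
        q = 4.0e6
        n = 100_000
        draws = np.array([waiting_time(q, _kernel.next_uniform(rng)) for _ in range(n)])
        assert draws.mean() == pytest.approx(1 / q, rel=0.01)


class TestRunTrajectory:
    def test_times_strictly_increasing_and_stride(self, targets25, params_default):
        st_ = random_initial_state(15, targets25, 4)
        tr = run_trajectory(st_, params_default, targets25, 5000, 4, record_stride=10)
        assert np.all(np.diff(tr.times) > 0)
        # initial sample plus one record per stride
        assert len(tr.times) == 5000 // 10 + 1
        assert tr.steps[-1] == 5000

    def test_same_seed_reproduces_run(self, targets25, params_default):
        st_ = random_initial_state(15, targets25, 8)
        a = run_trajectory(st_, params_default, targets25, 3000, 8)
        b = run_trajectory(st_, params_default, targets25, 3000, 8)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.energy, b.energy)

    def test_python_backend_reproduces_kernel(self):
        """The compiled loop and the reference implementation built from
        enumerate_moves/select_move/waiting_time agree move for move."""
        st_, ts, p, _ = fixture_small_system("trap9", seed=3)
        a = run_trajectory(st_, p, ts, 300, 7, record_stride=1, backend="numba")
        b = run_trajectory(st_, p, ts, 300, 7, record_stride=1, backend="python")
        # the per-step integer distances fingerprint the move sequence
        assert np.array_equal(a.distances, b.distances)
        assert np.allclose(a.times, b.times, rtol=1e-9)
        assert np.allclose(a.energy, b.energy, atol=1e-9)

    def test_chunked_run_identical_to_single_advance(self, params_default):
        ts = make_targets(9, 2)
        st_ = random_initial_state(9, ts, 5)
        sim1 = Simulation(st_, params_default, ts, 5, record_stride=1)
        sim1.advance(max_steps=2000, t_cap=2000)
        sim2 = Simulation(st_, params_default, ts, 5, record_stride=1)
        while sim2.n_steps < 2000:
            sim2.advance(max_steps=137, t_cap=2000)
        assert np.array_equal(sim1.records()[0], sim2.records()[0])
        assert np.array_equal(sim1.records()[1], sim2.records()[1])

    def test_incremental_energy_validated_against_recomputation(
        self, params_default
    ):
        ts = make_targets(9, 2)
        st_ = random_initial_state(9, ts, 11)
        # frequent in-kernel checkpoints: any bookkeeping drift would raise
        tr = run_trajectory(
            st_, params_default, ts, 50_000, 11, validate_every=997
        )
        assert tr.n_steps == 50_000

    def test_final_energy_matches_recomputation(self, params_default):
        ts = make_targets(9, 2)
        st_ = random_initial_state(9, ts, 13)
        sim = Simulation(st_, params_default, ts, 13)
        sim.advance(max_steps=20_000, t_cap=20_000)
        assert sim.energy == pytest.approx(
            total_energy(sim.state(), params_default, ts), abs=1e-6
        )

    def test_stop_on_assembly_records_first_passage(self):
        st_, ts, p, system = fixture_small_system("mini9", seed=2)
        tr = run_trajectory(st_, p, ts, 300_000, 2, stop_on_assembly=True)
        if tr.assembled:
            assert tr.first_assembly_time <= tr.t_total
            assert tr.min_distance[-1] == 0
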