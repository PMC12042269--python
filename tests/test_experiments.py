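"""Ensemble statistics, region classification, distance-shock analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from slmassembly.control import ControlledTrajectory, ShockEvent
from slmassembly.engine import Trajectory
from slmassembly.experiments import (
    SystemSpec,
    classify_region,
    distance_shock_analysis,
    equilibrium_scan,
    first_assembly_stats,
    fixture_small_system,
)
from slmassembly.model import ConfigurationError


def _traj(tfas, t_tot, seed=0):
    """Minimal trajectory stub with a known first-assembly outcome."""
    assembled = tfas is not None
    times = np.array([0.0, t_tot])
    return Trajectory(
        times=times,
        energy=np.zeros(2),
        distances=np.zeros((2, 2), dtype=np.int64),
        steps=np.array([0, 10]),
        shock=np.zeros(2, dtype=bool),
        t_total=t_tot,
        n_steps=10,
        first_assembly_time=tfas if assembled else math.nan,
        seed=seed,
        record_stride=1,
    )


class TestFirstAssemblyStats:
    def test_yield_percentage(self):
        trajs = [_traj(1.0, 10.0)] * 3 + [_traj(None, 10.0)] * 7
        res = first_assembly_stats(trajs)
        assert res.sa_percent == pytest.approx(30.0)

    def test_unassembled_runs_sit_at_normalized_one(self):
        trajs = [_traj(4.0, 10.0), _traj(None, 10.0)]
        res = first_assembly_stats(trajs)
        assert res.tfas[1] == 10.0  # T_FAS = T_tot when no assembly
        assert res.t_hat[1] == 1.0

    def test_normalization_by_ensemble_max(self):
        trajs = [_traj(7.0, 10.0), _traj(None, 10.0)]
        res = first_assembly_stats(trajs)
        assert res.t_hat[0] == pytest.approx(0.7)

    def test_assembled_only_mean(self):
        trajs = [_traj(2.0, 10.0), _traj(4.0, 10.0), _traj(None, 10.0)]
        res = first_assembly_stats(trajs)
        assert res.tbar_fas == pytest.approx(3.0)

    def test_no_assemblies_flagged_nan(self):
        res = first_assembly_stats([_traj(None, 10.0)])
        assert math.isnan(res.tbar_fas)

    def test_statistics_invariant_to_ordering(self):
        trajs = [_traj(2.0, 10.0), _traj(None, 10.0), _traj(5.0, 10.0)]
        a = first_assembly_stats(trajs)
        b = first_assembly_stats(trajs[::-1])
        assert a.sa_percent == b.sa_percent
        assert a.median_tfas == b.median_tfas


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "js,region",
        [
            (-3.5, "III"),  # kinetic stagnation: strong binding, abundant traps
            (-2.5, "II"),   # efficient equilibrium self-assembly (optimum)
            (-2.2, "I"),    # unstable nucleation seeds
            (-3.15, "II"),
            (-2.25, "II"),
            (-4.0, "III"),
        ],
    )
    def test_boundaries(self, js, region):
        assert classify_region(js) == region


class TestEquilibriumScan:
    SYSTEM = SystemSpec(n_particles=4, lattice_size=5, m_targets=2, t_cap=500)

    def test_single_point_grid(self):
        res = equilibrium_scan([-2.5], 3, self.SYSTEM, seed=1)
        assert set(res) == {-2.5}
        assert res[-2.5].n == 3

    def test_seeds_disjoint_across_js_values(self):
        res = equilibrium_scan([-2.5, -3.0], 4, self.SYSTEM, seed=1)
        s1 = set(res[-2.5].seeds.tolist())
        s2 = set(res[-3.0].seeds.tolist())
        assert s1 and s2 and not (s1 & s2)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_scan([], 3, self.SYSTEM)


class TestDistanceShockAnalysis:
    @staticmethod
    def _controlled(times, dists, shocks, fa=math.nan):
        tr = Trajectory(
            times=np.asarray(times, dtype=float),
            energy=np.zeros(len(times)),
            distances=np.asarray(dists, dtype=np.int64)[:, None],
            steps=np.arange(len(times)),
            shock=np.zeros(len(times), dtype=bool),
            t_total=float(times[-1]),
            n_steps=len(times),
            first_assembly_time=fa,
            seed=0,
            record_stride=1,
        )
        return ControlledTrajectory(
            trajectory=tr, shocks=shocks, rho=1.4, w1=1.0, w2=2.0
        )

    def test_hand_computed_triplets(self):
        # piecewise-constant distance: 12 before, 20 during, 6 after
        times = [0.0, 2.0, 2.0001, 3.0, 3.0001, 6.0]
        dists = [12, 12, 20, 20, 6, 6]
        ev = ShockEvent(t_on=2.0, t_off=3.0, trigger_trend=0.0, seg_start=0.0)
        records, binned = distance_shock_analysis(
            [self._controlled(times, dists, [ev])]
        )
        assert len(records) == 1
        row = records.iloc[0]
        assert row.d_before == pytest.approx(12.0, rel=1e-3)
        assert row.d_during == pytest.approx(20.0, rel=1e-2)
        assert row.d_after == pytest.approx(6.0, rel=1e-2)
        # <d>_before = 12 falls into the bin centred at 10
        assert set(binned.bin_center) == {10.0}

    def test_after_window_is_next_triggering_segment(self):
        times = [0.0, 10.0]
        dists = [50, 50]
        evs = [
            ShockEvent(t_on=2.0, t_off=3.0, trigger_trend=0.0, seg_start=1.0),
            ShockEvent(t_on=7.0, t_off=8.0, trigger_trend=0.0, seg_start=5.5),
        ]
        records, _ = distance_shock_analysis([self._controlled(times, dists, evs)])
        assert len(records) == 2  # both activations analysed

    def test_post_assembly_activations_excluded(self):
        times = [0.0, 10.0]
        dists = [30, 30]
        evs = [
            ShockEvent(t_on=2.0, t_off=3.0, trigger_trend=0.0, seg_start=1.0),
            ShockEvent(t_on=8.0, t_off=9.0, trigger_trend=0.0, seg_start=7.5),
        ]
        records, _ = distance_shock_analysis(
            [self._controlled(times, dists, evs, fa=5.0)]
        )
        assert len(records) == 1  # the activation after first assembly is dropped

    def test_boxplot_statistics_shape(self, rng):
        runs = []
        for k in range(30):
            before = float(rng.uniform(0, 100))
            times = [0.0, 2.0, 3.0, 6.0]
            dists = [int(before)] * 4
            ev = ShockEvent(t_on=2.0, t_off=3.0, trigger_trend=0.0, seg_start=0.0)
            runs.append(self._controlled(times, dists, [ev]))
        records, binned = distance_shock_analysis(runs)
        assert {"q1", "median", "q3", "whisker_lo", "whisker_hi"} <= set(binned.columns)
        assert set(binned.bin_center) <= {10.0, 30.0, 50.0, 70.0, 90.0}


class TestFixtures:
    def test_known_scenarios_deterministic(self):
        for name in ("toy2", "trap9", "mini9"):
            a = fixture_small_system(name, seed=4)
            b = fixture_small_system(name, seed=4)
            assert np.array_equal(a[0].positions, b[0].positions)
            assert np.array_equal(a[0].states, b[0].states)

    def test_toy2_state_space_enumerable(self):
        state, ts, p, system = fixture_small_system("toy2")
        n_states = 9 * 8  # ordered placements of 2 labelled particles
        assert ts.m_targets == 1 and state.n_particles == 2
        assert n_states <= 200

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            fixture_small_system("nope")
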