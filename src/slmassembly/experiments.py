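"""Experiment orchestration: equilibrium scans, learning, controlled scans,
first-assembly statistics, and the before/during/after distance analysis.

Ensemble conventions: a realization that never assembles within the step
cap contributes its total simulated time T_tot as its first-assembly time
T_FAS and appears at normalised time T^ = 1; the assembly yield SA[%] is
the percentage of realizations that assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .control import ControlConfig, ControlledTrajectory, run_controlled
from .engine import RateLaw, Trajectory, run_trajectory
from .landscape import (
    LearnedControl,
    SegmentEnsemble,
    build_landscape,
    calibrate_w2,
    collect_segments_online,
    find_trap_region,
)
from .model import (
    ConfigurationError,
    InteractionParams,
    LatticeState,
    TargetSet,
    make_targets,
    random_initial_state,
)
from .segmentation import SegmentationConfig

__all__ = [
    "SystemSpec",
    "EnsembleResult",
    "first_assembly_stats",
    "equilibrium_scan",
    "classify_region",
    "learn_control",
    "control_scan",
    "distance_shock_analysis",
    "fixture_small_system",
    "DISTANCE_BIN_CENTERS",
]

#: Region boundaries of the equilibrium T_FAS(J_s) curve (k_BT): III below
#: the lower boundary (kinetic stagnation, abundant traps), II between
#: (efficient self-assembly), I above (unstable nucleation seeds).
REGION_BOUNDARY_III_II = -3.15
REGION_BOUNDARY_II_I = -2.25

DISTANCE_BIN_CENTERS = (10.0, 30.0, 50.0, 70.0, 90.0)
DISTANCE_BIN_HALF_WIDTH = 10.0


@dataclass(frozen=True)
class SystemSpec:
    """One simulated system: sizes, targets and the step cap."""

    n_particles: int = 25
    lattice_size: int = 15
    m_targets: int = 2
    t_cap: int = 50_000_000
    shape_spec: object = "auto"
    target_seed: int = 0

    def targets(self) -> TargetSet:
        return make_targets(
            self.n_particles, self.m_targets, self.shape_spec, self.target_seed
        )


def _spawn_seeds(seed: int, n: int, stream: int = 0) -> np.ndarray:
    """n deterministic, disjoint 31-bit seeds from a root seed."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


@dataclass
class EnsembleResult:
    """Per-realization first-assembly outcomes of one ensemble.

    tfas holds T_FAS in seconds (T_tot for unassembled runs); t_hat is the
    max-normalised value (unassembled runs land at 1); sa_percent is the
    assembly yield; tbar_fas averages only assembled runs (NaN if none).
    """

    tfas: np.ndarray
    assembled: np.ndarray
    t_tot: np.ndarray
    seeds: np.ndarray

    def __post_init__(self) -> None:
        self.tfas = np.asarray(self.tfas, dtype=np.float64)
        self.assembled = np.asarray(self.assembled, dtype=bool)
        self.t_tot = np.asarray(self.t_tot, dtype=np.float64)
        self.seeds = np.asarray(self.seeds, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.tfas)

    @property
    def sa_percent(self) -> float:
        return 100.0 * float(self.assembled.sum()) / self.n

    @property
    def median_tfas(self) -> float:
        return float(np.median(self.tfas))

    @property
    def t_hat(self) -> np.ndarray:
        mx = float(self.tfas.max())
        return self.tfas / mx if mx > 0 else np.zeros_like(self.tfas)

    @property
    def tbar_fas(self) -> float:
        if not self.assembled.any():
            return math.nan
        return float(self.tfas[self.assembled].mean())


def first_assembly_stats(
    trajectories: Sequence[Trajectory],
) -> EnsembleResult:
    """Collect T_FAS, assembled flags and totals from an ensemble of runs."""
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    tfas = np.array(
        [
            tr.first_assembly_time if tr.assembled else tr.t_total
            for tr in trajectories
        ]
    )
    return EnsembleResult(
        tfas=tfas,
        assembled=np.array([tr.assembled for tr in trajectories]),
        t_tot=np.array([tr.t_total for tr in trajectories]),
        seeds=np.array([tr.seed for tr in trajectories]),
    )


def equilibrium_scan(
    js_values: Sequence[float],
    reps: int,
    system: SystemSpec = SystemSpec(),
    *,
    j_weak: float = -1.0,
    seed: int = 0,
    rate_law: RateLaw = "symmetric",
    stop_on_assembly: bool = False,
    record_stride: Optional[int] = None,
    keep_trajectories: bool = False,
):
    """Run ``reps`` seeded equilibrium realizations for every J_s value.

    Seeds are disjoint across J_s values and realizations (one seed stream
    per J_s).  Returns ``{J_s: EnsembleResult}``, or additionally
    ``{J_s: [Trajectory]}`` with ``keep_trajectories``.
    """
    js_values = list(js_values)
    if not js_values:
        raise ValueError("empty J_s grid")
    targets = system.targets()
    results: dict[float, EnsembleResult] = {}
    kept: dict[float, list[Trajectory]] = {}
    for i, js in enumerate(js_values):
        params = InteractionParams(j_strong=js, j_weak=j_weak)
        seeds = _spawn_seeds(seed, reps, stream=i)
        trajs = []
        for s in seeds:
            state = random_initial_state(system.lattice_size, targets, int(s))
            trajs.append(
                run_trajectory(
                    state, params, targets, system.t_cap, int(s),
                    stop_on_assembly=stop_on_assembly,
                    record_stride=record_stride, rate_law=rate_law,
                )
            )
        results[js] = first_assembly_stats(trajs)
        if keep_trajectories:
            kept[js] = trajs
    if keep_trajectories:
        return results, kept
    return results


def classify_region(j_strong: float) -> str:
    """Self-assembly region of a strong-interaction value.

    III (kinetic stagnation, abundant traps) for J_s < -3.15; II (efficient
    equilibrium self-assembly) for -3.15 <= J_s <= -2.25; I (unstable
    nucleation seeds) for J_s > -2.25.
    """
    if j_strong < REGION_BOUNDARY_III_II:
        return "III"
    if j_strong <= REGION_BOUNDARY_II_I:
        return "II"
    return "I"


def learn_control(
    j_strong: float,
    reps: int,
    system: SystemSpec = SystemSpec(),
    *,
    j_weak: float = -1.0,
    seed: int = 0,
    seg_config: SegmentationConfig = SegmentationConfig(),
    rate_law: RateLaw = "symmetric",
    record_stride: Optional[int] = None,
) -> LearnedControl:
    """Learning phase at one J_s: calibrate W2, pool online segments, learn T*.

    Runs an equilibrium ensemble, sets W2 = 0.01 x median(T_FAS), replays
    the near-real-time segmentation over each recorded energy trajectory,
    and extracts the trap region and the dwelling-time landscape from the
    pooled segments.
    """
    results, kept = equilibrium_scan(
        [j_strong], reps, system, j_weak=j_weak, seed=seed,
        rate_law=rate_law, record_stride=record_stride,
        keep_trajectories=True,
    )
    res = results[j_strong]
    w2 = calibrate_w2(res.tfas)
    segments = []
    tags = []
    for k, tr in enumerate(kept[j_strong]):
        segs = collect_segments_online(tr.times, tr.energy, w2, seg_config)
        segments.extend(segs)
        tags.extend([k] * len(segs))
    ensemble = SegmentEnsemble(segments=segments, realization=np.array(tags))
    trap = find_trap_region(ensemble)
    scape = build_landscape(ensemble)
    return LearnedControl(
        j_strong=j_strong, w2=w2, trap_region=trap,
        n_trajectories=res.n, n_segments=len(ensemble),
        seeds=tuple(int(s) for s in res.seeds), landscape=scape,
    )


@dataclass
class ControlScanResult:
    """Controlled-ensemble outcomes over a drive-amplitude grid."""

    results: dict            # rho -> EnsembleResult
    trajectories: dict       # rho -> list[ControlledTrajectory] (may be empty)
    j_strong: float

    @property
    def sa_percent(self) -> dict:
        return {rho: r.sa_percent for rho, r in self.results.items()}

    @property
    def t_tilde(self) -> dict:
        """Mean first-assembly time rescaled by the rho = 1 reference.

        NaN when the reference (or that amplitude) had no assemblies.
        """
        ref = self.results[1.0].tbar_fas
        return {
            rho: (r.tbar_fas / ref if math.isfinite(ref) else math.nan)
            for rho, r in self.results.items()
        }


def control_scan(
    j_strong: float,
    rho_values: Sequence[float],
    learned: LearnedControl,
    reps: int,
    system: SystemSpec = SystemSpec(),
    *,
    j_weak: float = -1.0,
    seed: int = 1000,
    w1: Optional[float] = None,
    relaxation_gap: Optional[float] = None,
    seg_config: Optional[SegmentationConfig] = None,
    rate_law: RateLaw = "symmetric",
    record_stride: Optional[int] = None,
    keep_trajectories: bool = False,
) -> ControlScanResult:
    """Controlled ensembles across drive amplitudes, with the rho = 1
    equilibrium reference always included.

    Realizations are paired across amplitudes: the same seed stream (hence
    the same initial conditions) is reused for every rho.
    """
    rhos = sorted(set(float(r) for r in rho_values) | {1.0})
    targets = system.targets()
    params = InteractionParams(j_strong=j_strong, j_weak=j_weak)
    seeds = _spawn_seeds(seed, reps, stream=10_000)
    results: dict[float, EnsembleResult] = {}
    kept: dict[float, list[ControlledTrajectory]] = {}
    for rho in rhos:
        kw = dict(seg_config=seg_config) if seg_config is not None else {}
        config = ControlConfig.from_learned(
            learned, rho, w1=w1, relaxation_gap=relaxation_gap, **kw
        )
        ctrajs = []
        for s in seeds:
            state = random_initial_state(system.lattice_size, targets, int(s))
            ctrajs.append(
                run_controlled(
                    state, params, targets, config, system.t_cap, int(s),
                    rate_law=rate_law, record_stride=record_stride,
                )
            )
        results[rho] = first_assembly_stats([c.trajectory for c in ctrajs])
        if keep_trajectories:
            kept[rho] = ctrajs
    return ControlScanResult(results=results, trajectories=kept, j_strong=j_strong)


def _time_weighted_mean(
    times: np.ndarray, values: np.ndarray, t0: float, t1: float
) -> float:
    """Mean of a sampled signal over [t0, t1], weighted by time."""
    if not (t1 > t0):
        return math.nan
    inside = (times > t0) & (times < t1)
    xs = np.concatenate([[t0], times[inside], [t1]])
    ys = np.interp(xs, times, values)
    return float(np.trapezoid(ys, xs) / (t1 - t0))


def distance_shock_analysis(
    controlled: Sequence[ControlledTrajectory],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean min-distance before, during and after every drive activation.

    Per activation: <d>_before over the triggering segment, <d>_during over
    the shock interval, and <d>_after over the segment preceding the next
    activation (i.e. the next activation's triggering segment) or, for the
    last activation, the stretch to final assembly / end of run.  Averages
    are time-weighted.  For assembled runs only pre-first-assembly windows
    enter; unassembled runs contribute all their activations.

    Returns ``(records, binned)``: one row per activation, and boxplot
    statistics of <d>_during and <d>_after grouped into five
    <d>_before bins of width 20 centred at 10, 30, 50, 70, 90 (whiskers at
    1.5 x IQR, points beyond them listed as outliers).
    """
    rows = []
    for run_idx, ct in enumerate(controlled):
        tr = ct.trajectory
        if not ct.shocks:
            continue
        t, d = tr.times, tr.min_distance.astype(np.float64)
        fa = tr.first_assembly_time
        horizon = fa if tr.assembled else tr.t_total
        for i, ev in enumerate(ct.shocks):
            if tr.assembled and ev.t_on >= fa:
                continue
            before = _time_weighted_mean(t, d, ev.seg_start, ev.t_on)
            during = _time_weighted_mean(t, d, ev.t_on, min(ev.t_off, horizon))
            if i + 1 < len(ct.shocks):
                nxt = ct.shocks[i + 1]
                after = _time_weighted_mean(
                    t, d, min(nxt.seg_start, horizon), min(nxt.t_on, horizon)
                )
            else:
                after = _time_weighted_mean(t, d, ev.t_off, horizon)
            rows.append(
                {
                    "run": run_idx,
                    "activation": i,
                    "t_on": ev.t_on,
                    "trigger_trend": ev.trigger_trend,
                    "d_before": before,
                    "d_during": during,
                    "d_after": after,
                }
            )
    records = pd.DataFrame(
        rows,
        columns=[
            "run", "activation", "t_on", "trigger_trend",
            "d_before", "d_during", "d_after",
        ],
    )

    stats = []
    for center in DISTANCE_BIN_CENTERS:
        lo = center - DISTANCE_BIN_HALF_WIDTH
        hi = center + DISTANCE_BIN_HALF_WIDTH
        sel = records[(records.d_before >= lo) & (records.d_before < hi)]
        for metric in ("d_during", "d_after"):
            vals = sel[metric].dropna().to_numpy()
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_w = vals[vals >= q1 - 1.5 * iqr].min()
            hi_w = vals[vals <= q3 + 1.5 * iqr].max()
            outliers = vals[(vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)]
            stats.append(
                {
                    "bin_center": center,
                    "metric": metric,
                    "n": len(vals),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "whisker_lo": lo_w,
                    "whisker_hi": hi_w,
                    "outliers": outliers.tolist(),
                }
            )
    binned = pd.DataFrame(
        stats,
        columns=[
            "bin_center", "metric", "n", "q1", "median", "q3",
            "whisker_lo", "whisker_hi", "outliers",
        ],
    )
    return records, binned


_FIXTURES = {
    # name: (N, L, M_T, J_s, J_w, suggested t_cap)
    "toy2": (2, 3, 1, -2.5, -1.0, 1_000_000),
    "trap9": (9, 9, 2, -6.5, -1.0, 100_000),
    "mini9": (9, 9, 2, -2.5, -1.0, 1_000_000),
}


def fixture_small_system(
    spec: str, seed: int = 0
) -> tuple[LatticeState, TargetSet, InteractionParams, SystemSpec]:
    """Registered miniature scenarios for oracles and desk-scale studies.

    ``toy2``: 2 particles on a 3x3 board, one stored domino target — the
    state space is fully enumerable, so long-run occupancies can be checked
    against the exact Boltzmann distribution.
    ``trap9``: 9 particles on a 9x9 board, two 3x3 targets with deep bonds
    (J_s = -6.5) and a 1e5-step cap — misassembled, mixed-state clusters
    are long-lived kinetic traps (equilibrium yield well below 50%), so
    the closed-loop drive has traps to break.  A trap must compete with a
    fast "clock" to be expensive in *steps*: here the near-free state
    switches of bonded particles provide it, which is why the trapped
    fixture stores two targets.
    ``mini9``: 9 particles on a 9x9 board, two 3x3 targets with default
    energies — a reduced version of the standard system.
    """
    if spec not in _FIXTURES:
        raise ConfigurationError(
            f"unknown scenario {spec!r}; known: {sorted(_FIXTURES)}"
        )
    n, L, mt, js, jw, t_cap = _FIXTURES[spec]
    system = SystemSpec(n_particles=n, lattice_size=L, m_targets=mt, t_cap=t_cap)
    targets = system.targets()
    params = InteractionParams(j_strong=js, j_weak=jw)
    state = random_initial_state(L, targets, seed)
    return state, targets, params, system
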