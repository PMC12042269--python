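"""Rejection-free (n-fold way / Gillespie) kinetic Monte Carlo engine.

Each step enumerates all N_tot = 4N + (M_T - 1)N candidate moves — the 4N
single-particle translations first, then the state switches, both
particle-major — computes their rates from the energy change, selects one
proportionally to its rate via the cumulative rate function, and advances
simulated time by an exponential waiting time with the total escape rate Q.

Rate laws (both satisfy detailed balance, rate(dE)/rate(-dE) = exp(-dE)):

* ``symmetric`` (default): r = r0 * exp(-dE / 2)
* ``metropolis``:          r = r0 * min(1, exp(-dE))

State-switch moves carry the prefactor 4 r0 / (M_T - 1) so that switches
and translations of a free particle are equally likely overall when the
initial and final energies coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

import numpy as np
import pandas as pd

from . import model
from .model import (
    DIRECTIONS,
    ConfigurationError,
    InteractionParams,
    LatticeState,
    TargetSet,
    delta_energy,
)

__all__ = [
    "Move",
    "MoveSet",
    "Trajectory",
    "Simulation",
    "move_rate",
    "enumerate_moves",
    "select_move",
    "waiting_time",
    "run_trajectory",
]

RateLaw = Literal["symmetric", "metropolis"]
_RATE_LAWS = {"symmetric": 0, "metropolis": 1}
_DIST_CONVS = {"state_bonds": 0, "hamming": 1}


class BookkeepingError(RuntimeError):
    """Incremental energy/distance bookkeeping diverged from recomputation."""


@dataclass(frozen=True)
class Move:
    """One candidate transition: a translation or an internal-state switch.

    ``payload`` is the destination (row, col) for translations (possibly
    off-board/occupied for forbidden zero-rate candidates) or the new
    1-based state for switches.
    """

    kind: Literal["translate", "switch"]
    particle: int
    payload: tuple


@dataclass
class MoveSet:
    """All candidate moves of one state, in canonical order, with rates."""

    moves: list
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.moves)

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative rate function R_i; the last entry is Q."""
        return np.cumsum(self.rates)

    @property
    def total_rate(self) -> float:
        return float(self.rates.sum())


def move_rate(
    kind: str,
    delta_e: float,
    params: InteractionParams,
    m_targets: int,
    rate_law: RateLaw = "symmetric",
) -> float:
    """Rate (1/s) of a move with energy change ``delta_e`` (k_BT)."""
    if rate_law not in _RATE_LAWS:
        raise ValueError(f"unknown rate law {rate_law!r}")
    if kind == "translate":
        pref = params.r0
    elif kind == "switch":
        if m_targets < 2:
            raise ConfigurationError("no state-switch moves exist for M_T = 1")
        pref = 4.0 * params.r0 / (m_targets - 1)
    else:
        raise ValueError(f"unknown move kind {kind!r}")
    if rate_law == "symmetric":
        return pref * math.exp(-0.5 * delta_e)
    return pref * min(1.0, math.exp(-delta_e))


def enumerate_moves(
    state: LatticeState,
    params: InteractionParams,
    targets: TargetSet,
    rate_law: RateLaw = "symmetric",
) -> MoveSet:
    """Canonical move set: 4N translations then (M_T - 1)N switches.

    Forbidden translations (occupied or off-board destination) are included
    with rate 0 so the ordering is position-independent.
    """
    occ = state.occupancy()
    L = state.lattice_size
    n = state.n_particles
    mt = targets.m_targets
    moves: list[Move] = []
    rates = np.zeros(4 * n + (mt - 1) * n, dtype=np.float64)
    for a in range(n):
        r, c = (int(x) for x in state.positions[a])
        for k, (dr, dc) in enumerate(DIRECTIONS):
            dest = (r + dr, c + dc)
            mv = Move("translate", a, dest)
            moves.append(mv)
            in_board = 0 <= dest[0] < L and 0 <= dest[1] < L
            if in_board and occ[dest] < 0:
                de = delta_energy(state, mv, params, targets)
                rates[4 * a + k] = move_rate("translate", de, params, mt, rate_law)
    for a in range(n):
        s_a = int(state.states[a])
        k = 0
        for s_new in range(1, mt + 1):
            if s_new == s_a:
                continue
            mv = Move("switch", a, s_new)
            moves.append(mv)
            de = delta_energy(state, mv, params, targets)
            rates[4 * n + a * (mt - 1) + k] = move_rate(
                "switch", de, params, mt, rate_law
            )
            k += 1
    return MoveSet(moves=moves, rates=rates)


def select_move(cumulative: np.ndarray, u: float) -> int:
    """Index I with R_{I-1} < u*Q <= R_I (0-based); skips zero-rate moves."""
    if not 0.0 < u <= 1.0:
        raise ValueError("u must lie in (0, 1]")
    q = float(cumulative[-1])
    if q <= 0.0:
        raise RuntimeError("total escape rate is zero: stalled state")
    idx = int(np.searchsorted(cumulative, u * q, side="left"))
    return min(idx, len(cumulative) - 1)


def waiting_time(total_rate: float, u_prime: float) -> float:
    """Exponential waiting time ln(1/u') / Q (s)."""
    if not 0.0 < u_prime <= 1.0:
        raise ValueError("u' must lie in (0, 1]")
    if total_rate <= 0.0:
        raise RuntimeError("total escape rate is zero: stalled state")
    return math.log(1.0 / u_prime) / total_rate


@dataclass
class Trajectory:
    """Strided record of one KMC run.

    ``distances`` has one column per target (the convention used is stored
    in ``distance_convention``); ``shock`` flags samples recorded while a
    transient interaction-energy shock was active (always False for
    equilibrium runs).
    """

    times: np.ndarray           # (n_rec,) s, strictly increasing
    energy: np.ndarray          # (n_rec,) k_BT
    distances: np.ndarray       # (n_rec, M_T)
    steps: np.ndarray           # (n_rec,) global KMC step index
    shock: np.ndarray           # (n_rec,) bool
    t_total: float              # simulated time at the end of the run (s)
    n_steps: int                # KMC steps executed
    first_assembly_time: float  # s; NaN if never assembled
    seed: int
    record_stride: int
    distance_convention: str = "state_bonds"

    @property
    def assembled(self) -> bool:
        return bool(np.isfinite(self.first_assembly_time))

    @property
    def min_distance(self) -> np.ndarray:
        return self.distances.min(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"step": self.steps, "t": self.times, "energy": self.energy}
        )
        for m in range(self.distances.shape[1]):
            df[f"d_{m + 1}"] = self.distances[:, m]
        df["shock"] = self.shock
        return df


class Simulation:
    """Mutable KMC run that can be advanced in chunks.

    The controller uses this to interleave stepping with monitoring epochs
    and parameter shocks; ``run_trajectory`` is a one-shot convenience
    wrapper.  RNG state persists across ``advance`` calls, so the move
    sequence for a given seed does not depend on the chunking.
    """

    def __init__(
        self,
        state: LatticeState,
        params: InteractionParams,
        targets: TargetSet,
        seed: int,
        *,
        rate_law: RateLaw = "symmetric",
        record_stride: int = 1,
        distance_convention: str = "state_bonds",
        validate_every: int = 100_000,
        encode_microstates: bool = False,
    ) -> None:
        from . import _kernel  # deferred: triggers numba compilation lazily

        self._kernel = _kernel
        if targets.n_particles != state.n_particles:
            raise ConfigurationError("state/targets particle count mismatch")
        self.params = params
        self.targets = targets
        self.seed = int(seed)
        self.rate_law = rate_law
        self.record_stride = int(record_stride)
        self.distance_convention = distance_convention
        self.validate_every = int(validate_every)
        self._rate_flag = _RATE_LAWS[rate_law]
        self._dist_flag = _DIST_CONVS[distance_convention]
        self._encode = bool(encode_microstates)

        self.lattice_size = state.lattice_size
        self._pos = state.positions.copy()
        self._occ = state.occupancy()
        self._states0 = state.states.copy() - 1  # 0-based for the kernel
        self._tadj = np.ascontiguousarray(targets.adjacency)
        self._tbonds = targets.bond_counts.astype(np.int64)

        mt = targets.m_targets
        e0 = model.total_energy(state, params, targets)
        d0, _ = model.distance_to_targets(state, targets, distance_convention)
        b_adj = model.board_adjacency(state)
        self._fstate = np.array([e0, 0.0], dtype=np.float64)
        self._istate = np.array([0, int(b_adj.sum()) // 2], dtype=np.int64)
        self._ov = np.zeros(mt, dtype=np.int64)
        self._sat = np.zeros(mt, dtype=np.int64)
        self._mism = np.zeros(mt, dtype=np.int64)
        self._kernel._recompute(
            self._pos, self._occ, self._states0, self._tadj,
            params.j_strong, params.j_weak, self._ov, self._sat, self._mism,
        )
        self._rng = self._kernel.seed_state(self.seed)
        self._fa = np.array([np.nan], dtype=np.float64)
        if float(d0.min()) == 0.0:
            self._fa[0] = 0.0

        self._rec: list[tuple[np.ndarray, ...]] = []
        self._codes: list[np.ndarray] = []
        # initial sample at t = 0
        self._rec.append(
            (
                np.array([0.0]),
                np.array([e0]),
                np.array([0], dtype=np.int64),
                d0[None, :].astype(np.int64),
                np.array([False]),
            )
        )
        if self._encode:
            self._codes.append(np.array([self._encode_now()], dtype=np.int64))
        self.shock_active = False
        self.status: Optional[int] = None

    # -- basic accessors -------------------------------------------------
    @property
    def time(self) -> float:
        return float(self._fstate[1])

    @property
    def energy(self) -> float:
        return float(self._fstate[0])

    @property
    def n_steps(self) -> int:
        return int(self._istate[0])

    @property
    def first_assembly_time(self) -> float:
        return float(self._fa[0])

    @property
    def assembled(self) -> bool:
        return bool(np.isfinite(self._fa[0]))

    def state(self) -> LatticeState:
        return LatticeState(
            self.lattice_size, self._pos.copy(), self._states0.copy() + 1
        )

    def _encode_now(self) -> int:
        L = self.lattice_size
        mt = self.targets.m_targets
        code = 0
        for a in range(len(self._pos)):
            code = code * (L * L) + int(self._pos[a, 0] * L + self._pos[a, 1])
        for a in range(len(self._pos)):
            code = code * mt + int(self._states0[a])
        return code

    def set_params(self, params: InteractionParams) -> None:
        """Swap interaction energies mid-run (the controller's shock).

        The stored total energy is a function of the parameters, so it is
        recomputed under the new ones; positions, states and the RNG stream
        are untouched.
        """
        self.params = params
        e, bonds = self._kernel._recompute(
            self._pos, self._occ, self._states0, self._tadj,
            params.j_strong, params.j_weak, self._ov, self._sat, self._mism,
        )
        self._fstate[0] = e
        self._istate[1] = bonds

    # -- stepping --------------------------------------------------------
    def advance(
        self,
        *,
        max_steps: int,
        t_cap: int,
        t_stop: float = np.inf,
        stop_on_assembly: bool = False,
    ) -> int:
        """Run until t >= t_stop, the global step cap, the chunk budget, or
        (optionally) first assembly.  Returns a ``_kernel.STATUS_*`` code."""
        k = self._kernel
        max_steps = int(min(max_steps, max(0, t_cap - self.n_steps)))
        cap = max_steps // self.record_stride + 2
        rec_t = np.empty(cap)
        rec_e = np.empty(cap)
        rec_step = np.empty(cap, dtype=np.int64)
        rec_d = np.empty((cap, self.targets.m_targets), dtype=np.int64)
        rec_code = np.empty(cap if self._encode else 0, dtype=np.int64)
        rec_n = np.zeros(1, dtype=np.int64)
        status = k.run_chunk(
            self._pos, self._occ, self._states0, self._tadj, self._tbonds,
            self.params.j_strong, self.params.j_weak, self.params.r0,
            self._rate_flag, self._dist_flag,
            self._fstate, self._istate, self._ov, self._sat, self._mism,
            t_cap, max_steps, t_stop, stop_on_assembly,
            self._rng,
            rec_t, rec_e, rec_step, rec_d, rec_n, self.record_stride,
            rec_code, self._fa, self.validate_every,
        )
        if status == k.STATUS_BOOKKEEPING:
            raise BookkeepingError(
                f"incremental bookkeeping check failed at step {self.n_steps} "
                f"(seed {self.seed}); state dump: {self.state().to_json()}"
            )
        m = int(rec_n[0])
        if m:
            self._rec.append(
                (
                    rec_t[:m].copy(),
                    rec_e[:m].copy(),
                    rec_step[:m].copy(),
                    rec_d[:m].copy(),
                    np.full(m, self.shock_active),
                )
            )
            if self._encode:
                self._codes.append(rec_code[:m].copy())
        self.status = status
        return status

    def records(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(times, energy, steps, distances, shock) concatenated so far."""
        ts = np.concatenate([r[0] for r in self._rec])
        es = np.concatenate([r[1] for r in self._rec])
        ks = np.concatenate([r[2] for r in self._rec])
        ds = np.concatenate([r[3] for r in self._rec])
        sh = np.concatenate([r[4] for r in self._rec])
        return ts, es, ks, ds, sh

    def microstate_codes(self) -> np.ndarray:
        if not self._encode:
            raise RuntimeError("simulation was created without microstate encoding")
        return np.concatenate(self._codes)

    def trajectory(self) -> Trajectory:
        ts, es, ks, ds, sh = self.records()
        return Trajectory(
            times=ts, energy=es, distances=ds, steps=ks, shock=sh,
            t_total=self.time, n_steps=self.n_steps,
            first_assembly_time=self.first_assembly_time,
            seed=self.seed, record_stride=self.record_stride,
            distance_convention=self.distance_convention,
        )


def _auto_stride(t_cap: int, max_records: int = 20_000) -> int:
    return max(1, int(t_cap) // max_records)


def run_trajectory(
    initial_state: LatticeState,
    params: InteractionParams,
    targets: TargetSet,
    t_cap: int,
    seed: int,
    *,
    stop_on_assembly: bool = False,
    record_stride: Optional[int] = None,
    rate_law: RateLaw = "symmetric",
    distance_convention: str = "state_bonds",
    validate_every: int = 100_000,
    backend: Literal["numba", "python"] = "numba",
) -> Trajectory:
    """Run one equilibrium KMC trajectory of at most ``t_cap`` steps.

    ``t_cap`` counts KMC steps (not seconds).  With ``stop_on_assembly``
    the run ends at the first step where min_m d_m = 0; the first-assembly
    time is recorded either way.  The ``python`` backend is a slow
    reference implementation built from :func:`enumerate_moves`,
    :func:`select_move` and :func:`waiting_time`; it consumes the same RNG
    stream and reproduces the compiled backend move for move.
    """
    if t_cap < 1:
        raise ConfigurationError("t_cap must be at least 1")
    if record_stride is None:
        record_stride = _auto_stride(t_cap)
    if backend == "python":
        return _run_python(
            initial_state, params, targets, t_cap, seed,
            stop_on_assembly=stop_on_assembly, record_stride=record_stride,
            rate_law=rate_law, distance_convention=distance_convention,
        )
    sim = Simulation(
        initial_state, params, targets, seed,
        rate_law=rate_law, record_stride=record_stride,
        distance_convention=distance_convention, validate_every=validate_every,
    )
    sim.advance(max_steps=t_cap, t_cap=t_cap, stop_on_assembly=stop_on_assembly)
    return sim.trajectory()


def _run_python(
    initial_state, params, targets, t_cap, seed, *,
    stop_on_assembly, record_stride, rate_law, distance_convention,
) -> Trajectory:
    from . import _kernel

    state = initial_state.copy()
    rng = _kernel.seed_state(seed)
    t = 0.0
    e = model.total_energy(state, params, targets)
    fa = np.nan
    rec = [(0.0, e, 0)]
    rec_d = [model.distance_to_targets(state, targets, distance_convention)[0]]
    step = 0
    while step < t_cap:
        ms = enumerate_moves(state, params, targets, rate_law)
        cum = ms.cumulative
        q = float(cum[-1])
        u = _kernel.next_uniform(rng)
        idx = select_move(cum, u)
        u2 = _kernel.next_uniform(rng)
        dt = waiting_time(q, u2)
        mv = ms.moves[idx]
        e += delta_energy(state, mv, params, targets)
        if mv.kind == "translate":
            state.positions[mv.particle] = mv.payload
        else:
            state.states[mv.particle] = mv.payload
        t += dt
        step += 1
        d, dmin = model.distance_to_targets(state, targets, distance_convention)
        if dmin == 0 and not np.isfinite(fa):
            fa = t
        if step % record_stride == 0:
            rec.append((t, e, step))
            rec_d.append(d)
        if dmin == 0 and stop_on_assembly:
            break
    ts, es, ks = (np.asarray(x) for x in zip(*rec))
    return Trajectory(
        times=ts, energy=es, distances=np.asarray(rec_d),
        steps=ks.astype(np.int64), shock=np.zeros(len(ts), dtype=bool),
        t_total=t, n_steps=step, first_assembly_time=fa,
        seed=seed, record_stride=record_stride,
        distance_convention=distance_convention,
    )
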