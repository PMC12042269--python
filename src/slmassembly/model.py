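"""Lattice self-assembly model: particles, encoded targets, energies, distances.

The system is a bounded L x L square lattice populated by N distinguishable
particles.  Each particle carries an internal state s_a in {1, .., M_T}
selecting which of the M_T encoded target structures it currently "commits"
to.  A target is stored as the nearest-neighbour adjacency matrix I^m of a
particular spatial arrangement of all N particles; the targets are the
global energy minima of the model.

Pairwise energies (in units of k_B T, with k_B T = 1) between particles that
are currently lattice neighbours:

* strong attraction J_s when the pair is a target bond in the state-targets
  of both particles,
* weak attraction J_w when it is a target bond in neither,
* the intermediate value J_w + (J_s - J_w)/2 when in exactly one,

which is summarised by the affine form

    J(a, b) = J_w + (J_s - J_w)/2 * (I^{s_a}(a, b) + I^{s_b}(a, b)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DIRECTIONS",
    "InteractionParams",
    "TargetSet",
    "LatticeState",
    "make_targets",
    "board_adjacency",
    "pair_interaction",
    "total_energy",
    "delta_energy",
    "distance_to_targets",
    "random_initial_state",
]

#: Canonical direction order for single-particle translations: up, down,
#: left, right in (row, col) coordinates.  The KMC move ordering depends on it.
DIRECTIONS = ((-1, 0), (1, 0), (0, -1), (0, 1))

#: Distance conventions available behind :func:`distance_to_targets`.
DISTANCE_CONVENTIONS = ("state_bonds", "hamming")


class ConfigurationError(ValueError):
    """Raised for infeasible model configurations."""


@dataclass(frozen=True)
class InteractionParams:
    """Interaction energies (k_BT units) and the base attempt rate r0 (1/s).

    Defaults correspond to the standard simulation conditions: J_s = -2.5,
    J_w = -1, r0 = 2.5e6 1/s (the inverse time for a free particle to
    diffuse one lattice spacing).
    """

    j_strong: float = -2.5
    j_weak: float = -1.0
    r0: float = 2.5e6

    def __post_init__(self) -> None:
        if not (self.j_strong < self.j_weak < 0):
            raise ConfigurationError(
                f"interaction energies must satisfy J_s < J_w < 0, "
                f"got J_s={self.j_strong}, J_w={self.j_weak}"
            )
        if not self.r0 > 0:
            raise ConfigurationError(f"r0 must be positive, got {self.r0}")

    @property
    def j_intermediate(self) -> float:
        """Energy of a pair that is a target bond for exactly one partner."""
        return self.j_weak + 0.5 * (self.j_strong - self.j_weak)


@dataclass(frozen=True)
class TargetSet:
    """M_T encoded target structures over N labelled particles.

    adjacency : (M_T, N, N) uint8, symmetric 0/1 with zero diagonal; entry
        (m, a, b) = 1 iff particles a and b are nearest neighbours in the
        placement of target m.
    placements : (M_T, N, 2) int64, the (row, col) tile of each particle in
        the canonical realisation of each target.
    """

    adjacency: np.ndarray
    placements: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.uint8)
        plc = np.asarray(self.placements, dtype=np.int64)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "placements", plc)
        mt, n, n2 = adj.shape
        if n != n2 or plc.shape != (mt, n, 2):
            raise ConfigurationError("inconsistent adjacency/placement shapes")
        for m in range(mt):
            a = adj[m]
            if np.any(np.diag(a)):
                raise ConfigurationError(f"target {m}: nonzero diagonal")
            if not np.array_equal(a, a.T):
                raise ConfigurationError(f"target {m}: adjacency not symmetric")
            if not np.array_equal(a, _placement_adjacency(plc[m])):
                raise ConfigurationError(
                    f"target {m}: adjacency does not match placement"
                )
            if n > 1 and not _is_connected(a):
                raise ConfigurationError(f"target {m}: bond graph not connected")
        for m in range(mt):
            for m2 in range(m + 1, mt):
                if np.array_equal(adj[m], adj[m2]):
                    raise ConfigurationError(
                        f"targets {m} and {m2} have identical adjacency"
                    )

    @property
    def n_particles(self) -> int:
        return self.adjacency.shape[1]

    @property
    def m_targets(self) -> int:
        return self.adjacency.shape[0]

    @property
    def bond_counts(self) -> np.ndarray:
        """Number of (unordered) bonds in each target."""
        return self.adjacency.sum(axis=(1, 2)) // 2

    def assembled_state(self, m: int, lattice_size: int) -> "LatticeState":
        """The canonical fully assembled configuration of target ``m``."""
        if lattice_size * lattice_size < self.n_particles:
            raise ConfigurationError("lattice too small for target placement")
        return LatticeState(
            lattice_size=lattice_size,
            positions=self.placements[m].copy(),
            states=np.full(self.n_particles, m + 1, dtype=np.int64),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_particles": self.n_particles,
                "m_targets": self.m_targets,
                "bonds": [
                    [[int(a), int(b)] for a, b in zip(*np.nonzero(np.triu(adj)))]
                    for adj in self.adjacency
                ],
                "placements": self.placements.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TargetSet":
        obj = json.loads(text)
        n = obj["n_particles"]
        adj = np.zeros((obj["m_targets"], n, n), dtype=np.uint8)
        for m, bonds in enumerate(obj["bonds"]):
            for a, b in bonds:
                adj[m, a, b] = adj[m, b, a] = 1
        return cls(adjacency=adj, placements=np.asarray(obj["placements"]))


@dataclass
class LatticeState:
    """Positions and internal states of the N particles on the L x L board.

    positions : (N, 2) int64 (row, col), injective, all within [0, L)^2.
    states : (N,) int64, values in {1, .., M_T}.
    """

    lattice_size: int
    positions: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int64)
        L = self.lattice_size
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ConfigurationError("positions must have shape (N, 2)")
        if np.any(self.positions < 0) or np.any(self.positions >= L):
            raise ConfigurationError("positions out of lattice bounds")
        tiles = self.positions[:, 0] * L + self.positions[:, 1]
        if len(np.unique(tiles)) != len(tiles):
            raise ConfigurationError("two particles share a tile")
        if len(self.states) != len(self.positions):
            raise ConfigurationError("states/positions length mismatch")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def occupancy(self) -> np.ndarray:
        """(L, L) int64 grid: particle label at each tile, -1 if empty."""
        occ = np.full((self.lattice_size, self.lattice_size), -1, dtype=np.int64)
        occ[self.positions[:, 0], self.positions[:, 1]] = np.arange(
            self.n_particles
        )
        return occ

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.lattice_size, self.positions.copy(), self.states.copy()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "lattice_size": self.lattice_size,
                "positions": self.positions.tolist(),
                "states": self.states.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LatticeState":
        obj = json.loads(text)
        return cls(
            lattice_size=obj["lattice_size"],
            positions=np.asarray(obj["positions"]),
            states=np.asarray(obj["states"]),
        )


def _placement_adjacency(placement: np.ndarray) -> np.ndarray:
    d = np.abs(placement[:, None, :] - placement[None, :, :]).sum(axis=-1)
    return (d == 1).astype(np.uint8)


def _is_connected(adjacency: np.ndarray) -> bool:
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        a = stack.pop()
        for b in np.nonzero(adjacency[a])[0]:
            if not seen[b]:
                seen[b] = True
                stack.append(int(b))
    return bool(seen.all())


def _block_shape(n_particles: int, shape_spec) -> tuple[int, int]:
    if isinstance(shape_spec, tuple):
        rows, cols = shape_spec
        if rows * cols != n_particles:
            raise ConfigurationError(
                f"shape {shape_spec} does not hold {n_particles} particles"
            )
        return rows, cols
    if shape_spec != "auto":
        raise ConfigurationError(f"unknown shape spec {shape_spec!r}")
    for rows in range(int(np.sqrt(n_particles)), 0, -1):
        if n_particles % rows == 0:
            return rows, n_particles // rows
    raise ConfigurationError("cannot factor particle count")  # pragma: no cover


def _block_orders(rows: int, cols: int):
    """Deterministic labelling orders of an rows x cols block of tiles."""
    cells_row_major = [(i, j) for i in range(rows) for j in range(cols)]

    boustro = []
    for i in range(rows):
        js = range(cols) if i % 2 == 0 else range(cols - 1, -1, -1)
        boustro.extend((i, j) for j in js)

    col_major = [(i, j) for j in range(cols) for i in range(rows)]

    spiral = []
    top, bottom, left, right = 0, rows - 1, 0, cols - 1
    while top <= bottom and left <= right:
        spiral.extend((top, j) for j in range(left, right + 1))
        spiral.extend((i, right) for i in range(top + 1, bottom + 1))
        if top < bottom:
            spiral.extend((bottom, j) for j in range(right - 1, left - 1, -1))
        if left < right:
            spiral.extend((i, left) for i in range(bottom - 1, top, -1))
        top, bottom, left, right = top + 1, bottom - 1, left + 1, right - 1

    return [cells_row_major, boustro, spiral, col_major]


def make_targets(
    n_particles: int,
    m_targets: int = 2,
    shape_spec="auto",
    seed: int = 0,
) -> TargetSet:
    """Construct ``m_targets`` compact-block targets with distinct adjacency.

    Target 1 labels the block in row-major order; further targets reuse the
    same footprint with different deterministic labelling orders
    (boustrophedon, spiral, column-major), falling back to seeded random
    label permutations when those coincide or run out.  The footprint is the
    most-square rows x cols factorisation of N (a perfect square gives a
    sqrt(N) x sqrt(N) block); ``shape_spec`` may also be an explicit
    ``(rows, cols)`` tuple.
    """
    if m_targets < 1:
        raise ConfigurationError("need at least one target")
    if n_particles < 1:
        raise ConfigurationError("need at least one particle")
    rows, cols = _block_shape(n_particles, shape_spec)

    rng = np.random.default_rng(seed)
    placements: list[np.ndarray] = []
    adjacencies: list[np.ndarray] = []

    def try_add(order: Sequence[tuple[int, int]]) -> bool:
        plc = np.asarray(order, dtype=np.int64)
        adj = _placement_adjacency(plc)
        if any(np.array_equal(adj, prev) for prev in adjacencies):
            return False
        placements.append(plc)
        adjacencies.append(adj)
        return True

    candidates = _block_orders(rows, cols)
    for order in candidates:
        if len(placements) == m_targets:
            break
        try_add(order)

    attempts = 0
    base = np.asarray(candidates[0], dtype=np.int64)
    while len(placements) < m_targets:
        attempts += 1
        if attempts > 1000:
            raise ConfigurationError(
                f"cannot build {m_targets} distinct targets for N={n_particles}"
            )
        perm = rng.permutation(n_particles)
        try_add(base[perm])

    return TargetSet(
        adjacency=np.stack(adjacencies), placements=np.stack(placements)
    )


def board_adjacency(state: LatticeState) -> np.ndarray:
    """(N, N) uint8: 1 iff the two particles occupy edge-sharing tiles."""
    d = np.abs(
        state.positions[:, None, :] - state.positions[None, :, :]
    ).sum(axis=-1)
    adj = (d == 1).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


def pair_interaction(
    params: InteractionParams,
    targets: TargetSet,
    a: int,
    b: int,
    s_a: int,
    s_b: int,
) -> float:
    """Pairwise energy of currently adjacent particles a and b (k_BT).

    Symmetric under (a, s_a) <-> (b, s_b).  States are 1-based.
    """
    if a == b:
        raise ValueError("a particle does not interact with itself")
    ia = int(targets.adjacency[s_a - 1, a, b])
    ib = int(targets.adjacency[s_b - 1, a, b])
    return params.j_weak + 0.5 * (params.j_strong - params.j_weak) * (ia + ib)


def total_energy(
    state: LatticeState, params: InteractionParams, targets: TargetSet
) -> float:
    """Total energy: sum of pair interactions over adjacent (unordered) pairs."""
    adj = board_adjacency(state)
    e = 0.0
    for a, b in zip(*np.nonzero(np.triu(adj))):
        e += pair_interaction(
            params, targets, int(a), int(b), int(state.states[a]), int(state.states[b])
        )
    return e


def _local_energy(
    state: LatticeState,
    params: InteractionParams,
    targets: TargetSet,
    a: int,
    tile: tuple[int, int],
    s_a: int,
    occ: np.ndarray,
) -> float:
    """Energy of particle ``a`` (state ``s_a``) with neighbours of ``tile``."""
    L = state.lattice_size
    e = 0.0
    for dr, dc in DIRECTIONS:
        r, c = tile[0] + dr, tile[1] + dc
        if 0 <= r < L and 0 <= c < L:
            b = occ[r, c]
            if b >= 0 and b != a:
                e += pair_interaction(
                    params, targets, a, int(b), s_a, int(state.states[b])
                )
    return e


def delta_energy(state, move, params: InteractionParams, targets: TargetSet) -> float:
    """Energy change of a candidate move, from the local neighbourhood only.

    ``move`` is an :class:`slmassembly.engine.Move`; translations carry the
    destination tile as payload, state switches the new (1-based) state.
    Raises ``ValueError`` for illegal moves (off-board or occupied
    destination, non-adjacent destination, out-of-range or identity switch).
    """
    occ = state.occupancy()
    a = move.particle
    if not 0 <= a < state.n_particles:
        raise ValueError(f"no particle {a}")
    s_a = int(state.states[a])
    r, c = (int(x) for x in state.positions[a])
    if move.kind == "translate":
        nr, nc = move.payload
        L = state.lattice_size
        if not (0 <= nr < L and 0 <= nc < L):
            raise ValueError("destination off the board")
        if occ[nr, nc] >= 0:
            raise ValueError("destination occupied")
        if abs(nr - r) + abs(nc - c) != 1:
            raise ValueError("destination not adjacent to particle")
        e_old = _local_energy(state, params, targets, a, (r, c), s_a, occ)
        e_new = _local_energy(state, params, targets, a, (nr, nc), s_a, occ)
        return e_new - e_old
    if move.kind == "switch":
        s_new = int(move.payload)
        if not 1 <= s_new <= targets.m_targets:
            raise ValueError(f"state {s_new} out of range")
        if s_new == s_a:
            raise ValueError("switch to the current state is not a move")
        e_old = _local_energy(state, params, targets, a, (r, c), s_a, occ)
        e_new = _local_energy(state, params, targets, a, (r, c), s_new, occ)
        return e_new - e_old
    raise ValueError(f"unknown move kind {move.kind!r}")


def distance_to_targets(
    state: LatticeState,
    targets: TargetSet,
    convention: str = "state_bonds",
) -> tuple[np.ndarray, float]:
    """Per-target distances d_m and the minimum distance d = min_m d_m.

    Both conventions count ordered adjacency mismatches between the board
    and target m plus the number of particles whose state differs from m,
    and satisfy d_m = 0 iff the board exactly realises target m with all
    states equal to m.  They differ in when a board bond is credited to
    target m:

    ``state_bonds`` (default, calibrated against the random-initialisation
        ensemble mean): a bond (a, b) counts toward target m only when it is
        a target-m bond *and* both particles hold state m — the same
        condition under which the bond is energetically strong for a single
        target.
    ``hamming``: plain entrywise comparison of the board adjacency matrix
        with I^m, ignoring states in the bond term.
    """
    if convention not in DISTANCE_CONVENTIONS:
        raise ValueError(f"unknown distance convention {convention!r}")
    b_adj = board_adjacency(state)
    mt = targets.m_targets
    d = np.empty(mt, dtype=np.int64)
    n_bonds_board = int(b_adj.sum()) // 2
    for m in range(mt):
        t_adj = targets.adjacency[m]
        n_bonds_target = int(t_adj.sum()) // 2
        mismatched_states = int(np.sum(state.states != m + 1))
        if convention == "hamming":
            credit = int((b_adj & t_adj).sum()) // 2
        else:
            in_state = state.states == m + 1
            mask = np.outer(in_state, in_state)
            credit = int((b_adj & t_adj & mask).sum()) // 2
        d[m] = (
            2 * (n_bonds_board + n_bonds_target - 2 * credit) + mismatched_states
        )
    return d, float(d.min())


def random_initial_state(
    lattice_size: int, targets: TargetSet, seed: int
) -> LatticeState:
    """Particles uniformly placed on distinct tiles, states uniform in 1..M_T."""
    n = targets.n_particles
    if n > lattice_size * lattice_size:
        raise ConfigurationError(
            f"{n} particles do not fit on a {lattice_size}x{lattice_size} board"
        )
    rng = np.random.default_rng(seed)
    tiles = rng.choice(lattice_size * lattice_size, size=n, replace=False)
    positions = np.stack([tiles // lattice_size, tiles % lattice_size], axis=1)
    states = rng.integers(1, targets.m_targets + 1, size=n)
    return LatticeState(lattice_size, positions, states)
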