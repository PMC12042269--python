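"""Lattice model: targets, energies, distances, random initialisation."""

import numpy as np
import pytest

from slmassembly import (
    ConfigurationError,
    InteractionParams,
    LatticeState,
    Move,
    delta_energy,
    distance_to_targets,
    make_targets,
    pair_interaction,
    random_initial_state,
    total_energy,
)
from slmassembly.model import board_adjacency


class TestMakeTargets:
    def test_square_block_bond_count(self, targets25):
        # a 5x5 grid graph has 2*5*4 = 40 edges
        assert list(targets25.bond_counts) == [40, 40]
        for m in range(2):
            adj = targets25.adjacency[m]
            assert np.array_equal(adj, adj.T)
            assert not np.diag(adj).any()

    def test_single_particle_empty_adjacency(self):
        ts = make_targets(1, 1)
        assert ts.adjacency.sum() == 0

    def test_targets_distinct(self, targets25):
        assert not np.array_equal(targets25.adjacency[0], targets25.adjacency[1])

    def test_deterministic_given_seed(self):
        a = make_targets(9, 4, seed=5)
        b = make_targets(9, 4, seed=5)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_infeasible_raises(self):
        with pytest.raises(ConfigurationError):
            make_targets(1, 2)  # two distinct targets need at least one bond


class TestPairInteraction:
    def test_strong_same_state_target_bond(self, targets25, params_default):
        a, b = 0, 1  # horizontal neighbours in the row-major block: bond in both
        assert targets25.adjacency[0, a, b] == 1
        assert pair_interaction(params_default, targets25, a, b, 1, 1) == -2.5

    def test_weak_when_bond_in_no_target(self, targets25, params_default):
        a, b = 0, 24  # opposite corners: not a bond anywhere
        assert targets25.adjacency[:, a, b].sum() == 0
        assert pair_interaction(params_default, targets25, a, b, 1, 2) == -1.0

    def test_intermediate_when_bond_in_one_state_target(self, params_default):
        # vertical pairs differ between row-major and boustrophedon labellings
        ts = make_targets(25, 2)
        a, b = 0, 5  # bond in target 1 only
        assert ts.adjacency[0, a, b] == 1 and ts.adjacency[1, a, b] == 0
        assert pair_interaction(params_default, ts, a, b, 1, 2) == pytest.approx(-1.75)

    def test_strong_for_mixed_states_bond_in_both(self, targets25, params_default):
        a, b = 0, 1  # horizontal bond shared by both labellings
        assert targets25.adjacency[1, a, b] == 1
        assert pair_interaction(params_default, targets25, a, b, 1, 2) == -2.5

    def test_symmetry(self, targets25, params_default, rng):
        for _ in range(200):
            a, b = rng.choice(25, size=2, replace=False)
            sa_, sb_ = rng.integers(1, 3, size=2)
            assert pair_interaction(
                params_default, targets25, int(a), int(b), int(sa_), int(sb_)
            ) == pair_interaction(
                params_default, targets25, int(b), int(a), int(sb_), int(sa_)
            )


class TestTotalEnergy:
    def test_no_adjacent_pairs_zero(self, targets25, params_default):
        pos = np.array([[2 * i, 2 * j] for i in range(5) for j in range(5)])
        st_ = LatticeState(15, pos, np.ones(25, dtype=int))
        assert total_energy(st_, params_default, targets25) == 0.0

    def test_perfect_assembly_energy(self, targets25, params_default):
        for m in range(2):
            st_ = targets25.assembled_state(m, 15)
            assert total_energy(st_, params_default, targets25) == pytest.approx(
                40 * -2.5
            )

    def test_full_assembly_equals_bondcount_times_js(self):
        ts = make_targets(6, 2)
        p = InteractionParams(j_strong=-3.3)
        for m in range(2):
            st_ = ts.assembled_state(m, 8)
            assert total_energy(st_, p, ts) == pytest.approx(
                int(ts.bond_counts[m]) * -3.3
            )


class TestDeltaEnergy:
    def test_isolated_particle_moves_free(self, targets25, params_default):
        pos = np.array([[3 * i, 3 * j] for i in range(5) for j in range(5)])
        st_ = LatticeState(15, pos, np.ones(25, dtype=int))
        mv = Move("translate", 0, (0, 1))
        assert delta_energy(st_, mv, params_default, targets25) == 0.0

    def test_switch_without_neighbours_free(self, targets25, params_default):
        pos = np.array([[3 * i, 3 * j] for i in range(5) for j in range(5)])
        st_ = LatticeState(15, pos, np.ones(25, dtype=int))
        mv = Move("switch", 3, 2)
        assert delta_energy(st_, mv, params_default, targets25) == 0.0

    def test_matches_full_recomputation(self, targets25, params_default, rng):
        """Local-update delta equals the difference of two total energies."""
        for _ in range(300):
            st_ = random_initial_state(8, targets25, int(rng.integers(2**31)))
            occ = st_.occupancy()
            a = int(rng.integers(25))
            if rng.random() < 0.5:
                r, c = st_.positions[a]
                dr, dc = [(-1, 0), (1, 0), (0, -1), (0, 1)][int(rng.integers(4))]
                dest = (int(r + dr), int(c + dc))
                if not (0 <= dest[0] < 8 and 0 <= dest[1] < 8) or occ[dest] >= 0:
                    continue
                mv = Move("translate", a, dest)
                after = st_.copy()
                after.positions[a] = dest
            else:
                s_new = 1 if st_.states[a] == 2 else 2
                mv = Move("switch", a, s_new)
                after = st_.copy()
                after.states[a] = s_new
            de = delta_energy(st_, mv, params_default, targets25)
            full = total_energy(after, params_default, targets25) - total_energy(
                st_, params_default, targets25
            )
            assert de == pytest.approx(full, abs=1e-9)

    def test_illegal_moves_raise(self, targets25, params_default):
        st_ = targets25.assembled_state(0, 15)
        with pytest.raises(ValueError):
            delta_energy(st_, Move("translate", 0, (0, 1)), params_default, targets25)
        with pytest.raises(ValueError):
            delta_energy(st_, Move("translate", 0, (-1, 0)), params_default, targets25)
        with pytest.raises(ValueError):
            delta_energy(st_, Move("switch", 0, 1), params_default, targets25)
        with pytest.raises(ValueError):
            delta_energy(st_, Move("switch", 0, 7), params_default, targets25)


class TestDistance:
    def test_zero_iff_assembled(self, targets25):
        st_ = targets25.assembled_state(0, 15)
        d, dmin = distance_to_targets(st_, targets25)
        assert d[0] == 0 and dmin == 0

    def test_one_broken_bond_costs_two(self):
        ts = make_targets(2, 1)
        st_ = LatticeState(5, np.array([[0, 0], [0, 3]]), np.array([1, 1]))
        d, _ = distance_to_targets(st_, ts)
        assert d[0] == 2  # two ordered adjacency entries flip

    @pytest.mark.parametrize("convention", ["state_bonds", "hamming"])
    def test_nonnegative_and_state_term(self, targets25, convention, rng):
        for _ in range(50):
            st_ = random_initial_state(15, targets25, int(rng.integers(2**31)))
            d, dmin = distance_to_targets(st_, targets25, convention)
            assert (d >= 0).all()
            assert dmin == d.min()
            # the state-mismatch term alone forbids d_m = 0 for mixed states
            for m in range(2):
                if (st_.states != m + 1).any():
                    assert d[m] > 0


class TestRandomInitialState:
    def test_deterministic(self, targets25):
        a = random_initial_state(15, targets25, 7)
        b = random_initial_state(15, targets25, 7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.states, b.states)

    def test_full_board_still_injective(self):
        ts = make_targets(9, 2)
        st_ = random_initial_state(3, ts, 0)
        assert len(np.unique(st_.positions[:, 0] * 3 + st_.positions[:, 1])) == 9

    def test_overfull_board_raises(self):
        ts = make_targets(9, 2)
        with pytest.raises(ConfigurationError):
            random_initial_state(2, ts, 0)

    def test_tile_occupancy_uniform(self, targets25):
        from scipy.stats import chisquare

        counts = np.zeros(15 * 15)
        n_draws = 4000
        for s in range(n_draws):
            st_ = random_initial_state(15, targets25, s)
            tiles = st_.positions[:, 0] * 15 + st_.positions[:, 1]
            counts[tiles] += 1
        res = chisquare(counts)
        assert res.pvalue > 1e-3

    def test_board_adjacency_row_sums(self, targets25):
        st_ = random_initial_state(15, targets25, 3)
        adj = board_adjacency(st_)
        assert np.array_equal(adj, adj.T)
        assert adj.sum(axis=0).max() <= 4
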