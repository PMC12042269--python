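"""Targets, pair energies, total energy and the distance-to-target metric.

Builds the standard system (25 particles, two 5x5 targets on a 15x15
board) and prints the energies of the three bond classes, the energy of a
perfect assembly, and the distance of a random initial configuration.
"""

import slmassembly as sa

targets = sa.make_targets(25, 2)
params = sa.InteractionParams()  # J_s=-2.5, J_w=-1 (k_BT), r0=2.5e6/s

print("bonds per target:", [int(b) for b in targets.bond_counts])

# bond (0,1) is a target bond in both labellings; (0,5) only in the first;
# (0,24) in neither
print("strong (shared bond, matching states):",
      sa.pair_interaction(params, targets, 0, 1, 1, 1))
print("intermediate (bond in one state-target):",
      sa.pair_interaction(params, targets, 0, 5, 1, 2))
print("weak (bond in no target):",
      sa.pair_interaction(params, targets, 0, 24, 1, 2))

assembled = targets.assembled_state(0, 15)
print("energy of perfect assembly:", sa.total_energy(assembled, params, targets),
      "(= 40 bonds x J_s)")

state = sa.random_initial_state(15, targets, seed=1)
d, dmin = sa.distance_to_targets(state, targets)
print("random start: per-target distances", [int(x) for x in d], "-> min", dmin)
print("(0 means fully assembled; random starts sit near 100)")
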