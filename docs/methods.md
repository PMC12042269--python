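# Methods

## Model

`slm-assembly` simulates the self-assembly of `N` distinguishable particles
on a bounded `L x L` square lattice (hard walls, 0-based `(row, col)`
coordinates). Each particle `a` carries an internal state
`s_a in {1, .., M_T}` that selects which of `M_T` stored target structures
it currently commits to. A target `m` is encoded as the nearest-neighbour
adjacency matrix `I^m` (over particle labels) of a particular placement of
all `N` particles; the fully assembled targets are the global energy
minima.

Currently adjacent particles interact with

```
J(a, b) = J_w + (J_s - J_w)/2 * (I^{s_a}(a,b) + I^{s_b}(a,b))
```

which realises three rules: the strong attraction `J_s` when the pair is a
target bond in the state-targets of both partners (including partners in
different states whose pair is a bond in both those targets), the weak
attraction `J_w` when it is a bond in neither, and the midpoint
`(J_s + J_w)/2` when in exactly one. The total energy is the sum over
currently adjacent unordered pairs. All energies are in units of
`k_B T = 1`; defaults are `J_s = -2.5`, `J_w = -1`.

Default targets are compact blocks (the most-square `rows x cols`
factorisation of `N`; a perfect square gives a `sqrt(N) x sqrt(N)` block)
with deterministic distinct labelling orders (row-major, boustrophedon,
spiral, column-major, then seeded permutations). Distinctness of the
adjacency matrices is enforced.

## Kinetic Monte Carlo

Dynamics are rejection-free n-fold-way KMC (equivalently Gillespie). Each
step enumerates `N_tot = 4N + (M_T - 1)N` candidates — four translations
per particle, then the state switches, particle-major — with rates

```
translations:  r = r0 * exp(-dE / 2)
switches:      q = (4 r0 / (M_T - 1)) * exp(-dE / 2)
```

where `dE` is the energy change of the candidate and
`r0 = 2.5e6 s^-1` is the attempt rate (the inverse time for a free
particle to diffuse one lattice spacing); translations into occupied or
off-board tiles carry rate 0. The symmetric exponent is the default rate
law; a Metropolis variant `r0 * min(1, exp(-dE))` is available behind the
`rate_law` switch. Both satisfy detailed balance
`rate(dE)/rate(-dE) = exp(-dE)` exactly. The switch prefactor makes
switches and translations of a free particle equally likely overall when
`dE = 0`. A move is selected by the index `I` with
`R_{I-1} < uQ <= R_I` on the cumulative rate function (`u in (0,1]`), and
time advances by `dt = ln(1/u') / Q`. `T_cap` caps the number of KMC
*steps*, not seconds.

Energy and the per-target distances are maintained incrementally and
revalidated against full recomputation inside the compiled kernel every
`validate_every` steps (tolerance `1e-6 k_BT`; any mismatch aborts the
run). One explicit xorshift64\* RNG per trajectory (seeded through
splitmix64, draw order `u` then `u'`) makes runs bit-reproducible and
independent of how the driver chunks the loop — which is what lets a
controlled run at `rho = 1` be bit-identical to the equilibrium run with
the same seed. A slow pure-Python reference loop built from the public
`enumerate_moves` / `select_move` / `waiting_time` operations consumes the
same RNG stream and is used in tests as an independent implementation of
the step logic.

## Distance to target

`d_m` counts ordered adjacency mismatches between the board and target `m`
plus the number of particles whose state differs from `m`; `d = min_m d_m`
and `d_m = 0` iff the board exactly realises target `m` with all states
`m`. Two conventions for when a board bond is credited to target `m` sit
behind `distance_to_targets(..., convention=...)`:

* `state_bonds` (default): a bond counts toward target `m` only when it is
  a target-`m` bond *and* both partners hold state `m` — the condition
  under which the bond is energetically strong for a single target.
* `hamming`: plain entrywise comparison of the adjacency matrices.

The default was fixed by the random-initialisation calibration: over
seeded random configurations of the standard system (`N = 25`, `L = 15`,
two targets) the mean minimum distance is ~99.5 under `state_bonds`
(within 2% of the 101.6 reference calibration) versus ~97.6 under `hamming`
(3.9% off). Both remain available.

## Trend segmentation

The monitoring layer models the energy trajectory as noisy segments with
stable linear trends separated by abrupt changepoints. A window is
resampled onto a uniform grid (`n_grid`, default 1000; windows with fewer
samples use their own sample count) and segmented by exact
dynamic-programming optimal partitioning: per-segment cost is the OLS
line-fit SSE (O(1) per candidate via prefix sums), plus a per-changepoint
penalty, with a minimum segment length (default 10 grid points). The
default penalty is BIC-type, `3 * sigma^2 * ln(n)`, with `sigma` estimated
robustly from second differences (MAD), so noiseless signals are segmented
essentially exactly. The engine sits behind a small interface
(`segment_series`) so a Bayesian changepoint engine could be substituted;
the contract is the segment decomposition, not a particular posterior.
Trends are in `k_BT` per second of simulated time; negative trend =
assembly progress.

`latest_trend` implements the near-real-time protocol: at each monitoring
epoch the partial window from the last confirmed changepoint to "now" is
segmented, interior changepoints are confirmed, and the trend `t*` of the
final (open) segment is reported. Windows with fewer than
`min_window_samples` (default 8) samples return a no-decision sentinel,
treated as "not trapped".

## Learning phase

For one `J_s`: run an equilibrium ensemble (default 288 trajectories at
full scale, configurable down; desk studies here use 40-50), record
`T_FAS` per realization (unassembled runs contribute `T_tot`), and set the
monitoring interval `W2 = 0.01 * median(T_FAS)`. The online monitoring is
then replayed over each recorded energy trajectory to pool segments; from
the pooled trends and dwelling times the package builds the stochastic
landscape (21-bin mean dwelling time vs trend, piecewise-linear
interpolation — diagnostic only) and the trap region
`T* = [-tau, +tau]`: the smallest symmetric interval around zero trend
containing 20-21% of the segments. The inclusion fraction is a step
function of `tau`, so the bisection target is solved exactly on the order
statistics of `|trend|`; when ties make the band unattainable the closest
fraction is returned with a flag.

## Closed-loop drive

Every `W2` seconds of simulated time the controller evaluates `t*`; if
`t*` lies in `T*`, no shock is active, and the relaxation gap since the
previous shock has elapsed, a shock starts: both interaction energies are
divided by the drive amplitude `rho >= 1` (`r0` unchanged) for a duration
`W1`, then restored. Defaults: `W1 = W2/2` (inside the stated bound
`W1 < 0.01 * median(T_FAS)`) and relaxation gap `= W2`; both are exposed
in `ControlConfig`. Parameter switches take effect at the first KMC event
on or after the nominal boundary (events are discrete); recorded shock
intervals carry the nominal `[t_on, t_on + W1)`. The stored total energy
is recomputed at each switch since it is a function of the parameters.
Segmentation state persists across shocks and shocked samples are part of
the analysed window by default (`mask_shocks` inverts this).

## Ensemble statistics and the distance analysis

`T_FAS` is the first time `min_m d_m = 0` (else `T_tot`); `T^` is the
per-ensemble max-normalised value (unassembled runs at 1); `SA[%]` is the
assembled percentage; `T-bar` averages assembled runs only; `T~(rho)`
rescales by the `rho = 1` reference. The equilibrium `T_FAS(J_s)` curve
divides into regions III / II / I (strong-binding stagnation / efficient /
unstable seeds) at the boundaries -3.15 and -2.25.

The before/during/after analysis assigns each activation a triplet of
time-weighted mean minimum distances: over the triggering segment, the
shock interval, and the segment preceding the next activation (for the
last activation: the stretch to first assembly or end of run). Assembled
runs contribute only pre-assembly windows. Triplets are grouped by
`<d>_before` into five bins of width 20 centred at 10..90 and summarised
as boxplot statistics (quartiles, 1.5 IQR whiskers, outliers listed).

## Miniature fixtures and what desk-scale results show

Registered scenarios (`fixture_small_system`):

* `toy2` — 2 particles, `L = 3`, one domino target: 72 enumerable
  microstates; simulated time-weighted occupancy is checked against the
  exact Boltzmann distribution (total-variation distance < 0.05 at 1e6
  steps).
* `trap9` — 9 particles, `L = 9`, two 3x3 targets, `J_s = -6.5`,
  `T_cap = 1e5`: misassembled mixed-state clusters are long-lived traps
  and the equilibrium yield is ~30%. A trap is expensive *in steps* only
  when slow escapes compete against fast near-zero-`dE` moves; with a
  single stored target and few particles no such clock exists (a fully
  bonded cluster rearranges in O(1) steps however deep the bonds), which
  is why the trapped fixture stores two targets — the near-free state
  switches of bonded particles provide the clock, and are themselves the
  trap mechanism of the multi-target model.
* `mini9` — the same geometry at default energies, used for identity and
  consistency checks.

Desk-scale studies in the test suite use: 24 realizations x 1e6 steps for
the reduced equilibrium scan (the convex `median T_FAS(J_s)` check uses
J_s in {-6.5, -4.5, -3.0}; at `N = 9` a 3x3 target has 12 bonds against
40 for 5x5, so the optimal binding strength sits near -4.5, deeper than
the full-size optimum of -2.5), 40 learning realizations, and 120 paired
controlled realizations per drive amplitude. These sizes were chosen as
the smallest ensembles that resolve the directional effects cleanly.
Passing desk-scale tests shows the machinery (rates, bookkeeping,
segmentation, learning, triggering) is correct and that the drive's
trap-escape mechanism operates; it does not by itself reproduce
full-scale yield numbers, which require the standard system
(`N = 25`, `T_cap = 5e7`, 48-288 reps; `examples/full_scale_protocol.py`
runs that protocol unchanged, at a cost of CPU-days).

## Numerical choices

* Move selection skips zero-rate candidates exactly (strict bracketing on
  the cumulative rate function); a float round-off at the very top of the
  cumulative sum falls back to the last positive-rate move.
* `u, u' in (0, 1]` are generated as `(k + 1) * 2^-53` from the top 53
  bits of the xorshift64* stream, so `log(u')` is always finite.
* DP segmentation ties are broken toward fewer changepoints via a tiny
  penalty floor; `argmin` prefers the earliest equal-cost split start.
* Trap-region degeneracies (atomic trend distributions) return the
  closest achievable fraction flagged `band_attained = False`.
* Recording is strided (default ~20k samples per run) and the per-target
  distances are recorded alongside energy; the first-assembly time is
  detected every step regardless of stride.

## Known limitations

* Single-particle moves only: no cluster moves, so large-cluster mobility
  is underestimated relative to models with collective moves.
* The segmentation engine is an optimal-partitioning stand-in for a
  Bayesian changepoint method: contract-equivalent (same segment
  decomposition task), not numerically identical to any particular
  Bayesian implementation, and it reports no posterior uncertainty.
* `W1` and the relaxation gap are package defaults (`W2/2` and `W2`);
  only the bound `W1 < W2` is externally constrained.
* The distance convention is fixed by a single reference calibration
  value; other conventions consistent with "compare adjacency matrices"
  remain admissible and are kept behind the same interface.
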