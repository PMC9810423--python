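# Methods

## Model

A cell population of integer size `N` evolves in discrete time steps.
Each cell uses one of two metabolic modes `m ∈ {def, aggr}` with
intrinsic per-step birth/death rates `(β_m, δ_m)`; defaults

| mode       | β     | δ     | β−δ  | 1/δ    | β/δ   |
|------------|-------|-------|------|--------|-------|
| defensive  | 0.025 | 0.005 | 0.02 | 200    | 5     |
| aggressive | 0.125 | 0.075 | 0.05 | ~13.33 | ~1.67 |

so the defensive mode maximizes survival (lifetime `1/δ`) and the
aggressive mode maximizes instantaneous net growth — a growth–survival
trade-off (`0 < δ_def < δ_aggr`, `0 < β_def−δ_def < β_aggr−δ_aggr`,
validated by `validate_config`).

Density regulation acts only on death: at population size `N` the
effective rates are `β̃ = β_m` and `δ̃ = δ_m + (β_m − δ_m)·N/K`, so net
per-capita growth is exactly `(β_m − δ_m)(1 − N/K)` — zero at the
carrying capacity `K` (default 500).  One step draws
`births ~ Poisson(N β̃)` and `deaths ~ Poisson(N δ̃)` independently;
the increment is therefore Skellam distributed.  `N = 0` absorbs
(extinction), and the state grid is truncated at `ceil(K·l)` with the
head-room factor `l = 1.5` chosen so that the mass reaching the top
states is negligible (`propagate` warns when the top five states carry
more than 1e−9 of probability; at the defaults they carry effectively
none).  The time step is the unit of time throughout.

## Exact kernels and propagation

Transition rows are exact: the destination probability is the Skellam
pmf of the increment, with all outcomes ≤ 0 absorbed into state 0 and
all outcomes above the grid lumped onto the top state (each row sums to
1 to machine precision).  Rows are built by FFT convolution of the two
Poisson pmfs — the definition of the Skellam law — in blocks whose
temporaries stay small; log-pmf terms below e⁻⁶⁰ are flushed to exact
zeros to keep the arrays free of subnormals.  The scalar `skellam_pmf`
instead uses the exponentially scaled Bessel form
`exp(−(μ₁+μ₂) + 2√(μ₁μ₂) + k/2·log(μ₁/μ₂))·ive(|k|, 2√(μ₁μ₂))`.
Both routes are verified in the tests against a truncated Poisson
double-sum oracle (agreement ≤ 1e−12) and against each other.

Distributions are pushed forward by the master equation
`P_{t+1} = P_t W`, selecting each state's row from the defensive or
aggressive kernel according to the strategy — equivalent to (and tested
against) the vector–matrix product with the strategy-induced matrix.

## Optimal control

The expected gain `J(N, t)` is the expected final size under the
optimal policy with boundary `J(N, T) = N`; backward induction over the
full grid compares both modes' expected one-step-ahead gains and keeps
the argmax.  Exact floating-point ties go to the defensive
(lower-variance) mode, which also fixes the absorbing state's label.
No intermediate-time rewards and no switching costs are modelled.

Numerical caveats worth knowing:

* At community density exactly `K` the two modes' gains are equal up to
  rounding (~1e−11), so the stored mode there is decided by float noise.
  Comparisons against the greedy rule (defensive iff `N > K`) are made
  where the gain margin exceeds 1e−9.
* The solved maps genuinely assign the defensive mode at sizes of order
  1 even for short horizons (the absorbing boundary makes survival
  dominant there), and — in biculture — the aggressive mode at focal
  size 1 above community capacity (the extinction floor truncates
  losses, rewarding variance).  Neither sliver is a lag regime; the
  package therefore defines "the map has a lag region"
  (`has_lag_region`) as the low-density defensive region reaching the
  inoculum size `N_initial` (default 10).

With that definition the maps change regime with the cycle length: no
lag region at `T = 150`, a distinct one at `T = 300` whose extent in
time grows by `T = 750`.

*Lag time* is the median first step at which a simulated trajectory
under the map is assigned the aggressive mode (default 1000 replicates
from `N_initial`; re-entries ignored; trajectories that never switch,
including extinct ones, count as non-switching, and an unresolved median
returns NaN as the "no switch within horizon" sentinel).  The lag curve
solves one control problem per cycle length on the grid
100…1500 and is zero for short cycles, grows with `T`, and plateaus
(lag 49 at both `T = 1200` and `T = 1500` at the defaults).

## Serial transfer and competition

A serial-transfer experiment chains fixed-length growth cycles; at each
boundary either a fixed proportion of every phenotype is transferred
(rounded half-up; default 20%) or a fixed founder total is drawn
multinomially from the final frequencies (default 50 = 0.1 K; the
"fixed 0.1 K (50 individuals)" protocol is read as 50 founders in
total, configurable).  In a biculture both phenotypes' intensities are
computed from the same pre-update joint state; each phenotype's death
rate uses the community density `(N_a + N_c)/K`.  Outcomes are
classified after the final cycle's growth, before any further transfer:
win/loss require the opponent (only) to be extinct.

The *anticipative* phenotype uses the control tensor: for every frozen
competitor size `c` the monoculture problem is re-solved with density
`(N + c)/K`.  Slice `c = 0` is bit-identical to the monoculture map
because the monoculture solver *is* the `c = 0` slice of the same
batched routine.  The *greedy* phenotype is the tensor's terminal
slice: defensive iff `N_a + N_c > K`, symmetric and time-invariant.
The *biculture-optimal* phenotype folds the competitor's full dynamics
into a backward induction over joint states `(N_a, N_c)` (product of
the two Skellam kernels, competitor's mode fixed by its — necessarily
time-invariant — strategy).  The joint solver works on the full
rectangle `[0, ceil(K·l)]²`, matching the simulator's per-phenotype
caps, and refuses state spaces beyond a configurable memory budget
(default 2 GB; in practice `K ≲ 120`).

## Problem sizes and design choices

* The headline competition (anticipative vs aggressive) runs at full
  scale: `K = 500`, cycle length 300 (the intermediate map regime; the
  canonical description does not pin the value), 7 cycles, 20%
  transfers, equal initial sizes of 50.  Under these conditions the
  anticipative phenotype wins ~43% and loses ~15% of 2000 runs
  (~42% coexist), a clear majority of decided runs.
* Cycle-length sweep checks use 2000 simulations per point at full
  scale (`K = 500`): short-cycle parity at `T = 40`, and the
  anticipative-vs-pure and greedy-vs-anticipative orderings at
  `T = 300` (reusing the one solved tensor; one cycle length per
  regime rather than a dense grid).  Reducing `K` instead is *not*
  neutral for every pairing: at `K = 100` with 10 founders the lag
  region is large relative to the inoculum and the anticipative
  phenotype loses its edge over the pure aggressive one, so the
  orderings are asserted only at full scale.
* The biculture-optimal claim is asserted as exact dominance (expected
  final focal size under exact joint propagation, `K = 30`) rather than
  as a win-fraction difference: the published sweeps average 20 000
  runs per point, and the margin ("slightly better than greedy") is far
  inside Monte-Carlo noise at desk scale.  The joint optimum also
  switches to the defensive mode at community densities strictly below
  `K` — earlier than the frozen-competitor tensor — which the tests
  assert on the solved tensors.
* Monte-Carlo replicate counts (1000 for lag estimates, 2000 for
  outcome fractions, 10⁵ for distribution-level agreement) were chosen
  so that the assertions' statistical margins are several times the
  binomial/TV noise at those counts.

## What the generator does not emulate

Simulations and kernels share one idealized model: no resource
dynamics or media depletion within a cycle, no switching costs or
sensing costs, no mutation of the rates, at most two phenotypes, and
mode decisions that depend only on the current (joint) state.  Passing
tests therefore validate the control theory and its implementation, not
the biological completeness of the model; in particular lag emerges
here purely from demographic stochasticity, which is a minimal — not an
exhaustive — explanation of observed lag phases.

## Known limitations

* The anticipative tensor at full scale costs one Bellman solve per
  competitor size (~5 minutes at `K = 500`, `T = 300` on one core);
  competitions themselves are cheap.
* The joint-optimal solver is exact but `O(n⁴)` per step in the state
  count `n`, hence restricted to reduced capacities.
* Batch competitions draw from one seeded generator in lock-step; they
  are reproducible as a batch, but run `i` of a batch is not the same
  stream as a single run seeded individually.
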