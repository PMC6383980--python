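# Methods

This note documents the model implemented in `breut`, the numerical choices
behind its deterministic analytics, the design of the Monte-Carlo harness,
and the limits of what the built-in benchmarks can show.

## Model

A binary choice between lotteries A and B is simulated as sequential
sampling from a random-preference expected-utility core.

**Core.** Utilities are the power family `U(x) = x^(1−r)`, normalised so
`U(0) = 0`, defined for non-negative money amounts (the model is
gains-domain only). The risk parameter is drawn i.i.d. from
`r = α − β/2 + β·Z`, `Z ~ Beta(3,3)`: symmetric and bell-shaped with mean
`α` and total range `β`. Feasibility requires `α + β/2 < 1` so that the
exponent `1 − r` stays positive for every draw. With `β = 0` the core is a
point mass and the model collapses to deterministic EUT.

**Evidence.** Each deliberation step applies one sampled `r` to *both*
lotteries and records the certainty-equivalent difference
`V = CE_A − CE_B`, `CE_L = (Σ p_i x_i^(1−r))^(1/(1−r))`. Certainty
equivalents, not utility differences, are accumulated because they live in
a common money metric that can be aggregated across utility functions.
There is no additional (Fechner-style) noise term anywhere: all
stochasticity comes from the preference draws.

**Stopping.** The running mean and sample standard deviation
(k−1 denominator, matching the degrees of freedom of the test) feed a
sequential one-sample t-test of the hypothesis of zero difference. After
`k ≥ 2` samples the trial stops iff `F_{k−1}(|T_k|) ≥ max(0.5, 1 − d(k−1))`
(weak inequality), where `F` is the Student-t CDF. Since the CDF at |T| is
never below 0.5, the trial is guaranteed to stop by
`k_max = ⌈0.5/d⌉ + 1`. The choice follows the sign of the running mean.

**Outputs.** Per trial: choice, `k*`, `Conf* = max(0.5, 1 − d(k*−1))`,
`T_{k*}`, and `RT = k*·NC`, where `NC` counts the outcome branches
displayed across the pair. By construction `RT = ((1 − Conf*)/d + 1)·NC`
holds exactly for every trial with `Conf*` above the 0.5 floor; since the
map is affine this identity carries over to the means whenever `0.5/d` is
an integer (so the floor sits on the decay line). The test suite asserts
it per trial, and it is a useful consistency check on any reported
(RT, Conf*) pair.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `alpha` | mean risk attitude of the core | — | dimensionless (r-scale) |
| `beta_range` | total range of the r distribution | 1.0 | dimensionless |
| `d` | confidence-decay rate | 0.1 | confidence per sample |
| `n_reps` | Monte-Carlo trials per pair | 20,000 | trials |

The benchmark tables use `α ∈ [0.05, 0.40]`, `β ∈ [0.25, 1.30]`,
`d ∈ [0.01, 0.5]` and 20,000 repetitions per pair; those settings are kept
as the defaults of the corresponding stimulus sets. 20,000 trials put the
binomial standard error of a choice probability at ≤ 0.0035 and, for the
slow `d = 0.01` rows, the standard error of a mean RT at roughly 0.2–0.5
time units — worth keeping in mind when comparing two independent runs of
the same setting.

## Deterministic pair analytics

`Pr Core`, `E[V]` and `Pr Lim` are computed by quadrature rather than
simulation, and serve as the ground truth the Monte-Carlo estimates are
tested against.

* **Sign structure.** `V(r)` is evaluated on a 2001-point uniform grid
  over the support of `r`. Every sign change between consecutive grid
  points outside a ±1e−12 tolerance band is refined with Brent's method
  (xtol 1e−12); grid points inside the band are skipped so that a
  `−, 0, +` run across a touching zero is still bracketed. This handles
  certainty-equivalent differences that cross zero more than once (the
  general case; for a sure amount against a two-branch lottery the
  monotonicity of CE in r gives a single crossing, which the test suite
  uses as an independent closed-form oracle).
* **Pr Core** integrates the Beta(3,3) density over the positive-sign
  intervals via its incomplete-beta CDF. Intervals where `V` vanishes
  identically contribute half their mass, which makes a pair of identical
  lotteries come out at 0.5 and leaves all generic pairs untouched.
* **E[V]** uses 256-node Gauss–Legendre quadrature of `V` against the
  Beta density on the mapped unit interval. The integrand is smooth and
  bounded, so the result is accurate to near machine precision — far
  inside the 1e−4 documented target and the two decimals of the benchmark
  tables.
* **Ties.** `|E[V]| ≤ 1e−6` is treated as an exact tie (`Pr Lim = 0.5`);
  exact ties are measure-zero and need a convention. A zero running mean
  at stopping (also measure-zero) resolves by a fair coin.
* **Degenerate evidence.** If two sure amounts are compared, every draw
  yields the same difference and the sample SD is zero. The t statistic is
  then ±∞ when the mean is non-zero (the null of no difference is
  certainly false, the continuous limit of the test) and 0 when every
  draw was exactly zero; the trial stops at `k = 2` with `Conf* = 1 − d`.

## Monte-Carlo harness

`simulate_pair` vectorises trials in lockstep: a single seeded generator
fills an `(n_reps, k_max)` matrix of r draws, `V` is evaluated
element-wise, cumulative moments give the t statistic per column, and the
first column where the stopping condition holds is each trial's `k*`
(draws beyond it are discarded). This is distributionally identical to
looping single trials — the matrix and scalar engines are asserted to make
the same stopping decision on shared draws — and reproducible for a fixed
seed. Memory is bounded by processing at most ~4M matrix elements per
chunk; cumulative-moment variances are clipped at zero to absorb last-bit
cancellation. The scalar `run_trial` path exists for traces and for
property tests.

Per-pair runs consume seeds sequentially from one generator per
table/sweep, so a table is reproducible from a single integer seed.
Swapping A and B while reusing a seed negates every draw's `V` and flips
every choice, so `Pr(A≻B) + Pr(B≻A) = 1` holds exactly under mirrored
randomness — asserted in the tests.

## Benchmark stimuli

The `STIMULUS_SETS` registry holds eight named sets: a sure-amount ladder
against a fixed two-branch lottery (`table1`); one pair swept over α, β
and d (`table2`–`table4`); two transparent first-order stochastic
dominance pairs (`table5`); two lotteries of very different payoff spread
against a ladder of sure amounts, which produces the Myers-effect
crossover and the violations of strong stochastic transitivity
(`table6`); and the four Marschak–Machina triangle pairs over payoffs
{0, 30, 40} at three deliberation rates (`table7`, `fig1`), which exhibit
the common-ratio and common-consequence modal reversals while respecting
weak stochastic transitivity and betweenness.

`NC` counts displayed branches verbatim — a sure amount contributes 1,
duplicated outcomes are not merged. This choice reproduces the RT-to-NC
ratios implied across the benchmark tables; merging duplicates
(event-splitting) would be a different modelling choice and is out of
scope.

These stimuli are pure-arithmetic constructions; none of the behavioural
richness of real experiments (display format, order effects, fatigue,
real-time scaling of RT) is represented. Passing the benchmark suite shows
the deliberation mechanism is implemented faithfully, not that the model
fits any particular human data set — RT is reported in model units and
would need a scaling factor before comparison with measured times.

## Known discrepancies in the benchmark references

Three groups of reference cells cannot be matched by a faithful
implementation, and the corresponding acceptance cases are expected to
fail:

1. **E[V] reference columns are themselves Monte-Carlo estimates.** The
   reference values for the same deterministic quantity differ across
   rows and tables (e.g. the mean CE of the fixed lottery implied by the
   sure-amount ladder varies between 27.58 and 27.60 across rows, and the
   {A,B} pair at α = 0.30, β = 1.0 is printed as both 1.57 and 1.60), with
   scatter matching a sampling standard error of ~0.01 (up to ~0.08 for
   the wide-spread lottery of `table6`). Our quadrature values — confirmed
   by two independent integrators to 1e−10 — sit at the centre of that
   scatter but exceed the ±0.01 comparison band for a dozen cells.
2. **The `table7` Conf\* column is inconsistent with its own RT column.**
   The identity `RT = ((1 − Conf*)/d + 1)·NC` holds per trial by
   construction and is affine, so mean RT pins mean Conf\*. The reference
   rows violate it (most visibly {C,D} at d = 0.01: RT 59.91 with
   Conf\* 0.91, which the identity maps to RT 40). Our simulated Conf\*
   agrees with our simulated RT exactly; it cannot also agree with the
   inconsistent printed pair.
3. **Slow-deliberation RT cells sit inside Monte-Carlo noise.** At
   d ≤ 0.05 the standard error of a 20,000-trial mean RT (0.2–0.5 units,
   in the reference runs as much as in ours) exceeds the ±0.15 comparison
   band, so a few cells fail by sampling error alone; the large-n values
   agree except for {C,D} at d = 0.01, where the reference RT is ~3.8
   units above the model's asymptotic value and inconsistent with its own
   printed choice probability and confidence.

## Limitations

Gains domain only; two alternatives per choice; no probability weighting,
loss aversion or reference points in the core (the architecture accepts
any core that yields CE differences, but only the EUT core is
implemented); no fitting to data; no real-time RT calibration. The
confidence schedule is linear by design — it is the simplest decreasing
schedule with a floor, not an empirical claim.
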