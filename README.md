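# breut

**Boundedly rational expected utility**: a simulator of deliberative binary
choice between monetary lotteries that predicts not only *what* a decision
maker chooses, but *how long* she deliberates and *how confident* she is.

## The problem

Classic expected utility theory (EUT) is deterministic: one utility function,
one answer, instantly. Real choices between lotteries are probabilistic
(the same person picks differently on different occasions), take variable
amounts of time, and come with varying degrees of confidence. This package
implements a process model that produces all three behavioural variables
from an orthodox EUT core embedded in a boundedly rational deliberation
procedure — and, in doing so, generates several classic "anomalies"
(common-ratio and common-consequence effects, violations of strong
stochastic transitivity) without ever departing from EU preferences.

## The model

A decision maker's underlying preferences are a *population* of power
utility functions

    U(x) = x^(1−r),    r < 1,

with the risk-attitude parameter drawn from a transformed Beta distribution

    r ~ α − β/2 + β · Beta(3,3),

a symmetric bell on [α−β/2, α+β/2] with mean α and range β (β = 0 recovers
deterministic EUT with r = α). One deliberation step samples a single r,
applies it to **both** lotteries of a pair {A, B}, and records the
certainty-equivalent difference

    V(A,B) = CE_A − CE_B,    CE_L = (Σᵢ pᵢ xᵢ^(1−r))^(1/(1−r)).

Steps accumulate; after k ≥ 2 samples the running mean V̄ and sample
standard deviation s_V form the one-sample t statistic
T_k = V̄ / (s_V/√k). Deliberation stops at the first k where

    F_{k−1}(|T_k|) ≥ Conf(k) = max(0.5, 1 − d(k−1)),

with F the Student-t CDF. The confidence-decay rate d ∈ (0, 0.5] is the
single process parameter: the longer she deliberates, the lower the
confidence she is willing to settle for, so every trial terminates by
k_max = ⌈0.5/d⌉ + 1. The chosen option follows the sign of V̄, and the
trial reports

* **Conf\*** — the desired confidence at stopping, and
* **RT = k\* · NC** — response time, where NC is the total number of
  outcome branches displayed across the pair (a complexity index).

Deterministic companions computed by quadrature:

* **Pr Core(A≻B)** — the probability a *single* sampled utility function
  favours A (the one-shot random-preference model);
* **E[V(A,B)]** — the mean certainty-equivalent difference;
* **Pr Lim(A≻B)** — the unlimited-deliberation limit, 0 or 1 by the sign
  of E[V]. Simulated choice probabilities always lie between Pr Core and
  Pr Lim, which is how modal choices can reverse even though the core is
  strictly EU.

## Worked example

```bash
breut simulate --a "30:1" --b "40:0.8,0:0.2" --alpha 0.35 --beta 1.0 \
               --d 0.1 --reps 20000 --seed 7
```

```
               label  alpha  beta_range   d  pr_core    e_v  pr_lim   pr_a     rt   conf  n_reps
30:1 vs 40:0.8,0:0.2   0.35         1.0 0.1   0.7259 2.4093     1.0 0.9215 9.6345 0.7788   20000
```

Reading the row: 73% of the core utility functions favour the sure 30 over
the 0.8 chance of 40 (`pr_core`), and the mean CE difference is +2.41 in
money units (`e_v`), so with unlimited deliberation the sure amount would
always be chosen (`pr_lim` = 1). With the decay rate d = 0.1, simulated
deliberation picks the sure amount in 92% of 20,000 trials (`pr_a`) —
more extreme than the one-shot core, less extreme than the limit — after
an average response time of 9.63 time units (`rt`, i.e. a mean of ~3.2
samples × 3 displayed branches) at an average stopping confidence of 0.78
(`conf`).

The same machinery is scriptable:

```python
import breut

pair = breut.parse_pair("30:1", "40:0.8,0:0.2")
core = breut.CorePrefs(alpha=0.35, beta_range=1.0)
breut.pair_analytics(pair, core)
# PairAnalytics(pr_core=0.7259, e_v=2.4093, pr_lim=1.0)
breut.simulate_pair(pair, core, breut.DeliberationConfig(d=0.1), 20_000, rng=7)
# AggregateResult(pr_a=0.9215, mean_rt=9.6345, mean_conf=0.7788, ...)
```

Other entry points: `breut table --id {1..7|fig1}` reproduces the built-in
benchmark tables (sure-amount ladders, parameter sweeps, transparent
dominance, the Myers-effect crossover, the Marschak–Machina triangle
pairs); `breut sweep` runs custom grids; `breut check` runs the invariant
battery (bracketing, termination, complementarity, dominance) on random
pairs. Runs can also be described in a YAML/JSON config (see
`breut.load_config`).

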