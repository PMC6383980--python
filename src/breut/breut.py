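"""Boundedly rational expected utility: a simulator of deliberative risky choice.

The model treats a binary choice between monetary lotteries as a sequential
deliberation process built on an expected-utility core.  A decision maker does
not own a single utility function; her underlying preferences are a population
of power utilities ``U(x) = x**(1 - r)`` whose risk-attitude parameter ``r``
follows a transformed Beta(3,3) distribution with mean ``alpha`` and range
``beta_range``.  Each deliberation step draws one ``r``, applies it to both
lotteries, and records the certainty-equivalent difference
``V = CE_A - CE_B``.  The running mean and sample standard deviation of the
accumulated differences feed a sequential one-sample t-test: deliberation
stops at the first sample count ``k`` (k >= 2) at which the t CDF with
``k - 1`` degrees of freedom evaluated at ``|T_k|`` reaches the desired
confidence ``Conf = max(0.5, 1 - d*(k - 1))``.  The chosen option is the one
favoured by the sign of the running mean; the trial also yields a confidence
level ``Conf*`` and a response time ``RT = k* * NC``, where ``NC`` is the
total number of branches displayed across the pair.

The module is laid out in the order the method runs:

1.  constants, logging and errors;
2.  lottery representation, parsing, stochastic dominance, named stimuli;
3.  the expected-utility core: utilities, certainty equivalents, the risk
    parameter sampler and deterministic pair analytics (Pr Core, E[V],
    Pr Lim);
4.  the deliberation engine: confidence schedule, running statistics,
    sequential t-test, single trials;
5.  the Monte-Carlo harness: vectorised aggregation, parameter sweeps, the
    built-in benchmark tables and the bracketing diagnostic;
6.  configuration files and result writers.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial.legendre import leggauss
from scipy import optimize, special, stats

__all__ = [
    "PROB_TOL",
    "VALUE_TOL",
    "TIE_TOL",
    "DEFAULT_REPS",
    "BreutError",
    "ValidationError",
    "ConfigError",
    "Lottery",
    "LotteryPair",
    "parse_lottery",
    "format_lottery",
    "parse_pair",
    "dominates_fosd",
    "FIG1_LOTTERIES",
    "STIMULUS_SETS",
    "stimulus_pairs",
    "stimulus_settings",
    "CorePrefs",
    "PairAnalytics",
    "utility",
    "certainty_equivalent",
    "ce_difference",
    "sample_r",
    "pair_analytics",
    "DeliberationConfig",
    "RunningStats",
    "TrialOutcome",
    "conf_schedule",
    "max_samples",
    "t_statistic",
    "stop_test",
    "run_trial",
    "AggregateResult",
    "simulate_pair",
    "trials_dataframe",
    "sweep",
    "run_table",
    "BracketingReport",
    "bracketing_check",
    "random_pair_generator",
    "RunConfig",
    "load_config",
    "save_config",
    "write_results",
]

__version__ = "1.0.0"

log = logging.getLogger("breut")

# -- global numerical conventions -------------------------------------------

#: absolute tolerance for probability bookkeeping (sums to one, equality)
PROB_TOL = 1e-12
#: absolute tolerance for outcome/parameter equality comparisons
VALUE_TOL = 1e-12
#: |E[V]| below this is treated as an exact tie (Pr Lim = 0.5)
TIE_TOL = 1e-6
#: default number of Monte-Carlo trials per choice pair
DEFAULT_REPS = 20_000

# deterministic analytics: grid used to isolate sign changes of V(r), and the
# Gauss-Legendre order used for E[V]
_SIGN_GRID = 2001
_GL_NODES = 256

_BETA33 = stats.beta(3, 3)


class BreutError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(BreutError, ValueError):
    """An input failed validation; the message names the offending field."""


class ConfigError(ValidationError):
    """A run-configuration file violated the documented schema."""


# ===========================================================================
# 1. Lotteries
# ===========================================================================


@dataclass(frozen=True)
class Lottery:
    """A finite distribution over non-negative monetary outcomes.

    ``branches`` is an ordered tuple of ``(outcome, probability)`` pairs as
    displayed to the decision maker.  Branch order is preserved and duplicate
    outcomes are deliberately not merged: the displayed description defines
    the complexity of the stimulus (see :attr:`LotteryPair.nc`).
    """

    branches: tuple[tuple[float, float], ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.branches) == 0:
            raise ValidationError("branches: a lottery needs at least one branch")
        clean = []
        for i, branch in enumerate(self.branches):
            try:
                x, p = branch
                x, p = float(x), float(p)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"branches[{i}]: expected (outcome, probability) pair") from exc
            if not math.isfinite(x) or x < 0:
                raise ValidationError(f"branches[{i}].outcome: must be a finite non-negative amount, got {x!r}")
            if not math.isfinite(p) or p <= 0 or p > 1 + PROB_TOL:
                raise ValidationError(f"branches[{i}].probability: must lie in (0, 1], got {p!r}")
            clean.append((x, min(p, 1.0)))
        total = math.fsum(p for _, p in clean)
        if abs(total - 1.0) > PROB_TOL:
            raise ValidationError(f"branches: probabilities must sum to 1, got {total!r}")
        object.__setattr__(self, "branches", tuple(clean))

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([x for x, _ in self.branches])

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.branches])

    def is_sure(self) -> bool:
        return len(self.branches) == 1

    def cdf(self, x: float | np.ndarray) -> np.ndarray:
        """P(outcome <= x), evaluated branch-wise (duplicates accumulate)."""
        xs = np.asarray(x, dtype=float)[..., None]
        return np.sum(np.where(self.outcomes <= xs + VALUE_TOL, self.probabilities, 0.0), axis=-1)

    def __str__(self) -> str:
        return format_lottery(self)


@dataclass(frozen=True)
class LotteryPair:
    """An ordered pair of lotteries {A, B} presented as one binary choice."""

    a: Lottery
    b: Lottery
    label: str | None = None

    @property
    def nc(self) -> int:
        """Total consequence count: branches of A plus branches of B.

        This is the complexity index that scales response times.  A sure
        amount contributes one consequence; listed branches count verbatim,
        including zero outcomes and duplicated outcomes.
        """
        return len(self.a.branches) + len(self.b.branches)

    def swapped(self) -> "LotteryPair":
        return LotteryPair(self.b, self.a, label=self.label)

    def __str__(self) -> str:
        return self.label or f"{self.a} vs {self.b}"


_BRANCH_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*([^:\s]+)\s*$")


def parse_lottery(text: str, label: str | None = None) -> Lottery:
    """Parse the compact ``"outcome:prob,outcome:prob"`` lottery syntax.

    ``"30:1"`` is the sure amount 30; ``"40:0.8,0:0.2"`` offers 40 with
    probability 0.8 and 0 otherwise.  Branch order is preserved.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValidationError("lottery: empty lottery string")
    branches = []
    for i, token in enumerate(text.split(",")):
        m = _BRANCH_RE.match(token)
        if m is None:
            raise ValidationError(f"branches[{i}]: malformed branch {token.strip()!r}, expected 'outcome:prob'")
        try:
            x = float(m.group(1))
        except ValueError:
            raise ValidationError(f"branches[{i}].outcome: not a number: {m.group(1)!r}") from None
        try:
            p = float(m.group(2))
        except ValueError:
            raise ValidationError(f"branches[{i}].probability: not a number: {m.group(2)!r}") from None
        branches.append((x, p))
    return Lottery(tuple(branches), label=label)


def _fmt(v: float) -> str:
    # shortest exact decimal: repr round-trips floats; integers drop the '.0'
    return str(int(v)) if float(v).is_integer() and abs(v) < 1e16 else repr(float(v))


def format_lottery(lottery: Lottery) -> str:
    """Inverse of :func:`parse_lottery`; the round trip is value-exact."""
    return ",".join(f"{_fmt(x)}:{_fmt(p)}" for x, p in lottery.branches)


def parse_pair(a: str, b: str, label: str | None = None) -> LotteryPair:
    return LotteryPair(parse_lottery(a), parse_lottery(b), label=label)


def dominates_fosd(a: Lottery, b: Lottery) -> bool:
    """True iff ``a`` first-order stochastically dominates ``b``.

    Checked at the union of the two supports: the CDF of ``a`` must lie
    weakly below the CDF of ``b`` everywhere and strictly below somewhere.
    """
    support = np.unique(np.concatenate([a.outcomes, b.outcomes]))
    fa, fb = a.cdf(support), b.cdf(support)
    return bool(np.all(fa <= fb + PROB_TOL) and np.any(fa < fb - PROB_TOL))


# -- named stimuli -----------------------------------------------------------

#: the five Marschak-Machina triangle lotteries over payoffs {0, 30, 40}
FIG1_LOTTERIES: dict[str, Lottery] = {
    "A": parse_lottery("30:1", label="A"),
    "B": parse_lottery("40:0.8,0:0.2", label="B"),
    "C": parse_lottery("30:0.25,0:0.75", label="C"),
    "D": parse_lottery("40:0.2,0:0.8", label="D"),
    "E": parse_lottery("40:0.2,30:0.75,0:0.05", label="E"),
}


def _sure(amount: float) -> Lottery:
    return Lottery(((float(amount), 1.0),), label=f"({_fmt(amount)}, 1)")


def _fig1_pairs() -> list[LotteryPair]:
    f = FIG1_LOTTERIES
    return [
        LotteryPair(f["A"], f["B"], label="{A,B}"),
        LotteryPair(f["C"], f["D"], label="{C,D}"),
        LotteryPair(f["A"], f["E"], label="{A,E}"),
        LotteryPair(f["E"], f["B"], label="{E,B}"),
    ]


def _table6_pairs() -> list[LotteryPair]:
    k = parse_lottery("180:0.25,0:0.75", label="K")
    l = parse_lottery("40:0.8,0:0.2", label="L")
    pairs = [LotteryPair(k, _sure(m), label=f"K vs ({m}, 1)") for m in range(25, 34)]
    pairs += [LotteryPair(l, _sure(m), label=f"L vs ({m}, 1)") for m in range(25, 34)]
    return pairs


#: benchmark stimulus sets used by :func:`run_table`; each entry carries the
#: lottery pairs together with the core/deliberation settings of that sweep
STIMULUS_SETS: dict[str, dict] = {
    "table1": {
        "pairs": lambda: [
            LotteryPair(_sure(m), FIG1_LOTTERIES["B"], label=f"({m}, 1)") for m in range(20, 33, 2)
        ],
        "alpha": 0.35, "beta_range": 1.0, "d": 0.1,
        "vary": "sure amount", "values": list(range(20, 33, 2)),
    },
    "table2": {
        "pairs": lambda: [LotteryPair(FIG1_LOTTERIES["A"], FIG1_LOTTERIES["B"], label="{A,B}")],
        "beta_range": 1.0, "d": 0.1,
        "vary": "alpha", "values": [0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40],
    },
    "table3": {
        "pairs": lambda: [LotteryPair(FIG1_LOTTERIES["A"], FIG1_LOTTERIES["B"], label="{A,B}")],
        "alpha": 0.30, "d": 0.1,
        "vary": "beta_range", "values": [0.25, 0.40, 0.55, 0.70, 0.85, 1.00, 1.15, 1.30],
    },
    "table4": {
        "pairs": lambda: [LotteryPair(FIG1_LOTTERIES["A"], FIG1_LOTTERIES["B"], label="{A,B}")],
        "alpha": 0.30, "beta_range": 1.0,
        "vary": "d", "values": [0.50, 0.40, 0.30, 0.20, 0.15, 0.10, 0.05, 0.03, 0.02, 0.01],
    },
    "table5": {
        "pairs": lambda: [
            parse_pair("60:0.5,0:0.5", "50:0.5,0:0.5", label="(60,.5;0,.5) vs (50,.5;0,.5)"),
            parse_pair("51:0.5,0:0.5", "50:0.5,0:0.5", label="(51,.5;0,.5) vs (50,.5;0,.5)"),
        ],
        "alpha": 0.23, "beta_range": 1.0, "d": 0.1, "vary": None,
    },
    "table6": {
        "pairs": _table6_pairs,
        "alpha": 0.23, "beta_range": 1.0, "d": 0.1, "vary": None,
    },
    "table7": {
        "pairs": _fig1_pairs,
        "alpha": 0.23, "beta_range": 1.0,
        "vary": "d", "values": [0.10, 0.05, 0.01],
    },
    "fig1": {
        "pairs": _fig1_pairs,
        "alpha": 0.23, "beta_range": 1.0, "d": 0.1, "vary": None,
    },
}


def stimulus_pairs(set_id: str) -> list[LotteryPair]:
    """Return the lottery pairs of a built-in benchmark set, in row order.

    Valid identifiers are ``table1`` .. ``table7`` and ``fig1``.
    """
    try:
        entry = STIMULUS_SETS[set_id]
    except KeyError:
        raise ValidationError(
            f"set_id: unknown stimulus set {set_id!r}; choose from {sorted(STIMULUS_SETS)}"
        ) from None
    return entry["pairs"]()


def stimulus_settings(set_id: str) -> dict:
    """Core and deliberation settings attached to a benchmark set."""
    if set_id not in STIMULUS_SETS:
        raise ValidationError(f"set_id: unknown stimulus set {set_id!r}")
    entry = dict(STIMULUS_SETS[set_id])
    entry.pop("pairs")
    return entry


# ===========================================================================
# 2. The expected-utility core
# ===========================================================================


@dataclass(frozen=True)
class CorePrefs:
    """The population of power utilities behind a decision maker.

    ``r ~ alpha - beta_range/2 + beta_range * Beta(3, 3)``: a symmetric
    bell-shaped distribution with mean ``alpha`` and total range
    ``beta_range``, bounded on ``[alpha - beta_range/2, alpha + beta_range/2]``.
    ``beta_range = 0`` collapses to deterministic expected utility with
    ``r = alpha``.  The upper endpoint must stay strictly below 1 so that the
    utility exponent ``1 - r`` is positive for every draw.
    """

    alpha: float
    beta_range: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValidationError("alpha: must be finite")
        if not math.isfinite(self.beta_range) or self.beta_range < 0:
            raise ValidationError(f"beta_range: must be a finite non-negative range, got {self.beta_range!r}")
        if self.alpha + self.beta_range / 2 >= 1:
            raise ValidationError(
                f"alpha + beta_range/2 must be < 1 so every sampled r stays below 1 "
                f"(got {self.alpha!r} + {self.beta_range!r}/2)"
            )

    @property
    def support(self) -> tuple[float, float]:
        half = self.beta_range / 2
        return (self.alpha - half, self.alpha + half)


@dataclass(frozen=True)
class PairAnalytics:
    """Deterministic description of a pair under a core distribution.

    pr_core
        probability that a single sampled utility function strictly favours
        A (the one-shot random-preference choice probability);
    e_v
        mean certainty-equivalent difference E[V(A,B)] in money units;
    pr_lim
        choice probability after unlimited deliberation: 1 if ``e_v`` is
        positive, 0 if negative, 0.5 at an exact tie (|e_v| <= TIE_TOL).
    """

    pr_core: float
    e_v: float
    pr_lim: float


def utility(x, r: float):
    """Power utility ``U(x) = x**(1 - r)``, normalised so U(0) = 0.

    ``r < 1`` is required; ``r = 0`` is risk neutrality, ``0 < r < 1`` risk
    aversion and ``r < 0`` risk seeking.  ``x`` may be a scalar or array of
    non-negative amounts.
    """
    if r >= 1:
        raise ValidationError(f"r: risk parameter must be < 1, got {r!r}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValidationError("x: outcomes must be non-negative")
    out = np.power(x, 1.0 - r)
    return float(out) if out.ndim == 0 else out


def certainty_equivalent(lottery: Lottery, r):
    """Certainty equivalent of a lottery under the utility with parameter r.

    ``CE = (sum_i p_i x_i**(1-r)) ** (1/(1-r))``.  A sure amount maps to
    itself exactly, for every r.  ``r`` may be an array; the return value is
    broadcast accordingly.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r >= 1):
        raise ValidationError("r: risk parameter must be < 1")
    if lottery.is_sure():
        x0 = lottery.branches[0][0]
        return x0 if r.ndim == 0 else np.full(r.shape, x0)
    s = 1.0 - r
    eu = np.zeros(r.shape)
    for x, p in lottery.branches:
        if x > 0:
            eu = eu + p * np.power(x, s)
    with np.errstate(divide="ignore"):
        ce = np.where(eu > 0, np.power(eu, 1.0 / s), 0.0)
    return float(ce) if ce.ndim == 0 else ce


def ce_difference(pair: LotteryPair, r):
    """``V(A, B) = CE_A - CE_B`` with the same r applied to both lotteries."""
    return certainty_equivalent(pair.a, r) - certainty_equivalent(pair.b, r)


def sample_r(core: CorePrefs, rng: np.random.Generator, size=None):
    """Draw risk parameters from the transformed Beta(3,3) core.

    With ``beta_range = 0`` the distribution is a point mass at ``alpha`` and
    no random numbers are consumed.
    """
    if core.beta_range == 0:
        return core.alpha if size is None else np.full(size, core.alpha)
    lo, _ = core.support
    return lo + core.beta_range * rng.beta(3.0, 3.0, size=size)


def _sign_intervals(pair: LotteryPair, core: CorePrefs) -> list[tuple[float, float, int]]:
    """Partition the r-support into maximal intervals of constant sign of V.

    V is sampled on a uniform grid; every sign flip between consecutive
    non-zero grid values is refined by a bracketed root search, and grid
    points where V vanishes (within VALUE_TOL) act as interval cuts
    themselves.  Returns ``(lo, hi, sign)`` triples with sign in {-1, 0, +1}.
    """
    lo, hi = core.support
    grid = np.linspace(lo, hi, _SIGN_GRID)
    v = np.asarray(ce_difference(pair, grid))
    sgn = np.where(v > VALUE_TOL, 1, np.where(v < -VALUE_TOL, -1, 0))

    # bracket every crossing between consecutive grid points of opposite
    # non-zero sign; grid points where V sits inside the tolerance band are
    # skipped so that a -,0,+ run is still refined across the plateau
    nz = np.nonzero(sgn)[0]
    f = lambda r: ce_difference(pair, r)
    cuts = [lo]
    for i, j in zip(nz[:-1], nz[1:]):
        if sgn[i] != sgn[j]:
            cuts.append(optimize.brentq(f, grid[i], grid[j], xtol=1e-12))
    cuts.append(hi)

    intervals = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a <= 0:
            continue
        mid = 0.5 * (a + b)
        vm = ce_difference(pair, mid)
        s = 1 if vm > VALUE_TOL else (-1 if vm < -VALUE_TOL else 0)
        intervals.append((a, b, s))
    return intervals


def pair_analytics(pair: LotteryPair, core: CorePrefs) -> PairAnalytics:
    """Deterministic Pr Core, E[V] and Pr Lim for one pair.

    Pr Core integrates the Beta(3,3) density over the r-intervals where
    ``V(r) > 0`` (sign changes are isolated on a 2001-point grid and refined
    by bracketed root finding; intervals where V vanishes identically count
    half their mass, which makes a pair of identical lotteries come out at
    0.5).  E[V] uses 256-node Gauss-Legendre quadrature of V against the
    Beta density, accurate far beyond the 1e-4 documented target for these
    smooth bounded integrands.
    """
    if core.beta_range == 0:
        v = ce_difference(pair, core.alpha)
        pr_core = 1.0 if v > VALUE_TOL else (0.0 if v < -VALUE_TOL else 0.5)
        e_v = v
    else:
        lo, _ = core.support
        width = core.beta_range
        pr_core = 0.0
        for a, b, s in _sign_intervals(pair, core):
            if s == 0 and b - a <= 0:
                continue
            mass = _BETA33.cdf((b - lo) / width) - _BETA33.cdf((a - lo) / width)
            if s > 0:
                pr_core += mass
            elif s == 0:
                pr_core += 0.5 * mass
        pr_core = min(1.0, max(0.0, pr_core))

        nodes, weights = leggauss(_GL_NODES)
        t = 0.5 * (nodes + 1.0)
        w = 0.5 * weights
        e_v = float(np.sum(w * _BETA33.pdf(t) * ce_difference(pair, lo + width * t)))

    pr_lim = 1.0 if e_v > TIE_TOL else (0.0 if e_v < -TIE_TOL else 0.5)
    return PairAnalytics(pr_core=float(pr_core), e_v=float(e_v), pr_lim=pr_lim)


# ===========================================================================
# 3. The deliberation engine
# ===========================================================================


@dataclass(frozen=True)
class DeliberationConfig:
    """Stopping-rule settings for one decision maker.

    ``d`` in (0, 0.5] is the confidence-decay rate: the desired confidence
    after k samples is ``max(0.5, 1 - d*(k - 1))``.  Small d means an
    unhurried decision maker who deliberates long and chooses near the
    unlimited-deliberation limit; ``d = 0.5`` stops every trial at k = 2.
    ``rng_seed`` optionally pins the random stream when no generator is
    passed explicitly.
    """

    d: float
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.d <= 0.5):
            raise ValidationError(f"d: confidence-decay rate must lie in (0, 0.5], got {self.d!r}")
        if self.rng_seed is not None and int(self.rng_seed) != self.rng_seed:
            raise ValidationError("rng_seed: must be an integer")


def conf_schedule(k: int, d: float) -> float:
    """Desired confidence at sample count k: ``max(0.5, 1 - d*(k-1))``."""
    if k < 2:
        raise ValidationError(f"k: confidence is defined from the second sample on, got {k!r}")
    if not (0 < d <= 0.5):
        raise ValidationError(f"d: must lie in (0, 0.5], got {d!r}")
    return max(0.5, 1.0 - d * (k - 1))


def max_samples(d: float) -> int:
    """Hard cap on deliberation length: the first k whose desired confidence
    has decayed to the 0.5 floor, where the stopping test always passes
    (the t CDF at |T| is at least 0.5).  Equals ``ceil(0.5/d) + 1``.
    """
    k = 2
    while conf_schedule(k, d) > 0.5:
        k += 1
    return k


class RunningStats:
    """Streaming mean and sample standard deviation (Welford update).

    Matches a naive batch recomputation of the mean and the k-1-denominator
    standard deviation to full precision on any trace.
    """

    __slots__ = ("k", "mean", "m2")

    def __init__(self) -> None:
        self.k = 0
        self.mean = 0.0
        self.m2 = 0.0

    def push(self, x: float) -> None:
        self.k += 1
        delta = x - self.mean
        self.mean += delta / self.k
        self.m2 += delta * (x - self.mean)

    @property
    def sd(self) -> float:
        if self.k < 2:
            raise ValidationError("sd: sample standard deviation needs k >= 2")
        return math.sqrt(max(self.m2, 0.0) / (self.k - 1))


def t_statistic(stats_: RunningStats) -> float:
    """One-sample t statistic ``mean / (sd / sqrt(k))`` of the accumulated
    certainty-equivalent differences.

    Degenerate evidence (sd = 0) returns signed infinity when the mean is
    non-zero -- the hypothesis of no difference is then certainly false --
    and 0.0 when every draw was exactly zero.
    """
    if stats_.k < 2:
        raise ValidationError("t_statistic: needs at least two samples")
    sd = stats_.sd
    if sd == 0.0:
        return 0.0 if stats_.mean == 0.0 else math.copysign(math.inf, stats_.mean)
    return stats_.mean / (sd / math.sqrt(stats_.k))


def stop_test(stats_: RunningStats, d: float) -> bool:
    """Sequential t-test: stop iff ``F_{k-1}(|T_k|) >= conf_schedule(k, d)``.

    ``F`` is the Student-t CDF with k-1 degrees of freedom.  At the
    confidence floor the test is trivially satisfied, which guarantees
    termination.
    """
    t = t_statistic(stats_)
    p = 1.0 if math.isinf(t) else float(special.stdtr(stats_.k - 1, abs(t)))
    return p >= conf_schedule(stats_.k, d)


@dataclass(frozen=True)
class TrialOutcome:
    """One deliberation trace: the choice plus its process measures."""

    choice: str           # "A" or "B"
    k_star: int           # samples accumulated when the test first passed
    conf_star: float      # desired confidence at that point
    t_star: float         # value of the t statistic at that point
    rt: float             # response time, k_star * NC


def run_trial(
    pair: LotteryPair,
    core: CorePrefs,
    config: DeliberationConfig,
    rng: np.random.Generator,
) -> TrialOutcome:
    """Simulate a single deliberation over one pair.

    Risk parameters are drawn one at a time; each draw is applied to both
    lotteries and its CE difference pushed into the running statistics.  The
    sequential test is evaluated from k = 2 onwards and first passage stops
    the trial.  The choice follows the sign of the final running mean; an
    exact zero mean (a measure-zero event) is resolved by a fair coin.
    """
    stats_ = RunningStats()
    stats_.push(ce_difference(pair, sample_r(core, rng)))
    while True:
        stats_.push(ce_difference(pair, sample_r(core, rng)))
        if stop_test(stats_, config.d):
            break
    if stats_.mean > 0:
        choice = "A"
    elif stats_.mean < 0:
        choice = "B"
    else:
        choice = "A" if rng.random() < 0.5 else "B"
    k_star = stats_.k
    return TrialOutcome(
        choice=choice,
        k_star=k_star,
        conf_star=conf_schedule(k_star, config.d),
        t_star=t_statistic(stats_),
        rt=float(k_star * pair.nc),
    )


# ===========================================================================
# 4. Monte-Carlo aggregation and the experiment harness
# ===========================================================================


@dataclass(frozen=True)
class AggregateResult:
    """Monte-Carlo summary of many independent trials on one pair."""

    pr_a: float      # estimated Pr(A is chosen)
    mean_rt: float
    mean_conf: float
    n_reps: int
    mc_se_pr: float  # binomial standard error sqrt(p(1-p)/n)


def _deliberate_matrix(v: np.ndarray, d: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised stopping rule on a (n_trials, k_max) matrix of CE draws.

    Column k-1 holds each trial's k-th sampled difference.  Returns
    ``(k_star, mean_at_stop, conf_star)`` arrays.  The cumulative-moment
    formulation reproduces the scalar Welford engine decision-for-decision
    (verified in the test suite); variances are clipped at zero to absorb
    last-bit cancellation.
    """
    n, kmax = v.shape
    ks = np.arange(1, kmax + 1, dtype=float)
    cs = np.cumsum(v, axis=1)
    cs2 = np.cumsum(v * v, axis=1)
    mean = cs / ks
    var = np.clip((cs2 - cs * cs / ks) / np.maximum(ks - 1.0, 1.0), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean * np.sqrt(ks / var)
    t = np.where(var == 0.0, np.where(mean == 0.0, 0.0, np.inf * np.sign(mean)), t)
    conf = np.maximum(0.5, 1.0 - d * (ks - 1.0))
    p = np.where(np.isinf(t), 1.0, special.stdtr(ks - 1.0, np.abs(t)))
    stop = p >= conf
    stop[:, 0] = False  # the test is defined from k = 2 onwards
    k_star = np.argmax(stop, axis=1) + 1
    rows = np.arange(n)
    mean_at_stop = cs[rows, k_star - 1] / k_star
    conf_star = np.maximum(0.5, 1.0 - d * (k_star - 1.0))
    return k_star, mean_at_stop, conf_star


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_pair(
    pair: LotteryPair,
    core: CorePrefs,
    config: DeliberationConfig,
    n_reps: int = DEFAULT_REPS,
    rng: np.random.Generator | int | None = None,
) -> AggregateResult:
    """Estimate Pr(A), mean RT and mean Conf* from ``n_reps`` trials.

    Trials are simulated in vectorised lockstep: a single seeded stream
    fills an ``(n_reps, k_max)`` matrix of risk-parameter draws (each row one
    trial's potential sample path, truncated at the stopping cap), the
    sequential test is applied column-wise, and unused draws are discarded.
    This is distributionally identical to looping :func:`run_trial` and
    reproducible for a fixed seed.  Memory is bounded by chunking.
    """
    if n_reps < 1:
        raise ValidationError(f"n_reps: need at least one trial, got {n_reps!r}")
    gen = _as_rng(config.rng_seed if rng is None else rng)
    kmax = max_samples(config.d)
    nc = pair.nc

    chunk = max(1, min(n_reps, (1 << 22) // kmax))
    n_a = 0
    sum_rt = 0.0
    sum_conf = 0.0
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        if core.beta_range == 0:
            r = np.full((m, kmax), core.alpha)
        else:
            lo, _ = core.support
            r = lo + core.beta_range * gen.beta(3.0, 3.0, size=(m, kmax))
        v = certainty_equivalent(pair.a, r) - certainty_equivalent(pair.b, r)
        k_star, mean_stop, conf_star = _deliberate_matrix(v, config.d)
        ties = mean_stop == 0.0
        choice_a = mean_stop > 0.0
        if ties.any():
            choice_a = np.where(ties, gen.random(m) < 0.5, choice_a)
        n_a += int(np.count_nonzero(choice_a))
        sum_rt += float(np.sum(k_star)) * nc
        sum_conf += float(np.sum(conf_star))
        done += m

    pr_a = n_a / n_reps
    result = AggregateResult(
        pr_a=pr_a,
        mean_rt=sum_rt / n_reps,
        mean_conf=sum_conf / n_reps,
        n_reps=n_reps,
        mc_se_pr=math.sqrt(pr_a * (1.0 - pr_a) / n_reps),
    )
    log.info(
        "simulate %s: n=%d pr_a=%.4f rt=%.3f conf=%.4f",
        pair, n_reps, result.pr_a, result.mean_rt, result.mean_conf,
    )
    return result


def trials_dataframe(trials: Iterable[TrialOutcome]) -> pd.DataFrame:
    """Per-trial audit table (choice, k_star, conf_star, t_star, rt)."""
    return pd.DataFrame([dataclasses.asdict(t) for t in trials])


# -- sweeps and benchmark tables --------------------------------------------

_ROW_COLUMNS = [
    "label", "alpha", "beta_range", "d",
    "pr_core", "e_v", "pr_lim", "pr_a", "rt", "conf", "n_reps",
]


def _result_row(pair, core, config, n_reps, rng) -> dict:
    an = pair_analytics(pair, core)
    agg = simulate_pair(pair, core, config, n_reps, rng)
    return {
        "label": str(pair),
        "alpha": core.alpha,
        "beta_range": core.beta_range,
        "d": config.d,
        "pr_core": an.pr_core,
        "e_v": an.e_v,
        "pr_lim": an.pr_lim,
        "pr_a": agg.pr_a,
        "rt": agg.mean_rt,
        "conf": agg.mean_conf,
        "n_reps": n_reps,
    }


def sweep(
    pairs: Sequence[LotteryPair],
    core: CorePrefs,
    config: DeliberationConfig,
    *,
    param: str | None = None,
    values: Sequence[float] | None = None,
    n_reps: int = DEFAULT_REPS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Run a one-dimensional parameter sweep over one or more pairs.

    ``param`` is one of ``"alpha"``, ``"beta_range"`` or ``"d"`` (or None to
    simulate the pairs at the base settings).  Every grid point is validated
    before any simulation starts, so an infeasible value (for example
    ``alpha + beta_range/2 >= 1``) rejects the whole sweep up front.  Output
    rows join the deterministic analytics with the Monte-Carlo aggregates,
    one row per (grid value, pair), pairs iterated within each grid point.
    """
    if (param is None) != (values is None):
        raise ValidationError("sweep: param and values must be given together")
    if param is None:
        settings = [(core, config)]
    elif param == "alpha":
        settings = [(CorePrefs(float(v), core.beta_range), config) for v in values]
    elif param == "beta_range":
        settings = [(CorePrefs(core.alpha, float(v)), config) for v in values]
    elif param == "d":
        settings = [(core, DeliberationConfig(float(v), config.rng_seed)) for v in values]
    else:
        raise ValidationError(f"param: unknown sweep parameter {param!r}")

    gen = _as_rng(rng if rng is not None else config.rng_seed)
    rows = []
    for c, cfg in settings:
        for pair in pairs:
            rows.append(_result_row(pair, c, cfg, n_reps, gen))
    return pd.DataFrame(rows, columns=_ROW_COLUMNS)


def run_table(
    table_id: str,
    n_reps: int = DEFAULT_REPS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Reproduce one of the built-in benchmark tables.

    ``table1``: a fixed two-branch lottery against a ladder of sure amounts;
    ``table2``-``table4``: one pair swept over alpha, beta_range and d;
    ``table5``: two transparent-dominance pairs; ``table6``: two lotteries
    of different payoff spread against a ladder of sure amounts (the
    strong-stochastic-transitivity crossover); ``table7``: the four
    Marschak-Machina triangle pairs at three deliberation rates.  Returns
    one row per table row with analytics and simulated aggregates.
    """
    settings = stimulus_settings(table_id)
    pairs = stimulus_pairs(table_id)
    gen = _as_rng(rng)
    vary = settings.get("vary")

    if vary in (None, "sure amount"):
        core = CorePrefs(settings["alpha"], settings["beta_range"])
        config = DeliberationConfig(settings["d"])
        return sweep(pairs, core, config, n_reps=n_reps, rng=gen)

    if vary == "alpha":
        core = CorePrefs(settings["values"][0], settings["beta_range"])
        return sweep(pairs, core, DeliberationConfig(settings["d"]),
                     param="alpha", values=settings["values"], n_reps=n_reps, rng=gen)
    if vary == "beta_range":
        core = CorePrefs(settings["alpha"], settings["values"][0])
        return sweep(pairs, core, DeliberationConfig(settings["d"]),
                     param="beta_range", values=settings["values"], n_reps=n_reps, rng=gen)
    # vary == "d"
    core = CorePrefs(settings["alpha"], settings["beta_range"])
    return sweep(pairs, core, DeliberationConfig(settings["values"][0]),
                 param="d", values=settings["values"], n_reps=n_reps, rng=gen)


@dataclass(frozen=True)
class BracketingReport:
    """Does a simulated choice probability sit between Pr Core and Pr Lim?

    After finite deliberation the choice probability must lie between the
    one-shot probability (Pr Core) and the unlimited-deliberation limit
    (Pr Lim, 0 or 1 by the sign of E[V]).  ``slack`` widens the bracket by
    three binomial standard errors to absorb Monte-Carlo noise.  Violations
    are reported, never raised.
    """

    pr_core: float
    pr_lim: float
    pr_a: float
    mc_se_pr: float
    slack: float
    bracketed: bool


def bracketing_check(
    pair: LotteryPair,
    core: CorePrefs,
    config: DeliberationConfig,
    n_reps: int = DEFAULT_REPS,
    rng: np.random.Generator | int | None = None,
) -> BracketingReport:
    """Check the core/limit bracketing of the simulated choice probability."""
    an = pair_analytics(pair, core)
    if an.pr_lim == 0.5:
        raise ValidationError("bracketing_check: E[V] is an exact tie; the bracket is undefined")
    agg = simulate_pair(pair, core, config, n_reps, rng)
    lo, hi = sorted((an.pr_core, an.pr_lim))
    slack = 3.0 * agg.mc_se_pr
    ok = (lo - slack) <= agg.pr_a <= (hi + slack)
    return BracketingReport(
        pr_core=an.pr_core, pr_lim=an.pr_lim, pr_a=agg.pr_a,
        mc_se_pr=agg.mc_se_pr, slack=slack, bracketed=bool(ok),
    )


def random_pair_generator(
    rng: np.random.Generator | int | None,
    *,
    outcome_range: tuple[float, float] = (0.0, 100.0),
    branch_counts: tuple[int, int] = (1, 4),
    force_fosd: bool = False,
) -> LotteryPair:
    """Draw a random valid lottery pair, optionally with A dominating B.

    Outcomes are uniform on ``outcome_range``; branch probabilities are a
    Dirichlet draw renormalised so the last probability absorbs rounding.
    With ``force_fosd`` the pair shares branch probabilities and A's outcomes
    are B's shifted up by strictly positive amounts, which guarantees
    first-order stochastic dominance by construction.
    """
    gen = _as_rng(rng)
    lo, hi = outcome_range
    if not (0 <= lo < hi):
        raise ValidationError(f"outcome_range: need 0 <= lo < hi, got {outcome_range!r}")
    nb_lo, nb_hi = branch_counts
    if not (1 <= nb_lo <= nb_hi):
        raise ValidationError(f"branch_counts: need 1 <= lo <= hi, got {branch_counts!r}")

    def _branches(nb: int, outcomes: np.ndarray) -> Lottery:
        if nb == 1:
            return Lottery(((float(outcomes[0]), 1.0),))
        p = gen.dirichlet(np.ones(nb))
        p = np.clip(p, 1e-9, None)
        p[-1] = 1.0 - math.fsum(p[:-1])
        return Lottery(tuple((float(x), float(q)) for x, q in zip(outcomes, p)))

    if force_fosd:
        nb = int(gen.integers(nb_lo, nb_hi + 1))
        xb = gen.uniform(lo, hi * 0.8, size=nb)
        shifts = gen.uniform((hi - lo) * 1e-3, hi * 0.2, size=nb)
        b = _branches(nb, xb)
        a = Lottery(tuple((float(x + s), p) for (x, p), s in zip(b.branches, shifts)))
        return LotteryPair(a, b)

    na, nb = (int(gen.integers(nb_lo, nb_hi + 1)) for _ in range(2))
    return LotteryPair(
        _branches(na, gen.uniform(lo, hi, size=na)),
        _branches(nb, gen.uniform(lo, hi, size=nb)),
    )


# ===========================================================================
# 5. Configuration files and result writers
# ===========================================================================


@dataclass
class RunConfig:
    """A fully validated simulation run loaded from JSON or YAML."""

    pairs: list[LotteryPair]
    core: CorePrefs
    d: float
    n_reps: int = DEFAULT_REPS
    seed: int | None = None
    out: str | None = None
    format: str = "csv"

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ConfigError("pairs: at least one lottery pair is required")
        DeliberationConfig(self.d)  # validates d
        if self.n_reps < 1:
            raise ConfigError(f"n_reps: must be >= 1, got {self.n_reps!r}")
        if self.format not in ("csv", "json", "table"):
            raise ConfigError(f"format: must be csv, json or table, got {self.format!r}")


def _config_dict(raw: dict, path: str) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"pairs", "core", "d", "n_reps", "seed", "out", "format"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown field(s): {', '.join(sorted(unknown))}")
    for fld in ("pairs", "core", "d"):
        if fld not in raw:
            raise ConfigError(f"{fld}: required field is missing")

    pairs = []
    if not isinstance(raw["pairs"], list):
        raise ConfigError("pairs: must be a list of {a, b[, label]} mappings")
    for i, entry in enumerate(raw["pairs"]):
        if not isinstance(entry, dict) or "a" not in entry or "b" not in entry:
            raise ConfigError(f"pairs[{i}]: must be a mapping with 'a' and 'b' lottery strings")
        try:
            pairs.append(parse_pair(str(entry["a"]), str(entry["b"]), label=entry.get("label")))
        except ValidationError as exc:
            raise ConfigError(f"pairs[{i}]: {exc}") from exc

    core_raw = raw["core"]
    if not isinstance(core_raw, dict) or "alpha" not in core_raw:
        raise ConfigError("core: must be a mapping with 'alpha' (and optional 'beta_range')")
    try:
        core = CorePrefs(float(core_raw["alpha"]), float(core_raw.get("beta_range", 1.0)))
    except ValidationError as exc:
        raise ConfigError(f"core.{exc}") from exc

    try:
        return RunConfig(
            pairs=pairs,
            core=core,
            d=float(raw["d"]),
            n_reps=int(raw.get("n_reps", DEFAULT_REPS)),
            seed=None if raw.get("seed") is None else int(raw["seed"]),
            out=raw.get("out"),
            format=raw.get("format", "csv"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration (JSON or YAML by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
    else:
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    cfg = _config_dict(raw, str(path))
    log.info("loaded config %s: %d pair(s), alpha=%g beta=%g d=%g reps=%d seed=%s",
             path, len(cfg.pairs), cfg.core.alpha, cfg.core.beta_range,
             cfg.d, cfg.n_reps, cfg.seed)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back out; load/save round-trips exactly."""
    path = Path(path)
    raw = {
        "pairs": [
            {"a": format_lottery(p.a), "b": format_lottery(p.b),
             **({"label": p.label} if p.label else {})}
            for p in cfg.pairs
        ],
        "core": {"alpha": cfg.core.alpha, "beta_range": cfg.core.beta_range},
        "d": cfg.d,
        "n_reps": cfg.n_reps,
        "seed": cfg.seed,
        "out": cfg.out,
        "format": cfg.format,
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(raw, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=True))


def write_results(
    rows: pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
    metadata: dict | None = None,
) -> Path:
    """Write result rows as CSV, JSON or a 2-dp rounded display table.

    CSV and table modes prepend '#'-prefixed metadata lines (seed,
    parameters, package version); JSON mode nests the metadata object and
    keeps full float precision, and is byte-for-byte reproducible for
    identical inputs.  Rounding to two decimals happens only in table mode.
    """
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("package", f"breut {__version__}")
    if fmt == "json":
        payload = {"metadata": meta, "rows": rows.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n")
        return path
    if fmt not in ("csv", "table"):
        raise ValidationError(f"format: must be csv, json or table, got {fmt!r}")
    out = rows.round(2) if fmt == "table" else rows
    with path.open("w", newline="") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        out.to_csv(fh, index=False, quoting=csv.QUOTE_MINIMAL)
    return path
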