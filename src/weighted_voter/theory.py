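"""Closed-form, noise-free results for the weighted voter model.

With the better option's mean signalling time normalised to 1 and the worse
option's to q_B < 1, worse-option holders update at rate lambda = 1/q_B > 1.
On any connected regular graph the count of agents preferring the better
option is a birth-death martingale transform and its absorption
probabilities are exactly those of a biased gambler's ruin:

    P(consensus on worse) = (lambda^(N-l) - 1) / (lambda^N - 1),

where l agents initially prefer the better option.  This module evaluates
that fixation probability (stably, in the lambda^(-x) parameterisation so
N ~ 1e6 does not overflow), its companion bounds, best-of-n bounds and
heuristics, consensus-time bounds in terms of the isoperimetric constant,
the approximate-regular extension (mu = lambda d_min/d_max), and the exact
mean consensus time on the complete graph via the fundamental matrix of the
embedded birth-death chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .errors import CapabilityError, ParameterError
from .graphs import GraphStats

#: Dense/banded linear solves on the transient chain are capped here.
EXACT_TIME_CAP = 5000


@dataclass(frozen=True)
class NoiseFreeModel:
    """Population of ``num_agents`` with rate ratio ``lam`` >= 1 and
    ``init_best`` agents initially preferring the better option."""

    num_agents: int
    lam: float
    init_best: int

    def __post_init__(self) -> None:
        if self.num_agents < 1:
            raise ParameterError(f"need N >= 1, got {self.num_agents}")
        if self.lam < 1.0:
            raise ParameterError(
                f"lam must be >= 1 (relabel options via from_qualities), got {self.lam}"
            )
        if not (0 <= self.init_best <= self.num_agents):
            raise ParameterError(
                f"init_best must lie in [0, {self.num_agents}], got {self.init_best}"
            )

    @classmethod
    def from_qualities(
        cls, num_agents: int, q_a: float, q_b: float, init_a: int
    ) -> "NoiseFreeModel":
        """Build a model from raw qualities; the better option is relabelled
        as the focal one, so ``init_best`` counts its initial supporters."""
        if q_a <= 0 or q_b <= 0:
            raise ParameterError("qualities must be positive")
        if q_a >= q_b:
            return cls(num_agents, q_a / q_b, init_a)
        return cls(num_agents, q_b / q_a, num_agents - init_a)


@dataclass(frozen=True)
class ErrorBounds:
    error_upper: float  # lambda^(-l), bound on P(consensus on worse)
    single_seed_A_lower: float  # (lambda-1)/lambda, bound at l=1


@dataclass(frozen=True)
class BestOfNBounds:
    cor1_error_bound: float
    conj1_error_heuristic: float


@dataclass(frozen=True)
class TimeBounds:
    complete_bound: float
    regular_bound: float


@dataclass(frozen=True)
class ApproxRegularBounds:
    mu: float
    error_bound: float
    time_bound: float


@dataclass(frozen=True)
class BirthDeathChain:
    """Embedded birth-death chain of the better-option count on K_N.

    At a state-changing jump the count increases with probability
    ``up_prob`` = lambda/(1+lambda) independent of the state; the mean
    residence time in state j is (N-1)/((1+lambda) j (N-j)).
    """

    num_agents: int
    lam: float
    up_prob: float
    down_prob: float
    residence_mean: np.ndarray  # index j-1 holds state j, j = 1..N-1


@dataclass(frozen=True)
class ExactConsensusTime:
    expected_time: float
    fixation_prob: float  # absorption at all-best, from the same linear system


def _ratio(a: float, n: float, lam: float) -> float:
    """(lam^a - 1)/(lam^n - 1) for 0 <= a <= n, lam > 1, overflow-safe."""
    ll = math.log(lam)
    return math.exp((a - n) * ll) * math.expm1(-a * ll) / math.expm1(-n * ll)


def fixation_prob(model: NoiseFreeModel) -> float:
    """Probability of consensus on the better option (Markov-chain exact)."""
    n, lam, l = model.num_agents, model.lam, model.init_best
    if l == 0:
        return 0.0
    if l == n:
        return 1.0
    if lam == 1.0:
        return l / n
    ll = math.log(lam)
    return math.expm1(-l * ll) / math.expm1(-n * ll)


def error_prob(model: NoiseFreeModel) -> float:
    """Probability of consensus on the worse option; complements
    :func:`fixation_prob` exactly."""
    n, lam, l = model.num_agents, model.lam, model.init_best
    if l == 0:
        return 1.0
    if l == n:
        return 0.0
    if lam == 1.0:
        return (n - l) / n
    return _ratio(n - l, n, lam)


def error_bounds(model: NoiseFreeModel) -> ErrorBounds:
    """Exponential error bound lambda^(-l) and the single-seed fixation
    lower bound (lambda-1)/lambda; both require lam > 1."""
    if model.lam <= 1.0:
        raise ParameterError("error bounds are undefined at lam = 1")
    return ErrorBounds(
        error_upper=model.lam ** (-model.init_best),
        single_seed_A_lower=(model.lam - 1.0) / model.lam,
    )


def best_of_n_bounds(
    num_agents: int, counts: Sequence[int], lam2: float
) -> BestOfNBounds:
    """Best-of-n error bound and heuristic.

    ``counts`` are the initial supporter counts of the options in decreasing
    quality order; ``lam2`` is the rate of the second-best option relative to
    the best.  The rigorous bound collapses all options 2..n onto the
    second-best; the heuristic instead freezes options 1 and 2 until the rest
    have been absorbed, which yields the non-integer exponent
    N * N_2/(N_1+N_2), evaluated as a real power.
    """
    if len(counts) < 2:
        raise ParameterError("best-of-n needs at least two options")
    if any(c <= 0 for c in counts):
        raise ParameterError("all option counts must be positive")
    if sum(counts) != num_agents:
        raise ParameterError("counts must sum to the number of agents")
    if lam2 <= 1.0:
        raise ParameterError("lam2 must exceed 1 (options sorted by quality)")
    n1, n2 = counts[0], counts[1]
    n = float(num_agents)
    cor1 = _ratio(n - n1, n, lam2)
    conj1 = _ratio(n * n2 / (n1 + n2), n, lam2)
    return BestOfNBounds(cor1_error_bound=cor1, conj1_error_heuristic=conj1)


def time_bounds(num_agents: int, lam: float, stats: GraphStats) -> TimeBounds:
    """Mean consensus-time bounds, in units of the better option's mean
    signalling time: 2(1+ln N)/(lam-1) on the complete graph and
    2d(1+ln N)/(eta (lam-1)) on a d-regular graph with isoperimetric
    constant eta."""
    if lam <= 1.0:
        raise ParameterError("time bounds require lam > 1")
    if stats.eta is None:
        raise ParameterError("stats must carry an isoperimetric constant")
    if stats.eta <= 0:
        raise CapabilityError("eta <= 0: graph is disconnected, no consensus bound")
    if not stats.is_regular:
        raise ParameterError("the regular bound requires a regular graph")
    n = num_agents
    complete = 2.0 * (1.0 + math.log(n)) / (lam - 1.0)
    regular = 2.0 * stats.d_max * (1.0 + math.log(n)) / (stats.eta * (lam - 1.0))
    return TimeBounds(complete_bound=complete, regular_bound=regular)


def bollobas_time_bound(num_agents: int, lam: float, d: int) -> float:
    """High-probability consensus-time bound for random d-regular graphs,
    4(1+ln N)/((lam-1)(1-sqrt(ln2/d))), obtained by substituting the
    random-regular isoperimetric lower bound into the regular-graph bound."""
    if d < 3:
        raise ParameterError(f"requires d >= 3, got d={d}")
    if lam <= 1.0:
        raise ParameterError("requires lam > 1")
    return (
        4.0
        * (1.0 + math.log(num_agents))
        / ((lam - 1.0) * (1.0 - math.sqrt(math.log(2.0) / d)))
    )


def approx_regular_bounds(
    model: NoiseFreeModel, d_min: int, d_max: int, eta: float
) -> ApproxRegularBounds:
    """Bounds for approximately regular graphs via mu = lam * d_min/d_max.

    Requires mu > 1; with d_min = d_max these reduce to the regular-graph
    fixation formula and time bound.
    """
    if eta <= 0:
        raise CapabilityError("eta <= 0: graph is disconnected")
    mu = model.lam * d_min / d_max
    if mu <= 1.0:
        raise CapabilityError(
            f"mu = lam*d_min/d_max = {mu:.6g} <= 1: the near-regular bounds do not apply"
        )
    n, k = model.num_agents, model.init_best
    err = _ratio(n - k, n, mu)
    time = (
        2.0
        * d_max
        * (mu + 1.0)
        * (1.0 + math.log(n))
        / (eta * (mu - 1.0) * (model.lam + 1.0))
    )
    return ApproxRegularBounds(mu=mu, error_bound=err, time_bound=time)


def birth_death_chain(num_agents: int, lam: float) -> BirthDeathChain:
    """Embedded chain of the better-option count on the complete graph."""
    if num_agents < 2:
        raise ParameterError("need N >= 2")
    if lam < 1.0:
        raise ParameterError("need lam >= 1")
    n = num_agents
    j = np.arange(1, n, dtype=float)
    residence = (n - 1.0) / ((1.0 + lam) * j * (n - j))
    return BirthDeathChain(
        num_agents=n,
        lam=lam,
        up_prob=lam / (1.0 + lam),
        down_prob=1.0 / (1.0 + lam),
        residence_mean=residence,
    )


def _transient_solve(num_agents: int, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Solve (I-P) x = tau and (I-P) h = e_up on the transient states
    1..N-1 of the embedded chain; returns (expected times, fixation probs)."""
    n = num_agents
    if n > EXACT_TIME_CAP:
        raise CapabilityError(
            f"exact consensus time uses a dense banded solve, capped at N <= {EXACT_TIME_CAP}"
        )
    chain = birth_death_chain(n, lam)
    m = n - 1
    p, q = chain.up_prob, chain.down_prob
    ab = np.zeros((3, m))
    ab[0, 1:] = -p  # superdiagonal: jump j -> j+1
    ab[1, :] = 1.0
    ab[2, :-1] = -q  # subdiagonal: jump j -> j-1
    rhs = np.column_stack([chain.residence_mean, np.zeros(m)])
    rhs[m - 1, 1] = p  # one jump from N-1 lands in the all-best state
    sol = solve_banded((1, 1), ab, rhs)
    return sol[:, 0], sol[:, 1]


def exact_mean_consensus_time(
    num_agents: int, lam: float, j0: int
) -> ExactConsensusTime:
    """Exact mean consensus time on K_N from initial better-option count j0.

    Computed as sum_k [(I-P)^{-1}]_{j0,k} * residence_mean[k] via one banded
    solve; the same system yields the absorption probability, returned as a
    cross-check against the closed-form fixation probability.
    """
    if not (1 <= j0 <= num_agents - 1):
        raise ParameterError(f"j0 must lie in [1, N-1], got {j0}")
    times, probs = _transient_solve(num_agents, lam)
    return ExactConsensusTime(
        expected_time=float(times[j0 - 1]), fixation_prob=float(probs[j0 - 1])
    )


def absorption_prob_oracle(num_agents: int, lam: float, j0: int) -> float:
    """Independent linear-system oracle for the fixation probability.

    Solves the first-step equations of the birth-death chain directly rather
    than using the closed form; used to cross-validate :func:`fixation_prob`.
    """
    if not (1 <= j0 <= num_agents - 1):
        raise ParameterError(f"j0 must lie in [1, N-1], got {j0}")
    _, probs = _transient_solve(num_agents, lam)
    return float(probs[j0 - 1])
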