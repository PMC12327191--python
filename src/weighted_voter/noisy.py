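"""Branching-process theory for noisy quality measurements.

When each quality measurement is a random draw T (a mean signalling time),
a rare better-option lineage in a large well-mixed population behaves as a
multitype branching process: an individual of type r = 1/T lives for an
Exp(r) time and gives birth at rate lambda = 1/E[T_B], each child's type
drawn afresh from the better option's measurement distribution.  The
lineage's survival probability c* solves the scalar fixed-point equation

    c = E[ lambda c / (lambda c + R_A) ],

whose unique positive root exists exactly when lambda E[T_A] > 1; the
extinction probability of a type-r founder is pi_r = r/(r + lambda c*),
and a founder with freshly sampled type goes extinct with probability
pi = 1 - c*.  Fixation of k initial supporters in the large-population
limit is approximated by 1 - pi^k.

This module provides the quality-distribution objects (point mass, gamma,
finite support), their size-biased forms, the fixed-point solver with
guaranteed monotone bracketing, the finite-support generating-function
oracle, a Monte-Carlo simulator of the branching process, and the
convex-order comparison of noise levels.
"""

from __future__ import annotations

import heapq
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .errors import NumericalError, ParameterError

#: |lambda E[T_A] - 1| below this is treated as critical (extinction certain).
CRITICALITY_TOL = 1e-12


class QualityDist(ABC):
    """Distribution of a measured site quality T > 0 (a mean holding time).

    The induced opinion-update rate is R = 1/T.  Subclasses provide the
    mean, sampling, the size-biased transform (the distribution of the
    quality held by a randomly inspected signalling agent in steady state),
    and the expectation E[b*T/(b*T + 1)] needed by the fixed-point solver.
    """

    kind: str

    @property
    @abstractmethod
    def mean(self) -> float:
        """E[T], the mean holding time."""

    @abstractmethod
    def sample(self, rng: np.random.Generator, size=None):
        """Draw holding times."""

    @abstractmethod
    def size_biased(self) -> "QualityDist":
        """Distribution reweighted by t: dG(t) proportional to t dF(t)."""

    @abstractmethod
    def expect_bt_frac(self, b: float) -> float:
        """E[ bT/(bT+1) ] for b >= 0, computed in T-space so that heavy
        rate tails (E[1/T] = inf) pose no problem."""

    @abstractmethod
    def spec_string(self) -> str:
        """Canonical parseable representation."""


@dataclass(frozen=True)
class PointMass(QualityDist):
    """Noise-free measurement: every draw equals ``value``."""

    value: float
    kind = "point"

    def __post_init__(self):
        if self.value <= 0:
            raise ParameterError(f"point mass must be positive, got {self.value}")

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def size_biased(self) -> "PointMass":
        return self

    def expect_bt_frac(self, b: float) -> float:
        bt = b * self.value
        return bt / (bt + 1.0)

    def spec_string(self) -> str:
        return f"point:{self.value:g}"


@dataclass(frozen=True)
class GammaDist(QualityDist):
    """Gamma-distributed measurements; smaller shape means noisier."""

    shape: float
    scale: float
    kind = "gamma"

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ParameterError(
                f"gamma needs positive shape and scale, got {self.shape}, {self.scale}"
            )

    @classmethod
    def from_mean(cls, shape: float, mean: float) -> "GammaDist":
        """Scale chosen so that E[T] equals the true site quality."""
        if shape <= 0 or mean <= 0:
            raise ParameterError("gamma needs positive shape and mean")
        return cls(shape=shape, scale=mean / shape)

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def sample(self, rng, size=None):
        return rng.gamma(self.shape, self.scale, size=size)

    def size_biased(self) -> "GammaDist":
        # t * t^(a-1) e^(-t/s) renormalises to Gamma(a+1, s)
        return GammaDist(self.shape + 1.0, self.scale)

    def expect_bt_frac(self, b: float) -> float:
        if b == 0.0:
            return 0.0
        a, s = self.shape, self.scale
        lognorm = math.lgamma(a) + a * math.log(s)

        def integrand(t: float) -> float:
            bt = b * t
            return (bt / (bt + 1.0)) * math.exp(
                (a - 1.0) * math.log(t) - t / s - lognorm
            )

        out = quad(integrand, 0.0, np.inf, epsabs=1e-13, epsrel=1e-12,
                   limit=200, full_output=1)
        if len(out) > 3:
            raise NumericalError(
                f"quadrature failed for gamma(shape={a}, scale={s}), b={b}: {out[3]}"
            )
        return min(max(out[0], 0.0), 1.0)

    def spec_string(self) -> str:
        return f"gamma:shape={self.shape:g},mean={self.mean:g}"


@dataclass(frozen=True)
class FiniteSupport(QualityDist):
    """Measurements on finitely many positive values with given weights.

    Also serves tabulated/empirical qualities.
    """

    values: tuple
    probs: tuple
    kind = "finite_support"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if v.ndim != 1 or v.size == 0 or v.size != p.size:
            raise ParameterError("values and probs must be equal-length, nonempty")
        if np.any(v <= 0):
            raise ParameterError("support must be strictly positive")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ParameterError("probabilities must be nonnegative and sum to 1")

    @classmethod
    def of(cls, values: Sequence[float], probs: Sequence[float]) -> "FiniteSupport":
        return cls(tuple(float(x) for x in values), tuple(float(x) for x in probs))

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))

    def sample(self, rng, size=None):
        cum = np.cumsum(self.probs)
        if size is None:
            return self.values[int(np.searchsorted(cum, rng.random()))]
        idx = np.searchsorted(cum, rng.random(size))
        return np.asarray(self.values)[idx]

    def size_biased(self) -> "FiniteSupport":
        v = np.asarray(self.values)
        p = np.asarray(self.probs)
        w = p * v / float(np.dot(v, p))
        return FiniteSupport.of(self.values, w)

    def expect_bt_frac(self, b: float) -> float:
        v = np.asarray(self.values)
        bt = b * v
        return float(np.dot(self.probs, bt / (bt + 1.0)))

    def spec_string(self) -> str:
        t = ",".join(f"{x:g}" for x in self.values)
        p = ",".join(f"{x:g}" for x in self.probs)
        return f"finite:t={t};p={p}"


def parse_quality(spec: str) -> QualityDist:
    """Parse ``"point:0.9"``, ``"gamma:shape=2,mean=0.9"`` (or ``scale=``),
    or ``"finite:t=0.5,1.5;p=0.5,0.5"``."""
    head, sep, rest = spec.partition(":")
    head = head.strip().lower()
    if not sep:
        raise ParameterError(f"quality spec {spec!r} is missing ':'")
    if head == "point":
        try:
            return PointMass(float(rest))
        except ValueError as exc:
            raise ParameterError(f"bad point value in {spec!r}") from exc
    if head == "gamma":
        kv: dict[str, float] = {}
        for tok in rest.split(","):
            key, eq, val = tok.partition("=")
            key = key.strip()
            if not eq or key not in {"shape", "mean", "scale"}:
                raise ParameterError(f"bad token {tok!r} in {spec!r}")
            try:
                kv[key] = float(val)
            except ValueError as exc:
                raise ParameterError(f"bad number in token {tok!r}") from exc
        if "shape" not in kv or ("mean" in kv) == ("scale" in kv):
            raise ParameterError(
                f"gamma spec needs shape plus exactly one of mean/scale: {spec!r}"
            )
        if "mean" in kv:
            return GammaDist.from_mean(kv["shape"], kv["mean"])
        return GammaDist(kv["shape"], kv["scale"])
    if head in {"finite", "finite_support", "tabulated"}:
        parts = dict()
        for group in rest.split(";"):
            key, eq, val = group.partition("=")
            if not eq or key.strip() not in {"t", "p"}:
                raise ParameterError(f"bad group {group!r} in {spec!r}")
            try:
                parts[key.strip()] = [float(x) for x in val.split(",")]
            except ValueError as exc:
                raise ParameterError(f"bad number in group {group!r}") from exc
        if set(parts) != {"t", "p"}:
            raise ParameterError(f"finite spec needs both t= and p=: {spec!r}")
        return FiniteSupport.of(parts["t"], parts["p"])
    raise ParameterError(f"unknown quality kind {head!r} in {spec!r}")


@dataclass(frozen=True)
class BranchingSolution:
    """Solution of the branching-process fixed point.

    ``c_star`` is the survival probability of a lineage founded by a fresh
    measurement, ``pi = 1 - c_star`` its extinction probability.
    ``history`` (optional) records the (lower, upper) bracket per iteration.
    """

    lam: float
    c_star: float
    pi: float
    supercritical: bool
    iterations: int
    bracket_width: float
    history: tuple | None = None


@dataclass(frozen=True)
class FiniteSupportExtinction:
    pi: np.ndarray  # per-type extinction probabilities
    c: float  # 1 - sum p_j pi_j


@dataclass(frozen=True)
class BranchingMC:
    extinct_freq: float
    se: float
    reps: int
    n_extinct: int
    pop_cap: int


@dataclass(frozen=True)
class NoiseComparison:
    pi_1: float
    pi_2: float
    convex_order_expected: bool


def rate_lambda(spec_b: QualityDist) -> float:
    """Birth rate lambda = 1/E[T_B]: in equilibrium a tagged agent is
    contacted by worse-option holders at the renewal rate of their
    signalling cycles, which depends on the measurement noise only through
    its mean."""
    m = spec_b.mean
    if not math.isfinite(m) or m <= 0:
        raise ParameterError(f"E[T_B] must be finite and positive, got {m}")
    return 1.0 / m


def size_biased(spec: QualityDist) -> QualityDist:
    """Size-biased-by-t transform of a holding-time distribution."""
    return spec.size_biased()


def g_map(c: float, spec_a: QualityDist, lam: float) -> float:
    """One step of the fixed-point iteration, h(c) = E[lam c T_A/(lam c T_A + 1)].

    h is nondecreasing and concave on [0, 1] with h(0) = 0; its unique
    positive fixed point (when lam E[T_A] > 1) is the survival probability.
    """
    if not (0.0 <= c <= 1.0):
        raise ParameterError(f"c must lie in [0,1], got {c}")
    if lam <= 0:
        raise ParameterError("lam must be positive")
    return spec_a.expect_bt_frac(lam * c)


def solve_extinction(
    spec_a: QualityDist,
    lam: float,
    tol: float = 1e-12,
    max_iter: int = 10**6,
    track_history: bool = False,
) -> BranchingSolution:
    """Solve the fixed point by monotone bracketing iteration.

    Iterates h from a machine-scale positive seed (h(0) = 0 is itself a
    fixed point) and from 1; the lower sequence increases and the upper
    decreases to c*, so the bracket width is a certified error bound at
    every step.  Subcritical or critical inputs (lam E[T_A] <= 1) return
    pi = 1 without iterating.
    """
    if lam <= 0:
        raise ParameterError("lam must be positive")
    m = lam * spec_a.mean
    if m <= 1.0 + CRITICALITY_TOL:
        hist = ((0.0, 0.0),) if track_history else None
        return BranchingSolution(lam, 0.0, 1.0, False, 0, 0.0, hist)
    lo = min(1e-12, tol)
    hi = 1.0
    history = [(lo, hi)] if track_history else None
    for it in range(1, max_iter + 1):
        lo = spec_a.expect_bt_frac(lam * lo)
        hi = spec_a.expect_bt_frac(lam * hi)
        if history is not None:
            history.append((lo, hi))
        if hi - lo < tol:
            c = 0.5 * (lo + hi)
            return BranchingSolution(
                lam, c, 1.0 - c, True, it, hi - lo,
                tuple(history) if history is not None else None,
            )
    raise NumericalError(
        f"fixed-point iteration did not reach tol={tol} in {max_iter} steps; "
        f"bracket [{lo}, {hi}]"
    )


def extinction_by_type(r: float, sol: BranchingSolution) -> float:
    """Extinction probability pi_r = r/(r + lambda c*) of a type-r founder."""
    if r < 0:
        raise ParameterError("rate must be nonnegative")
    if not sol.supercritical:
        return 1.0
    return r / (r + sol.lam * sol.c_star)


def fixation_large_N(sol: BranchingSolution, k: int) -> float:
    """Large-population fixation approximation 1 - pi^k for k initial
    supporters (conjectured limit; exact for the noise-free special case)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return 1.0 - sol.pi**k


def finite_support_oracle(
    rates: Sequence[float],
    probs: Sequence[float],
    lam: float,
    tol: float = 1e-14,
    max_iter: int = 10**6,
) -> FiniteSupportExtinction:
    """Generating-function oracle for finitely many types.

    Iterates G_i(u) = r_i/(r_i + lam (1 - sum_j p_j u_j)) from the zero
    vector, which converges monotonically to the minimal solution, i.e. the
    vector of per-type extinction probabilities.  Independent of the scalar
    fixed-point route, hence usable as a cross-check.
    """
    r = np.asarray(rates, dtype=float)
    p = np.asarray(probs, dtype=float)
    if r.ndim != 1 or r.size == 0 or r.size != p.size:
        raise ParameterError("rates and probs must be equal-length, nonempty")
    if np.any(r < 0) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
        raise ParameterError("rates nonnegative, probs a distribution")
    u = np.zeros_like(r)
    for _ in range(max_iter):
        nxt = r / (r + lam * (1.0 - float(np.dot(p, u))))
        if float(np.max(np.abs(nxt - u))) < tol:
            u = nxt
            break
        u = nxt
    return FiniteSupportExtinction(pi=u, c=1.0 - float(np.dot(p, u)))


def branching_mc(
    spec_a: QualityDist,
    lam: float,
    rng: np.random.Generator,
    reps: int,
    pop_cap: int = 1000,
    time_cap: float | None = None,
) -> BranchingMC:
    """Monte-Carlo extinction frequency of the multitype branching process.

    Each path starts from one individual whose type r = 1/T is a fresh
    measurement; individuals die at their own rate and give birth at rate
    ``lam``.  A path counts as extinct when the population hits 0 and as
    surviving when it reaches ``pop_cap`` (a supercritical lineage that
    large dies out later with probability <= pi^pop_cap, negligible) or
    outlives ``time_cap`` if one is set.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    n_ext = sum(
        _branch_once(spec_a, lam, rng, pop_cap, time_cap) for _ in range(reps)
    )
    f = n_ext / reps
    return BranchingMC(
        extinct_freq=f,
        se=math.sqrt(f * (1.0 - f) / reps),
        reps=reps,
        n_extinct=n_ext,
        pop_cap=pop_cap,
    )


def _branch_once(spec_a, lam, rng, pop_cap, time_cap) -> bool:
    """Simulate one path; True if it goes extinct."""
    rexp = rng.standard_exponential
    t0 = 0.0
    T = float(spec_a.sample(rng))
    death = [t0 + T * rexp()]  # lifetime Exp(1/T) = T * Exp(1)
    heap = [(death[0], 0, 0), (t0 + rexp() / lam, 1, 0)]
    heapq.heapify(heap)
    alive = 1
    while heap:
        t, tag, i = heapq.heappop(heap)
        if time_cap is not None and t > time_cap:
            return False
        if tag == 0:  # death
            alive -= 1
            if alive == 0:
                return True
        else:  # birth opportunity of individual i
            if death[i] <= t:
                continue  # parent already dead; its stream ends
            child_T = float(spec_a.sample(rng))
            death.append(t + child_T * rexp())
            j = len(death) - 1
            heapq.heappush(heap, (death[j], 0, j))
            heapq.heappush(heap, (t + rexp() / lam, 1, j))
            heapq.heappush(heap, (t + rexp() / lam, 1, i))
            alive += 1
            if alive >= pop_cap:
                return False
    return True  # unreachable for valid inputs


def _cx_dominated(spec_1: QualityDist, spec_2: QualityDist) -> bool:
    """True when spec_1 is known analytically to precede spec_2 in the
    convex order (same mean, spec_2 at least as noisy)."""
    if spec_1 == spec_2:
        return True
    if isinstance(spec_1, PointMass):
        return True  # a constant is convex-order minimal at fixed mean
    if isinstance(spec_1, GammaDist) and isinstance(spec_2, GammaDist):
        return spec_1.shape >= spec_2.shape  # larger shape = less noisy
    return False


def compare_noise(
    spec_a_1: QualityDist,
    spec_a_2: QualityDist,
    spec_b: QualityDist,
    mean_tol: float = 1e-9,
) -> NoiseComparison:
    """Compare extinction probabilities under two same-mean noise models.

    When spec_a_1 precedes spec_a_2 in the convex order (knowable
    analytically within the gamma/point families), noisier measurements
    cannot help: pi_1 <= pi_2 is checked and a violation raises.
    """
    if abs(spec_a_1.mean - spec_a_2.mean) > mean_tol:
        raise ParameterError(
            f"means differ: {spec_a_1.mean} vs {spec_a_2.mean} (tol {mean_tol})"
        )
    lam = rate_lambda(spec_b)
    pi_1 = solve_extinction(spec_a_1, lam).pi
    pi_2 = solve_extinction(spec_a_2, lam).pi
    expected = _cx_dominated(spec_a_1, spec_a_2)
    if expected and pi_1 > pi_2 + 1e-9:
        raise NumericalError(
            f"convex-order monotonicity violated: pi_1={pi_1} > pi_2={pi_2}"
        )
    return NoiseComparison(pi_1=pi_1, pi_2=pi_2, convex_order_expected=expected)
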