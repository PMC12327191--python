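"""Event-driven continuous-time simulation of the weighted voter model.

Each agent signals its current opinion for an exponential time whose mean
is its measured quality, then copies a uniformly random neighbour and
remeasures the quality of the (possibly unchanged) opinion.  Because an
agent's rate changes only when the agent itself fires, the simulation keeps
exactly one pending firing event per agent in a heap; this per-agent
schedule is equal in law to racing all the exponential clocks and costs
O(log N) per event.  Measurement lags, best-of-n opinions and
degree-preserving dynamic rewiring are supported.

The readable single-event path is :meth:`Simulation.step`; :func:`run` is a
tightened loop over the same event logic (an equivalence test keeps the two
bit-identical under a shared seed).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError
from .graphs import InteractionGraph, rewire_adjacency
from .noisy import FiniteSupport, GammaDist, PointMass, QualityDist


@dataclass
class SimOptions:
    """Protocol knobs: measurement-lag mean (0 disables), dynamic rewiring,
    event cap, and whether initial qualities are fresh draws or drawn from
    the size-biased steady-state distribution."""

    lag_mean: float = 0.0
    dynamic: bool = False
    max_events: int = 10_000_000
    init_mode: str | tuple = "fresh"

    def __post_init__(self):
        if self.lag_mean < 0:
            raise ParameterError("lag_mean must be >= 0")
        modes = (
            (self.init_mode,) if isinstance(self.init_mode, str) else self.init_mode
        )
        for m in modes:
            if m not in {"fresh", "size_biased"}:
                raise ParameterError(f"unknown init_mode {m!r}")


@dataclass
class PopulationState:
    """Opinions, current measured qualities, clock and pending events."""

    opinions: np.ndarray
    qualities: np.ndarray
    clock: float
    counts: np.ndarray
    lag_end: np.ndarray
    queue: list  # heap of (fire_time, agent)

    @property
    def rates(self) -> np.ndarray:
        return 1.0 / self.qualities

    def in_lag(self, agent: int) -> bool:
        return self.clock < self.lag_end[agent]

    def consensus_winner(self) -> int | None:
        n = self.opinions.size
        for opt, c in enumerate(self.counts):
            if c == n:
                return int(opt)
        return None


@dataclass
class EventRecord:
    time: float
    agent: int
    neighbor: int | None
    old_opinion: int
    new_opinion: int
    quality: float
    rewired: bool


@dataclass
class SimulationResult:
    """Outcome of one run; ``winner`` is None when the event cap was hit."""

    winner: int | None
    consensus_time: float
    n_updates: int
    seed: int | None = None

    @property
    def capped(self) -> bool:
        return self.winner is None


@dataclass(frozen=True)
class WinnerStats:
    count: int
    freq: float
    se: float
    mean_time: float
    time_q1: float
    time_q3: float


@dataclass
class SimulationSummary:
    """Replicate-level summary: fixation frequency per option with binomial
    standard error, and consensus-time mean/interquartile range overall and
    conditioned on each winner (capped runs excluded from time stats)."""

    reps: int
    n_options: int
    fixation_freq: np.ndarray
    fixation_se: np.ndarray
    capped_freq: float
    mean_time: float
    time_q1: float
    time_q3: float
    per_winner: dict
    results: list = field(default_factory=list)


def _sampler(spec: QualityDist) -> Callable[[np.random.Generator], float]:
    """Scalar quality sampler with a fixed rng draw-count per call, so the
    fast loop and the step path consume the stream identically."""
    if isinstance(spec, PointMass):
        v = spec.value
        return lambda rng: v
    if isinstance(spec, GammaDist):
        a, s = spec.shape, spec.scale
        return lambda rng: rng.gamma(a, s)
    if isinstance(spec, FiniteSupport):
        cum = np.cumsum(spec.probs)
        vals = spec.values
        return lambda rng: vals[int(np.searchsorted(cum, rng.random()))]
    return lambda rng: float(spec.sample(rng))


def init_state(
    graph: InteractionGraph,
    assignment: Sequence[int],
    specs: Sequence[QualityDist],
    init_mode: str | Sequence[str] = "fresh",
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Initial population: per-agent opinions plus a measured quality drawn
    from the option's measurement distribution (``fresh``) or its
    size-biased steady-state form (``size_biased``); each agent's first
    firing time is scheduled immediately.  ``init_mode`` may be a single
    mode or one mode per option (e.g. a fresh seed inside a steady-state
    majority, the regime the branching approximation describes).
    """
    rng = np.random.default_rng(rng)
    n = graph.num_nodes
    opinions = np.asarray(assignment, dtype=np.int64)
    if opinions.shape != (n,):
        raise ParameterError(f"assignment must have length {n}")
    if opinions.min() < 0 or opinions.max() >= len(specs):
        raise ParameterError(
            f"assignment uses option {int(opinions.max())} but only "
            f"{len(specs)} quality specs were given"
        )
    modes = (
        [init_mode] * len(specs) if isinstance(init_mode, str) else list(init_mode)
    )
    if len(modes) != len(specs):
        raise ParameterError(
            f"init_mode needs one entry per option, got {len(modes)} for {len(specs)}"
        )
    draw = []
    for s, mode in zip(specs, modes):
        if mode == "fresh":
            draw.append(_sampler(s))
        elif mode == "size_biased":
            draw.append(_sampler(s.size_biased()))
        else:
            raise ParameterError(f"unknown init_mode {mode!r}")
    qualities = np.empty(n, dtype=float)
    queue = []
    for v in range(n):
        t_v = float(draw[opinions[v]](rng))
        qualities[v] = t_v
        queue.append((t_v * rng.standard_exponential(), v))
    heapq.heapify(queue)
    counts = np.bincount(opinions, minlength=len(specs))
    return PopulationState(
        opinions=opinions,
        qualities=qualities,
        clock=0.0,
        counts=counts,
        lag_end=np.zeros(n),
        queue=queue,
    )


class Simulation:
    """Stepwise simulation exposing one event at a time.

    Per event: the earliest-scheduled agent fires, copies a uniformly
    random neighbour's current opinion (itself excluded; an isolated agent
    only remeasures), optionally triggers rewiring, redraws its quality
    from the adopted option's measurement distribution even when the
    opinion is unchanged, and schedules its next firing after an optional
    exponential measurement lag plus the new signalling time.
    """

    def __init__(
        self,
        graph: InteractionGraph,
        assignment: Sequence[int],
        specs: Sequence[QualityDist],
        options: SimOptions | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.options = options or SimOptions()
        self.rng = np.random.default_rng(rng)
        self.graph = graph
        self.specs = list(specs)
        self._samplers = [_sampler(s) for s in self.specs]
        self.num_nodes = graph.num_nodes
        if self.options.dynamic:
            self.adj: list = graph.adjacency_sets()
        else:
            self.adj = graph.adjacency()
        self.state = init_state(
            graph, assignment, specs, self.options.init_mode, self.rng
        )
        self.n_events = 0

    def step(self) -> EventRecord:
        """Advance by one firing event and return its record."""
        st = self.state
        winner = st.consensus_winner()
        if winner is not None:
            raise ParameterError("population is already at consensus")
        rng = self.rng
        t, v = heapq.heappop(st.queue)
        st.clock = t
        self.n_events += 1
        nbrs = self.adj[v]
        if self.options.dynamic:
            nbrs = sorted(nbrs)
        deg = len(nbrs)
        rewired = False
        old_op = int(st.opinions[v])
        if deg:
            w = nbrs[int(rng.random() * deg)]
            new_op = int(st.opinions[w])
            if new_op != old_op:
                st.opinions[v] = new_op
                st.counts[old_op] -= 1
                st.counts[new_op] += 1
            if self.options.dynamic:
                rewired = rewire_adjacency(self.adj, v, rng)
        else:
            w = None
            new_op = old_op
        t_new = float(self._samplers[new_op](rng))
        st.qualities[v] = t_new
        dt = t_new * rng.standard_exponential()
        if self.options.lag_mean > 0.0:
            lag = self.options.lag_mean * rng.standard_exponential()
            st.lag_end[v] = t + lag
            dt += lag
        heapq.heappush(st.queue, (t + dt, v))
        return EventRecord(
            time=t,
            agent=v,
            neighbor=w,
            old_opinion=old_op,
            new_opinion=new_op,
            quality=t_new,
            rewired=rewired,
        )

    def run(self) -> SimulationResult:
        """Step until consensus or the event cap."""
        winner = self.state.consensus_winner()
        if winner is not None:
            return SimulationResult(winner, 0.0, 0)
        while self.n_events < self.options.max_events:
            self.step()
            winner = self.state.consensus_winner()
            if winner is not None:
                return SimulationResult(winner, self.state.clock, self.n_events)
        return SimulationResult(None, self.state.clock, self.n_events)

    def current_graph(self) -> InteractionGraph:
        if self.options.dynamic:
            return InteractionGraph.from_adjacency_sets(self.adj)
        return self.graph


def run(
    graph: InteractionGraph,
    assignment: Sequence[int],
    specs: Sequence[QualityDist],
    options: SimOptions | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulationResult:
    """Run one replicate to consensus (tight loop; law- and stream-identical
    to repeatedly calling :meth:`Simulation.step`)."""
    options = options or SimOptions()
    rng = np.random.default_rng(rng)
    n = graph.num_nodes
    state = init_state(graph, assignment, specs, options.init_mode, rng)
    counts = state.counts.tolist()
    for opt, c in enumerate(counts):
        if c == n:
            return SimulationResult(opt, 0.0, 0)
    ops = state.opinions.tolist()
    dynamic = options.dynamic
    adj = graph.adjacency_sets() if dynamic else graph.adjacency()
    lag = options.lag_mean
    heap = state.queue
    samplers = [_sampler(s) for s in specs]
    pop, push = heapq.heappop, heapq.heappush
    rexp = rng.standard_exponential
    runif = rng.random
    events = 0
    max_events = options.max_events
    clock = 0.0
    while events < max_events:
        t, v = pop(heap)
        clock = t
        events += 1
        nbrs = sorted(adj[v]) if dynamic else adj[v]
        deg = len(nbrs)
        if deg:
            w = nbrs[int(runif() * deg)]
            new_op = ops[w]
            old_op = ops[v]
            if new_op != old_op:
                ops[v] = new_op
                counts[old_op] -= 1
                c = counts[new_op] + 1
                counts[new_op] = c
                if c == n:
                    return SimulationResult(new_op, t, events)
            if dynamic:
                rewire_adjacency(adj, v, rng)
        else:
            new_op = ops[v]
        dt = samplers[new_op](rng) * rexp()
        if lag > 0.0:
            dt += lag * rexp()
        push(heap, (t + dt, v))
    return SimulationResult(None, clock, events)


def replicate_seed(base_seed: int, rep: int) -> int:
    """Stable per-replicate seed derived via SeedSequence((base_seed, rep))."""
    return int(np.random.SeedSequence((base_seed, rep)).generate_state(1)[0])


def run_many(
    graph: InteractionGraph | None,
    assignment: Sequence[int] | None,
    specs: Sequence[QualityDist],
    *,
    reps: int,
    base_seed: int,
    options: SimOptions | None = None,
    graph_factory: Callable[[np.random.Generator], InteractionGraph] | None = None,
    keep_results: bool = True,
) -> SimulationSummary:
    """Replicated runs with deterministically derived per-replicate seeds.

    ``graph_factory`` (called with the replicate rng) resamples the graph
    each trial, as in protocols that average single trajectories over many
    random graphs; otherwise the fixed ``graph`` is reused.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    if graph is None and graph_factory is None:
        raise ParameterError("need a graph or a graph_factory")
    results = []
    for rep in range(reps):
        s = replicate_seed(base_seed, rep)
        rng = np.random.default_rng(s)
        g = graph_factory(rng) if graph_factory is not None else graph
        res = run(g, assignment, specs, options, rng)
        res.seed = s
        results.append(res)
    return summarize(results, len(specs), keep_results=keep_results)


def summarize(
    results: Sequence[SimulationResult], n_options: int, keep_results: bool = True
) -> SimulationSummary:
    reps = len(results)
    winners = np.array([-1 if r.winner is None else r.winner for r in results])
    times = np.array([r.consensus_time for r in results])
    done = winners >= 0
    freq = np.array([(winners == o).mean() for o in range(n_options)])
    se = np.sqrt(freq * (1.0 - freq) / reps)
    if done.any():
        mt = float(times[done].mean())
        q1, q3 = (float(x) for x in np.quantile(times[done], [0.25, 0.75]))
    else:
        mt = q1 = q3 = math.nan
    per_winner = {}
    for o in range(n_options):
        sel = winners == o
        if not sel.any():
            continue
        tw = times[sel]
        p = float(sel.mean())
        per_winner[o] = WinnerStats(
            count=int(sel.sum()),
            freq=p,
            se=math.sqrt(p * (1.0 - p) / reps),
            mean_time=float(tw.mean()),
            time_q1=float(np.quantile(tw, 0.25)),
            time_q3=float(np.quantile(tw, 0.75)),
        )
    return SimulationSummary(
        reps=reps,
        n_options=n_options,
        fixation_freq=freq,
        fixation_se=se,
        capped_freq=float((~done).mean()),
        mean_time=mt,
        time_q1=q1,
        time_q3=q3,
        per_winner=per_winner,
        results=list(results) if keep_results else [],
    )
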