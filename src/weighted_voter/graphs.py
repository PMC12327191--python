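"""Interaction graphs for weighted-voter consensus dynamics.

Agents are the nodes of a simple undirected graph; an edge means the two
agents can copy each other's opinion.  This module generates the graph
families used in the analysis (complete, expanded cycle, random regular,
Erdős–Rényi, random geometric), characterises them (degree statistics,
isoperimetric constant by exact enumeration or closed form), and implements
the degree-preserving rewiring move used to model agents that change their
neighbourhood whenever they update their opinion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import CapabilityError, NumericalError, ParameterError

log = logging.getLogger(__name__)

#: Exact isoperimetric enumeration visits one representative of each
#: {S, S^c} bipartition, i.e. 2^(N-1) subsets; above this cap it refuses.
ISOPERIMETRIC_CAP = 20

#: Bounded resampling attempts for the rewiring move before aborting it.
REWIRE_MAX_TRIES = 64

_FAMILIES = {
    "complete": "complete",
    "excycle": "expanded_cycle",
    "expanded_cycle": "expanded_cycle",
    "rr": "random_regular",
    "random_regular": "random_regular",
    "er": "erdos_renyi",
    "erdos_renyi": "erdos_renyi",
    "rgg": "random_geometric",
    "random_geometric": "random_geometric",
}


def _canon(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class InteractionGraph:
    """Simple undirected graph of ``num_nodes`` agents.

    ``edges`` is a frozenset of sorted node-index pairs.  ``positions`` keeps
    the sampled unit-square coordinates for random geometric graphs (as a
    tuple of (x, y) tuples) and is ``None`` otherwise.
    """

    num_nodes: int
    edges: frozenset
    positions: tuple | None = None

    def __post_init__(self) -> None:
        n = self.num_nodes
        if n < 1:
            raise ParameterError("graph needs at least one node")
        for u, v in self.edges:
            if u == v:
                raise ParameterError(f"self-loop at node {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ParameterError(f"edge ({u},{v}) outside [0,{n})")
            if u > v:
                raise ParameterError("edges must be stored as sorted pairs")

    @classmethod
    def from_edges(
        cls,
        num_nodes: int,
        edges: Iterable[tuple[int, int]],
        positions: np.ndarray | None = None,
    ) -> "InteractionGraph":
        canon = frozenset(_canon(int(u), int(v)) for u, v in edges)
        pos = tuple(map(tuple, positions)) if positions is not None else None
        return cls(num_nodes, canon, pos)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.num_nodes, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency(self) -> list[tuple[int, ...]]:
        """Neighbour lists as sorted tuples (fast to index, immutable)."""
        adj: list[list[int]] = [[] for _ in range(self.num_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return [tuple(sorted(a)) for a in adj]

    def adjacency_sets(self) -> list[set]:
        """Mutable neighbour sets, used by the rewiring move."""
        adj: list[set] = [set() for _ in range(self.num_nodes)]
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.num_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_adjacency_sets(
        cls, adj: Sequence[set], positions: tuple | None = None
    ) -> "InteractionGraph":
        edges = set()
        for u, nbrs in enumerate(adj):
            for v in nbrs:
                edges.add(_canon(u, v))
        return cls(len(adj), frozenset(edges), positions)


@dataclass(frozen=True)
class GraphStats:
    """Degree and expansion summary of an interaction graph.

    ``eta`` is the isoperimetric (Cheeger) constant when known, together with
    the method that produced it: ``exact_bruteforce``,
    ``closed_form_expanded_cycle``, ``closed_form_complete`` or
    ``lower_bound_bollobas``.
    """

    d_min: int
    d_max: int
    is_regular: bool
    is_connected: bool
    eta: float | None = None
    eta_method: str | None = None


@dataclass(frozen=True)
class GraphSpec:
    """Descriptor of a graph family, parseable from strings like
    ``"excycle:n=100,d=4"``."""

    family: str
    n: int
    d: int | None = None
    p: float | None = None
    r: float | None = None

    def __str__(self) -> str:
        parts = [f"n={self.n}"]
        if self.d is not None:
            parts.append(f"d={self.d}")
        if self.p is not None:
            parts.append(f"p={self.p:g}")
        if self.r is not None:
            parts.append(f"r={self.r:g}")
        return f"{self.family}:{','.join(parts)}"


def parse_graph_spec(spec: str) -> GraphSpec:
    """Parse ``"family:key=value,..."`` into a :class:`GraphSpec`."""
    head, _, rest = spec.partition(":")
    head = head.strip().lower()
    if head not in _FAMILIES:
        raise ParameterError(
            f"unknown graph family {head!r} (known: {sorted(set(_FAMILIES.values()))})"
        )
    family = _FAMILIES[head]
    kwargs: dict = {}
    if rest:
        for tok in rest.split(","):
            key, eq, val = tok.partition("=")
            key = key.strip()
            if not eq or key not in {"n", "d", "p", "r"}:
                raise ParameterError(f"bad token {tok!r} in graph spec {spec!r}")
            kwargs[key] = int(val) if key in {"n", "d"} else float(val)
    if "n" not in kwargs:
        raise ParameterError(f"graph spec {spec!r} is missing n")
    return GraphSpec(family=family, **kwargs)


def make_graph(
    spec: GraphSpec | str,
    rng: np.random.Generator | None = None,
    require_connected: bool = True,
) -> InteractionGraph:
    """Generate a graph from a family descriptor.

    Random families (``random_regular``, ``erdos_renyi``, ``random_geometric``)
    require ``rng`` and are bit-reproducible from its state.
    ``require_connected`` applies to random regular graphs only, where the
    theory assumes connectedness; disconnected draws are rejected and
    resampled.
    """
    if isinstance(spec, str):
        spec = parse_graph_spec(spec)
    n = spec.n
    if n < 2:
        raise ParameterError(f"need at least two agents, got N={n}")

    if spec.family == "complete":
        edges = [(u, v) for u in range(n) for v in range(u + 1, n)]
        return InteractionGraph.from_edges(n, edges)

    if spec.family == "expanded_cycle":
        d = spec.d
        if d is None or d % 2 != 0 or not (2 <= d <= n - 1):
            raise ParameterError(
                f"expanded cycle needs even d with 2 <= d <= N-1, got d={d}, N={n}"
            )
        edges = [(i, (i + j) % n) for i in range(n) for j in range(1, d // 2 + 1)]
        return InteractionGraph.from_edges(n, edges)

    if rng is None:
        raise ParameterError(f"family {spec.family!r} requires an rng")

    if spec.family == "random_regular":
        d = spec.d
        if d is None or not (0 <= d < n):
            raise ParameterError(f"random regular needs 0 <= d < N, got d={d}")
        if (n * d) % 2 != 0:
            raise ParameterError(f"N*d must be even, got N={n}, d={d}")
        for _ in range(1000):
            g = nx.random_regular_graph(d, n, seed=rng)
            if not require_connected or nx.is_connected(g):
                return InteractionGraph.from_edges(n, g.edges())
        raise NumericalError(
            f"failed to draw a connected {d}-regular graph on {n} nodes in 1000 tries"
        )

    if spec.family == "erdos_renyi":
        p = spec.p
        if p is None or not (0.0 <= p <= 1.0):
            raise ParameterError(f"Erdős–Rényi needs p in [0,1], got p={p}")
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < p
        edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
        return InteractionGraph.from_edges(n, edges)

    if spec.family == "random_geometric":
        r = spec.r
        if r is None or r <= 0:
            raise ParameterError(f"random geometric needs r > 0, got r={r}")
        pos = rng.random((n, 2))
        close = squareform(pdist(pos)) < r
        iu, ju = np.triu_indices(n, k=1)
        mask = close[iu, ju]
        edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
        return InteractionGraph.from_edges(n, edges, positions=pos)

    raise ParameterError(f"unknown family {spec.family!r}")


def degree_stats(graph: InteractionGraph) -> GraphStats:
    """Exact degree extremes plus regularity and connectivity flags."""
    deg = graph.degrees()
    d_min = int(deg.min())
    d_max = int(deg.max())
    g = graph.to_networkx()
    connected = graph.num_nodes == 1 or nx.is_connected(g)
    return GraphStats(
        d_min=d_min,
        d_max=d_max,
        is_regular=d_min == d_max,
        is_connected=connected,
    )


def with_eta(stats: GraphStats, eta: float, method: str) -> GraphStats:
    return replace(stats, eta=float(eta), eta_method=method)


def isoperimetric_exact(graph: InteractionGraph) -> float:
    """Isoperimetric constant by exhaustive enumeration of cuts.

    min over vertex subsets S with 1 <= |S| <= N/2 of |E(S, S^c)| / |S|.
    Enumerates one representative of each {S, S^c} pair (node N-1 is pinned
    to one side) and divides each cut by the size of its smaller side.
    Returns 0 exactly when the graph is disconnected.
    """
    n = graph.num_nodes
    if n < 2:
        raise ParameterError("isoperimetric constant needs N >= 2")
    if n > ISOPERIMETRIC_CAP:
        raise CapabilityError(
            f"exact isoperimetric enumeration is capped at N <= {ISOPERIMETRIC_CAP}"
            f" (got N={n}); use a closed form or a lower bound instead"
        )
    masks = np.arange(1, 1 << (n - 1), dtype=np.uint64)
    cut = np.zeros(masks.shape, dtype=np.int64)
    one = np.uint64(1)
    for u, v in graph.edges:
        cut += (((masks >> np.uint64(u)) ^ (masks >> np.uint64(v))) & one).astype(
            np.int64
        )
    sizes = np.bitwise_count(masks).astype(np.int64)
    small = np.minimum(sizes, n - sizes)
    return float(np.min(cut / small))


def expanded_cycle_eta(n: int, d: int) -> float:
    """Closed-form isoperimetric constant of the expanded cycle.

    For a ring of N nodes each joined to its d nearest neighbours (d even),
    the minimising cut is a contiguous arc and eta = (2/N) * sum_{i=1}^{d/2} 2i.
    """
    if d % 2 != 0:
        raise ParameterError(f"expanded cycle degree must be even, got d={d}")
    if not (2 <= d < n):
        raise ParameterError(f"need 2 <= d < N, got d={d}, N={n}")
    m = d // 2
    return 2.0 * m * (m + 1) / n


def regular_eta_lower_bound(d: int) -> float:
    """High-probability lower bound d/2 - sqrt(d ln 2) on the isoperimetric
    constant of a random d-regular graph (natural log).

    May be <= 0 for very small d; returned as-is, the caller decides
    usability.
    """
    if d < 3:
        raise ParameterError(f"the random-regular bound requires d >= 3, got d={d}")
    return d / 2.0 - math.sqrt(d * math.log(2.0))


def complete_eta(n: int) -> float:
    """Isoperimetric constant ceil(N/2) of the complete graph."""
    if n < 2:
        raise ParameterError("need N >= 2")
    return float(math.ceil(n / 2))


def rewire_adjacency(
    adj: list[set],
    u: int,
    rng: np.random.Generator,
    max_tries: int = REWIRE_MAX_TRIES,
) -> bool:
    """Degree-preserving rewiring move at node ``u``, in place.

    ``u`` severs its d current edges and connects to d nodes drawn uniformly
    from its current non-neighbours.  Each severed neighbour v is matched to
    one new neighbour w; a random existing edge (w, x) with x not in
    {u, v} and x not already adjacent to v is removed and (x, v) added, which
    restores every degree.  Collisions are resampled up to ``max_tries``;
    if any pair cannot be placed, the whole move is rolled back and the graph
    left unchanged (returns False).
    """
    n = len(adj)
    old = sorted(adj[u])
    d = len(old)
    if d == 0:
        return False
    nbrs = adj[u]
    candidates = [w for w in range(n) if w != u and w not in nbrs]
    if len(candidates) < d:
        log.debug("rewire at %d skipped: only %d candidates", u, len(candidates))
        return False
    snapshot = [s.copy() for s in adj]
    idx = rng.choice(len(candidates), size=d, replace=False)
    new = [candidates[int(i)] for i in idx]
    for v in old:
        adj[u].discard(v)
        adj[v].discard(u)
    for w in new:
        adj[u].add(w)
        adj[w].add(u)
    for v, w in zip(old, new):
        placed = False
        for _ in range(max_tries):
            pool = sorted(adj[w] - {u})
            if not pool:
                break
            x = pool[int(rng.random() * len(pool))]
            if x == v or x in adj[v]:
                continue
            adj[w].discard(x)
            adj[x].discard(w)
            adj[x].add(v)
            adj[v].add(x)
            placed = True
            break
        if not placed:
            for i in range(n):
                adj[i] = snapshot[i]
            log.debug("rewire at %d aborted: no legal edge swap", u)
            return False
    return True


def dynamic_rewire(
    graph: InteractionGraph, updating_node: int, rng: np.random.Generator
) -> InteractionGraph:
    """Functional wrapper around :func:`rewire_adjacency`.

    Returns the rewired graph, or the input graph unchanged when no legal
    move exists (e.g. on the complete graph, which has no non-neighbours).
    """
    if not (0 <= updating_node < graph.num_nodes):
        raise ParameterError(f"node {updating_node} outside graph")
    adj = graph.adjacency_sets()
    changed = rewire_adjacency(adj, updating_node, rng)
    if not changed:
        return graph
    return InteractionGraph.from_adjacency_sets(adj, positions=graph.positions)


def read_edgelist_tsv(path, num_nodes: int | None = None) -> InteractionGraph:
    """Read a two-column tab-separated edge list (0-based, no header).

    The reader symmetrises and deduplicates edges and rejects self-loops.
    """
    try:
        arr = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ParameterError(f"malformed edge list {path}: {exc}") from exc
    if arr.size == 0:
        if num_nodes is None:
            raise ParameterError(f"empty edge list {path} needs explicit num_nodes")
        return InteractionGraph.from_edges(num_nodes, [])
    if arr.shape[1] != 2:
        raise ParameterError(f"edge list {path} must have exactly two columns")
    if np.any(arr[:, 0] == arr[:, 1]):
        raise ParameterError(f"edge list {path} contains a self-loop")
    n = num_nodes if num_nodes is not None else int(arr.max()) + 1
    return InteractionGraph.from_edges(n, [tuple(row) for row in arr])


def write_edgelist_tsv(graph: InteractionGraph, path) -> None:
    rows = np.array(sorted(graph.edges), dtype=np.int64).reshape(-1, 2)
    np.savetxt(path, rows, fmt="%d", delimiter="\t")
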