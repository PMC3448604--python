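"""Global pairwise connection strengths on a probabilistic segmentation graph.

The connection strength between two superpixels is approximated by the best
single path: the maximum over paths of the product of edge probabilities,
found with a max-product variant of Dijkstra's algorithm.  Exploration is
pruned once the running product drops below a threshold ``tau``, which keeps
the all-pairs table sparse.  An optional multi-path refinement combines
successively extracted edge-disjoint strongest paths with a noisy-OR.
"""

from __future__ import annotations

import hashlib
import heapq
from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

from .graph_core import Edge, ProbabilisticSegmentationGraph, edge_key

DEFAULT_TAU = 0.01


def _fingerprint(g: ProbabilisticSegmentationGraph) -> str:
    h = hashlib.md5()
    for (u, v), p in sorted(g.p.items()):
        h.update(f"{u},{v},{p:.17g};".encode())
    return h.hexdigest()


@dataclass
class PairwiseConnectionTable:
    """Sparse symmetric map of connection strengths >= tau.

    Self-strengths are implicitly 1 and not stored; absent pairs have
    strength < tau and are read back as 0.
    """

    strengths: Dict[Edge, float]
    tau: float
    fingerprint: str
    _partners: Dict[int, Set[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._partners:
            self._rebuild_partners()

    def _rebuild_partners(self):
        self._partners = {}
        for u, v in self.strengths:
            self._partners.setdefault(u, set()).add(v)
            self._partners.setdefault(v, set()).add(u)

    def strength(self, u: int, v: int) -> float:
        if u == v:
            return 1.0
        return self.strengths.get(edge_key(u, v), 0.0)

    def partners(self, u: int) -> Set[int]:
        return self._partners.get(u, set())

    def copy(self) -> "PairwiseConnectionTable":
        return PairwiseConnectionTable(
            dict(self.strengths),
            self.tau,
            self.fingerprint,
            {k: set(v) for k, v in self._partners.items()},
        )


def _check_tau(tau: float) -> None:
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must be in (0, 1], got {tau}")


def connection_strengths_from(
    g: ProbabilisticSegmentationGraph,
    source: int,
    tau: float = DEFAULT_TAU,
    adjacency: Optional[Dict[int, list]] = None,
) -> Dict[int, float]:
    """Best-path strengths from ``source`` to every node reachable above tau.

    strength(v) = max over paths source→v of the product of edge
    probabilities; nodes whose best product falls below tau are absent.
    Ties on the frontier break toward the lowest node id for determinism.
    """
    _check_tau(tau)
    if source not in g.rag.node_sizes:
        raise KeyError(f"unknown source node {source}")
    if adjacency is None:
        adjacency = g.rag.adjacency()
    best: Dict[int, float] = {}
    heap = [(-1.0, source)]
    while heap:
        neg_s, u = heapq.heappop(heap)
        s = -neg_s
        if u in best:
            continue
        best[u] = s
        for v in adjacency[u]:
            if v in best:
                continue
            ns = s * g.p[edge_key(u, v)]
            if ns >= tau:
                heapq.heappush(heap, (-ns, v))
    return best


def all_pairs_table(
    g: ProbabilisticSegmentationGraph, tau: float = DEFAULT_TAU
) -> PairwiseConnectionTable:
    """Union of single-source best-path runs from every node."""
    _check_tau(tau)
    adjacency = g.rag.adjacency()
    strengths: Dict[Edge, float] = {}
    for source in sorted(g.rag.node_sizes):
        reached = connection_strengths_from(g, source, tau, adjacency)
        for v, s in reached.items():
            if v > source:
                strengths[(source, v)] = s
    return PairwiseConnectionTable(strengths, tau, _fingerprint(g))


def update_table_after_decision(
    table: PairwiseConnectionTable,
    g: ProbabilisticSegmentationGraph,
    edge: Edge,
    new_p: float,
) -> PairwiseConnectionTable:
    """Table for ``g`` with ``edge`` set to ``new_p``, updated incrementally.

    ``g`` is the graph the table was built from (probability of ``edge`` still
    the old value); the returned table equals a fresh ``all_pairs_table`` on
    the updated graph.  Only sources whose stored strengths touch the edge's
    endpoints are recomputed: any pair whose best path can change has a
    stored prefix reaching an endpoint (path products are monotone), so the
    affected-source set {a, b} ∪ partners(a) ∪ partners(b) is exhaustive.
    """
    e = edge_key(*edge)
    if e not in g.p:
        raise KeyError(f"unknown edge {e}")
    old_p = g.p[e]
    if new_p == old_p:
        return table
    g2 = g.with_edge_p(e, new_p)
    a, b = e
    affected = {a, b} | set(table.partners(a)) | set(table.partners(b))

    new_table = table.copy()
    new_table.fingerprint = _fingerprint(g2)
    for x in affected:
        for y in list(new_table.partners(x)):
            new_table.strengths.pop(edge_key(x, y), None)
            new_table._partners[y].discard(x)
        new_table._partners[x] = set()
    adjacency = g2.rag.adjacency()
    for x in sorted(affected):
        reached = connection_strengths_from(g2, x, table.tau, adjacency)
        for v, s in reached.items():
            if v == x:
                continue
            new_table.strengths[edge_key(x, v)] = s
            new_table._partners.setdefault(x, set()).add(v)
            new_table._partners.setdefault(v, set()).add(x)
    return new_table


def _best_path(
    g: ProbabilisticSegmentationGraph,
    u: int,
    v: int,
    tau: float,
    excluded: Set[Edge],
    adjacency: Dict[int, list],
) -> Tuple[float, list]:
    """Strongest u→v path avoiding ``excluded`` edges; ([], 0.0) if none."""
    settled: Dict[int, float] = {}
    tentative: Dict[int, float] = {}
    parent: Dict[int, int] = {}
    heap = [(-1.0, u)]
    while heap:
        neg_s, x = heapq.heappop(heap)
        s = -neg_s
        if x in settled:
            continue
        settled[x] = s
        if x == v:
            path = [v]
            while path[-1] != u:
                path.append(parent[path[-1]])
            return s, path[::-1]
        for y in adjacency[x]:
            if y in settled:
                continue
            e = edge_key(x, y)
            if e in excluded:
                continue
            ns = s * g.p[e]
            if ns >= tau and ns > tentative.get(y, 0.0):
                tentative[y] = ns
                parent[y] = x
                heapq.heappush(heap, (-ns, y))
    return 0.0, []


def multipath_strength(
    g: ProbabilisticSegmentationGraph,
    u: int,
    v: int,
    max_paths: int,
    tau: float = DEFAULT_TAU,
) -> float:
    """Noisy-OR combination of up to ``max_paths`` edge-disjoint best paths.

    With independent edges, edge-disjoint path events are independent, so
    1 - Π(1 - s_k) never exceeds the exact connection probability and equals
    it on trees (single path).  max_paths=1 reduces to the one-path strength.
    """
    if max_paths < 1:
        raise ValueError("max_paths must be >= 1")
    if u == v:
        return 1.0
    adjacency = g.rag.adjacency()
    excluded: Set[Edge] = set()
    miss = 1.0
    for _ in range(max_paths):
        s, path = _best_path(g, u, v, tau, excluded, adjacency)
        if not path:
            break
        miss *= 1.0 - s
        for a, b in zip(path[:-1], path[1:]):
            excluded.add(edge_key(a, b))
    return 1.0 - miss


def multipath_table(
    g: ProbabilisticSegmentationGraph,
    tau: float = DEFAULT_TAU,
    max_paths: int = 16,
) -> PairwiseConnectionTable:
    """All-pairs table with multi-path strengths for every stored pair.

    Pair support is that of the one-path table (pairs pruned there stay
    pruned); each surviving pair's strength is refined by ``multipath_strength``.
    """
    base = all_pairs_table(g, tau)
    strengths = {
        pair: multipath_strength(g, pair[0], pair[1], max_paths, tau)
        for pair in base.strengths
    }
    return PairwiseConnectionTable(strengths, tau, base.fingerprint)
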