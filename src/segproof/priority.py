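"""Edge prioritization for manual inspection.

An edge's impact is the expected absolute change of the graph certainty
score if that edge were resolved: the merge outcome weighted by the edge
probability plus the split outcome weighted by its complement.  Edges whose
probability lies outside a band are heuristically skipped, and the ranking
is only refreshed every few decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .connectivity import PairwiseConnectionTable, update_table_after_decision
from .graph_core import Edge, ProbabilisticSegmentationGraph, edge_key
from .metrics import gpr

DEFAULT_BAND = (0.01, 0.99)
EDGE_PROBABILITY_BAND = (0.10, 0.90)
DEFAULT_BATCH_SIZE = 10

STRATEGIES = ("gpr", "random", "edge_probability")


@dataclass(frozen=True)
class ImpactRanking:
    ranking: Tuple[Tuple[Edge, float], ...]  # sorted by impact, descending
    band: Tuple[float, float]
    batch_size: int

    @property
    def edges(self) -> List[Edge]:
        return [e for e, _ in self.ranking]


def edge_impact(
    g: ProbabilisticSegmentationGraph,
    table: PairwiseConnectionTable,
    edge: Edge,
    _baseline: Optional[float] = None,
) -> float:
    """Expected absolute change in the certainty score from deciding ``edge``."""
    e = edge_key(*edge)
    if e not in g.p:
        raise KeyError(f"unknown edge {e}")
    p_e = g.p[e]
    base = gpr(g, table).gpr if _baseline is None else _baseline

    impact = 0.0
    for outcome, weight in ((1.0, p_e), (0.0, 1.0 - p_e)):
        if weight == 0.0:
            continue
        t2 = update_table_after_decision(table, g, e, outcome)
        g2 = g.with_edge_p(e, outcome)
        impact += weight * abs(gpr(g2, t2).gpr - base)
    return impact


def rank_edges(
    g: ProbabilisticSegmentationGraph,
    table: PairwiseConnectionTable,
    band: Tuple[float, float] = DEFAULT_BAND,
    batch_size: int = DEFAULT_BATCH_SIZE,
    candidates: Optional[Sequence[Edge]] = None,
) -> ImpactRanking:
    """Score band-interior edges by impact; ties break on the edge key."""
    low, high = band
    if not (0.0 <= low <= 1.0 and 0.0 <= high <= 1.0):
        raise ValueError(f"band limits must lie in [0, 1], got {band}")
    if low >= high:
        return ImpactRanking(ranking=(), band=band, batch_size=batch_size)
    pool = g.p.keys() if candidates is None else [edge_key(*e) for e in candidates]
    in_band = [e for e in sorted(pool) if low < g.p[e] < high]
    if not in_band:
        return ImpactRanking(ranking=(), band=band, batch_size=batch_size)
    base = gpr(g, table).gpr
    scored = [(e, edge_impact(g, table, e, _baseline=base)) for e in in_band]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return ImpactRanking(ranking=tuple(scored), band=band, batch_size=batch_size)


def strategy_order(
    g: ProbabilisticSegmentationGraph,
    table: PairwiseConnectionTable,
    strategy: str,
    seed: int = 0,
    band: Tuple[float, float] = DEFAULT_BAND,
) -> List[Edge]:
    """Initial edge inspection order for a named strategy.

    gpr: impact ranking (a snapshot; the loop refreshes it in batches);
    random: seeded shuffle of band-interior edges; edge_probability: edges
    with p in [0.10, 0.90], most uncertain first.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "gpr":
        return rank_edges(g, table, band=band).edges
    if strategy == "random":
        low, high = band
        pool = [e for e in sorted(g.p) if low < g.p[e] < high]
        rng = np.random.default_rng(seed)
        rng.shuffle(pool)
        return pool
    low, high = EDGE_PROBABILITY_BAND
    pool = [e for e in sorted(g.p) if low <= g.p[e] <= high]
    pool.sort(key=lambda e: (abs(g.p[e] - 0.5), e))
    return pool
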