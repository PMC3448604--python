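"""Simulated proofreading: pick an edge, ask the oracle, update, repeat.

The loop alternates ranking (per the chosen strategy), a yes/no decision
from a ground-truth oracle, a graph/table update, and an exact certainty
re-evaluation, terminating once the score exceeds the cutoff or the
candidate pool is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Set, Tuple

from .connectivity import (
    DEFAULT_TAU,
    PairwiseConnectionTable,
    all_pairs_table,
    update_table_after_decision,
)
from .edge_model import EdgeLabelSet
from .graph_core import Edge, ProbabilisticSegmentationGraph, edge_key
from .metrics import gpr
from .priority import (
    DEFAULT_BAND,
    DEFAULT_BATCH_SIZE,
    rank_edges,
    strategy_order,
)

logger = logging.getLogger(__name__)

CONNECTED = "connected"
SEPARATED = "separated"


@dataclass(frozen=True)
class Decision:
    edge: Edge
    verdict: str
    index: int


@dataclass
class ProofreadSession:
    strategy: str
    cutoff: float
    seed: int
    initial_gpr: float
    decisions: List[Decision] = field(default_factory=list)
    trace: List[float] = field(default_factory=list)
    exhausted: bool = False
    n_edges: int = 0
    final_graph: Optional[ProbabilisticSegmentationGraph] = None
    final_table: Optional[PairwiseConnectionTable] = None

    @property
    def final_gpr(self) -> float:
        return self.trace[-1] if self.trace else self.initial_gpr

    @property
    def effort(self) -> float:
        return len(self.decisions) / self.n_edges if self.n_edges else 0.0

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "cutoff": self.cutoff,
            "seed": self.seed,
            "initial_gpr": self.initial_gpr,
            "final_gpr": self.final_gpr,
            "n_decisions": len(self.decisions),
            "n_edges": self.n_edges,
            "effort": self.effort,
            "exhausted": self.exhausted,
        }


def oracle_decide(edge: Edge, gt_edge_labels: EdgeLabelSet) -> str:
    """Yes/no verdict from ground truth: connected iff same segment."""
    e = edge_key(*edge)
    if e not in gt_edge_labels.labels:
        raise KeyError(f"edge {e} has no ground-truth label")
    return CONNECTED if gt_edge_labels.labels[e] else SEPARATED


def apply_decision(
    g: ProbabilisticSegmentationGraph,
    table: PairwiseConnectionTable,
    decision: Decision,
    decided: Optional[Set[Edge]] = None,
) -> Tuple[ProbabilisticSegmentationGraph, PairwiseConnectionTable]:
    """Set the decided edge's probability to 0/1 and update the table.

    Neighboring edge probabilities are deliberately not re-estimated after a
    merge; only the decided edge changes.
    """
    e = edge_key(*decision.edge)
    if e not in g.p:
        raise KeyError(f"unknown edge {e}")
    if decided is not None and e in decided:
        raise ValueError(f"edge {e} was already decided")
    new_p = 1.0 if decision.verdict == CONNECTED else 0.0
    new_table = update_table_after_decision(table, g, e, new_p)
    new_g = g.with_edge_p(e, new_p)
    return new_g, new_table


def run_session(
    g: ProbabilisticSegmentationGraph,
    gt_edge_labels: EdgeLabelSet,
    strategy: str,
    cutoff: float = 0.9,
    batch_size: int = DEFAULT_BATCH_SIZE,
    seed: int = 0,
    band: Tuple[float, float] = DEFAULT_BAND,
    tau: float = DEFAULT_TAU,
    table: Optional[PairwiseConnectionTable] = None,
) -> ProofreadSession:
    """Run proofreading until the certainty score exceeds ``cutoff``.

    The score is recomputed exactly after every decision; only the impact
    ranking (gpr strategy) is refreshed in batches.  If the band-interior
    candidates run out below the cutoff, the band widens once to (0, 1)
    before the session is declared exhausted.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    missing = set(g.p) - set(gt_edge_labels.labels)
    if missing:
        raise ValueError(f"ground truth does not cover edges: {sorted(missing)[:3]}")
    if table is None:
        table = all_pairs_table(g, tau)
    current = gpr(g, table).gpr
    session = ProofreadSession(
        strategy=strategy,
        cutoff=cutoff,
        seed=seed,
        initial_gpr=current,
        n_edges=len(g.p),
    )
    decided: Set[Edge] = set()
    widened = False
    queue = strategy_order(g, table, strategy, seed=seed, band=band)
    since_refresh = 0

    while current <= cutoff:
        edge = next((e for e in queue if e not in decided), None)
        if edge is None:
            if not widened:
                widened = True
                logger.warning(
                    "band %s exhausted at score %.4f < cutoff %.4f; widening to (0, 1)",
                    band,
                    current,
                    cutoff,
                )
                band = (0.0, 1.0)
                queue = [
                    e
                    for e in strategy_order(g, table, strategy, seed=seed, band=band)
                    if e not in decided
                ]
                if strategy == "edge_probability":
                    # its fixed band is part of the strategy; fall back to
                    # uncertainty order over all undecided uncertain edges
                    pool = [e for e in sorted(g.p) if 0.0 < g.p[e] < 1.0 and e not in decided]
                    pool.sort(key=lambda e: (abs(g.p[e] - 0.5), e))
                    queue = pool
                continue
            session.exhausted = True
            break
        verdict = oracle_decide(edge, gt_edge_labels)
        decision = Decision(edge=edge, verdict=verdict, index=len(session.decisions))
        g, table = apply_decision(g, table, decision, decided)
        decided.add(edge)
        session.decisions.append(decision)
        current = gpr(g, table).gpr
        session.trace.append(current)
        since_refresh += 1
        if strategy == "gpr" and since_refresh >= batch_size:
            since_refresh = 0
            queue = [
                e
                for e in rank_edges(g, table, band=band, batch_size=batch_size).edges
                if e not in decided
            ]
    session.final_graph = g
    session.final_table = table
    return session


def replay_session(
    g: ProbabilisticSegmentationGraph,
    session: ProofreadSession,
    tau: float = DEFAULT_TAU,
) -> Tuple[ProbabilisticSegmentationGraph, PairwiseConnectionTable, List[float]]:
    """Re-apply a session's decision log; returns final graph, table, trace."""
    table = all_pairs_table(g, tau)
    trace: List[float] = []
    decided: Set[Edge] = set()
    for decision in session.decisions:
        g, table = apply_decision(g, table, decision, decided)
        decided.add(edge_key(*decision.edge))
        trace.append(gpr(g, table).gpr)
    return g, table, trace
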