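"""Concrete segmentations from the graph by threshold merging, and sweeps
comparing the graph-predicted quality curve with the actual one.

The mean-boundary threshold axis runs 0..256 with the printed endpoint
semantics: at 0 every boundary counts as a connection (single segment), at
256 none does (superpixels unchanged).  Merging is simultaneous: all edges
passing the criterion are closed transitively in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .connectivity import PairwiseConnectionTable
from .graph_core import (
    Partition,
    ProbabilisticSegmentationGraph,
    RegionAdjacencyGraph,
    components_partition,
)
from .metrics import adjusted_rand_index, gpr_vs_segmentation

MEAN_BOUNDARY = "mean_boundary"
EDGE_PROBABILITY = "edge_probability"


@dataclass
class AgglomerationResult:
    partition: Partition
    method: str
    threshold: float
    n_segments: int
    gpr_vs_seg: Optional[float] = None
    ari: Optional[float] = None


def _connection_evidence(rag: RegionAdjacencyGraph) -> dict:
    """Edge connection evidence on the 0..256 axis: 256·(1 − mean boundary)."""
    return {e: 256.0 * (1.0 - st.mean) for e, st in rag.edge_stats.items()}


def agglomerate_mean_boundary(
    rag: RegionAdjacencyGraph,
    threshold: float,
    overrides: Optional[dict] = None,
) -> AgglomerationResult:
    """Merge every edge whose connection evidence reaches the threshold.

    threshold 0 merges everything (one segment); threshold 256 merges
    nothing, by the endpoint contract.  ``overrides`` maps edges to proofread
    verdicts (True = connected) that trump the threshold criterion, so manual
    decisions are re-incorporated into the agglomeration.
    """
    if not (0.0 <= threshold <= 256.0):
        raise ValueError(f"threshold must be in [0, 256], got {threshold}")
    overrides = overrides or {}
    evidence = _connection_evidence(rag)
    merged: List = []
    for e, ev in evidence.items():
        if e in overrides:
            if overrides[e]:
                merged.append(e)
        elif threshold < 256.0 and ev >= threshold:
            merged.append(e)
    partition = components_partition(rag.node_sizes, merged)
    return AgglomerationResult(
        partition=partition,
        method=MEAN_BOUNDARY,
        threshold=threshold,
        n_segments=partition.n_segments,
    )


def agglomerate_edge_probability(
    g: ProbabilisticSegmentationGraph, threshold: float
) -> AgglomerationResult:
    """Merge every edge with connection probability >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    merged = [e for e, p in g.p.items() if p >= threshold]
    partition = components_partition(g.rag.node_sizes, merged)
    return AgglomerationResult(
        partition=partition,
        method=EDGE_PROBABILITY,
        threshold=threshold,
        n_segments=partition.n_segments,
    )


def relabel_image(sp_labels, partition: Partition):
    """Merged label image: superpixel ids mapped through the partition."""
    import numpy as np

    from .graph_core import SuperpixelLabeling

    arr = sp_labels.labels
    lut = np.zeros(int(arr.max()) + 1, dtype=arr.dtype)
    for sp_id, seg in partition.assignment.items():
        if sp_id <= arr.max():
            lut[sp_id] = seg
    return SuperpixelLabeling(lut[arr])


@dataclass
class SweepSummary:
    results: List[AgglomerationResult]
    predicted_optimal: Optional[float] = None  # argmax of the graph-predicted curve
    actual_optimal: Optional[float] = None  # argmax of the ARI curve (needs gt)
    best_ari: Optional[float] = None


def threshold_sweep(
    g: ProbabilisticSegmentationGraph,
    method: str,
    thresholds: Sequence[float],
    table: Optional[PairwiseConnectionTable] = None,
    gt_partition: Optional[Partition] = None,
    overrides: Optional[dict] = None,
) -> SweepSummary:
    """Agglomerate at each threshold and score the resulting partitions.

    With a table, each partition gets the graph-vs-segmentation score; with a
    ground-truth partition, the adjusted Rand index.  Optima are the
    thresholds maximizing each curve (ties toward the lower threshold).
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    results: List[AgglomerationResult] = []
    for t in thresholds:
        if method == MEAN_BOUNDARY:
            res = agglomerate_mean_boundary(g.rag, t, overrides=overrides)
        elif method == EDGE_PROBABILITY:
            res = agglomerate_edge_probability(g, t)
        else:
            raise ValueError(f"unknown method {method!r}")
        if table is not None:
            res.gpr_vs_seg = gpr_vs_segmentation(g, table, res.partition).gpr
        if gt_partition is not None:
            res.ari = adjusted_rand_index(res.partition, gt_partition, g.rag.node_sizes)
        results.append(res)

    summary = SweepSummary(results=results)
    if table is not None:
        summary.predicted_optimal = max(results, key=lambda r: (r.gpr_vs_seg, -r.threshold)).threshold
    if gt_partition is not None:
        best = max(results, key=lambda r: (r.ari, -r.threshold))
        summary.actual_optimal = best.threshold
        summary.best_ari = best.ari
    return summary
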