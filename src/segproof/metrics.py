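"""Partition similarity and graph-certainty metrics.

Implements the pixel-weighted Rand index and Hubert–Arabie adjusted Rand
index between two partitions, and their ground-truth-free analogues on a
probabilistic segmentation graph: the unnormalized index ``u_gpr`` (expected
self-agreement of two independent draws from the graph) and its normalized
form ``gpr`` anchored at 1 for full certainty and 0 for chance-level
self-agreement.  ``gpr_vs_segmentation`` scores a concrete partition against
the graph and reduces exactly to the adjusted Rand index when the graph is
certain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

from .graph_core import Partition, ProbabilisticSegmentationGraph

_DEGENERATE_EPS = 1e-12


@dataclass(frozen=True)
class MetricResult:
    rand_index: float
    adjusted_rand_index: float
    max_index: float
    expected: float


@dataclass(frozen=True)
class GprReport:
    u_gpr: float
    expected_max: float
    expected: float
    gpr: float
    #: (within-superpixel, cross stored, cross pruned) pixel-pair counts
    pair_counts: Tuple[int, int, int]

    def to_dict(self) -> dict:
        return {
            "u_gpr": self.u_gpr,
            "expected_max": self.expected_max,
            "expected": self.expected,
            "gpr": self.gpr,
            "pair_counts": {
                "within_superpixel": self.pair_counts[0],
                "cross_stored": self.pair_counts[1],
                "cross_pruned": self.pair_counts[2],
            },
        }


def _comb2(x: int) -> int:
    return x * (x - 1) // 2


def _check_universe(a: Partition, b: Partition, sizes: Mapping[int, int]) -> None:
    ka, kb, ks = set(a.assignment), set(b.assignment), set(sizes)
    if ka != kb or ka != ks:
        raise ValueError("partitions and sizes must share the same superpixel universe")


def compare_partitions(a: Partition, b: Partition, sizes: Mapping[int, int]) -> MetricResult:
    """Rand index and adjusted Rand index, with superpixels weighted by size.

    Exact integer pair counting: each superpixel of size s stands for s pixels
    that share both partitions' segment assignments.
    """
    _check_universe(a, b, sizes)
    n = sum(sizes.values())
    if n < 2:
        raise ValueError("need at least 2 pixels")
    total = _comb2(n)

    cont: Dict[Tuple[int, int], int] = {}
    row: Dict[int, int] = {}
    col: Dict[int, int] = {}
    for sp, s in sizes.items():
        key = (a.assignment[sp], b.assignment[sp])
        cont[key] = cont.get(key, 0) + s
        row[key[0]] = row.get(key[0], 0) + s
        col[key[1]] = col.get(key[1], 0) + s

    index = sum(_comb2(c) for c in cont.values())
    sum_a = sum(_comb2(c) for c in row.values())
    sum_b = sum(_comb2(c) for c in col.values())

    # agreements = same-same + different-different
    agreements = total + 2 * index - sum_a - sum_b
    ri = agreements / total

    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    denom = max_index - expected
    if abs(denom) < _DEGENERATE_EPS:
        warnings.warn("degenerate ARI normalization (max_index == expected); defining ARI = 0")
        ari = 0.0
    else:
        ari = (index - expected) / denom
    return MetricResult(rand_index=ri, adjusted_rand_index=ari, max_index=max_index, expected=expected)


def rand_index(a: Partition, b: Partition, sizes: Mapping[int, int]) -> float:
    return compare_partitions(a, b, sizes).rand_index


def adjusted_rand_index(a: Partition, b: Partition, sizes: Mapping[int, int]) -> float:
    return compare_partitions(a, b, sizes).adjusted_rand_index


def _graph_pair_sums(g: ProbabilisticSegmentationGraph, table):
    """Shared bookkeeping for the graph self-comparison metrics."""
    sizes = g.rag.node_sizes
    n = sum(sizes.values())
    if n < 2:
        raise ValueError("graph must cover at least 2 pixels")
    within = sum(_comb2(s) for s in sizes.values())
    total = _comb2(n)
    cross_total = total - within

    stored_w = 0  # Σ s_i s_j over stored pairs
    agree = 0.0  # Σ s_i s_j (q² + (1-q)²)
    same = 0.0  # Σ s_i s_j q
    for (u, v), q in table.strengths.items():
        w = sizes[u] * sizes[v]
        stored_w += w
        agree += w * (q * q + (1.0 - q) * (1.0 - q))
        same += w * q
    return sizes, n, within, total, cross_total, stored_w, agree, same


def u_gpr(g: ProbabilisticSegmentationGraph, table) -> float:
    """Unnormalized certainty index: expected pixel-pair self-agreement.

    Within-superpixel pairs agree with certainty; a cross pair with connection
    strength q agrees with probability q² + (1-q)²; pairs pruned from the
    table are treated as q = 0 (certain separation, agreement 1).
    """
    _, _, within, total, cross_total, stored_w, agree, _ = _graph_pair_sums(g, table)
    return (within + agree + (cross_total - stored_w)) / total


def gpr(g: ProbabilisticSegmentationGraph, table) -> GprReport:
    """Normalized certainty index of the graph compared with itself.

    ``expected_max`` is the expected fraction of same-segment pixel pairs (the
    graph's expected granularity); ``expected`` the chance self-agreement at
    that granularity.  Full certainty gives 1, maximal uncertainty 0.
    """
    _, _, within, total, cross_total, stored_w, agree, same = _graph_pair_sums(g, table)
    u = (within + agree + (cross_total - stored_w)) / total
    expected_max = (within + same) / total
    expected = expected_max**2 + (1.0 - expected_max) ** 2
    denom = 1.0 - expected
    if abs(denom) < _DEGENERATE_EPS:
        if abs(u - 1.0) < _DEGENERATE_EPS:
            value = 1.0
        else:
            warnings.warn("degenerate GPR normalization with u_gpr < 1; defining GPR = 0")
            value = 0.0
    else:
        value = (u - expected) / denom
    return GprReport(
        u_gpr=u,
        expected_max=expected_max,
        expected=expected,
        gpr=value,
        pair_counts=(within, stored_w, cross_total - stored_w),
    )


def gpr_vs_segmentation(
    g: ProbabilisticSegmentationGraph, table, seg: Partition
) -> GprReport:
    """Score a concrete segmentation against the probabilistic graph.

    Per-pair agreement is q for same-segment pairs and 1-q otherwise; the
    normalization uses the graph's and the segmentation's granularities like
    the adjusted Rand index, to which this reduces when the graph is certain.
    """
    sizes, n, within, total, cross_total, stored_w, _, same = _graph_pair_sums(g, table)
    missing = set(sizes) - set(seg.assignment)
    if missing:
        raise ValueError(f"segmentation does not cover nodes: {sorted(missing)[:3]}")

    # Σ s_i s_j over all same-segment cross pairs of seg
    seg_tot: Dict[int, int] = {}
    seg_sq: Dict[int, int] = {}
    for sp, s in sizes.items():
        lab = seg.assignment[sp]
        seg_tot[lab] = seg_tot.get(lab, 0) + s
        seg_sq[lab] = seg_sq.get(lab, 0) + s * s
    same_seg_w = sum((seg_tot[k] ** 2 - seg_sq[k]) // 2 for k in seg_tot)

    agree = 0.0
    stored_same_w = 0
    for (u, v), q in table.strengths.items():
        w = sizes[u] * sizes[v]
        if seg.same_segment(u, v):
            agree += w * q
            stored_same_w += w
        else:
            agree += w * (1.0 - q)
    # pruned pairs have q = 0: agreement 1 on different-segment pairs only
    absent_same = same_seg_w - stored_same_w
    absent_diff = (cross_total - stored_w) - absent_same
    u_val = (within + agree + absent_diff) / total

    em_graph = (within + same) / total
    em_seg = (within + same_seg_w) / total
    expected = em_graph * em_seg + (1.0 - em_graph) * (1.0 - em_seg)
    denom = 1.0 - expected
    if abs(denom) < _DEGENERATE_EPS:
        if abs(u_val - 1.0) < _DEGENERATE_EPS:
            value = 1.0
        else:
            warnings.warn("degenerate normalization with u < 1; defining score = 0")
            value = 0.0
    else:
        value = (u_val - expected) / denom
    return GprReport(
        u_gpr=u_val,
        expected_max=0.5 * (em_graph + em_seg),
        expected=expected,
        gpr=value,
        pair_counts=(within, stored_w, cross_total - stored_w),
    )
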