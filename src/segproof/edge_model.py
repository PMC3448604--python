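"""Edge features, ground-truth edge labels, and the edge classifier.

Eight features are derived per RAG edge from the boundary map; a random
forest trained against ground-truth connected/separated labels turns them
into connection probabilities.  Training-set probabilities are out-of-bag so
the uncertainty estimate is not contaminated by memorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .graph_core import (
    Edge,
    Partition,
    ProbabilisticSegmentationGraph,
    RegionAdjacencyGraph,
    SuperpixelLabeling,
    _scan_interfaces,
    edge_key,
    normalize_boundary_map,
)

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8")
#: column layout of the feature matrix; f4 spans two columns (sizes small, large)
FEATURE_COLUMNS = ("f1", "f2", "f3", "f4a", "f4b", "f5", "f6", "f7", "f8")
_FEATURE_TO_COLS = {
    "f1": (0,),
    "f2": (1,),
    "f3": (2,),
    "f4": (3, 4),
    "f5": (5,),
    "f6": (6,),
    "f7": (7,),
    "f8": (8,),
}

# matches VIGRA's default forest size; sklearn's other defaults are kept
N_TREES = 255


@dataclass(frozen=True)
class EdgeLabelSet:
    """Connected/separated label per RAG edge, derived from ground truth."""

    labels: Dict[Edge, bool]  # True = connected (same ground-truth segment)
    assignment: Partition  # superpixel -> majority ground-truth segment
    violation_fraction: float  # superpixels whose majority share < 100%

    def is_connected(self, edge: Edge) -> bool:
        return self.labels[edge_key(*edge)]


def project_to_ground_truth(
    sp_labels: SuperpixelLabeling, gt: SuperpixelLabeling
) -> Tuple[Partition, float]:
    """Assign each superpixel the ground-truth segment covering most of it.

    Returns the assignment and the fraction of superpixels whose pixels are
    not wholly inside one ground-truth segment (atomicity violations).
    """
    sp = sp_labels.labels
    if sp.shape != gt.labels.shape:
        raise ValueError("superpixel and ground-truth shapes differ")
    mask = sp > 0
    pairs = sp[mask].astype(np.int64) * (int(gt.labels.max()) + 1) + gt.labels[mask]
    uniq, counts = np.unique(pairs, return_counts=True)
    base = int(gt.labels.max()) + 1
    overlap: Dict[int, Dict[int, int]] = {}
    for code, c in zip(uniq.tolist(), counts.tolist()):
        sp_id, gt_id = divmod(code, base)
        overlap.setdefault(sp_id, {})[gt_id] = c

    assignment: Dict[int, int] = {}
    violations = 0
    for sp_id, seen in overlap.items():
        nonzero = {g: c for g, c in seen.items() if g > 0}
        if not nonzero:
            raise ValueError(f"superpixel {sp_id} has no overlap with any ground-truth segment")
        # deterministic: largest overlap, ties to the lowest segment id
        best = min(nonzero, key=lambda g: (-nonzero[g], g))
        assignment[sp_id] = best
        total = sum(seen.values())
        if nonzero[best] < total:
            violations += 1
    return Partition(assignment), violations / len(overlap)


def ground_truth_edge_labels(
    rag: RegionAdjacencyGraph,
    sp_labels: SuperpixelLabeling,
    gt: SuperpixelLabeling,
) -> EdgeLabelSet:
    assignment, violation = project_to_ground_truth(sp_labels, gt)
    labels = {
        e: assignment.assignment[e[0]] == assignment.assignment[e[1]]
        for e in rag.edge_stats
    }
    return EdgeLabelSet(labels=labels, assignment=assignment, violation_fraction=violation)


def _interior_means(sp: np.ndarray, bmap: np.ndarray) -> Dict[int, float]:
    """Mean boundary value over each superpixel's interior pixels.

    A pixel is interior when all in-bounds 4-neighbors carry the same id;
    superpixels without interior pixels fall back to all their pixels.
    """
    same = np.ones(sp.shape, dtype=bool)
    same[1:, :] &= sp[1:, :] == sp[:-1, :]
    same[:-1, :] &= sp[:-1, :] == sp[1:, :]
    same[:, 1:] &= sp[:, 1:] == sp[:, :-1]
    same[:, :-1] &= sp[:, :-1] == sp[:, 1:]
    means: Dict[int, float] = {}
    for arr_mask in (same & (sp > 0), sp > 0):
        ids = sp[arr_mask]
        if ids.size:
            sums = np.bincount(ids, weights=bmap[arr_mask])
            counts = np.bincount(ids)
            present = np.nonzero(counts)[0]
            for i in present:
                if i > 0 and int(i) not in means:
                    means[int(i)] = float(sums[i] / counts[i])
    return means


def extract_edge_features(
    rag: RegionAdjacencyGraph,
    sp_labels: SuperpixelLabeling,
    boundary_map: np.ndarray,
) -> Dict[Edge, np.ndarray]:
    """Per-edge feature vectors (columns per ``FEATURE_COLUMNS``).

    f1/f2/f3: mean/min/max boundary value over the edge's separating pixels;
    f4: both node sizes, small then large; f5: absolute difference of the
    nodes' interior means; f6: product of (edge mean - interior mean) over the
    two nodes; f7: max over the nodes of the summed boundary value of the
    node's pixels touching this edge, divided by node size; f8: edge size.
    """
    sp = sp_labels.labels
    bmap = normalize_boundary_map(boundary_map)
    if bmap.shape != sp.shape:
        raise ValueError("boundary map shape differs from labels")
    interior = _interior_means(sp, bmap)
    zero_pixels, contacts = _scan_interfaces(sp)
    rows, cols = sp.shape

    features: Dict[Edge, np.ndarray] = {}
    for e, st in rag.edge_stats.items():
        u, v = e
        su, sv = rag.node_sizes[u], rag.node_sizes[v]
        # pixels of each endpoint adjacent to this edge's interface
        touching: Dict[int, set] = {u: set(), v: set()}
        for r, c in zero_pixels.get(e, []):
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    lab = int(sp[rr, cc])
                    if lab in touching:
                        touching[lab].add((rr, cc))
        for p1, p2 in contacts.get(e, []):
            touching[int(sp[p1])].add(p1)
            touching[int(sp[p2])].add(p2)
        edge_sum = {
            node: sum(bmap[px] for px in pixels) for node, pixels in touching.items()
        }
        f7 = max(edge_sum[u] / su, edge_sum[v] / sv)
        f6 = (st.mean - interior[u]) * (st.mean - interior[v])
        features[e] = np.array(
            [
                st.mean,
                st.min,
                st.max,
                min(su, sv),
                max(su, sv),
                abs(interior[u] - interior[v]),
                f6,
                f7,
                st.count,
            ],
            dtype=float,
        )
    return features


def _subset_columns(feature_subset: Optional[Iterable[str]]) -> Sequence[int]:
    if feature_subset is None:
        return tuple(range(len(FEATURE_COLUMNS)))
    cols: list = []
    for name in feature_subset:
        if name not in _FEATURE_TO_COLS:
            raise ValueError(f"unknown feature {name!r}")
        cols.extend(_FEATURE_TO_COLS[name])
    return tuple(sorted(set(cols)))


@dataclass
class EdgeClassifier:
    """Random forest over edge features, exposing P(connected)."""

    model: RandomForestClassifier
    columns: Sequence[int]
    feature_subset: Optional[Tuple[str, ...]] = None
    oob_proba: Dict[Edge, float] = field(default_factory=dict)

    def predict_proba_map(self, features: Mapping[Edge, np.ndarray]) -> Dict[Edge, float]:
        edges = sorted(features)
        X = np.array([features[e] for e in edges])[:, self.columns]
        idx = list(self.model.classes_).index(1)
        proba = self.model.predict_proba(X)[:, idx]
        return {e: float(np.clip(p, 0.0, 1.0)) for e, p in zip(edges, proba)}


def train_edge_classifier(
    features: Mapping[Edge, np.ndarray],
    labels: EdgeLabelSet,
    seed: int = 0,
    feature_subset: Optional[Iterable[str]] = None,
    n_estimators: Optional[int] = None,
) -> EdgeClassifier:
    """Fit the forest; training-set probabilities are out-of-bag estimates."""
    edges = sorted(features)
    cols = _subset_columns(feature_subset)
    X = np.array([features[e] for e in edges])[:, cols]
    y = np.array([1 if labels.is_connected(e) else 0 for e in edges])
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=n_estimators or N_TREES, random_state=seed, oob_score=True, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse OOB coverage warning at tiny n
        model.fit(X, y)
    idx = list(model.classes_).index(1)
    oob = model.oob_decision_function_[:, idx]
    bad = ~np.isfinite(oob)
    if bad.any():  # samples never out-of-bag: fall back to the fitted forest
        oob[bad] = model.predict_proba(X[bad])[:, idx]
    oob_proba = {e: float(np.clip(p, 0.0, 1.0)) for e, p in zip(edges, oob)}
    subset = tuple(feature_subset) if feature_subset is not None else None
    return EdgeClassifier(model=model, columns=cols, feature_subset=subset, oob_proba=oob_proba)


def attach_probabilities(
    rag: RegionAdjacencyGraph,
    probabilities: Optional[Mapping[Edge, float]] = None,
    classifier: Optional[EdgeClassifier] = None,
    features: Optional[Mapping[Edge, np.ndarray]] = None,
) -> ProbabilisticSegmentationGraph:
    """Build the probabilistic graph from an explicit map or a classifier."""
    if probabilities is None:
        if classifier is None or features is None:
            raise ValueError("need either an explicit probability map or classifier+features")
        probabilities = classifier.predict_proba_map(features)
    p: Dict[Edge, float] = {}
    for e in rag.edge_stats:
        if e not in probabilities:
            raise ValueError(f"missing probability for edge {e}")
        p[e] = float(np.clip(probabilities[e], 0.0, 1.0))
    return ProbabilisticSegmentationGraph(rag, p)
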