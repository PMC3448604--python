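"""Synthetic scenes: ground-truth partitions, oversegmented superpixels,
noisy boundary maps, and calibration-controlled edge probabilities.

Scenes are Voronoi partitions refined by a secondary Voronoi inside each
ground-truth cell, which guarantees superpixel atomicity.  The boundary map
decays with distance from the ground-truth boundary and is corrupted by
Gaussian noise, giving the edge classifier a realistic, imperfect signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .edge_model import (
    EdgeClassifier,
    EdgeLabelSet,
    attach_probabilities,
    extract_edge_features,
    ground_truth_edge_labels,
    train_edge_classifier,
)
from .graph_core import (
    ProbabilisticSegmentationGraph,
    RegionAdjacencyGraph,
    SuperpixelLabeling,
    build_rag,
)

#: e-folding length (pixels) of the boundary-evidence decay
_DECAY = 6.0
#: smoothing radius (pixels) of the correlated noise field
_NOISE_SMOOTH = 3.0
#: seed offset separating the training scenes from the test scene
_TRAIN_OFFSET = 100_003
#: number of training scenes pooled for the fixture classifier and its
#: forest size; a single desk-scale scene has too few edges for a
#: seed-stable probability estimate
_N_TRAIN_SCENES = 20
_FIXTURE_TREES = 4096


@dataclass(frozen=True)
class SceneSpec:
    shape: Tuple[int, int] = (128, 128)
    n_cells: int = 20
    fragmentation: float = 3.0
    boundary_noise: float = 0.15
    miscalibration: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.fragmentation < 1:
            raise ValueError("fragmentation must be >= 1")
        if self.boundary_noise < 0:
            raise ValueError("boundary_noise must be >= 0")
        if not (0.0 <= self.miscalibration <= 1.0):
            raise ValueError("miscalibration must be in [0, 1]")
        if self.n_cells > self.shape[0] * self.shape[1]:
            raise ValueError("n_cells exceeds pixel count")


def _voronoi_labels(shape: Tuple[int, int], points: np.ndarray) -> np.ndarray:
    """Nearest-point labels (1-based); ties break toward the earlier point."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = (rr[None] - points[:, 0, None, None]) ** 2 + (cc[None] - points[:, 1, None, None]) ** 2
    return np.argmin(d2, axis=0).astype(np.int32) + 1


def _carve_superpixels(gt_arr, per_cell, shape, n_cells):
    """Voronoi refinement inside each cell, 0-lines carved, ids compacted."""
    sp_arr = np.zeros_like(gt_arr)
    next_id = 1
    for cell in range(1, n_cells + 1):
        mask = gt_arr == cell
        pts = np.array(per_cell[cell])
        rr, cc = np.nonzero(mask)
        d2 = (rr[None, :] - pts[:, 0, None]) ** 2 + (cc[None, :] - pts[:, 1, None]) ** 2
        nearest = np.argmin(d2, axis=0)
        sp_arr[rr, cc] = nearest + next_id
        next_id += len(pts)

    # carve one-pixel boundary lines where the superpixel id changes
    line = np.zeros(shape, dtype=bool)
    line[:, :-1] |= sp_arr[:, :-1] != sp_arr[:, 1:]
    line[:-1, :] |= sp_arr[:-1, :] != sp_arr[1:, :]
    sp_arr = sp_arr.copy()
    sp_arr[line] = 0
    # compact ids in case a tiny region was swallowed by its boundary line
    ids = np.unique(sp_arr[sp_arr > 0])
    remap = np.zeros(int(sp_arr.max()) + 1, dtype=sp_arr.dtype)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[sp_arr]


def _gt_interface_band(gt_arr, shape):
    """Pixels on either side of a ground-truth interface."""
    gt_line = np.zeros(shape, dtype=bool)
    diff_h = gt_arr[:, :-1] != gt_arr[:, 1:]
    gt_line[:, :-1] |= diff_h
    gt_line[:, 1:] |= diff_h
    diff_v = gt_arr[:-1, :] != gt_arr[1:, :]
    gt_line[:-1, :] |= diff_v
    gt_line[1:, :] |= diff_v
    return gt_line


def _has_degenerate_interior_interface(gt_arr, sp_arr, gt_line) -> bool:
    """True if two same-cell superpixels meet only along the interface band.

    Such sliver interfaces carry maximal boundary evidence despite being
    spurious, which would break the noiseless separability guarantee.
    """
    from .graph_core import _scan_interfaces

    zero_pixels, contacts = _scan_interfaces(sp_arr)
    cell_of: Dict[int, int] = {}
    mask = sp_arr > 0
    for sp_id, cell in zip(sp_arr[mask].tolist(), gt_arr[mask].tolist()):
        cell_of.setdefault(sp_id, cell)
    for e in set(zero_pixels) | set(contacts):
        if cell_of[e[0]] != cell_of[e[1]]:
            continue
        zp = zero_pixels.get(e, [])
        if zp:
            if all(gt_line[r, c] for r, c in zp):
                return True
        elif all(gt_line[p1] and gt_line[p2] for p1, p2 in contacts[e]):
            return True
    return False


def generate_scene(
    spec: SceneSpec,
) -> Tuple[SuperpixelLabeling, SuperpixelLabeling, np.ndarray]:
    """Return (ground truth, superpixels, boundary map) for a scene spec.

    The superpixel image carries one-pixel 0-boundary lines between regions;
    every superpixel is nested inside exactly one ground-truth cell.
    """
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)

    flat = rng.choice(rows * cols, size=spec.n_cells, replace=False)
    gt_points = np.stack(np.unravel_index(flat, (rows, cols)), axis=1)
    gt_arr = _voronoi_labels(spec.shape, gt_points)
    gt_line = _gt_interface_band(gt_arr, spec.shape)

    # secondary points: every cell keeps its own seed (so fragmentation 1
    # reproduces the ground truth exactly); extra points land uniformly and
    # are claimed by the cell they fall in.  Resample on the rare draw that
    # leaves a same-cell interface entirely on the interface band.
    n_extra = int(round((spec.fragmentation - 1.0) * spec.n_cells))
    for _attempt in range(64):
        per_cell: Dict[int, list] = {
            c: [gt_points[c - 1]] for c in range(1, spec.n_cells + 1)
        }
        if n_extra > 0:
            flat2 = rng.choice(rows * cols, size=n_extra, replace=False)
            sub_points = np.stack(np.unravel_index(flat2, (rows, cols)), axis=1)
            for pt in sub_points:
                per_cell[int(gt_arr[pt[0], pt[1]])].append(pt)
        sp_arr = _carve_superpixels(gt_arr, per_cell, spec.shape, spec.n_cells)
        if not _has_degenerate_interior_interface(gt_arr, sp_arr, gt_line):
            break
    else:
        raise RuntimeError("could not draw a non-degenerate superpixel refinement")
    if gt_line.any():
        dist = distance_transform_edt(~gt_line)
    else:
        dist = np.full(spec.shape, max(rows, cols), dtype=float)
    boundary = np.exp(-dist / _DECAY)
    if spec.boundary_noise > 0:
        # spatially correlated noise: without correlation the per-edge mean
        # would average the noise away and every edge would stay separable
        field = gaussian_filter(rng.normal(0.0, 1.0, size=spec.shape), _NOISE_SMOOTH)
        field /= field.std()
        boundary = boundary + spec.boundary_noise * field
    boundary = np.clip(boundary, 0.0, 1.0)

    return SuperpixelLabeling(gt_arr), SuperpixelLabeling(sp_arr), boundary


def simulate_edge_probabilities(
    rag: RegionAdjacencyGraph,
    sp_labels: SuperpixelLabeling,
    gt_labels: SuperpixelLabeling,
    miscalibration: float,
    seed: int = 0,
    jitter: float = 0.0,
) -> ProbabilisticSegmentationGraph:
    """Edge probabilities interpolating ground truth and uninformativeness.

    p = (1 - miscalibration) * truth + miscalibration * 0.5 + U(-jitter, jitter),
    clipped to [0, 1]; truth is 1 for edges inside a ground-truth segment.
    """
    if not (0.0 <= miscalibration <= 1.0):
        raise ValueError("miscalibration must be in [0, 1]")
    labels = ground_truth_edge_labels(rag, sp_labels, gt_labels)
    rng = np.random.default_rng(seed)
    p = {}
    for e in sorted(rag.edge_stats):
        truth = 1.0 if labels.is_connected(e) else 0.0
        noise = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
        p[e] = float(np.clip((1 - miscalibration) * truth + miscalibration * 0.5 + noise, 0, 1))
    return ProbabilisticSegmentationGraph(rag, p)


from functools import lru_cache


@lru_cache(maxsize=8)
def fixture_training_set(spec: SceneSpec):
    """Pooled edge features/labels from the fixture's training scenes.

    Edge keys are offset per scene so the pooled dicts stay well-formed;
    the pool approximates a single large training slice at desk scale.
    Cached per spec: callers must not mutate the returned structures.
    """
    from .graph_core import Partition

    pooled_feat: Dict = {}
    pooled_labels: Dict = {}
    pooled_assign: Dict = {}
    offset = 10_000_000
    for k in range(_N_TRAIN_SCENES):
        train_spec = replace(spec, seed=spec.seed + _TRAIN_OFFSET + k)
        tr_gt, tr_sp, tr_boundary = generate_scene(train_spec)
        tr_rag = build_rag(tr_sp, tr_boundary)
        tr_feat = extract_edge_features(tr_rag, tr_sp, tr_boundary)
        tr_labels = ground_truth_edge_labels(tr_rag, tr_sp, tr_gt)
        shift = k * offset
        for e, vec in tr_feat.items():
            pooled_feat[(e[0] + shift, e[1] + shift)] = vec
        for e, lab in tr_labels.labels.items():
            pooled_labels[(e[0] + shift, e[1] + shift)] = lab
        for sp_id, seg in tr_labels.assignment.assignment.items():
            pooled_assign[sp_id + shift] = seg + shift
    label_set = EdgeLabelSet(
        labels=pooled_labels, assignment=Partition(pooled_assign), violation_fraction=0.0
    )
    return pooled_feat, label_set


@dataclass
class FixtureBundle:
    """Everything needed to exercise the full pipeline on one test scene."""

    spec: SceneSpec
    gt: SuperpixelLabeling
    sp: SuperpixelLabeling
    boundary: np.ndarray
    rag: RegionAdjacencyGraph
    graph: ProbabilisticSegmentationGraph
    gt_labels: EdgeLabelSet
    classifier: EdgeClassifier


def standard_fixture(
    seed: int,
    *,
    shape: Tuple[int, int] = (128, 128),
    n_cells: int = 20,
    fragmentation: float = 3.0,
    boundary_noise: float = 0.15,
    feature_subset: Optional[Tuple[str, ...]] = None,
    classifier_seed: Optional[int] = None,
    train_fragmentation: Optional[float] = None,
) -> FixtureBundle:
    """Canonical pipeline fixture: classifier trained on disjoint scenes.

    The classifier is fit on same-spec scenes with different seeds and
    applied to this scene's edges, mimicking a train-on-one-slice /
    test-on-a-nearby-slice protocol.  ``classifier_seed`` varies only the
    forest's randomness (defaults to ``seed``), for stability studies.
    ``train_fragmentation`` lets a deliberately fragmented test watershed be
    classified by a standard-granularity classifier, mirroring re-use of one
    classifier across watershed granularities.
    """
    spec = SceneSpec(
        shape=shape,
        n_cells=n_cells,
        fragmentation=fragmentation,
        boundary_noise=boundary_noise,
        seed=seed,
    )
    train_spec = spec if train_fragmentation is None else replace(
        spec, fragmentation=train_fragmentation
    )
    pooled_feat, tr_label_set = fixture_training_set(train_spec)
    clf = train_edge_classifier(
        pooled_feat,
        tr_label_set,
        seed=seed if classifier_seed is None else classifier_seed,
        feature_subset=feature_subset,
        n_estimators=_FIXTURE_TREES,
    )

    gt, sp, boundary = generate_scene(spec)
    rag = build_rag(sp, boundary)
    feat = extract_edge_features(rag, sp, boundary)
    graph = attach_probabilities(rag, classifier=clf, features=feat)
    gt_labels = ground_truth_edge_labels(rag, sp, gt)
    return FixtureBundle(
        spec=spec,
        gt=gt,
        sp=sp,
        boundary=boundary,
        rag=rag,
        graph=graph,
        gt_labels=gt_labels,
        classifier=clf,
    )
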