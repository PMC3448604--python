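import numpy as np
import pytest

import segproof as sg
from segproof.edge_model import (
    attach_probabilities,
    extract_edge_features,
    ground_truth_edge_labels,
    project_to_ground_truth,
    train_edge_classifier,
)
from segproof.graph_core import (
    SuperpixelLabeling,
    build_rag,
    partition_from_certain_graph,
)


def _labeling(arr):
    return SuperpixelLabeling(np.asarray(arr))


class TestGroundTruthLabels:
    def test_exact_nesting(self):
        sp = _labeling([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]])
        gt = _labeling([[5, 5, 6, 6], [5, 5, 6, 6], [5, 5, 6, 6], [5, 5, 6, 6]])
        rag = build_rag(sp, np.zeros((4, 4)))
        labels = ground_truth_edge_labels(rag, sp, gt)
        assert labels.violation_fraction == 0.0
        assert labels.is_connected((1, 3))  # both in gt 5
        assert labels.is_connected((2, 4))
        assert not labels.is_connected((1, 2))
        assert not labels.is_connected((3, 4))

    def test_majority_split_flags_violation(self):
        # superpixel 1 covers gt 7 (6 px) and gt 8 (4 px): 60/40
        sp = _labeling([[1, 1, 1, 1, 1], [1, 1, 1, 1, 1]])
        gt = _labeling([[7, 7, 7, 8, 8], [7, 7, 7, 8, 8]])
        part, violation = project_to_ground_truth(sp, gt)
        assert part.assignment[1] == 7
        assert violation == 1.0

    def test_single_segment_all_connected(self):
        sp = _labeling([[1, 2], [3, 4]])
        gt = _labeling([[9, 9], [9, 9]])
        rag = build_rag(sp, np.zeros((2, 2)))
        labels = ground_truth_edge_labels(rag, sp, gt)
        assert all(labels.labels.values())

    def test_zero_overlap_rejected(self):
        sp = _labeling([[1, 2]])
        gt = _labeling([[3, 0]])
        with pytest.raises(ValueError):
            project_to_ground_truth(sp, gt)


def pixel_loop_features(sp, bmap, rag, edge):
    """Oracle: direct per-pixel recomputation of the feature vector."""
    rows, cols = sp.shape
    u, v = edge

    def neighbors(r, c):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                yield rr, cc

    # separating 0-pixels and directly touching pixel pairs
    zero_vals, contact_vals = [], []
    touch = {u: set(), v: set()}
    for r in range(rows):
        for c in range(cols):
            if sp[r, c] == 0:
                ids = {int(sp[rr, cc]) for rr, cc in neighbors(r, c) if sp[rr, cc] > 0}
                if u in ids and v in ids:
                    zero_vals.append(bmap[r, c])
                    for rr, cc in neighbors(r, c):
                        if int(sp[rr, cc]) in (u, v):
                            touch[int(sp[rr, cc])].add((rr, cc))
            elif sp[r, c] in (u, v):
                for rr, cc in neighbors(r, c):
                    if {int(sp[r, c]), int(sp[rr, cc])} == {u, v}:
                        contact_vals.append((bmap[r, c] + bmap[rr, cc]) / 2)
                        touch[int(sp[r, c])].add((r, c))
                        touch[int(sp[rr, cc])].add((rr, cc))
    # each direct-contact pair is visited twice with the same value, which
    # leaves mean/min/max unaffected
    vals = zero_vals if zero_vals else contact_vals

    def interior_mean(node):
        pix = [(r, c) for r in range(rows) for c in range(cols) if sp[r, c] == node]
        inner = [
            (r, c)
            for r, c in pix
            if all(sp[rr, cc] == node for rr, cc in neighbors(r, c))
        ]
        chosen = inner if inner else pix
        return float(np.mean([bmap[r, c] for r, c in chosen]))

    sizes = {n: int((sp == n).sum()) for n in (u, v)}
    f1, f2, f3 = float(np.mean(vals)), float(np.min(vals)), float(np.max(vals))
    imu, imv = interior_mean(u), interior_mean(v)
    f7 = max(
        sum(bmap[p] for p in touch[u]) / sizes[u],
        sum(bmap[p] for p in touch[v]) / sizes[v],
    )
    return np.array(
        [
            f1,
            f2,
            f3,
            min(sizes[u], sizes[v]),
            max(sizes[u], sizes[v]),
            abs(imu - imv),
            (f1 - imu) * (f1 - imv),
            f7,
            len(zero_vals),
        ]
    )


class TestFeatures:
    def test_constant_boundary_map(self):
        sp = _labeling([[1, 0, 2], [1, 0, 2]])
        bmap = np.full((2, 3), 0.3)
        rag = build_rag(sp, bmap)
        feats = extract_edge_features(rag, sp, bmap)
        f = feats[(1, 2)]
        assert f[0] == f[1] == f[2] == pytest.approx(0.3)

    def test_node_sizes_ordered(self):
        sp = _labeling([[1, 1, 1, 0, 2], [1, 1, 1, 0, 2]])
        bmap = np.zeros((2, 5))
        rag = build_rag(sp, bmap)
        f = extract_edge_features(rag, sp, bmap)[(1, 2)]
        assert (f[3], f[4]) == (2, 6)

    def test_crafted_fixture_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(0)
        sp = np.array(
            [
                [1, 1, 0, 2, 2, 2, 2, 2],
                [1, 1, 0, 2, 2, 2, 2, 2],
                [1, 1, 0, 2, 2, 2, 2, 2],
                [0, 0, 0, 0, 0, 2, 2, 2],
                [3, 3, 3, 3, 0, 2, 2, 2],
                [3, 3, 3, 3, 0, 0, 0, 0],
                [3, 3, 3, 3, 0, 4, 4, 4],
                [3, 3, 3, 3, 0, 4, 4, 4],
            ]
        )
        bmap = rng.random((8, 8))
        lab = _labeling(sp)
        rag = build_rag(lab, bmap)
        feats = extract_edge_features(rag, lab, bmap)
        for edge in rag.edges():
            expected = pixel_loop_features(sp, bmap, rag, edge)
            np.testing.assert_allclose(feats[edge], expected, atol=1e-12)

    def test_transposition_invariance(self):
        rng = np.random.default_rng(1)
        sp = rng.integers(0, 5, size=(12, 12))
        sp[0, 0] = 1
        bmap = rng.random((12, 12))
        lab, lab_t = _labeling(sp), _labeling(sp.T)
        f1 = extract_edge_features(build_rag(lab, bmap), lab, bmap)
        f2 = extract_edge_features(build_rag(lab_t, bmap.T), lab_t, bmap.T)
        assert set(f1) == set(f2)
        for e in f1:
            np.testing.assert_allclose(f1[e], f2[e], atol=1e-12)


def _separable_training_data(n=40, ambiguous=False, seed=0):
    rng = np.random.default_rng(seed)
    from segproof.edge_model import EdgeLabelSet
    from segproof.graph_core import Partition

    feats, labels, assign = {}, {}, {}
    for i in range(n):
        e = (2 * i + 1, 2 * i + 2)
        connected = i % 2 == 0
        center = 0.5 if ambiguous else (0.1 if connected else 0.9)
        spread = 0.4 if ambiguous else 0.05
        base = float(np.clip(center + rng.uniform(-spread, spread), 0, 1))
        feats[e] = np.array([base, base, base, 5, 5, 0.0, 0.0, base, 4.0])
        labels[e] = connected
        assign[e[0]] = i if connected else 2 * i
        assign[e[1]] = i if connected else 2 * i + 1
    return feats, EdgeLabelSet(labels, Partition(assign), 0.0)


class TestClassifier:
    def test_separable_features_perfect_holdout(self):
        feats, labels = _separable_training_data(60)
        ordered = sorted(feats)
        train = {e: feats[e] for e in ordered[:30]}
        test = {e: feats[e] for e in ordered[30:]}
        clf = train_edge_classifier(train, labels, seed=0, n_estimators=100)
        proba = clf.predict_proba_map(test)
        acc = np.mean(
            [(proba[e] > 0.5) == labels.is_connected(e) for e in test]
        )
        assert acc == 1.0

    def test_deterministic_given_seed(self):
        feats, labels = _separable_training_data(30)
        p1 = train_edge_classifier(feats, labels, seed=7, n_estimators=50).oob_proba
        p2 = train_edge_classifier(feats, labels, seed=7, n_estimators=50).oob_proba
        assert p1 == p2

    def test_single_class_rejected(self):
        feats, labels = _separable_training_data(10)
        labels.labels.update({e: True for e in labels.labels})
        with pytest.raises(ValueError):
            train_edge_classifier(feats, labels, seed=0)

    def test_mean_only_subset_less_sharp_on_ambiguous_fixture(self):
        feats, labels = _separable_training_data(80, ambiguous=True, seed=3)
        full = train_edge_classifier(feats, labels, seed=0, n_estimators=200)
        mean_only = train_edge_classifier(
            feats, labels, seed=0, feature_subset=("f1",), n_estimators=200
        )
        sharp_full = np.mean([abs(p - 0.5) for p in full.oob_proba.values()])
        sharp_mean = np.mean([abs(p - 0.5) for p in mean_only.oob_proba.values()])
        assert sharp_mean <= sharp_full

    def test_unknown_feature_rejected(self):
        feats, labels = _separable_training_data(10)
        with pytest.raises(ValueError):
            train_edge_classifier(feats, labels, feature_subset=("f9",))


class TestAttachProbabilities:
    def test_uniform_half(self, small_scene):
        _, gt, sp, boundary = small_scene
        rag = build_rag(sp, boundary)
        g = attach_probabilities(rag, probabilities={e: 0.5 for e in rag.edge_stats})
        assert set(g.p.values()) == {0.5}

    def test_ground_truth_map_induces_projected_partition(self, small_scene):
        _, gt, sp, boundary = small_scene
        rag = build_rag(sp, boundary)
        labels = ground_truth_edge_labels(rag, sp, gt)
        g = attach_probabilities(
            rag,
            probabilities={e: 1.0 if labels.is_connected(e) else 0.0 for e in rag.edge_stats},
        )
        induced = partition_from_certain_graph(g)
        proj = labels.assignment
        for u in rag.node_sizes:
            for v in rag.node_sizes:
                assert induced.same_segment(u, v) == proj.same_segment(u, v)

    def test_missing_probability_rejected(self, small_scene):
        _, gt, sp, boundary = small_scene
        rag = build_rag(sp, boundary)
        probs = {e: 0.5 for e in rag.edge_stats}
        probs.pop(next(iter(probs)))
        with pytest.raises(ValueError):
            attach_probabilities(rag, probabilities=probs)

    def test_out_of_range_clipped(self, small_scene):
        _, gt, sp, boundary = small_scene
        rag = build_rag(sp, boundary)
        g = attach_probabilities(rag, probabilities={e: 1.2 for e in rag.edge_stats})
        assert set(g.p.values()) == {1.0}


class TestPerfectMapGivesGprOne:
    def test_downstream_gpr(self, small_scene):
        _, gt, sp, boundary = small_scene
        rag = build_rag(sp, boundary)
        labels = ground_truth_edge_labels(rag, sp, gt)
        g = attach_probabilities(
            rag,
            probabilities={e: 1.0 if labels.is_connected(e) else 0.0 for e in rag.edge_stats},
        )
        table = sg.all_pairs_table(g, 0.01)
        assert sg.gpr(g, table).gpr == pytest.approx(1.0)


@pytest.mark.slow
def test_oob_probabilities_stable_across_reseedings(standard_training_set):
    """Mean |Δp| of out-of-bag training probabilities over 5 reseedings."""
    from segproof.synthdata import _FIXTURE_TREES

    feats, labels = standard_training_set
    runs = [
        train_edge_classifier(feats, labels, seed=s, n_estimators=_FIXTURE_TREES).oob_proba
        for s in range(5)
    ]
    edges = sorted(feats)
    diffs = []
    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            diffs.append(np.mean([abs(runs[a][e] - runs[b][e]) for e in edges]))
    assert float(np.mean(diffs)) < 0.005
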