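import numpy as np
import pytest

import segproof as sg
from segproof.synthdata import SceneSpec, fixture_training_set, generate_scene


@pytest.fixture(scope="session")
def standard_bundle():
    """One full standard fixture, shared across the suite (expensive)."""
    return sg.standard_fixture(5)


@pytest.fixture(scope="session")
def standard_training_set():
    """Pooled training features/labels matching ``standard_bundle``'s spec."""
    return fixture_training_set(SceneSpec(seed=5))


@pytest.fixture()
def small_scene():
    """Cheap scene for unit tests: 48x48, 6 cells."""
    spec = SceneSpec(shape=(48, 48), n_cells=6, fragmentation=3, boundary_noise=0.1, seed=11)
    gt, sp, boundary = generate_scene(spec)
    return spec, gt, sp, boundary


@pytest.fixture()
def small_graph(small_scene):
    """Probabilistic graph on the small scene with simulated probabilities."""
    _, gt, sp, boundary = small_scene
    rag = sg.build_rag(sp, boundary)
    g = sg.simulate_edge_probabilities(rag, sp, gt, miscalibration=0.4, seed=7, jitter=0.1)
    return gt, sp, g


def random_graph(rng, n_nodes, edge_prob=0.5, unit_sizes=False):
    """Random probabilistic graph for oracle comparisons."""
    from segproof.graph_core import (
        EdgeStats,
        ProbabilisticSegmentationGraph,
        RegionAdjacencyGraph,
    )

    sizes = {
        i: (1 if unit_sizes else int(rng.integers(1, 20)))
        for i in range(1, n_nodes + 1)
    }
    edges = {}
    p = {}
    for u in range(1, n_nodes + 1):
        for v in range(u + 1, n_nodes + 1):
            if rng.random() < edge_prob:
                edges[(u, v)] = EdgeStats(count=1, mean=0.5, min=0.5, max=0.5)
                p[(u, v)] = float(rng.random())
    return ProbabilisticSegmentationGraph(
        RegionAdjacencyGraph(node_sizes=sizes, edge_stats=edges), p
    )


def enumerate_simple_path_strength(g, source, target):
    """Oracle: max over all simple paths of the product of probabilities."""
    adj = g.rag.adjacency()
    best = [1.0 if source == target else 0.0]

    def dfs(node, product, visited):
        for nxt in adj[node]:
            if nxt in visited:
                continue
            np_ = product * g.p[(min(node, nxt), max(node, nxt))]
            if nxt == target:
                best[0] = max(best[0], np_)
            else:
                dfs(nxt, np_, visited | {nxt})

    if source != target:
        dfs(source, 1.0, {source})
    return best[0]


def enumerate_connection_probabilities(g):
    """Oracle: exact P(connected) for every pair by enumerating all 2^|E|
    edge configurations weighted by their likelihood."""
    import itertools

    from segproof.graph_core import components_partition

    edges = sorted(g.p)
    nodes = sorted(g.rag.node_sizes)
    prob = {(u, v): 0.0 for i, u in enumerate(nodes) for v in nodes[i + 1:]}
    for present in itertools.product([0, 1], repeat=len(edges)):
        w = 1.0
        active = []
        for bit, e in zip(present, edges):
            w *= g.p[e] if bit else (1.0 - g.p[e])
            if bit:
                active.append(e)
        if w == 0.0:
            continue
        part = components_partition(nodes, active)
        for pair in prob:
            if part.same_segment(*pair):
                prob[pair] += w
    return prob
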