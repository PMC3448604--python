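"""Core domain types: labelings, partitions, region adjacency graphs, and
probabilistic segmentation graphs.

A labeling is a 2D integer image whose positive ids name atomic superpixels;
id 0 marks boundary/unassigned pixels.  A region adjacency graph (RAG) links
superpixels that touch either directly or across a one-pixel-wide 0-boundary
line.  Attaching a connection probability to every RAG edge yields a
probabilistic segmentation graph, the central object of this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

Edge = Tuple[int, int]

#: neighbor offsets for 4-connectivity, scan order up/down/left/right
_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def edge_key(u: int, v: int) -> Edge:
    """Canonical (small, large) key for an unordered superpixel pair."""
    if u == v:
        raise ValueError(f"self-edge not allowed: {u}")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class SuperpixelLabeling:
    """2D integer label image; positive ids are superpixels, 0 is boundary."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"labels must be 2D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {arr.dtype}")
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    @property
    def n(self) -> int:
        """Number of non-boundary pixels (labels > 0)."""
        return int(np.count_nonzero(self.labels))

    def ids(self) -> np.ndarray:
        """Sorted distinct positive superpixel ids."""
        u = np.unique(self.labels)
        return u[u > 0]

    def sizes(self) -> Dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass(frozen=True)
class Partition:
    """Total map from superpixel id to segment id."""

    assignment: Mapping[int, int]

    def segment_of(self, sp: int) -> int:
        return self.assignment[sp]

    def same_segment(self, u: int, v: int) -> bool:
        return self.assignment[u] == self.assignment[v]

    def segments(self) -> Dict[int, list]:
        out: Dict[int, list] = {}
        for sp, seg in self.assignment.items():
            out.setdefault(seg, []).append(sp)
        return out

    @property
    def n_segments(self) -> int:
        return len(set(self.assignment.values()))


@dataclass(frozen=True)
class EdgeStats:
    """Boundary-pixel statistics of one RAG edge (values on the [0,1] scale)."""

    count: int  # number of separating 0-pixels (edge size)
    mean: float
    min: float
    max: float


@dataclass
class RegionAdjacencyGraph:
    node_sizes: Dict[int, int]
    edge_stats: Dict[Edge, EdgeStats]

    @property
    def n_pixels(self) -> int:
        return sum(self.node_sizes.values())

    def edges(self) -> Iterable[Edge]:
        return self.edge_stats.keys()

    @property
    def n_edges(self) -> int:
        return len(self.edge_stats)

    def neighbors(self, u: int) -> Iterable[int]:
        for a, b in self.edge_stats:
            if a == u:
                yield b
            elif b == u:
                yield a

    def adjacency(self) -> Dict[int, list]:
        adj: Dict[int, list] = {u: [] for u in self.node_sizes}
        for a, b in self.edge_stats:
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass
class ProbabilisticSegmentationGraph:
    """RAG plus a connection probability per edge.

    ``p[(u, v)]`` is the probability that superpixels u and v belong to the
    same object, i.e. that the boundary between them is spurious.
    """

    rag: RegionAdjacencyGraph
    p: Dict[Edge, float]

    def __post_init__(self):
        missing = set(self.rag.edge_stats) - set(self.p)
        if missing:
            raise ValueError(f"missing probability for {len(missing)} edge(s)")
        extra = set(self.p) - set(self.rag.edge_stats)
        if extra:
            raise ValueError(f"probability given for non-edges: {sorted(extra)[:3]}")
        for e, v in self.p.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"probability out of [0,1] on edge {e}: {v}")

    @property
    def nodes(self) -> Dict[int, int]:
        return self.rag.node_sizes

    def with_edge_p(self, edge: Edge, new_p: float) -> "ProbabilisticSegmentationGraph":
        """Cheap copy sharing the RAG, with one probability replaced."""
        e = edge_key(*edge)
        if e not in self.p:
            raise KeyError(f"unknown edge {e}")
        p2 = dict(self.p)
        p2[e] = float(new_p)
        return ProbabilisticSegmentationGraph(self.rag, p2)

    def is_certain(self) -> bool:
        return all(v in (0.0, 1.0) for v in self.p.values())


def normalize_boundary_map(boundary_map: np.ndarray) -> np.ndarray:
    """Return the boundary map on the [0,1] scale.

    Integer arrays (or float arrays with values > 1) are treated as 8-bit
    intensities and divided by 255.
    """
    arr = np.asarray(boundary_map, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("boundary map contains non-finite values")
    if np.issubdtype(np.asarray(boundary_map).dtype, np.integer) or arr.max() > 1.0:
        arr = arr / 255.0
    if arr.min() < 0.0 or arr.max() > 1.0 + 1e-12:
        raise ValueError("boundary map values out of range")
    return np.clip(arr, 0.0, 1.0)


def _scan_interfaces(labels: np.ndarray):
    """Brute scan of the label image for edge interfaces.

    Returns (zero_pixels, contacts) where ``zero_pixels`` maps each canonical
    edge to the list of separating 0-pixel coordinates and ``contacts`` maps it
    to the list of directly touching pixel-coordinate pairs.
    """
    rows, cols = labels.shape
    zero_pixels: Dict[Edge, list] = {}
    contacts: Dict[Edge, list] = {}

    # direct contacts: horizontal and vertical neighbor pairs of distinct ids
    for axis in (0, 1):
        if axis == 0:
            a, b = labels[:-1, :], labels[1:, :]
        else:
            a, b = labels[:, :-1], labels[:, 1:]
        mask = (a > 0) & (b > 0) & (a != b)
        rr, cc = np.nonzero(mask)
        for r, c in zip(rr.tolist(), cc.tolist()):
            if axis == 0:
                p1, p2 = (r, c), (r + 1, c)
            else:
                p1, p2 = (r, c), (r, c + 1)
            e = edge_key(int(labels[p1]), int(labels[p2]))
            contacts.setdefault(e, []).append((p1, p2))

    # 0-pixels: attribute to every pair of distinct positive ids among 4-neighbors
    zr, zc = np.nonzero(labels == 0)
    for r, c in zip(zr.tolist(), zc.tolist()):
        ids = set()
        for dr, dc in _OFFSETS:
            rr2, cc2 = r + dr, c + dc
            if 0 <= rr2 < rows and 0 <= cc2 < cols:
                val = int(labels[rr2, cc2])
                if val > 0:
                    ids.add(val)
        if len(ids) >= 2:
            ids = sorted(ids)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    zero_pixels.setdefault((ids[i], ids[j]), []).append((r, c))
    return zero_pixels, contacts


def build_rag(labels: SuperpixelLabeling, boundary_map: np.ndarray) -> RegionAdjacencyGraph:
    """Build a region adjacency graph from a label image and a boundary map.

    Adjacency is 4-connected; two superpixels are adjacent if they touch
    directly or across a one-pixel-wide 0-boundary.  Edge statistics are
    aggregated over the separating 0-pixels' boundary values; edges with no
    separating 0-pixel fall back to the mean of each touching pixel pair.
    """
    if not isinstance(labels, SuperpixelLabeling):
        labels = SuperpixelLabeling(np.asarray(labels))
    arr = labels.labels
    bmap = normalize_boundary_map(boundary_map)
    if bmap.shape != arr.shape:
        raise ValueError(f"shape mismatch: labels {arr.shape} vs boundary {bmap.shape}")
    node_sizes = labels.sizes()
    if not node_sizes:
        raise ValueError("empty labeling: no positive superpixel ids")

    zero_pixels, contacts = _scan_interfaces(arr)
    edge_stats: Dict[Edge, EdgeStats] = {}
    for e in sorted(set(zero_pixels) | set(contacts)):
        zp = zero_pixels.get(e, [])
        if zp:
            vals = np.array([bmap[r, c] for r, c in zp])
            count = len(zp)
        else:
            vals = np.array([(bmap[p1] + bmap[p2]) / 2.0 for p1, p2 in contacts[e]])
            count = 0
        edge_stats[e] = EdgeStats(
            count=count,
            mean=float(vals.mean()),
            min=float(vals.min()),
            max=float(vals.max()),
        )
    return RegionAdjacencyGraph(node_sizes=node_sizes, edge_stats=edge_stats)


def components_partition(nodes: Iterable[int], edges: Iterable[Edge]) -> Partition:
    """Partition from connected components; segment id = smallest member id."""
    node_list = sorted(nodes)
    index = {u: i for i, u in enumerate(node_list)}
    rows, cols = [], []
    for u, v in edges:
        rows.append(index[u])
        cols.append(index[v])
    n = len(node_list)
    mat = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, comp = connected_components(mat, directed=False)
    # deterministic segment ids: min node id in each component
    seg_min: Dict[int, int] = {}
    for u, ci in zip(node_list, comp):
        seg_min[ci] = min(seg_min.get(ci, u), u)
    return Partition({u: seg_min[ci] for u, ci in zip(node_list, comp)})


def partition_from_certain_graph(g: ProbabilisticSegmentationGraph) -> Partition:
    """Collapse a fully certain graph to its unique induced partition."""
    for e, v in g.p.items():
        if v not in (0.0, 1.0):
            raise ValueError(f"graph not certain: edge {e} has p={v}")
    merged = [e for e, v in g.p.items() if v == 1.0]
    return Partition(components_partition(g.nodes, merged).assignment)


# ---------------------------------------------------------------------------
# JSON serialization

def graph_to_json(g: ProbabilisticSegmentationGraph) -> str:
    nodes = [{"id": u, "size": s} for u, s in sorted(g.rag.node_sizes.items())]
    edges = []
    for (u, v), st in sorted(g.rag.edge_stats.items()):
        edges.append(
            {
                "u": u,
                "v": v,
                "p": g.p[(u, v)],
                "stats": {"count": st.count, "mean": st.mean, "min": st.min, "max": st.max},
            }
        )
    return json.dumps({"nodes": nodes, "edges": edges})


def graph_from_json(text: str) -> ProbabilisticSegmentationGraph:
    doc = json.loads(text)
    node_sizes = {int(n["id"]): int(n["size"]) for n in doc["nodes"]}
    edge_stats, p = {}, {}
    for e in doc["edges"]:
        key = edge_key(int(e["u"]), int(e["v"]))
        st = e["stats"]
        edge_stats[key] = EdgeStats(
            count=int(st["count"]), mean=st["mean"], min=st["min"], max=st["max"]
        )
        p[key] = float(e["p"])
    return ProbabilisticSegmentationGraph(
        RegionAdjacencyGraph(node_sizes=node_sizes, edge_stats=edge_stats), p
    )
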