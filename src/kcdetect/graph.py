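"""Undirected graphs over fractal-dimension vectors and their topology features.

Each of the 10 per-scale fractal dimensions of a segment becomes a graph
node; the distance between two nodes is the Euclidean distance of their
scalar values, d(i, j) = |fd_i - fd_j|. An edge connects two nodes when
their distance is at or below a threshold:

    (v_i, v_j) in E  iff  d(v_i, v_j) <= thr

Three thresholding schemes are provided: a fixed (arbitrary) threshold, a
data-driven threshold calibrated so the graph's mean degree
k = (1/n) sum_i deg(v_i) reaches a target (default 6), and the minimum
spanning tree (Kruskal). Every graph in a dataset has the same node count,
so the feature vectors are comparable across segments.

From the 0/1 adjacency matrix B three topology features are extracted:

* degree distribution P(k) = |{v : deg(v) = k}| / n for k = 0 ... n-1;
* mean clustering coefficient, CC = (1/n) sum_i cc_i, with cc_i the fraction
  of node i's neighbour pairs that are themselves connected (0 when
  deg < 2);
* mean Jaccard coefficient over unordered node pairs,
  M(i, j) = |G(i) n G(j)| / |G(i) u G(j)| with open neighbourhoods
  (pairs with an empty union count 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .fractal import FDVector

__all__ = [
    "DistanceMatrix",
    "AdjacencyMatrix",
    "GraphFeatures",
    "distance_matrix",
    "threshold_adjacency",
    "calibrate_threshold",
    "mst_adjacency",
    "degree_distribution",
    "clustering_coefficients",
    "jaccard_coefficients",
    "graph_feature_vector",
]


@dataclass(frozen=True)
class DistanceMatrix:
    d: np.ndarray  # symmetric nonnegative, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class AdjacencyMatrix:
    B: np.ndarray  # symmetric 0/1, zero diagonal
    thr: float | None = None  # threshold used, distance units (None for MST)

    def __post_init__(self) -> None:
        B = np.asarray(self.B)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(B, B.T) or np.any(np.diag(B) != 0):
            raise ValueError("adjacency matrix must be symmetric with zero diagonal")
        object.__setattr__(self, "B", B.astype(int))

    @property
    def n(self) -> int:
        return self.B.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.B.sum(axis=1)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())


@dataclass(frozen=True)
class GraphFeatures:
    degree_dist: np.ndarray  # P(k), k = 0 ... n-1
    mean_cc: float
    mean_jaccard: float
    cc_per_node: np.ndarray
    jaccard_pairs: np.ndarray  # unordered pairs in (i < j) lexicographic order


def distance_matrix(fd: FDVector | np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean distances |fd_i - fd_j| between scalar FD values."""
    values = np.asarray(fd.per_scale if isinstance(fd, FDVector) else fd, dtype=float)
    if values.size == 0:
        raise ValueError("FD vector must be nonempty")
    return DistanceMatrix(d=np.abs(values[:, None] - values[None, :]))


def threshold_adjacency(d: DistanceMatrix, thr: float) -> AdjacencyMatrix:
    """Connect node pairs with distance <= thr (no self-loops)."""
    if thr < 0:
        raise ValueError(f"threshold must be >= 0, got {thr}")
    B = (d.d <= thr).astype(int)
    np.fill_diagonal(B, 0)
    return AdjacencyMatrix(B=B, thr=thr)


def calibrate_threshold(d: DistanceMatrix, target_mean_degree: float = 6.0) -> float:
    """Smallest candidate threshold reaching a target mean degree.

    Candidates are the sorted unique off-diagonal distances (plus one value
    below the smallest positive distance so an empty graph is reachable);
    the mean degree is a step function of the threshold, so the scan is
    exact. The achieved mean degree overshoots the target by at most one
    edge increment (2/n).
    """
    n = d.n
    if not 0 <= target_mean_degree <= n - 1:
        raise ValueError(
            f"target mean degree must be in [0, {n - 1}], got {target_mean_degree}"
        )
    off = d.d[~np.eye(n, dtype=bool)]
    candidates = np.unique(off)
    positive = candidates[candidates > 0]
    if positive.size:
        candidates = np.concatenate(([positive[0] / 2.0], candidates))
    for thr in candidates:
        if threshold_adjacency(d, float(thr)).mean_degree >= target_mean_degree:
            return float(thr)
    return float(candidates[-1])  # complete graph; target <= n-1 guarantees reach


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def mst_adjacency(d: DistanceMatrix) -> AdjacencyMatrix:
    """Minimum spanning tree by Kruskal's algorithm.

    Edges are examined in increasing weight; equal weights are broken by
    lexicographic node-pair order, making the tree deterministic.
    """
    n = d.n
    edges = sorted(
        ((d.d[i, j], i, j) for i, j in combinations(range(n), 2)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    uf = _UnionFind(n)
    B = np.zeros((n, n), dtype=int)
    taken = 0
    for w, i, j in edges:
        if uf.union(i, j):
            B[i, j] = B[j, i] = 1
            taken += 1
            if taken == n - 1:
                break
    return AdjacencyMatrix(B=B, thr=None)


def degree_distribution(B: AdjacencyMatrix) -> np.ndarray:
    """P(k): fraction of nodes with degree k, for k = 0 ... n-1. Sums to 1."""
    counts = np.bincount(B.degrees, minlength=B.n)
    return counts[: B.n] / B.n


def clustering_coefficients(B: AdjacencyMatrix) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean.

    cc_i = (# edges among i's neighbours) / (deg_i choose 2); nodes with
    degree < 2 get 0.
    """
    A = B.B
    per_node = np.zeros(B.n)
    for i in range(B.n):
        nbrs = np.flatnonzero(A[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = A[np.ix_(nbrs, nbrs)].sum() / 2
        per_node[i] = links / (k * (k - 1) / 2)
    return per_node, float(per_node.mean())


def jaccard_coefficients(B: AdjacencyMatrix) -> tuple[np.ndarray, float]:
    """Neighbourhood-overlap similarity for every unordered node pair.

    M(i, j) = |G(i) n G(j)| / |G(i) u G(j)| with open neighbourhoods; a pair
    whose neighbourhoods are both empty counts 0. Returns the pair vector in
    (i < j) lexicographic order and its mean.
    """
    A = B.B.astype(bool)
    vals = []
    for i, j in combinations(range(B.n), 2):
        union = np.count_nonzero(A[i] | A[j])
        if union == 0:
            vals.append(0.0)
        else:
            vals.append(np.count_nonzero(A[i] & A[j]) / union)
    pairs = np.array(vals) if vals else np.zeros(0)
    mean = float(pairs.mean()) if pairs.size else 0.0
    return pairs, mean


def graph_features(B: AdjacencyMatrix) -> GraphFeatures:
    """All three topology features of one adjacency matrix."""
    cc_per_node, mean_cc = clustering_coefficients(B)
    jac_pairs, mean_jac = jaccard_coefficients(B)
    return GraphFeatures(
        degree_dist=degree_distribution(B),
        mean_cc=mean_cc,
        mean_jaccard=mean_jac,
        cc_per_node=cc_per_node,
        jaccard_pairs=jac_pairs,
    )


def graph_feature_vector(B: AdjacencyMatrix, mode: str = "scalar") -> np.ndarray:
    """Flatten graph features into one row of the classifier's design matrix.

    ``scalar`` mode (default): [P(0), ..., P(n-1), mean CC, mean Jaccard]
    (length n + 2). ``full`` mode appends the pairwise Jaccard vector.
    """
    gf = graph_features(B)
    vec = np.concatenate([gf.degree_dist, [gf.mean_cc], [gf.mean_jaccard]])
    if mode == "scalar":
        return vec
    if mode == "full":
        return np.concatenate([vec, gf.jaccard_pairs])
    raise ValueError(f"unknown feature mode: {mode!r}")
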