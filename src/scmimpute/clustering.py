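"""PCA embedding, k-NN graph construction and Louvain community detection.

The pipeline mirrors the standard single-cell workflow: reduce the imputed
matrix to 50 principal components, connect each cell to its 15 nearest
Euclidean neighbours (union-symmetrized), and partition the graph by
modularity optimisation (Louvain) at resolution 1.0.  No feature scaling is
applied before PCA — methylation levels already share the [0, 1] scale.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph
import numpy as np
from sklearn.decomposition import PCA

from .imputation import ImputedMatrix
from .io import Partition, ValidationError

__all__ = [
    "Embedding", "NeighborGraph",
    "pca_embed", "knn_graph", "louvain_cluster", "modularity",
]


@dataclass
class Embedding:
    """Cells x components real coordinates."""

    cell_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValidationError("cell_ids length does not match coordinates")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite embedding coordinates")

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborGraph:
    """Undirected weighted graph over cells; no self-loops, positive weights."""

    cell_ids: list[str]
    edges: np.ndarray  # (m, 2) vertex index pairs, i < j
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.edges):
            raise ValidationError("edge and weight counts differ")
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValidationError("self-loops are not allowed")
        if len(self.weights) and self.weights.min() <= 0:
            raise ValidationError("edge weights must be positive")

    @property
    def n_vertices(self) -> int:
        return len(self.cell_ids)


def pca_embed(matrix: ImputedMatrix, n_components: int = 50, seed: int = 0) -> Embedding:
    """Project cells onto the top principal axes of the imputed matrix.

    Columns are centered; ``n_components`` is clipped to ``min(n-1, R)``.
    Component signs are fixed by making each axis's largest-magnitude
    loading positive, so the embedding is deterministic.
    """
    n, r = matrix.values.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 cells")
    k = min(int(n_components), n - 1, r)
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(matrix.values)
    # canonical sign: largest-|loading| entry of each axis made positive
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    return Embedding(cell_ids=list(matrix.cell_ids), coords=coords)


def knn_graph(embedding: Embedding, k: int = 15) -> NeighborGraph:
    """Connect each cell to its k nearest Euclidean neighbours.

    Directed k-NN edges are symmetrized by union with unit weight.
    Distance ties are broken by the lower cell index.
    """
    x = embedding.coords
    n = x.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of cells n={n}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    sq = (x * x).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    # stable argsort breaks distance ties by lower index
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    pairs = set()
    for i in range(n):
        for j in order[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            pairs.add((a, b))
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    return NeighborGraph(
        cell_ids=list(embedding.cell_ids),
        edges=edges,
        weights=np.ones(len(edges)),
    )


def louvain_cluster(
    graph: NeighborGraph, resolution: float = 1.0, seed: int = 0
) -> Partition:
    """Louvain modularity optimisation on the neighbour graph.

    Uses igraph's multilevel algorithm with a seeded RNG, so the partition
    is deterministic for a fixed seed.  Cluster label ids are arbitrary
    but stable.
    """
    n = graph.n_vertices
    if n == 0:
        raise ValidationError("empty graph")
    g = igraph.Graph(n=n, edges=[tuple(e) for e in graph.edges])
    igraph.set_random_number_generator(random.Random(int(seed)))
    clustering = g.community_multilevel(
        weights=list(graph.weights), resolution=float(resolution)
    )
    igraph.set_random_number_generator(random)  # restore the default RNG
    return Partition(tuple(graph.cell_ids), tuple(int(m) for m in clustering.membership))


def modularity(
    graph: NeighborGraph, partition: Partition, resolution: float = 1.0
) -> float:
    """Newman modularity of a partition, evaluated directly from its definition.

    Q = (1/2m) sum_ij (A_ij - gamma * k_i k_j / 2m) [c_i == c_j], computed
    natively (independent of the community-detection library) so it can
    serve as an oracle for the optimiser.
    """
    n = graph.n_vertices
    if list(partition.cell_ids) != list(graph.cell_ids):
        raise ValidationError("partition cells do not match graph cells")
    labels = partition.label_array()
    m2 = 2.0 * graph.weights.sum()
    if m2 == 0:
        return 0.0
    deg = np.zeros(n)
    intra = 0.0
    for (a, b), w in zip(graph.edges, graph.weights):
        deg[a] += w
        deg[b] += w
        if labels[a] == labels[b]:
            intra += w
    q = 2.0 * intra / m2
    for c in np.unique(labels):
        dc = deg[labels == c].sum()
        q -= resolution * (dc / m2) ** 2
    return float(q)
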