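"""Cell grouping: user labels or label-free SNN + Louvain clustering."""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from ._consensus import consensus_matrix, cut_consensus, eigen_gap_count, prune_consensus


@dataclass
class CellGrouping:
    """Per-cell group assignment with ordered group names and sizes."""

    labels: np.ndarray  # per-cell group label (strings)
    group_names: list[str]
    cell_names: list[str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(self.labels.tolist())
        unknown = present - set(self.group_names)
        if unknown:
            raise ValueError(f"labels not in group_names: {sorted(unknown)}")

    @classmethod
    def from_labels(cls, labels, cell_names=None) -> "CellGrouping":
        labels = np.asarray([str(x) for x in labels])
        names = sorted(set(labels.tolist()))
        return cls(labels=labels, group_names=names, cell_names=cell_names)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([int(np.sum(self.labels == g)) for g in self.group_names])

    def indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.labels == group)

    def codes(self) -> np.ndarray:
        """Integer codes aligned with group_names order."""
        lookup = {g: i for i, g in enumerate(self.group_names)}
        return np.array([lookup[x] for x in self.labels])


def snn_graph(embedding: np.ndarray, k_neighbors: int) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph from a low-dimensional embedding.

    Edge weight between two cells is the fraction of their k nearest
    neighbors (self excluded) that they share.
    """
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    idx = idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k_neighbors)
    B = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (B @ B.T) / k_neighbors
    shared.setdiag(0)
    shared.eliminate_zeros()
    return shared.tocsr()


def _louvain(graph_w: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    import igraph as ig

    coo = sp.triu(graph_w, k=1).tocoo()
    g = ig.Graph(
        n=graph_w.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    random.seed(seed)  # igraph's Python build draws from the random module
    part = g.community_multilevel(weights="weight", resolution=resolution)
    return np.asarray(part.membership)


def cluster_cells(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float | None = None,
    seed: int = 0,
    resolution_grid: tuple[float, ...] = (0.3, 0.6, 0.9, 1.2, 1.5),
) -> CellGrouping:
    """Label-free grouping: SNN graph in the embedding, then Louvain.

    With an explicit ``resolution`` a single Louvain run decides the
    partition.  Without one, Louvain is run over ``resolution_grid``, a
    consensus co-assignment matrix is formed, pruned, and the group number
    is chosen at the largest Laplacian eigen-gap of the consensus; final
    labels cut the consensus dendrogram at that count.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if embedding.ndim != 2 or embedding.shape[1] < 2:
        raise ValueError("embedding must be cells x d with d >= 2")
    if np.allclose(embedding, embedding[0]):
        return CellGrouping.from_labels(np.zeros(n, dtype=int))
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} cells, got {n}")
    graph = snn_graph(embedding, k_neighbors)
    if resolution is not None:
        membership = _louvain(graph, resolution, seed)
    else:
        runs = [_louvain(graph, r, seed + t) for t, r in enumerate(resolution_grid)]
        C = prune_consensus(consensus_matrix(runs))
        n_groups = eigen_gap_count(C)
        membership = cut_consensus(C, n_groups)
    return CellGrouping.from_labels(membership)
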