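"""Consensus co-assignment matrices and eigen-gap model selection.

Shared by label-free cell clustering and pathway grouping: several
partitions of the same objects are combined into a consensus matrix
(probability two objects land in the same part), weak entries are pruned,
and the number of groups is read off the Laplacian eigenvalue spectrum of
the pruned consensus — the count at the largest (or, optionally, second
largest) gap between consecutive eigenvalues.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_PRUNE = 0.3


def consensus_matrix(labelings: list[np.ndarray]) -> np.ndarray:
    """Average co-assignment indicator across partitions; unit diagonal."""
    labelings = [np.asarray(m) for m in labelings]
    n = len(labelings[0])
    C = np.zeros((n, n))
    for m in labelings:
        C += (m[:, None] == m[None, :]).astype(float)
    C /= len(labelings)
    np.fill_diagonal(C, 1.0)
    return C


def prune_consensus(C: np.ndarray, threshold: float = DEFAULT_PRUNE) -> np.ndarray:
    """Zero entries below ``threshold`` for robustness to noise."""
    out = C.copy()
    out[out < threshold] = 0.0
    return out


def eigen_gap_count(C: np.ndarray, use_second: bool = False, max_count: int | None = None) -> int:
    """Group count from the Laplacian eigenvalue spectrum of a consensus.

    Eigenvalues of L = D - C are sorted ascending; the count is the index
    of the largest gap between consecutive eigenvalues (``use_second``
    picks the second largest gap instead).
    """
    L = np.diag(C.sum(axis=1)) - C
    ev = np.sort(np.linalg.eigvalsh(L))
    gaps = np.diff(ev)
    if max_count is not None:
        gaps = gaps[:max_count]
    order = np.argsort(gaps)[::-1]
    idx = order[1] if (use_second and len(order) > 1) else order[0]
    return int(idx) + 1


def cut_consensus(C: np.ndarray, n_groups: int) -> np.ndarray:
    """Labels from average-linkage clustering of consensus distance."""
    n = C.shape[0]
    if n_groups >= n:
        return np.arange(n)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=n_groups, criterion="maxclust") - 1


def cophenetic_correlation(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus distance dendrogram.

    Degenerate inputs (all distances equal, e.g. a perfect consensus of a
    single block) return 1.0 by convention.
    """
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    d = squareform(D, checks=False)
    if np.allclose(d, d[0] if len(d) else 0.0):
        return 1.0
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    return float(c) if np.isfinite(c) else 1.0
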