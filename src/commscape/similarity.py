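"""Similarity of signaling networks, manifold embedding and grouping.

Two complementary views: functional similarity is the Jaccard overlap of
the directed communication edge sets of two networks defined on the same
cell groups (who talks to whom); structural similarity ignores group
identity and compares topology via a weighted dissimilarity built from
node-distance distributions, network node dispersion, and alpha-centrality
profiles of the graph and its complement.  Pathways are then embedded on a
2-D manifold (UMAP of the SNN-smoothed similarity) and grouped by
consensus k-means with eigen-gap selection of the group number.

Conventions for the structural measure (the source topologies are small,
possibly disconnected, binarized undirected graphs):

* node-distance distribution p_i(j): fraction of the other n-1 nodes at
  shortest-path distance j from node i, j = 1..d, with unreachable nodes
  placed in an extra bin at distance d+1, where d is the diameter of the
  graph's largest-distance reachable pair (0 for edgeless graphs);
* distributions of unequal length are zero-padded on the right, and
  alpha-centrality profiles of graphs with different node counts are
  sorted descending before comparison;
* alpha-centrality uses alpha = 0.9 / spectral radius (convergent by
  construction) with a ones exogenous vector, normalized to sum 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._consensus import consensus_matrix, eigen_gap_count, prune_consensus
from .grouping import CellGrouping  # noqa: F401  (re-exported convenience)
from .inference import SignalingNetwork


@dataclass
class StructuralParams:
    """Term weights and conventions of the structural dissimilarity."""

    w1: float = 0.45
    w2: float = 0.45
    w3: float = 0.10
    binarize_threshold: float = 0.0
    alpha_factor: float = 0.9  # alpha = alpha_factor / spectral radius

    def __post_init__(self):
        if not np.isclose(self.w1 + self.w2 + self.w3, 1.0):
            raise ValueError("w1 + w2 + w3 must equal 1")


@dataclass
class ManifoldEmbedding:
    coords: np.ndarray  # N x 2
    names: list[str]
    datasets: list[str] | None = None


@dataclass
class PathwayGrouping:
    labels: np.ndarray
    n_groups: int
    names: list[str]


# ---------------------------------------------------------------- functional


def _edge_set(net: SignalingNetwork) -> set[tuple[int, int]]:
    return {(i, j) for i, j in zip(*np.nonzero(net.adjacency > 0))}


def functional_similarity(
    netA: SignalingNetwork,
    netB: SignalingNetwork,
    symmetric_difference: bool = False,
) -> float:
    """Jaccard overlap of directed communication edge sets.

    ``symmetric_difference`` divides by |union| - |intersection| instead
    of |union| (an alternative printed form); it is unbounded and
    undefined for identical edge sets, where infinity is returned.
    Two empty networks are identical by convention (similarity 1).
    """
    if netA.group_names != netB.group_names:
        raise ValueError("functional similarity requires identical ordered group sets")
    EA, EB = _edge_set(netA), _edge_set(netB)
    inter, union = len(EA & EB), len(EA | EB)
    if union == 0:
        return 1.0
    if symmetric_difference:
        denom = union - inter
        return float("inf") if denom == 0 else inter / denom
    return inter / union


# ---------------------------------------------------------------- structural


def _binarized_graph(net: SignalingNetwork, threshold: float) -> nx.Graph:
    A = net.adjacency
    g = nx.Graph()
    g.add_nodes_from(range(A.shape[0]))
    for i, j in zip(*np.nonzero(A > threshold)):
        if i != j:
            g.add_edge(int(i), int(j))
    return g


def _distance_profile(g: nx.Graph) -> tuple[np.ndarray, int]:
    """Per-node distance distributions (rows) and the diameter d.

    Row i has bins for distances 1..d plus one bin (index d) for
    unreachable nodes at conventional distance d+1.
    """
    n = g.number_of_nodes()
    if n < 2:
        return np.zeros((n, 1)), 0
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    finite = [
        dist
        for i, dd in lengths.items()
        for j, dist in dd.items()
        if i != j
    ]
    d = max(finite) if finite else 0
    P = np.zeros((n, d + 1))
    for i in range(n):
        dd = lengths.get(i, {i: 0})
        for j in range(n):
            if j == i:
                continue
            dist = dd.get(j)
            bin_idx = (dist - 1) if dist is not None else d
            P[i, bin_idx] += 1
    P /= n - 1
    return P, d


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _jsd2(p: np.ndarray, q: np.ndarray) -> float:
    """Two-distribution Jensen-Shannon divergence (natural log, <= log 2)."""
    L = max(len(p), len(q))
    p = np.pad(np.asarray(p, float), (0, L - len(p)))
    q = np.pad(np.asarray(q, float), (0, L - len(q)))
    m = (p + q) / 2
    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def _jsd_many(P: np.ndarray) -> float:
    """Generalized JSD of the row distributions of P (natural log)."""
    mu = P.mean(axis=0)
    return float(np.mean([_kl(P[i], mu) for i in range(P.shape[0])]))


def network_node_dispersion(g: nx.Graph) -> float:
    """NND: generalized JSD of node-distance distributions over log(d+1).

    Zero when all node distance distributions coincide (e.g. complete
    graphs) and for edgeless graphs.
    """
    P, d = _distance_profile(g)
    if P.shape[0] < 2:
        return 0.0
    jsd = _jsd_many(P)
    if jsd <= 1e-15 or d == 0:
        return 0.0
    return jsd / np.log(d + 1.0)


def _alpha_centrality_profile(g: nx.Graph, alpha_factor: float) -> np.ndarray:
    """Normalized alpha-centrality x = (I - a A)^-1 1 as a distribution."""
    n = g.number_of_nodes()
    if n == 0:
        return np.array([1.0])
    A = nx.to_numpy_array(g, nodelist=sorted(g.nodes()))
    lam = np.max(np.abs(np.linalg.eigvals(A))).real if A.any() else 0.0
    a = alpha_factor / lam if lam > 0 else 0.0
    x = np.linalg.solve(np.eye(n) - a * A.T, np.ones(n))
    x = np.abs(x)
    return x / x.sum()


def structural_dissimilarity(
    netA: SignalingNetwork,
    netB: SignalingNetwork,
    params: StructuralParams | None = None,
) -> float:
    """Weighted topological dissimilarity D in [0, 1] (0 iff same profile).

    D = w1 sqrt(JSD(u_A, u_B)/log 2) + w2 |sqrt(NND_A) - sqrt(NND_B)|
        + w3/2 [sqrt(JSD(Pa_A, Pa_B)/log 2) + sqrt(JSD(Pa_Ac, Pa_Bc)/log 2)]

    where u are graph-averaged node-distance distributions, NND the node
    dispersion, and Pa the alpha-centrality profiles of the binarized
    graphs and their complements.  Structural similarity is 1 - D.
    """
    params = params or StructuralParams()
    gA = _binarized_graph(netA, params.binarize_threshold)
    gB = _binarized_graph(netB, params.binarize_threshold)

    PA, _ = _distance_profile(gA)
    PB, _ = _distance_profile(gB)
    uA = PA.mean(axis=0) if PA.shape[0] else np.array([1.0])
    uB = PB.mean(axis=0) if PB.shape[0] else np.array([1.0])
    term1 = np.sqrt(max(_jsd2(uA, uB), 0.0) / np.log(2.0))

    term2 = abs(
        np.sqrt(network_node_dispersion(gA)) - np.sqrt(network_node_dispersion(gB))
    )

    def _sorted_profile(g):
        return np.sort(_alpha_centrality_profile(g, params.alpha_factor))[::-1]

    pa_A, pa_B = _sorted_profile(gA), _sorted_profile(gB)
    pc_A, pc_B = _sorted_profile(nx.complement(gA)), _sorted_profile(nx.complement(gB))
    term3 = 0.5 * (
        np.sqrt(max(_jsd2(pa_A, pa_B), 0.0) / np.log(2.0))
        + np.sqrt(max(_jsd2(pc_A, pc_B), 0.0) / np.log(2.0))
    )
    return float(params.w1 * term1 + params.w2 * term2 + params.w3 * term3)


def structural_similarity(netA, netB, params: StructuralParams | None = None) -> float:
    return 1.0 - structural_dissimilarity(netA, netB, params)


# ------------------------------------------------------- matrices & manifold


def similarity_matrix(
    nets: list[SignalingNetwork],
    kind: str = "functional",
    params: StructuralParams | None = None,
) -> np.ndarray:
    """Pairwise similarity (symmetric, unit diagonal) over networks."""
    N = len(nets)
    S = np.eye(N)
    for i in range(N):
        for j in range(i + 1, N):
            if kind == "functional":
                s = functional_similarity(nets[i], nets[j])
            elif kind == "structural":
                s = structural_similarity(nets[i], nets[j], params)
            else:
                raise ValueError("kind must be 'functional' or 'structural'")
            S[i, j] = S[j, i] = s
    return S


def snn_smooth(S: np.ndarray, k: int | None = None) -> np.ndarray:
    """Smooth a similarity matrix by its shared-nearest-neighbor graph.

    k defaults to round(sqrt(N)).  Neighbors are taken from S itself, SNN
    edge weights are shared-neighbor fractions, and the smoothed matrix is
    the symmetrized product Gs S.
    """
    N = S.shape[0]
    if k is None:
        k = max(1, int(round(np.sqrt(N))))
    order = np.argsort(-S, axis=1)
    neigh = np.zeros((N, N))
    for i in range(N):
        picks = [j for j in order[i] if j != i][:k]
        neigh[i, picks] = 1.0
    Gs = (neigh @ neigh.T) / k
    np.fill_diagonal(Gs, 1.0)
    sm = Gs @ S
    return (sm + sm.T) / 2


def embed_manifold(
    S_smoothed: np.ndarray,
    names: list[str],
    seed: int = 0,
    n_neighbors: int | None = None,
    min_dist: float = 0.3,
    datasets: list[str] | None = None,
) -> ManifoldEmbedding:
    """2-D UMAP of pathways from a smoothed similarity matrix."""
    import umap  # deferred: numba compilation is slow at import time

    N = S_smoothed.shape[0]
    if N < 3:
        raise ValueError("need >= 3 pathways to embed")
    if n_neighbors is None:
        n_neighbors = max(2, int(round(np.sqrt(N))))
    n_neighbors = min(n_neighbors, N - 1)
    lo, hi = S_smoothed.min(), S_smoothed.max()
    Sn = (S_smoothed - lo) / (hi - lo) if hi > lo else np.ones_like(S_smoothed)
    D = 1.0 - Sn
    np.fill_diagonal(D, 0.0)
    reducer = umap.UMAP(
        n_components=2,
        metric="precomputed",
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # umap layout chatter
        coords = reducer.fit_transform(D)
    return ManifoldEmbedding(coords=np.asarray(coords, float), names=list(names), datasets=datasets)


def group_pathways(
    emb: ManifoldEmbedding,
    candidate_k: range = range(2, 11),
    prune: float = 0.3,
    seed: int = 0,
    use_second_gap: bool = False,
) -> PathwayGrouping:
    """Consensus k-means over candidate k, eigen-gap choice of the count."""
    from sklearn.cluster import KMeans

    X = emb.coords
    N = X.shape[0]
    if np.allclose(X, X[0]):
        import warnings

        warnings.warn("all embedding points identical; single group", stacklevel=2)
        return PathwayGrouping(labels=np.zeros(N, dtype=int), n_groups=1, names=emb.names)
    runs = []
    ks = [k for k in candidate_k if k < N]
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        runs.append(km.fit_predict(X))
    C = prune_consensus(consensus_matrix(runs), prune)
    g = eigen_gap_count(C, use_second=use_second_gap, max_count=max(ks))
    km = KMeans(n_clusters=g, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return PathwayGrouping(labels=labels, n_groups=g, names=emb.names)


def joint_embed(
    datasets: dict[str, list[SignalingNetwork]],
    kind: str = "functional",
    seed: int = 0,
    params: StructuralParams | None = None,
) -> tuple[ManifoldEmbedding, PathwayGrouping]:
    """Embed the union of networks from several datasets on one manifold.

    Functional mode requires identical ordered group sets across all
    datasets; structural mode has no such requirement.  Each point is
    tagged (dataset, pathway).
    """
    nets, names, tags = [], [], []
    for tag, ns in datasets.items():
        for n in ns:
            nets.append(n)
            names.append(n.pathway)
            tags.append(tag)
    if len(nets) < 3:
        raise ValueError("need >= 3 networks across datasets")
    if kind == "functional":
        ref = nets[0].group_names
        if any(n.group_names != ref for n in nets):
            raise ValueError("functional mode requires the same cell group composition")
    S = similarity_matrix(nets, kind=kind, params=params)
    Ssm = snn_smooth(S)
    emb = embed_manifold(Ssm, names, seed=seed, datasets=tags)
    grouping = group_pathways(emb, seed=seed)
    return emb, grouping


def pathway_distance(emb: ManifoldEmbedding, pathway: str, dataset_a: str, dataset_b: str) -> float:
    """Euclidean distance between a shared pathway's two embedded copies."""
    if emb.datasets is None:
        raise ValueError("embedding has no dataset tags")
    idx = {
        (d, n): i for i, (d, n) in enumerate(zip(emb.datasets, emb.names))
    }
    try:
        ia, ib = idx[(dataset_a, pathway)], idx[(dataset_b, pathway)]
    except KeyError as e:
        raise KeyError(f"pathway not present in both datasets: {e}") from None
    return float(np.linalg.norm(emb.coords[ia] - emb.coords[ib]))
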