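import math

import networkx as nx
import numpy as np
import pytest

import commscape as cs
from commscape.inference import SignalingNetwork
from commscape.similarity import StructuralParams, structural_dissimilarity


def _net(A, names=None, pathway="X"):
    A = np.asarray(A, float)
    names = names or [f"G{i}" for i in range(A.shape[0])]
    return SignalingNetwork(pathway, A, names)


# ------------------------------------------------------ functional similarity

def test_functional_identity_disjoint_and_partial():
    A = np.zeros((3, 3)); A[0, 1] = A[1, 2] = 0.5       # a->b, b->c
    B = np.zeros((3, 3)); B[1, 2] = B[2, 0] = 0.2       # b->c, c->a
    C = np.zeros((3, 3)); C[2, 1] = 0.9                  # disjoint from A
    assert cs.functional_similarity(_net(A), _net(A)) == 1.0
    assert cs.functional_similarity(_net(A), _net(C)) == 0.0
    assert cs.functional_similarity(_net(A), _net(B)) == pytest.approx(1 / 3)


def test_functional_requires_same_groups():
    with pytest.raises(ValueError, match="group"):
        cs.functional_similarity(_net(np.zeros((2, 2))), _net(np.zeros((3, 3))))


def test_functional_both_empty_is_one_and_symmetric():
    assert cs.functional_similarity(_net(np.zeros((3, 3))), _net(np.zeros((3, 3)))) == 1.0
    rng = np.random.default_rng(0)
    for _ in range(5):
        A = (rng.random((4, 4)) < 0.4) * 1.0
        B = (rng.random((4, 4)) < 0.4) * 1.0
        np.fill_diagonal(A, 0); np.fill_diagonal(B, 0)
        s1 = cs.functional_similarity(_net(A), _net(B))
        s2 = cs.functional_similarity(_net(B), _net(A))
        assert s1 == s2
        assert 0.0 <= s1 <= 1.0


# ---------------------------------------------------- structural dissimilarity
# Independent brute-force oracle, same documented conventions, written with
# explicit loops and Floyd-Warshall rather than the library's BFS.

def _oracle_profile(adj):
    n = len(adj)
    if n < 2:
        return [[0.0] for _ in range(n)], 0
    INF = float("inf")
    d = [[0 if i == j else (1 if (adj[i][j] or adj[j][i]) else INF)
          for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < INF]
    diam = int(max(finite)) if finite else 0
    rows = []
    for i in range(n):
        bins = [0.0] * (diam + 1)
        for j in range(n):
            if j == i:
                continue
            if d[i][j] < INF:
                bins[int(d[i][j]) - 1] += 1
            else:
                bins[diam] += 1
        rows.append([b / (n - 1) for b in bins])
    return rows, diam


def _oracle_jsd2(p, q):
    L = max(len(p), len(q))
    p = list(p) + [0.0] * (L - len(p))
    q = list(q) + [0.0] * (L - len(q))
    total = 0.0
    for a, b in zip(p, q):
        m = (a + b) / 2
        if a > 0:
            total += 0.5 * a * math.log(a / m)
        if b > 0:
            total += 0.5 * b * math.log(b / m)
    return total


def _oracle_nnd(adj):
    rows, diam = _oracle_profile(adj)
    n = len(rows)
    if n < 2:
        return 0.0
    mu = [sum(r[j] for r in rows) / n for j in range(len(rows[0]))]
    jsd = 0.0
    for r in rows:
        for a, m in zip(r, mu):
            if a > 0:
                jsd += a * math.log(a / m)
    jsd /= n
    if jsd <= 1e-15 or diam == 0:
        return 0.0
    return jsd / math.log(diam + 1)


def _oracle_alpha_profile(adj, factor=0.9):
    n = len(adj)
    if n == 0:
        return [1.0]
    A = np.array(adj, float)
    A = ((A > 0) | (A.T > 0)).astype(float)
    np.fill_diagonal(A, 0)
    lam = max(abs(np.linalg.eigvals(A))) if A.any() else 0.0
    a = factor / lam if lam > 0 else 0.0
    x = np.linalg.solve(np.eye(n) - a * A.T, np.ones(n))
    x = np.abs(x)
    x = x / x.sum()
    return sorted(x, reverse=True)


def _oracle_D(adjA, adjB, w=(0.45, 0.45, 0.1)):
    rowsA, _ = _oracle_profile(adjA)
    rowsB, _ = _oracle_profile(adjB)
    nA, nB = len(rowsA), len(rowsB)
    uA = [sum(r[j] for r in rowsA) / nA for j in range(len(rowsA[0]))] if nA else [1.0]
    uB = [sum(r[j] for r in rowsB) / nB for j in range(len(rowsB[0]))] if nB else [1.0]
    t1 = math.sqrt(max(_oracle_jsd2(uA, uB), 0.0) / math.log(2))
    t2 = abs(math.sqrt(_oracle_nnd(adjA)) - math.sqrt(_oracle_nnd(adjB)))

    def compl(adj):
        n = len(adj)
        und = [[1 if (i != j and (adj[i][j] or adj[j][i])) else 0 for j in range(n)]
               for i in range(n)]
        return [[1 if (i != j and not und[i][j]) else 0 for j in range(n)]
                for i in range(n)]

    t3 = 0.5 * (
        math.sqrt(max(_oracle_jsd2(_oracle_alpha_profile(adjA),
                                   _oracle_alpha_profile(adjB)), 0.0) / math.log(2))
        + math.sqrt(max(_oracle_jsd2(_oracle_alpha_profile(compl(adjA)),
                                     _oracle_alpha_profile(compl(adjB))), 0.0) / math.log(2))
    )
    return w[0] * t1 + w[1] * t2 + w[2] * t3


def _atlas_graphs(max_nodes=5):
    return [g for g in nx.graph_atlas_g()[1:]
            if 1 <= g.number_of_nodes() <= max_nodes]


def test_self_dissimilarity_zero_on_all_small_graphs():
    for g in _atlas_graphs():
        A = nx.to_numpy_array(g)
        assert structural_dissimilarity(_net(A), _net(A)) == 0.0


def test_complete_graph_has_zero_node_dispersion():
    from commscape.similarity import network_node_dispersion

    for n in (3, 4, 5):
        assert network_node_dispersion(nx.complete_graph(n)) == 0.0


def test_structural_matches_bruteforce_oracle_on_small_graphs():
    """Implementation vs independent Floyd-Warshall oracle, graphs <= 5 nodes."""
    graphs = _atlas_graphs()
    rng = np.random.default_rng(0)
    idx = rng.choice(len(graphs), size=(120, 2))
    for i, j in idx:
        A = nx.to_numpy_array(graphs[i])
        B = nx.to_numpy_array(graphs[j])
        got = structural_dissimilarity(_net(A), _net(B))
        want = _oracle_D(A.tolist(), B.tolist())
        assert got == pytest.approx(want, abs=1e-9)


def test_star_vs_path_matches_oracle_and_symmetry():
    star = np.zeros((4, 4)); star[0, 1:] = 1
    path = np.zeros((4, 4)); path[0, 1] = path[1, 2] = path[2, 3] = 1
    d1 = structural_dissimilarity(_net(star), _net(path))
    d2 = structural_dissimilarity(_net(path), _net(star))
    assert d1 == pytest.approx(_oracle_D(star.tolist(), path.tolist()), abs=1e-12)
    assert d1 == pytest.approx(d2)
    assert 0.0 < d1 < 1.0


def test_structural_bounded_on_random_pairs():
    rng = np.random.default_rng(4)
    for _ in range(20):
        A = (rng.random((5, 5)) < 0.4) * 1.0
        B = (rng.random((5, 5)) < 0.4) * 1.0
        d = structural_dissimilarity(_net(A), _net(B))
        assert 0.0 <= d <= 1.0


def test_weights_must_sum_to_one():
    with pytest.raises(ValueError):
        StructuralParams(w1=0.5, w2=0.5, w3=0.5)


# ----------------------------------------------------------------- smoothing

def test_snn_k_is_sqrt_of_pathway_count():
    S = np.eye(9)
    sm = cs.snn_smooth(S)  # k = 3
    assert sm.shape == (9, 9)
    np.testing.assert_allclose(sm, sm.T)


def test_snn_smoothing_preserves_block_structure():
    S = np.zeros((8, 8))
    S[:4, :4] = 1.0
    S[4:, 4:] = 1.0
    sm = cs.snn_smooth(S)
    within = np.concatenate([sm[:4, :4].ravel(), sm[4:, 4:].ravel()])
    across = sm[:4, 4:].ravel()
    assert across.max() < within.min()


def test_snn_identity_diagonal_dominant():
    sm = cs.snn_smooth(np.eye(4), k=1)
    assert np.all(np.diag(sm) >= sm.max(axis=1) - 1e-12)


# ------------------------------------------------------- manifold & grouping

def test_embed_requires_three_pathways():
    with pytest.raises(ValueError, match=">= 3"):
        cs.embed_manifold(np.eye(2), ["a", "b"])


def test_embedding_separates_planted_blocks():
    hits = 0
    for seed in range(10):
        S = np.zeros((12, 12))
        S[:6, :6] = 1.0
        S[6:, 6:] = 1.0
        rng = np.random.default_rng(seed)
        S += 0.05 * rng.random((12, 12))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        emb = cs.embed_manifold(cs.snn_smooth(S), [f"p{i}" for i in range(12)], seed=seed)
        assert emb.coords.shape == (12, 2)
        assert np.all(np.isfinite(emb.coords))
        from scipy.spatial.distance import cdist

        intra = np.mean([cdist(emb.coords[:6], emb.coords[:6]).mean(),
                         cdist(emb.coords[6:], emb.coords[6:]).mean()])
        inter = cdist(emb.coords[:6], emb.coords[6:]).mean()
        hits += inter > intra
    assert hits >= 9


def test_group_pathways_recovers_four_planted_clusters():
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        pts = np.vstack([c + rng.normal(0, 0.05, (6, 2)) for c in centers])
        emb = cs.ManifoldEmbedding(coords=pts, names=[f"p{i}" for i in range(24)])
        pg = cs.group_pathways(emb, seed=seed)
        hits += pg.n_groups == 4
    assert hits >= 9


def test_group_pathways_identical_points_single_group():
    emb = cs.ManifoldEmbedding(coords=np.zeros((5, 2)), names=list("abcde"))
    with pytest.warns(UserWarning, match="identical"):
        pg = cs.group_pathways(emb)
    assert pg.n_groups == 1


def test_consensus_matrix_symmetric_unit_diagonal():
    from commscape._consensus import consensus_matrix

    C = consensus_matrix([np.array([0, 0, 1, 1]), np.array([0, 1, 1, 0])])
    np.testing.assert_allclose(C, C.T)
    np.testing.assert_allclose(np.diag(C), 1.0)


# ------------------------------------------------------------ joint manifold

def _random_structured_nets(seed, n_path=15, K=4):
    rng = np.random.default_rng(seed)
    nets = []
    for p in range(n_path):
        A = np.zeros((K, K))
        for _ in range(rng.integers(1, 4)):
            i, j = rng.choice(K, 2, replace=False)
            A[i, j] = 0.1 + 0.5 * rng.random()
        nets.append(_net(A, [f"G{i}" for i in range(K)], pathway=f"PW{p}"))
    return nets


def test_joint_embed_duplicates_near_coincident():
    """Two copies of the same networks land closer than typical pairs."""
    nets = _random_structured_nets(1)
    emb, grouping = cs.joint_embed({"A": nets, "B": nets}, kind="functional", seed=0)
    assert len(grouping.labels) == 30
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(emb.coords))
    thr = np.percentile(D[np.triu_indices_from(D, 1)], 5)
    dups = [cs.pathway_distance(emb, f"PW{p}", "A", "B") for p in range(15)]
    assert np.median(dups) <= thr


def test_joint_embed_functional_mode_rejects_mismatched_groups():
    netsA = _random_structured_nets(0, n_path=3, K=4)
    netsB = _random_structured_nets(0, n_path=3, K=3)
    with pytest.raises(ValueError, match="composition"):
        cs.joint_embed({"A": netsA, "B": netsB}, kind="functional")


def test_pathway_distance_euclidean():
    emb = cs.ManifoldEmbedding(
        coords=np.array([[0.0, 0.0], [3.0, 4.0]]),
        names=["PW0", "PW0"], datasets=["A", "B"],
    )
    assert cs.pathway_distance(emb, "PW0", "A", "B") == pytest.approx(5.0)
    assert cs.pathway_distance(emb, "PW0", "B", "A") == pytest.approx(5.0)
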