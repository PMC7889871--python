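"""Weighted-directed centrality measures for signaling networks.

Four measures map onto four communication roles: weighted out-degree
(dominant senders), weighted in-degree (dominant receivers), flow
betweenness (mediators / gatekeepers of flow between other groups) and
information centrality (influencers controlling information flow).
Optional extras (hub/authority, eigenvector, PageRank) are provided for
exploratory use.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .inference import SignalingNetwork

ROLE_BY_MEASURE = {
    "out_degree": "sender",
    "in_degree": "receiver",
    "flow_betweenness": "mediator",
    "information_centrality": "influencer",
}


def degree_centrality(net: SignalingNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Weighted out- and in-degree; their sums both equal the total flow."""
    return net.adjacency.sum(axis=1), net.adjacency.sum(axis=0)


def _digraph(adjacency: np.ndarray) -> nx.DiGraph:
    g = nx.DiGraph()
    K = adjacency.shape[0]
    g.add_nodes_from(range(K))
    for i in range(K):
        for j in range(K):
            if i != j and adjacency[i, j] > 0:
                g.add_edge(i, j, capacity=float(adjacency[i, j]))
    return g


def flow_betweenness(net: SignalingNetwork, normalized: bool = False) -> np.ndarray:
    """Freeman flow betweenness on the weighted directed network.

    For node v it is the total maximum flow between all ordered pairs of
    other nodes that depends on v: sum over (s, t) of
    maxflow(s, t) - maxflow(s, t) with v removed.  ``normalized`` divides
    by the total maxflow between the other pairs.
    """
    A = net.adjacency
    K = A.shape[0]
    g = _digraph(A)
    base = {}
    for s in range(K):
        for t in range(K):
            if s != t:
                base[(s, t)] = nx.maximum_flow_value(g, s, t)
    scores = np.zeros(K)
    for v in range(K):
        gv = _digraph(np.delete(np.delete(A, v, axis=0), v, axis=1))
        idx = [u for u in range(K) if u != v]
        dependent = 0.0
        total = 0.0
        for a, s in enumerate(idx):
            for b, t in enumerate(idx):
                if s == t:
                    continue
                total += base[(s, t)]
                dependent += base[(s, t)] - nx.maximum_flow_value(gv, a, b)
        scores[v] = dependent / total if (normalized and total > 0) else dependent
    return scores


def information_centrality(net: SignalingNetwork) -> np.ndarray:
    """Stephenson-Zelen information centrality on the symmetrized network.

    The measure is defined for undirected graphs, so the adjacency is
    symmetrized as (A + A^T)/2.  Computed per connected component via
    C = (L + J)^-1, I_v = 1 / (C_vv + (trace(C) - 2/n_c)/n_c); isolated
    nodes score 0 by convention.
    """
    A = (net.adjacency + net.adjacency.T) / 2.0
    np.fill_diagonal(A, 0.0)
    K = A.shape[0]
    scores = np.zeros(K)
    g = nx.from_numpy_array(A)
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        nc = len(nodes)
        if nc < 2:
            continue
        sub = A[np.ix_(nodes, nodes)]
        L = np.diag(sub.sum(axis=1)) - sub
        C = np.linalg.inv(L + np.ones((nc, nc)))
        T = np.trace(C)
        for local, node in enumerate(nodes):
            scores[node] = 1.0 / (C[local, local] + (T - 2.0 / nc) / nc)
    return scores


def extra_centralities(net: SignalingNetwork) -> dict[str, np.ndarray]:
    """Hub/authority, eigenvector and PageRank scores (exploratory)."""
    g = _digraph(net.adjacency)
    for _, _, d in g.edges(data=True):
        d["weight"] = d["capacity"]
    K = net.adjacency.shape[0]

    def _as_array(d):
        return np.array([d.get(i, 0.0) for i in range(K)])

    try:
        hubs, auths = nx.hits(g, max_iter=1000)
    except (nx.PowerIterationFailedConvergence, ZeroDivisionError):
        hubs, auths = {}, {}
    try:
        eig = nx.eigenvector_centrality_numpy(g.to_undirected(), weight="weight")
    except Exception:
        eig = {}
    pr = nx.pagerank(g, weight="weight")
    return {
        "hub": _as_array(hubs),
        "authority": _as_array(auths),
        "eigen": _as_array(eig),
        "pagerank": _as_array(pr),
    }


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x) if hi == 0 else np.ones_like(x)
    return (x - lo) / (hi - lo)


def centrality_scores(net: SignalingNetwork, extras: bool = False) -> pd.DataFrame:
    """All centrality measures plus min-max relative importance in [0, 1]."""
    out_deg, in_deg = degree_centrality(net)
    data = {
        "out_degree": out_deg,
        "in_degree": in_deg,
        "flow_betweenness": flow_betweenness(net),
        "information_centrality": information_centrality(net),
    }
    if extras:
        data.update(extra_centralities(net))
    df = pd.DataFrame(data, index=net.group_names)
    for col in list(df.columns):
        df[f"{col}_relative"] = _minmax(df[col].to_numpy())
    return df


def role_summary(scores: pd.DataFrame) -> dict[str, list[str]]:
    """Tie-aware argmax per measure -> dominant role labels per group."""
    roles: dict[str, list[str]] = {}
    for measure, role in ROLE_BY_MEASURE.items():
        col = scores[measure].to_numpy()
        if np.all(col == 0):
            warnings.warn(f"all-zero {measure}; no dominant {role}", stacklevel=2)
            roles[role] = []
            continue
        top = col.max()
        roles[role] = [g for g, v in zip(scores.index, col) if v == top]
    return roles
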