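"""Six node-centrality measures on undirected simple graphs, from scratch.

The measures are the ones network-pharmacology hub screens run on:

* DC — degree centrality, the raw incident-edge count.
* BC — betweenness centrality, unnormalized, each unordered pair {s, t}
  counted once: BC(v) = sum over s != v != t of sigma_st(v) / sigma_st.
* CC — closeness centrality over the reachable set:
  CC(v) = |R(v)| / sum of d(v, u) for u in R(v); isolated nodes get 0.
  On a disconnected graph this scores each node within its own component
  instead of zeroing the component out.
* EC — eigenvector centrality, the entrywise-nonnegative principal
  eigenvector of the adjacency matrix, Euclidean norm 1.
* LAC — local average connectivity: the mean, over v's neighbors u, of u's
  degree within the subgraph induced by N(v).
* NC — network centrality: the sum over neighbors u of the edge clustering
  coefficient ECC(v, u) = |N(v) & N(u)| / min(deg(v) - 1, deg(u) - 1), with
  a zero denominator (a degree-1 endpoint) defined as ECC = 0.

Conventions (no normalization for BC, reachable-set CC, ECC zero-denominator
rule) are pinned so that median-threshold screening over these values is
reproducible; they are exercised against independent oracles in the tests.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"eigenvector centrality did not converge in {max_iter} iterations "
            f"(last L2 residual {residual:.3e})"
        )
        self.residual = residual


def _adjacency(g: nx.Graph) -> dict:
    return {v: set(g.neighbors(v)) - {v} for v in g.nodes()}


def degree_centrality(g: nx.Graph) -> dict:
    """DC(v) = number of incident edges."""
    return {v: g.degree(v) for v in g.nodes()}


def betweenness_centrality(g: nx.Graph) -> dict:
    """Unnormalized shortest-path betweenness, unordered source-target pairs.

    Brandes' single-source accumulation; the undirected double count is
    halved at the end so each pair {s, t} contributes once.
    """
    adj = _adjacency(g)
    bc = dict.fromkeys(adj, 0.0)
    for s in adj:
        # single-source shortest paths with path counts
        dist = {s: 0}
        sigma = dict.fromkeys(adj, 0.0)
        sigma[s] = 1.0
        preds: dict = {v: [] for v in adj}
        order = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            order.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        # dependency accumulation, leaves of the BFS dag first
        delta = dict.fromkeys(adj, 0.0)
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: b / 2.0 for v, b in bc.items()}


def closeness_centrality(g: nx.Graph) -> dict:
    """CC(v) = |reachable(v)| / total BFS distance to the reachable set."""
    adj = _adjacency(g)
    cc = {}
    for s in adj:
        total = 0
        count = 0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    total += dist[w]
                    count += 1
                    queue.append(w)
        cc[s] = count / total if total > 0 else 0.0
    return cc


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> dict:
    """Principal adjacency eigenvector, entrywise nonnegative, L2 norm 1.

    Shifted power iteration (A + I) from the uniform vector; the shift keeps
    the iteration convergent on bipartite graphs without changing the
    eigenvector.  Raises on a graph with no edges and on non-convergence.
    """
    if g.number_of_edges() == 0:
        raise ValueError("eigenvector centrality needs a graph with at least one edge")
    nodes = list(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    x = np.full(n, 1.0 / np.sqrt(n))
    rows, cols = [], []
    for u, v in g.edges():
        if u == v:
            continue
        rows.append(index[u]); cols.append(index[v])
        rows.append(index[v]); cols.append(index[u])
    rows = np.asarray(rows); cols = np.asarray(cols)

    residual = np.inf
    for _ in range(max_iter):
        y = x.copy()                      # the +I shift
        np.add.at(y, rows, x[cols])
        y /= np.linalg.norm(y)
        residual = float(np.linalg.norm(y - x))
        x = y
        if residual < tol:
            return {v: float(x[index[v]]) for v in nodes}
    raise ConvergenceError(residual, max_iter)


def lac(g: nx.Graph) -> dict:
    """Mean degree of v's neighbors within the subgraph induced by N(v)."""
    adj = _adjacency(g)
    out = {}
    for v, nbrs in adj.items():
        if not nbrs:
            out[v] = 0.0
            continue
        # deg of u inside G[N(v)] = |N(u) & N(v)|
        out[v] = sum(len(adj[u] & nbrs) for u in nbrs) / len(nbrs)
    return out


def nc(g: nx.Graph) -> dict:
    """Sum of edge clustering coefficients over v's incident edges."""
    adj = _adjacency(g)
    deg = {v: len(nbrs) for v, nbrs in adj.items()}
    out = {}
    for v, nbrs in adj.items():
        total = 0.0
        for u in nbrs:
            denom = min(deg[v] - 1, deg[u] - 1)
            if denom > 0:
                total += len(adj[v] & adj[u]) / denom
        out[v] = total
    return out


MEASURES = ("dc", "bc", "ec", "cc", "nc", "lac")


def compute_all(
    g: nx.Graph,
    ec_tol: float = 1e-10,
    ec_max_iter: int = 1000,
    ec_fallback_zero: bool = False,
) -> pd.DataFrame:
    """All six measures as a DataFrame indexed by node (columns = MEASURES).

    ``ec_fallback_zero`` reports EC = 0 on an edgeless graph instead of
    raising; hub screening over an edgeless subnetwork needs the escape
    hatch, ordinary use should not.
    """
    if g.number_of_edges() == 0:
        if not ec_fallback_zero:
            if g.number_of_nodes() == 0:
                return pd.DataFrame(columns=list(MEASURES))
            raise ValueError(
                "graph has no edges: eigenvector centrality is undefined "
                "(pass ec_fallback_zero=True to report EC=0)"
            )
        ec = dict.fromkeys(g.nodes(), 0.0)
    else:
        ec = eigenvector_centrality(g, tol=ec_tol, max_iter=ec_max_iter)
    table = pd.DataFrame(
        {
            "dc": degree_centrality(g),
            "bc": betweenness_centrality(g),
            "ec": ec,
            "cc": closeness_centrality(g),
            "nc": nc(g),
            "lac": lac(g),
        }
    )
    table.index.name = "node"
    return table.sort_index()
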