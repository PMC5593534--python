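"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: betweenness enumerates
shortest paths explicitly, closeness sums BFS distances, eigenvector
centrality comes from a dense eigendecomposition, NC/LAC from naive set
arithmetic, and the hypergeometric tail from exhaustive draw enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


def bc_oracle(g: nx.Graph) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    bc = {v: 0.0 for v in g}
    for s, t in itertools.combinations(g.nodes(), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def cc_oracle(g: nx.Graph) -> dict:
    """Reachable-set closeness from per-source BFS distance maps."""
    cc = {}
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        del dist[v]
        total = sum(dist.values())
        cc[v] = len(dist) / total if total else 0.0
    return cc


def dc_oracle(g: nx.Graph) -> dict:
    return {v: sum(1 for _ in g.neighbors(v)) for v in g}


def ec_oracle(g: nx.Graph) -> dict:
    """Principal adjacency eigenvector via dense symmetric eigendecomposition."""
    nodes = list(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes)
    _, vecs = np.linalg.eigh(a)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = v / np.linalg.norm(v)
    return dict(zip(nodes, v))


def lac_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        nbrs = set(g.neighbors(v)) - {v}
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = sum(d for _, d in sub.degree()) / len(nbrs)
    return out


def nc_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        nv = set(g.neighbors(v)) - {v}
        total = 0.0
        for u in nv:
            nu = set(g.neighbors(u)) - {u}
            denom = min(len(nv) - 1, len(nu) - 1)
            if denom > 0:
                total += len(nv & nu) / denom
        out[v] = total
    return out


def hypergeom_oracle(x: int, big_n: int, big_k: int, n: int) -> float:
    """P(overlap >= x) by enumerating every C(N, n) draw. N <= ~12 only."""
    hits = 0
    total = 0
    marked = set(range(big_k))
    for draw in itertools.combinations(range(big_n), n):
        total += 1
        if len(marked.intersection(draw)) >= x:
            hits += 1
    assert total == comb(big_n, n)
    return hits / total


def connected_random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph resampled until connected (bounded retries)."""
    for attempt in range(50):
        g = nx.gnp_random_graph(n, p, seed=seed * 1000 + attempt)
        if n <= 1 or nx.is_connected(g):
            return g
    raise RuntimeError("could not draw a connected graph; raise p")
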