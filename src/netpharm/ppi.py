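"""Seed-expanded protein-protein interaction (PPI) networks and their merge.

Two seed sets — drug targets and disease targets — are each expanded against a
background interactome (seed nodes plus their first neighbors, with all
interactome edges among that node set), and the two expanded networks are
merged.  The merge defaults to intersection: the core PPI (CPPI) keeps only
nodes and edges present in both, so it is never larger than either input.
Expansion depth is configurable (0 = induced subgraph on the seeds alone).
"""

from __future__ import annotations

import logging

import networkx as nx

from . import io

logger = logging.getLogger(__name__)


def load_interactome(path) -> nx.Graph:
    """Undirected simple graph from a two-column TSV or SIF edge list.

    Symbols are upper-cased; self-loops are dropped (count logged); duplicate
    and reversed-duplicate rows collapse to one edge.
    """
    g = nx.Graph()
    n_self = 0
    for a, b in io.read_edge_list(path):
        a, b = a.strip().upper(), b.strip().upper()
        if a == b:
            n_self += 1
            continue
        g.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loops from %s", n_self, path)
    g.graph["n_self_loops_dropped"] = n_self
    return g


def seed_network(interactome: nx.Graph, seeds: set[str], depth: int = 1) -> nx.Graph:
    """Subnetwork of the interactome around a seed set.

    Node set = seeds plus nodes within ``depth`` interaction steps of a seed;
    edge set = every interactome edge with both endpoints in that node set.
    Seeds absent from the interactome are kept as isolated nodes (logged).
    """
    if not seeds:
        raise ValueError("seed set is empty")
    seeds = {s.upper() for s in seeds}
    missing = sorted(s for s in seeds if s not in interactome)
    if missing:
        logger.info("%d seeds absent from interactome (kept isolated)", len(missing))

    frontier = {s for s in seeds if s in interactome}
    nodes = set(frontier)
    for _ in range(depth):
        frontier = {v for u in frontier for v in interactome.neighbors(u)} - nodes
        nodes |= frontier

    g: nx.Graph = interactome.subgraph(nodes).copy()
    g.add_nodes_from(missing)
    g.graph["seeds"] = sorted(seeds)
    return g


def merge_networks(g1: nx.Graph, g2: nx.Graph, mode: str = "intersection") -> nx.Graph:
    """Set-wise merge of two graphs over a shared symbol namespace."""
    if mode == "intersection":
        nodes = set(g1.nodes()) & set(g2.nodes())
        edges = {frozenset(e) for e in g1.edges()} & {frozenset(e) for e in g2.edges()}
        out = nx.Graph()
        out.add_nodes_from(nodes)
        out.add_edges_from(tuple(e) for e in edges)
        return out
    if mode == "union":
        out = nx.Graph()
        out.add_nodes_from(g1.nodes())
        out.add_nodes_from(g2.nodes())
        out.add_edges_from(g1.edges())
        out.add_edges_from(g2.edges())
        return out
    raise ValueError(f"unknown merge mode {mode!r} (expected 'intersection' or 'union')")


def graph_stats(g: nx.Graph) -> dict:
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_isolated": sum(1 for n in g if g.degree(n) == 0),
    }
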