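"""Bipartite compound-target network construction and summaries.

Compounds (by name) and protein targets (by upper-cased gene symbol) form the
two partitions; an edge records that a compound is predicted or reported to
act on a target.  Direction is not modeled.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io

logger = logging.getLogger(__name__)

COMPOUND, TARGET = "compound", "target"


def build_ct_network(
    compounds: list[str],
    links: pd.DataFrame,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Bipartite graph from a retained-compound list and (compound, target) links.

    Links whose compound is not in ``compounds`` (case-insensitive match) are
    logged and dropped; the dropped count is stored in ``g.graph``.  Compounds
    with no link are excluded unless ``keep_isolated``.
    """
    if links.empty:
        logger.warning("empty compound-target link table: returning empty network")
    by_key = {c.casefold(): c for c in compounds}

    g = nx.Graph(n_links_dropped=0)
    n_dropped = 0
    for _, row in links.iterrows():
        comp = by_key.get(str(row.iloc[0]).casefold())
        if comp is None:
            n_dropped += 1
            continue
        target = str(row.iloc[1]).strip().upper()
        g.add_node(comp, partition=COMPOUND)
        g.add_node(target, partition=TARGET)
        g.add_edge(comp, target)
    if n_dropped:
        logger.warning("dropped %d links with unresolvable compounds", n_dropped)
    g.graph["n_links_dropped"] = n_dropped

    if keep_isolated:
        for c in compounds:
            if c not in g:
                g.add_node(c, partition=COMPOUND)
    return g


def target_nodes(g: nx.Graph) -> set[str]:
    return {n for n, d in g.nodes(data=True) if d.get("partition") == TARGET}


def compound_nodes(g: nx.Graph) -> set[str]:
    return {n for n, d in g.nodes(data=True) if d.get("partition") == COMPOUND}


def ct_degree_stats(g: nx.Graph, top_k: int = 10) -> dict:
    """Per-node degree table and the top-k nodes of each partition by degree."""
    rows = [
        {"node": n, "partition": d.get("partition", "?"), "degree": g.degree(n)}
        for n, d in g.nodes(data=True)
    ]
    table = pd.DataFrame(rows, columns=["node", "partition", "degree"]).sort_values(
        ["partition", "degree", "node"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)

    def top(partition):
        sub = table[table["partition"] == partition]
        return list(sub.head(top_k)[["node", "degree"]].itertuples(index=False, name=None))

    return {
        "table": table,
        "top_compounds": top(COMPOUND),
        "top_targets": top(TARGET),
        "n_compounds": len(compound_nodes(g)),
        "n_targets": len(target_nodes(g)),
        "n_edges": g.number_of_edges(),
    }


def write_ct_network(g: nx.Graph, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    def oriented(u, v):
        # compound first, so the SIF round-trips partition labels
        if g.nodes[u].get("partition") == TARGET:
            u, v = v, u
        return u, v

    with open(outdir / "ct_network.sif", "w") as fh:
        for u, v in sorted(oriented(*e) for e in g.edges()):
            fh.write(f"{u}\tct\t{v}\n")
        for n in sorted(g.nodes()):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")
    io.write_graphml(g, outdir / "ct_network.graphml")
    stats = ct_degree_stats(g)
    io.write_tsv(stats["table"], outdir / "ct_degrees.tsv")
    io.write_json(
        {k: stats[k] for k in ("top_compounds", "top_targets", "n_compounds", "n_targets", "n_edges")}
        | {"n_links_dropped": g.graph.get("n_links_dropped", 0)},
        outdir / "ct_stats.json",
    )


def read_ct_network(path) -> nx.Graph:
    """Rebuild a bipartite network from the SIF written by write_ct_network.

    Partition labels are recovered from edge orientation (compound first).
    """
    g = nx.Graph(n_links_dropped=0)
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            comp, tgt = parts[0], parts[2]
            g.add_node(comp, partition=COMPOUND)
            g.add_node(tgt, partition=TARGET)
            g.add_edge(comp, tgt)
        elif len(parts) == 1 and parts[0]:
            g.add_node(parts[0], partition=COMPOUND)
    return g
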