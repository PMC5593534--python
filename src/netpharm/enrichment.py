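"""Hypergeometric over-representation with kappa grouping of enriched terms.

For a query of n genes drawn against a universe of N genes, a term with K
annotated genes and x of them in the query gets the upper-tail
hypergeometric probability

    p = sum_{k = x .. min(K, n)}  C(K, k) C(N-K, n-k) / C(N, n)

(observed overlap included).  Significance is called at raw p < alpha, as is
conventional in this style of screen; a Benjamini-Hochberg column is reported
for information only.

Significant terms are then grouped the ClueGO way: Cohen's kappa between the
two terms' gene memberships over the universe, an edge where kappa >= a
threshold (default 0.4), and connected components as functional groups, each
labeled by its most significant member term.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import io

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Term id -> (name, gene set) plus the background universe.

    By default the universe is the union of all term genes; pass an explicit
    ``universe`` to use a custom background.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.terms:
            raise ValueError("gene-set collection has no terms")
        # one upper-cased symbol namespace, as everywhere in the pipeline
        self.terms = {
            tid: (name, frozenset(str(g).upper() for g in genes))
            for tid, (name, genes) in self.terms.items()
        }
        self.universe = frozenset(str(g).upper() for g in self.universe)
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")
        if not self.universe:
            self.universe = frozenset().union(*(g for _, g in self.terms.values()))
        outside = {
            tid for tid, (_, genes) in self.terms.items() if not genes <= self.universe
        }
        if outside:
            raise ValueError(f"terms with genes outside the universe: {sorted(outside)[:5]}")

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None) -> "GeneSetCollection":
        terms = io.read_gmt(path)
        uni = frozenset(str(s).upper() for s in universe) if universe else frozenset()
        return cls(terms=terms, universe=uni)


def hypergeom_pvalue(x: int, big_n: int, big_k: int, n: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeom(N=big_n, K=big_k, n)."""
    if x <= 0:
        return 1.0
    return float(hypergeom.sf(x - 1, big_n, big_k, n))


def hypergeom_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every term of the collection against a query gene set.

    Query genes outside the universe are dropped with a warning.  Returns a
    DataFrame sorted by (p_value, term_id) with columns term_id, term_name,
    overlap, term_size, query_size, universe_size, p_value, bh_adjusted_p,
    significant, overlap_genes.
    """
    q = {str(s).upper() for s in query}
    inside = q & collection.universe
    dropped = len(q) - len(inside)
    if dropped:
        logger.warning("dropped %d query genes outside the universe", dropped)
    if not inside:
        raise ValueError("query is empty after restricting to the universe")

    big_n = len(collection.universe)
    n = len(inside)
    rows = []
    for tid in sorted(collection.terms):
        name, genes = collection.terms[tid]
        overlap = inside & genes
        x = len(overlap)
        rows.append(
            {
                "term_id": tid,
                "term_name": name,
                "overlap": x,
                "term_size": len(genes),
                "query_size": n,
                "universe_size": big_n,
                "p_value": hypergeom_pvalue(x, big_n, len(genes), n),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows)
    table["bh_adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = table["p_value"] < alpha
    table = table.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    table.attrs["n_query_dropped"] = dropped
    return table


def kappa(set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]) -> float:
    """Cohen's kappa between two set memberships over a universe.

    The 2x2 agreement table counts genes in both sets, in one only, and in
    neither.  When expected agreement is exactly 1 (both sets equal the
    universe, or both empty) kappa is defined as 1 for identical sets and 0
    otherwise.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a = set(set_a) & uni
    b = set(set_b) & uni
    n = len(uni)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    p_o = (both + neither) / n
    p_yes = ((both + only_a) / n) * ((both + only_b) / n)
    p_no = ((only_b + neither) / n) * ((only_a + neither) / n)
    p_e = p_yes + p_no
    if p_e == 1.0:
        return 1.0 if a == b else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def group_terms(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    kappa_min: float = 0.4,
) -> pd.DataFrame:
    """Assign significant terms to kappa-linked functional groups.

    Builds a term graph with an edge where pairwise kappa >= ``kappa_min``;
    connected components become groups, numbered in order of their best
    (lowest) p-value; each group is labeled by its most significant term.
    Returns the significant rows with ``group_id`` and ``group_label`` added.
    """
    sig = results[results["significant"]].copy()
    if sig.empty:
        raise ValueError("no significant terms to group")
    term_ids = list(sig["term_id"])
    genes = {tid: collection.terms[tid][1] for tid in term_ids}

    tg = nx.Graph()
    tg.add_nodes_from(term_ids)
    for a, b in itertools.combinations(term_ids, 2):
        if kappa(genes[a], genes[b], collection.universe) >= kappa_min:
            tg.add_edge(a, b)

    pval = dict(zip(sig["term_id"], sig["p_value"]))
    components = sorted(
        (sorted(comp, key=lambda t: (pval[t], t)) for comp in nx.connected_components(tg)),
        key=lambda comp: (pval[comp[0]], comp[0]),
    )
    group_id: dict[str, int] = {}
    group_label: dict[str, str] = {}
    names = dict(zip(results["term_id"], results["term_name"]))
    for gid, comp in enumerate(components, start=1):
        label = names[comp[0]]
        for tid in comp:
            group_id[tid] = gid
            group_label[tid] = label
    sig["group_id"] = sig["term_id"].map(group_id)
    sig["group_label"] = sig["term_id"].map(group_label)
    return sig.reset_index(drop=True)


def write_enrichment(results: pd.DataFrame, path) -> None:
    io.write_tsv(results, path)
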