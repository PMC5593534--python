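"""Seeded synthetic inputs, with ground truth, for every pipeline stage.

Each generator emulates the statistical structure its downstream stage
assumes — ADME tables with known pass labels, heavy-tailed interactomes with
boosted hub nodes, two-group log2 expression matrices with planted
fold-change genes, gene-set collections with one planted enriched term, and
bipartite compound-target link tables — and returns a truth record
sufficient to score that stage without re-deriving labels.

One top-level seed fans out to fixed per-generator substreams
(``numpy.random.default_rng([seed, stream])``), so each artifact can be
regenerated independently and byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .compound_screen import DEFAULT_HERBS, AdmeThresholds, CompoundRecord
from .disease_targets import ExpressionMatrix
from .enrichment import GeneSetCollection

# fixed substream ids so generators are independent of call order
_STREAMS = {"compounds": 11, "interactome": 23, "expression": 37, "genesets": 53, "links": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SyntheticTruth:
    """Generator parameters, seed, and per-artifact ground-truth labels."""

    seed: int
    params: dict[str, Any]
    labels: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"seed": self.seed, "params": self.params, "labels": self.labels}


# ---------------------------------------------------------------------------
# compounds

def gen_compound_table(
    n: int = 200,
    herbs: tuple[str, ...] = DEFAULT_HERBS,
    pass_fraction: float = 0.8,
    thresholds: AdmeThresholds | None = None,
    seed: int = 0,
) -> tuple[list[CompoundRecord], SyntheticTruth]:
    """ADME table with known pass/fail labels.

    Passers draw each parameter uniformly above its threshold; failers fail a
    random nonempty subset of the four criteria (drawn strictly below the
    threshold) and pass the rest.  Truth records the passing ids and, for
    failers, which criteria were violated.
    """
    t = thresholds or AdmeThresholds()
    rng = _rng(seed, "compounds")
    n_pass = int(round(n * pass_fraction))
    is_pass = np.zeros(n, dtype=bool)
    is_pass[:n_pass] = True
    rng.shuffle(is_pass)

    # sampling windows: [threshold, high] for passes, [low, threshold) for fails
    windows = {
        "ob": (t.ob_min, 100.0, 0.0),
        "dl": (t.dl_min, 1.0, 0.0),
        "caco2": (t.caco2_min, 2.0, -2.0),
        "hl": (t.hl_min, 48.0, 0.0),
    }
    eps = 1e-6

    records: list[CompoundRecord] = []
    pass_ids: list[str] = []
    failed_criteria: dict[str, list[str]] = {}
    for i in range(n):
        cid = f"C{i:04d}"
        herb = herbs[int(rng.integers(len(herbs)))]
        if is_pass[i]:
            fail_set: list[str] = []
        else:
            mask = rng.random(4) < 0.5
            if not mask.any():
                mask[int(rng.integers(4))] = True
            fail_set = [f for f, m in zip(windows, mask) if m]
        vals = {}
        for fname, (cut, high, low) in windows.items():
            if fname in fail_set:
                vals[fname] = float(rng.uniform(low, cut - eps))
            else:
                vals[fname] = float(rng.uniform(cut, high))
        records.append(
            CompoundRecord(compound_id=cid, name=f"compound-{i:04d}", herb=herb, **vals)
        )
        if is_pass[i]:
            pass_ids.append(cid)
        else:
            failed_criteria[cid] = fail_set

    truth = SyntheticTruth(
        seed=seed,
        params={"n": n, "herbs": list(herbs), "pass_fraction": pass_fraction},
        labels={"pass_ids": pass_ids, "failed_criteria": failed_criteria},
    )
    return records, truth


# ---------------------------------------------------------------------------
# interactome

def gen_interactome(
    n: int = 500,
    model: str = "ba",
    m: int = 3,
    p: float = 0.02,
    n_planted_hubs: int = 10,
    hub_extra_degree: int = 60,
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Simple undirected graph with boosted hub nodes and hub ground truth.

    The base graph is Barabasi-Albert(m) (heavy-tailed, the default) or
    Erdos-Renyi(p); ``n_planted_hubs`` nodes are then wired to
    ``hub_extra_degree`` extra random partners each.  Truth records the
    boosted node set and — because a heavy-tailed base graph has natural
    high-degree nodes of its own — the full set of nodes whose final degree
    exceeds twice the median degree (``expected_hubs``), computed here from
    the generator's own degree array.
    """
    rng = _rng(seed, "interactome")
    base_seed = int(rng.integers(2**31 - 1))
    if model == "ba":
        g = nx.barabasi_albert_graph(n, m, seed=base_seed)
    elif model == "er":
        g = nx.gnp_random_graph(n, p, seed=base_seed)
    else:
        raise ValueError(f"unknown interactome model {model!r}")

    boosted = sorted(int(v) for v in rng.choice(n, size=n_planted_hubs, replace=False))
    for v in boosted:
        candidates = np.array([u for u in range(n) if u != v and not g.has_edge(v, u)])
        extra = min(hub_extra_degree, len(candidates))
        for u in rng.choice(candidates, size=extra, replace=False):
            g.add_edge(v, int(u))

    g = nx.relabel_nodes(g, {v: f"G{v:04d}" for v in g.nodes()})
    degrees = np.array([d for _, d in g.degree()])
    cut = 2.0 * float(np.median(degrees))
    expected = sorted(name for name, d in g.degree() if d > cut)

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n": n, "model": model, "m": m, "p": p,
            "n_planted_hubs": n_planted_hubs, "hub_extra_degree": hub_extra_degree,
        },
        labels={
            "boosted": [f"G{v:04d}" for v in boosted],
            "expected_hubs": expected,
            "degree_cut": cut,
        },
    )
    return g, truth


# ---------------------------------------------------------------------------
# expression

def gen_expression(
    n_genes: int = 2000,
    n_case: int = 22,
    n_control: int = 26,
    de_fraction: float = 0.025,
    lfc: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-group log2 expression matrix with planted fold-change genes.

    Baseline log2 intensities ~ N(8, 1) per gene; Gaussian noise with
    ``noise_sd`` per cell; a ``de_fraction`` of genes is shifted by +/-
    ``lfc`` in the case group (sign alternating deterministically).  Default
    group sizes mirror a small case/control kidney cohort (22 vs 26).
    """
    rng = _rng(seed, "expression")
    if gene_names is not None:
        if len(gene_names) != n_genes:
            raise ValueError("gene_names length must equal n_genes")
        genes = list(gene_names)
    else:
        genes = [f"GENE{i:05d}" for i in range(n_genes)]
    samples = [f"case_{i:02d}" for i in range(n_case)] + [
        f"ctrl_{i:02d}" for i in range(n_control)
    ]
    labels = {s: ("case" if s.startswith("case") else "control") for s in samples}

    baseline = rng.normal(8.0, 1.0, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_case + n_control))

    n_de = int(round(n_genes * de_fraction))
    de_idx = np.sort(rng.choice(n_genes, size=n_de, replace=False)) if n_de else np.array([], int)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    for j, (i, s) in enumerate(zip(de_idx, signs)):
        values[i, :n_case] += s * lfc

    matrix = ExpressionMatrix(genes=genes, samples=samples, values=values, labels=labels)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes, "n_case": n_case, "n_control": n_control,
            "de_fraction": de_fraction, "lfc": lfc, "noise_sd": noise_sd,
        },
        labels={
            "de_genes": [genes[i] for i in de_idx],
            "de_signs": {genes[i]: float(s) for i, s in zip(de_idx, signs)},
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# gene sets

def gen_genesets(
    universe_size: int = 500,
    n_terms: int = 50,
    size_range: tuple[int, int] = (10, 40),
    query_size: int = 30,
    planted_query_overlap: int = 15,
    seed: int = 0,
    universe_genes: list[str] | None = None,
) -> tuple[GeneSetCollection, set[str], SyntheticTruth]:
    """Gene-set collection with one planted enriched term and a query.

    Terms draw genes uniformly from the universe.  The query takes
    ``planted_query_overlap`` genes from the planted term (the first term)
    and fills the rest uniformly from outside it, so the planted term's
    overlap is large while other terms overlap only by chance.
    """
    lo, hi = size_range
    if not (0 < planted_query_overlap <= min(query_size, hi)):
        raise ValueError("planted overlap must fit in both the query and the term")
    rng = _rng(seed, "genesets")
    if universe_genes is not None:
        universe = sorted(str(s).upper() for s in universe_genes)
        universe_size = len(universe)
    else:
        universe = [f"GENE{i:05d}" for i in range(universe_size)]

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    sizes = rng.integers(lo, hi + 1, size=n_terms)
    for t in range(n_terms):
        members = rng.choice(universe_size, size=int(sizes[t]), replace=False)
        terms[f"T{t:03d}"] = (f"term-{t:03d}", frozenset(universe[i] for i in members))
    planted_id = "T000"
    planted_genes = sorted(terms[planted_id][1])

    take = min(planted_query_overlap, len(planted_genes))
    inside = [planted_genes[i] for i in rng.choice(len(planted_genes), size=take, replace=False)]
    outside_pool = sorted(set(universe) - set(planted_genes))
    n_out = query_size - take
    outside = [outside_pool[i] for i in rng.choice(len(outside_pool), size=n_out, replace=False)]
    query = set(inside) | set(outside)

    collection = GeneSetCollection(terms=terms, universe=frozenset(universe))
    truth = SyntheticTruth(
        seed=seed,
        params={
            "universe_size": universe_size, "n_terms": n_terms, "size_range": list(size_range),
            "query_size": query_size, "planted_query_overlap": planted_query_overlap,
        },
        labels={"planted_term": planted_id, "planted_overlap": sorted(inside)},
    )
    return collection, query, truth


# ---------------------------------------------------------------------------
# compound-target links

def gen_ct_links(
    compounds: list[str],
    n_targets: int = 100,
    mean_degree: float = 4.0,
    seed: int = 0,
    target_names: list[str] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Bipartite link table: each compound hits ~Poisson(mean_degree) targets.

    Every compound gets at least one target so the network has no silent
    dropouts; truth records the exact per-compound target lists.
    """
    rng = _rng(seed, "links")
    if target_names is not None:
        targets = sorted(str(s).upper() for s in target_names)
        n_targets = len(targets)
    else:
        targets = [f"TGT{i:04d}" for i in range(n_targets)]
    rows = []
    per_compound: dict[str, list[str]] = {}
    for comp in compounds:
        k = max(1, int(rng.poisson(mean_degree)))
        k = min(k, n_targets)
        chosen = sorted(targets[i] for i in rng.choice(n_targets, size=k, replace=False))
        per_compound[comp] = chosen
        rows.extend({"compound": comp, "target": t} for t in chosen)
    links = pd.DataFrame(rows, columns=["compound", "target"])
    n_edges = sum(len(v) for v in per_compound.values())
    truth = SyntheticTruth(
        seed=seed,
        params={"n_compounds": len(compounds), "n_targets": n_targets, "mean_degree": mean_degree},
        labels={
            "per_compound": per_compound,
            "n_edges": n_edges,
            "n_linked_targets": len({t for v in per_compound.values() for t in v}),
        },
    )
    return links, truth


# ---------------------------------------------------------------------------
# fixture sets on disk

def write_fixture_set(outdir, seed: int = 0, scale: float = 1.0) -> dict:
    """Write a coherent fixture set for an end-to-end run and return its truth.

    All stages share one gene namespace: the interactome lives on the first
    500 genes of a 2000-gene expression space, compound-target links point
    into the interactome, disease lists sample the expression space, and the
    gene-set universe is the interactome gene set (candidate targets are a
    subset of it).  ``scale`` shrinks every size proportionally for quick
    tests.  Files land in ``outdir`` in exactly the formats the pipeline
    readers consume; ground truth goes to ``truth.json``.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = float(scale)
    n_inter = max(50, int(500 * s))
    n_genes = max(2 * n_inter, int(2000 * s))
    n_compounds = max(20, int(200 * s))

    genes = [f"G{i:04d}" for i in range(n_genes)]
    inter_genes = genes[:n_inter]

    compounds, c_truth = gen_compound_table(n=n_compounds, seed=seed)
    rows = [
        {
            "compound_id": r.compound_id, "name": r.name, "herb": r.herb,
            "ob": r.ob, "dl": r.dl, "caco2": r.caco2, "hl": r.hl,
        }
        for r in compounds
    ]
    io.write_tsv(pd.DataFrame(rows), outdir / "compounds.tsv")

    # rescue a few known failers, as literature evidence would
    failers = sorted(c_truth.labels["failed_criteria"])
    rescue = failers[: max(3, len(failers) // 10)]
    (outdir / "rescue.txt").write_text("".join(f"{c}\n" for c in rescue))

    g, g_truth = gen_interactome(n=n_inter, seed=seed)
    g = nx.relabel_nodes(g, dict(zip(sorted(g.nodes()), inter_genes)))
    with open(outdir / "interactome.tsv", "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")

    names = [r.name for r in compounds]
    links, l_truth = gen_ct_links(
        names, mean_degree=4.0, seed=seed, target_names=inter_genes
    )
    io.write_tsv(links, outdir / "ct_links.tsv")

    matrix, e_truth = gen_expression(n_genes=n_genes, seed=seed, gene_names=genes)
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples)
    df.index.name = "gene"
    df.to_csv(outdir / "expression.tsv", sep="\t")
    lab = pd.DataFrame(
        {"sample": matrix.samples, "group": [matrix.labels[x] for x in matrix.samples]}
    )
    io.write_tsv(lab, outdir / "labels.tsv")

    # five "database" disease lists drawn from the expression gene space
    rng = np.random.default_rng([int(seed), 97])
    list_dir = outdir / "disease_lists"
    list_dir.mkdir(exist_ok=True)
    db_truth = {}
    for name in ("omim", "drugbank", "pharmgkb", "gad", "ttd"):
        size = int(rng.integers(60, 140))
        members = sorted(genes[i] for i in rng.choice(n_genes, size=size, replace=False))
        io.write_symbol_list(members, list_dir / f"{name}.txt")
        db_truth[name] = len(members)

    collection, _, gs_truth = gen_genesets(
        seed=seed, universe_genes=inter_genes, n_terms=50, size_range=(10, 40)
    )
    io.write_gmt(collection.terms, outdir / "genesets.gmt")

    truth = {
        "seed": seed,
        "scale": scale,
        "compounds": c_truth.as_dict(),
        "rescue_ids": rescue,
        "interactome": g_truth.as_dict(),
        "ct_links": l_truth.as_dict(),
        "expression": e_truth.as_dict(),
        "disease_list_sizes": db_truth,
        "genesets": gs_truth.as_dict(),
    }
    io.write_json(truth, outdir / "truth.json")
    return truth
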