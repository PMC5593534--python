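"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything here is deliberately dumb: tab-separated tables via pandas, SIF and
GMT as line-oriented text, symbol lists one per line.  Graphs are
:class:`networkx.Graph` throughout; GraphML export goes through networkx.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


class MalformedInputError(ValueError):
    """A parse error that carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_symbol_list(path) -> list[str]:
    """One symbol per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


def write_symbol_list(symbols: Iterable[str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{s}\n" for s in symbols))


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column TSV or SIF (``source relation target``) edge list.

    SIF rows with more than two targets (``a rel b c d``) are expanded.
    """
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t") if "\t" in s else s.split()
        if len(parts) == 2:
            edges.append((parts[0], parts[1]))
        elif len(parts) >= 3:
            # SIF: node relation target [target ...]
            src = parts[0]
            for tgt in parts[2:]:
                edges.append((src, tgt))
        else:
            raise MalformedInputError(path, lineno, f"expected >=2 columns, got {len(parts)}")
    return edges


def write_sif(g: nx.Graph, path, relation: str = "pp") -> None:
    """SIF with one edge per line; isolated nodes written as bare names."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
        lines.append(f"{u}\t{relation}\t{v}")
    for n in sorted(g.nodes()):
        if g.degree(n) == 0:
            lines.append(str(n))
    Path(path).write_text("".join(f"{l}\n" for l in lines))


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t") if "\t" in s else s.split()
        if len(parts) == 1:
            g.add_node(parts[0])
        elif len(parts) >= 3:
            for tgt in parts[2:]:
                if parts[0] != tgt:
                    g.add_edge(parts[0], tgt)
        else:
            raise MalformedInputError(path, lineno, "SIF rows need 1 or >=3 columns")
    return g


def write_graphml(g: nx.Graph, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT: term_id <tab> description <tab> gene [<tab> gene ...] per line."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.rstrip("\n")
        if not s.strip():
            continue
        parts = s.split("\t")
        if len(parts) < 3:
            raise MalformedInputError(path, lineno, "GMT rows need id, description and >=1 gene")
        genes = frozenset(p.strip().upper() for p in parts[2:] if p.strip())
        if not genes:
            raise MalformedInputError(path, lineno, f"term {parts[0]!r} has no genes")
        terms[parts[0]] = (parts[1], genes)
    return terms


def write_gmt(terms: Mapping[str, tuple[str, frozenset[str]]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            name, genes = terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
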