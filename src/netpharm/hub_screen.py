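"""Two-stage median-threshold topological screen for candidate targets.

Stage 1 ("hubs"): a node is a hub when its degree strictly exceeds twice the
median degree of the whole network.

Stage 2 ("candidates"): all six centrality measures are recomputed on the
subgraph induced by the hubs (default scope; the alternative slices the
full-graph values), their medians taken over that node set, and a hub is a
candidate when it strictly exceeds all six medians simultaneously.

Both stages use strict ">", so on a graph where any measure is constant the
candidate set is empty — a vertex-transitive network nominates nobody.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from . import centrality as ct


def median(values: Sequence[float]) -> float:
    """Midpoint of the order statistics; even n averages the middle pair."""
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        raise ValueError("median of empty sequence")
    mid = n // 2
    if n % 2:
        return float(vals[mid])
    return (vals[mid - 1] + vals[mid]) / 2.0


@dataclass
class ScreenThresholds:
    """Per-measure medians and the stage-1 degree cut actually applied."""

    stage1_degree_cut: float
    medians: dict[str, float]   # keyed by centrality.MEASURES

    def as_dict(self) -> dict:
        return {
            "stage1_degree_cut": self.stage1_degree_cut,
            **{f"median_{m}": self.medians[m] for m in ct.MEASURES},
        }


@dataclass
class ScreenOutcome:
    stage1_hubs: set[str]
    candidates: set[str]
    thresholds: ScreenThresholds
    verdicts: pd.DataFrame      # per-node measures + pass flags, stage-2 scope


def stage1_hubs(g: nx.Graph) -> set[str]:
    """Nodes whose degree strictly exceeds twice the network median degree."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = {v: g.degree(v) for v in g.nodes()}
    cut = 2.0 * median(list(degrees.values()))
    return {v for v, d in degrees.items() if d > cut}


def stage2_screen(
    g: nx.Graph,
    hubs: set[str],
    scope: str = "hub_subgraph",
    ec_fallback_zero: bool = False,
) -> ScreenOutcome:
    """Screen hubs against the medians of all six centrality measures.

    ``scope='hub_subgraph'`` recomputes the measures on the hub-induced
    subgraph; ``scope='full_graph'`` computes them on the whole graph and
    slices the hub rows.  Medians are always taken over the hub rows that
    are screened.
    """
    if not hubs:
        raise ValueError("hub set is empty")
    if scope not in ("hub_subgraph", "full_graph"):
        raise ValueError(f"unknown stage-2 scope {scope!r}")
    missing = hubs - set(g.nodes())
    if missing:
        raise ValueError(f"hubs not in graph: {sorted(missing)[:5]} ...")

    if scope == "hub_subgraph":
        sub = g.subgraph(hubs).copy()
        if sub.number_of_edges() == 0 and not ec_fallback_zero:
            raise ValueError(
                "hub-induced subgraph has no edges, so eigenvector centrality "
                "is undefined; use scope='full_graph' or ec_fallback_zero=True"
            )
        table = ct.compute_all(sub, ec_fallback_zero=ec_fallback_zero)
    else:
        table = ct.compute_all(g, ec_fallback_zero=ec_fallback_zero).loc[sorted(hubs)]

    medians = {m: median(table[m].tolist()) for m in ct.MEASURES}
    verdicts = table.copy()
    passing = pd.Series(True, index=table.index)
    for m in ct.MEASURES:
        flag = table[m] > medians[m]
        verdicts[f"pass_{m}"] = flag
        passing &= flag
    verdicts["candidate"] = passing

    degrees = [g.degree(v) for v in g.nodes()]
    thresholds = ScreenThresholds(
        stage1_degree_cut=2.0 * median(degrees), medians=medians
    )
    return ScreenOutcome(
        stage1_hubs=set(hubs),
        candidates=set(verdicts.index[passing]),
        thresholds=thresholds,
        verdicts=verdicts,
    )


def screen(
    g: nx.Graph, scope: str = "hub_subgraph", ec_fallback_zero: bool = False
) -> ScreenOutcome:
    """Convenience wrapper: stage 1 then stage 2 on one graph.

    A graph with no stage-1 hubs (e.g. a regular graph) yields an empty
    outcome rather than an error.
    """
    hubs = stage1_hubs(g)
    if not hubs:
        degrees = [g.degree(v) for v in g.nodes()]
        thresholds = ScreenThresholds(
            stage1_degree_cut=2.0 * median(degrees),
            medians=dict.fromkeys(ct.MEASURES, float("nan")),
        )
        empty = pd.DataFrame(
            columns=[*ct.MEASURES, *(f"pass_{m}" for m in ct.MEASURES), "candidate"]
        )
        return ScreenOutcome(set(), set(), thresholds, empty)
    return stage2_screen(g, hubs, scope=scope, ec_fallback_zero=ec_fallback_zero)
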