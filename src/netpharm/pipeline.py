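"""End-to-end orchestration: screen -> networks -> topological screen -> enrichment.

The stages run in dependency order, every intermediate is serialized under
the output directory, and a machine-readable run report (JSON) is written
last.  The report's ``timestamps`` block is the only non-deterministic
content: reruns on identical inputs and configuration produce byte-identical
reports apart from it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, centrality, ct_network, disease_targets, enrichment, hub_screen, io, ppi
from .compound_screen import AdmeThresholds, read_compound_table, screen_compounds, shared_ingredients, write_screen_report

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """All configuration problems, reported at once."""

    def __init__(self, problems: list[str]):
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))
        self.problems = problems


class DataError(ValueError):
    """A stage failed on its inputs; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_INPUT_KEYS = {
    "compounds", "rescue", "ct_links", "expression", "expression_labels",
    "disease_lists", "interactome", "genesets",
}
_PARAM_DEFAULTS = {
    "adme": {"ob_min": 30.0, "dl_min": 0.18, "caco2_min": -0.4, "hl_min": 4.0},
    "deg": {"p_cut": 0.01, "fc_cut": 2.0, "strict_fc": False, "linear": False},
    "keep_isolated": False,
    "ppi_depth": 1,
    "merge_mode": "intersection",
    "stage2_scope": "hub_subgraph",
    "alpha": 0.05,
    "kappa_min": 0.4,
}


@dataclass
class RunConfig:
    """Validated inputs + parameters for a full pipeline run."""

    inputs: dict[str, object]
    params: dict[str, object]
    output_dir: Path

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        problems: list[str] = []
        unknown_top = set(raw) - {"inputs", "params", "output_dir"}
        if unknown_top:
            problems.append(f"unknown top-level keys: {sorted(unknown_top)}")
        inputs = dict(raw.get("inputs") or {})
        params_in = dict(raw.get("params") or {})
        output_dir = raw.get("output_dir")

        unknown_in = set(inputs) - _INPUT_KEYS
        if unknown_in:
            problems.append(f"unknown input keys: {sorted(unknown_in)}")
        required = _INPUT_KEYS - {"rescue"}
        for key in sorted(required - set(inputs)):
            problems.append(f"missing input: {key}")

        def check_path(p, label):
            if p is not None and not Path(p).exists():
                problems.append(f"input {label}: file not found: {p}")

        for key in sorted(set(inputs) & _INPUT_KEYS):
            if key == "disease_lists":
                lists = inputs[key]
                if not isinstance(lists, (list, tuple)) or not lists:
                    problems.append("input disease_lists: need a non-empty list of paths")
                else:
                    for p in lists:
                        check_path(p, "disease_lists")
            else:
                check_path(inputs[key], key)

        unknown_par = set(params_in) - set(_PARAM_DEFAULTS)
        if unknown_par:
            problems.append(f"unknown param keys: {sorted(unknown_par)}")
        params: dict[str, object] = {}
        for key, default in _PARAM_DEFAULTS.items():
            value = params_in.get(key, default)
            if isinstance(default, dict):
                value = dict(value) if value is not None else {}
                unknown_sub = set(value) - set(default)
                if unknown_sub:
                    problems.append(f"unknown {key} keys: {sorted(unknown_sub)}")
                value = {**default, **{k: v for k, v in value.items() if k in default}}
            params[key] = value
        if params["merge_mode"] not in ("intersection", "union"):
            problems.append(f"merge_mode must be intersection|union, got {params['merge_mode']!r}")
        if params["stage2_scope"] not in ("hub_subgraph", "full_graph"):
            problems.append(
                f"stage2_scope must be hub_subgraph|full_graph, got {params['stage2_scope']!r}"
            )

        if not output_dir:
            problems.append("output_dir is required")
        if problems:
            raise ConfigError(problems)
        return cls(inputs=inputs, params=params, output_dir=Path(output_dir))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError([f"{path}: config must be a YAML mapping"])
        return cls.from_dict(raw)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    report: dict = {"stages": {}, "parameters": config.params}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # 1. ADME screen -------------------------------------------------------
    name = stage("compound_screen")
    try:
        table = read_compound_table(config.inputs["compounds"])
        rescue = (
            io.read_symbol_list(config.inputs["rescue"])
            if config.inputs.get("rescue")
            else []
        )
        screen_rep = screen_compounds(
            table, AdmeThresholds(**config.params["adme"]), rescue
        )
        write_screen_report(screen_rep, out / "screen")
        io.write_tsv(shared_ingredients(screen_rep.retained), out / "screen" / "shared_ingredients.tsv")
        report["stages"][name] = {
            "n_input": len(table),
            "n_passing": len(screen_rep.passing),
            "n_rescued": len(screen_rep.rescued),
            "n_rejected": len(screen_rep.rejected),
            "n_retained": len(screen_rep.retained),
            "n_cross_herb_duplicates": screen_rep.n_cross_herb_duplicates,
        }
    except (OSError, ValueError) as exc:
        raise DataError(name, exc) from exc

    # 2. compound-target network ------------------------------------------
    name = stage("ct_network")
    try:
        links = io.read_tsv(config.inputs["ct_links"])
        compound_names = [r.name for r in screen_rep.retained]
        ct = ct_network.build_ct_network(
            compound_names, links, keep_isolated=bool(config.params["keep_isolated"])
        )
        ct_network.write_ct_network(ct, out / "ct")
        drug_targets = ct_network.target_nodes(ct)
        report["stages"][name] = {
            "n_nodes": ct.number_of_nodes(),
            "n_edges": ct.number_of_edges(),
            "n_compounds": len(ct_network.compound_nodes(ct)),
            "n_targets": len(drug_targets),
            "n_links_dropped": ct.graph.get("n_links_dropped", 0),
        }
    except (OSError, ValueError) as exc:
        raise DataError(name, exc) from exc

    # 3. disease targets ---------------------------------------------------
    name = stage("disease_targets")
    try:
        matrix = disease_targets.read_expression(
            config.inputs["expression"], config.inputs["expression_labels"]
        )
        deg_par = config.params["deg"]
        deg_table = disease_targets.call_degs(
            matrix,
            p_cut=float(deg_par["p_cut"]),
            fc_cut=float(deg_par["fc_cut"]),
            strict_fc=bool(deg_par["strict_fc"]),
            linear=bool(deg_par["linear"]),
        )
        disease_targets.write_deg_table(deg_table, out / "degs.tsv")
        degs = disease_targets.significant_genes(deg_table)

        lists = {"degs": degs}
        for p in config.inputs["disease_lists"]:
            lists[Path(p).stem] = io.read_symbol_list(p)
        disease_set, provenance = disease_targets.merge_disease_targets(lists)
        io.write_tsv(provenance, out / "disease_targets.tsv")
        io.write_symbol_list(sorted(disease_set), out / "disease_targets.txt")

        overlap = disease_targets.intersect_targets(disease_set, drug_targets)
        io.write_symbol_list(overlap, out / "drug_disease_overlap.txt")
        report["stages"][name] = {
            "n_degs": len(degs),
            "n_disease_targets": len(disease_set),
            "n_drug_disease_overlap": len(overlap),
        }
    except (OSError, ValueError) as exc:
        raise DataError(name, exc) from exc

    # 4. PPI networks and the core (CPPI) ---------------------------------
    name = stage("ppi_core")
    try:
        interactome = ppi.load_interactome(config.inputs["interactome"])
        depth = int(config.params["ppi_depth"])
        drug_net = ppi.seed_network(interactome, set(drug_targets), depth=depth)
        disease_net = ppi.seed_network(interactome, set(disease_set), depth=depth)
        cppi = ppi.merge_networks(drug_net, disease_net, mode=str(config.params["merge_mode"]))
        io.write_sif(drug_net, out / "ppi" / "drug_ppi.sif")
        io.write_sif(disease_net, out / "ppi" / "disease_ppi.sif")
        io.write_sif(cppi, out / "ppi" / "cppi.sif")
        io.write_graphml(cppi, out / "ppi" / "cppi.graphml")
        report["stages"][name] = {
            "interactome": ppi.graph_stats(interactome),
            "drug_ppi": ppi.graph_stats(drug_net),
            "disease_ppi": ppi.graph_stats(disease_net),
            "cppi": ppi.graph_stats(cppi),
        }
    except (OSError, ValueError) as exc:
        raise DataError(name, exc) from exc

    # 5. centrality + two-stage hub screen ---------------------------------
    name = stage("hub_screen")
    try:
        # screen on the largest connected component: intersection merges can
        # leave small satellites whose centralities are not comparable
        import networkx as nx

        if cppi.number_of_edges() == 0:
            raise ValueError("CPPI has no edges; nothing to screen")
        core_nodes = max(nx.connected_components(cppi), key=lambda c: (len(c), sorted(c)[0]))
        core = cppi.subgraph(core_nodes).copy()
        full_table = centrality.compute_all(core)
        full_table.to_csv(out / "centrality_cppi.tsv", sep="\t")
        outcome = hub_screen.screen(core, scope=str(config.params["stage2_scope"]))
        outcome.verdicts.to_csv(out / "hub_verdicts.tsv", sep="\t")
        io.write_symbol_list(sorted(outcome.candidates), out / "candidates.txt")
        io.write_json(outcome.thresholds.as_dict(), out / "screen_thresholds.json")
        report["stages"][name] = {
            "n_cppi_core_nodes": core.number_of_nodes(),
            "n_stage1_hubs": len(outcome.stage1_hubs),
            "n_candidates": len(outcome.candidates),
            "thresholds": {
                k: (None if v != v else v) for k, v in outcome.thresholds.as_dict().items()
            },
        }
        candidates = sorted(outcome.candidates)
    except (OSError, ValueError) as exc:
        raise DataError(name, exc) from exc

    # 6. enrichment --------------------------------------------------------
    name = stage("enrichment")
    try:
        collection = enrichment.GeneSetCollection.from_gmt(config.inputs["genesets"])
        usable = sorted(set(candidates) & collection.universe)
        if not usable:
            report["stages"][name] = {
                "n_query": 0, "n_significant": 0, "n_groups": 0,
                "note": "no candidate targets inside the gene-set universe",
            }
        else:
            results = enrichment.hypergeom_enrich(
                usable, collection, alpha=float(config.params["alpha"])
            )
            enrichment.write_enrichment(results, out / "enrichment.tsv")
            n_sig = int(results["significant"].sum())
            n_groups = 0
            if n_sig:
                grouped = enrichment.group_terms(
                    results, collection, kappa_min=float(config.params["kappa_min"])
                )
                enrichment.write_enrichment(grouped, out / "enrichment_groups.tsv")
                n_groups = int(grouped["group_id"].nunique())
            report["stages"][name] = {
                "n_query": len(usable),
                "n_query_dropped": len(candidates) - len(usable),
                "n_significant": n_sig,
                "n_groups": n_groups,
            }
    except (OSError, ValueError) as exc:
        raise DataError(name, exc) from exc

    report["versions"] = _versions()
    report["timestamps"] = {
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    io.write_json(report, out / "run_report.json")
    return report


def _versions() -> dict:
    import networkx
    import numpy
    import pandas
    import scipy

    return {
        "netpharm": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
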