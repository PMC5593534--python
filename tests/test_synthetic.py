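import json

import networkx as nx
import numpy as np
import pytest

from netpharm import synthetic
from netpharm.compound_screen import passes_adme


class TestDeterminism:
    def test_compound_table_reproducible(self):
        a, ta = synthetic.gen_compound_table(n=50, seed=42)
        b, tb = synthetic.gen_compound_table(n=50, seed=42)
        assert a == b
        assert ta.as_dict() == tb.as_dict()

    def test_interactome_reproducible(self):
        g1, t1 = synthetic.gen_interactome(n=120, seed=42)
        g2, t2 = synthetic.gen_interactome(n=120, seed=42)
        assert set(g1.edges()) == set(g2.edges())
        assert t1.as_dict() == t2.as_dict()

    def test_different_seeds_differ(self):
        a, _ = synthetic.gen_compound_table(n=50, seed=1)
        b, _ = synthetic.gen_compound_table(n=50, seed=2)
        assert a != b

    def test_generators_are_independent_of_call_order(self):
        g1, _ = synthetic.gen_interactome(n=80, seed=7)
        synthetic.gen_compound_table(n=10, seed=7)  # interleaved call
        g2, _ = synthetic.gen_interactome(n=80, seed=7)
        assert set(g1.edges()) == set(g2.edges())

    def test_fixture_set_bytes_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthetic.write_fixture_set(d1, seed=5, scale=0.2)
        synthetic.write_fixture_set(d2, seed=5, scale=0.2)
        for f1 in sorted(p for p in d1.rglob("*") if p.is_file()):
            f2 = d2 / f1.relative_to(d1)
            assert f1.read_bytes() == f2.read_bytes(), f1.name


class TestCompoundGenerator:
    def test_pass_fraction_one_all_pass(self):
        records, truth = synthetic.gen_compound_table(n=30, pass_fraction=1.0, seed=0)
        assert all(passes_adme(r) for r in records)
        assert len(truth.labels["pass_ids"]) == 30

    def test_pass_fraction_zero_none_pass(self):
        records, truth = synthetic.gen_compound_table(n=30, pass_fraction=0.0, seed=0)
        assert not any(passes_adme(r) for r in records)
        assert truth.labels["pass_ids"] == []

    def test_labels_match_the_rule(self):
        records, truth = synthetic.gen_compound_table(n=200, pass_fraction=0.8, seed=7)
        passing = {r.compound_id for r in records if passes_adme(r)}
        assert passing == set(truth.labels["pass_ids"])

    def test_failers_fail_exactly_the_recorded_criteria(self):
        from netpharm.compound_screen import AdmeThresholds

        t = AdmeThresholds()
        cuts = {"ob": t.ob_min, "dl": t.dl_min, "caco2": t.caco2_min, "hl": t.hl_min}
        records, truth = synthetic.gen_compound_table(n=100, pass_fraction=0.5, seed=3)
        by_id = {r.compound_id: r for r in records}
        for cid, failed in truth.labels["failed_criteria"].items():
            r = by_id[cid]
            actual = [f for f, cut in cuts.items() if getattr(r, f) < cut]
            assert sorted(actual) == sorted(failed)


class TestInteractomeGenerator:
    def test_ba_without_boosting_with_m1_is_a_tree(self):
        g, _ = synthetic.gen_interactome(n=40, m=1, n_planted_hubs=0, seed=1)
        assert g.number_of_edges() == 39
        assert nx.is_connected(g)

    def test_er_p_zero_is_edgeless(self):
        g, _ = synthetic.gen_interactome(
            n=20, model="er", p=0.0, n_planted_hubs=0, seed=1
        )
        assert g.number_of_edges() == 0

    def test_boosted_nodes_occupy_top_degree_ranks(self):
        g, truth = synthetic.gen_interactome(
            n=300, n_planted_hubs=5, hub_extra_degree=120, seed=9
        )
        by_degree = sorted(g.degree(), key=lambda nd: -nd[1])
        top5 = {n for n, _ in by_degree[:5]}
        assert top5 == set(truth.labels["boosted"])

    def test_expected_hubs_computed_from_final_degrees(self):
        g, truth = synthetic.gen_interactome(n=150, seed=4)
        degrees = dict(g.degree())
        cut = truth.labels["degree_cut"]
        assert cut == 2 * float(np.median(sorted(degrees.values())))
        assert set(truth.labels["expected_hubs"]) == {
            v for v, d in degrees.items() if d > cut
        }

    def test_simple_graph_invariants(self):
        g, _ = synthetic.gen_interactome(n=100, seed=2)
        assert not any(u == v for u, v in g.edges())
        assert g.number_of_edges() == len({frozenset(e) for e in g.edges()})

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            synthetic.gen_interactome(model="smallworld")


class TestExpressionGenerator:
    def test_zero_de_fraction_plants_nothing(self):
        _, truth = synthetic.gen_expression(n_genes=100, de_fraction=0.0, seed=0)
        assert truth.labels["de_genes"] == []

    def test_zero_lfc_carries_no_signal(self):
        matrix, truth = synthetic.gen_expression(
            n_genes=100, de_fraction=0.2, lfc=0.0, seed=0
        )
        case = matrix.values[:, matrix.group_columns("case")]
        ctrl = matrix.values[:, matrix.group_columns("control")]
        diff = case.mean(axis=1) - ctrl.mean(axis=1)
        assert np.abs(diff).max() < 1.0  # noise only, no 2-unit shifts

    def test_planted_shift_visible_in_group_means(self):
        matrix, truth = synthetic.gen_expression(
            n_genes=200, de_fraction=0.1, lfc=2.0, noise_sd=0.3, seed=5
        )
        case = matrix.values[:, matrix.group_columns("case")]
        ctrl = matrix.values[:, matrix.group_columns("control")]
        diff = dict(zip(matrix.genes, case.mean(axis=1) - ctrl.mean(axis=1)))
        for gene, sign in truth.labels["de_signs"].items():
            assert diff[gene] * sign > 1.0

    def test_default_cohort_sizes(self):
        matrix, _ = synthetic.gen_expression(n_genes=10, seed=0)
        assert len(matrix.group_columns("case")) == 22
        assert len(matrix.group_columns("control")) == 26


class TestGenesetGenerator:
    def test_planted_overlap_equal_to_term_size_maximizes_overlap(self):
        coll, query, truth = synthetic.gen_genesets(
            n_terms=20, size_range=(10, 10), query_size=12,
            planted_query_overlap=10, seed=2,
        )
        planted = truth.labels["planted_term"]
        overlap = len(query & coll.terms[planted][1])
        assert overlap == 10
        others = max(
            len(query & genes) for tid, (_, genes) in coll.terms.items() if tid != planted
        )
        assert overlap >= others

    def test_oversized_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synthetic.gen_genesets(query_size=5, planted_query_overlap=10)


def test_fixture_set_is_coherent(tmp_path):
    truth = synthetic.write_fixture_set(tmp_path, seed=3, scale=0.2)
    assert (tmp_path / "truth.json").exists()
    on_disk = json.loads((tmp_path / "truth.json").read_text())
    assert on_disk["seed"] == 3
    # link targets live inside the interactome gene space
    import pandas as pd

    links = pd.read_csv(tmp_path / "ct_links.tsv", sep="\t")
    inter_nodes = set()
    for line in (tmp_path / "interactome.tsv").read_text().splitlines():
        a, b = line.split("\t")
        inter_nodes |= {a, b}
    assert set(links["target"]) <= inter_nodes
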