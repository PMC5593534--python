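import itertools

import numpy as np
import pytest

import helpers_oracles as oracle
from netpharm.enrichment import (
    GeneSetCollection,
    group_terms,
    hypergeom_enrich,
    hypergeom_pvalue,
    kappa,
)
from netpharm.synthetic import gen_genesets


def collection_from(terms: dict[str, set[str]], universe=None) -> GeneSetCollection:
    return GeneSetCollection(
        terms={tid: (tid, frozenset(genes)) for tid, genes in terms.items()},
        universe=frozenset(universe) if universe else frozenset(),
    )


class TestHypergeomPvalue:
    def test_closed_form_full_overlap(self):
        # drawing all 5 marked genes in 5 draws from 20: p = 1 / C(20,5)
        assert hypergeom_pvalue(5, 20, 5, 5) == pytest.approx(1 / 15504, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        assert hypergeom_pvalue(0, 50, 10, 5) == 1.0

    @pytest.mark.parametrize("big_n,big_k,n", [(8, 3, 4), (10, 4, 5), (12, 5, 6)])
    def test_matches_exhaustive_draw_enumeration(self, big_n, big_k, n):
        for x in range(0, min(big_k, n) + 1):
            expected = oracle.hypergeom_oracle(x, big_n, big_k, n)
            assert hypergeom_pvalue(x, big_n, big_k, n) == pytest.approx(expected, abs=1e-12)

    def test_monotone_nonincreasing_in_overlap(self):
        ps = [hypergeom_pvalue(x, 100, 20, 15) for x in range(16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestEnrich:
    def test_results_sorted_and_flagged(self):
        terms = {"T1": {"A", "B", "C"}, "T2": {"D", "E", "F", "G"}}
        coll = collection_from(terms)
        res = hypergeom_enrich({"A", "B", "C"}, coll, alpha=0.05)
        assert list(res["p_value"]) == sorted(res["p_value"])
        top = res.iloc[0]
        assert top["term_id"] == "T1"
        assert top["overlap"] == 3
        assert top["overlap_genes"] == "A,B,C"

    def test_query_outside_universe_dropped_with_count(self):
        coll = collection_from({"T1": {"A", "B"}})
        res = hypergeom_enrich({"A", "ZZZ"}, coll)
        assert res.attrs["n_query_dropped"] == 1
        assert res.iloc[0]["query_size"] == 1

    def test_empty_query_after_filtering_is_an_error(self):
        coll = collection_from({"T1": {"A", "B"}})
        with pytest.raises(ValueError, match="empty"):
            hypergeom_enrich({"ZZZ"}, coll)

    def test_planted_term_ranks_first(self):
        wins = 0
        for seed in range(20):
            coll, query, truth = gen_genesets(seed=seed)
            res = hypergeom_enrich(query, coll)
            wins += res.iloc[0]["term_id"] == truth.labels["planted_term"]
        assert wins >= 19

    def test_bh_column_does_not_drive_significance(self):
        coll = collection_from({f"T{i}": {f"G{i}a", f"G{i}b"} for i in range(30)})
        res = hypergeom_enrich({"G0A", "G0B"}, coll)
        assert (res["significant"] == (res["p_value"] < 0.05)).all()


class TestKappa:
    def test_identical_proper_subsets_agree_perfectly(self):
        uni = set("ABCDEFGH")
        assert kappa({"A", "B"}, {"A", "B"}, uni) == pytest.approx(1.0)

    def test_complementary_halves_disagree_maximally(self):
        uni = set("ABCD")
        assert kappa({"A", "B"}, {"C", "D"}, uni) == pytest.approx(-1.0)

    def test_symmetry(self):
        uni = {f"g{i}" for i in range(30)}
        rng = np.random.default_rng(4)
        a = set(rng.choice(sorted(uni), 10, replace=False))
        b = set(rng.choice(sorted(uni), 12, replace=False))
        assert kappa(a, b, uni) == pytest.approx(kappa(b, a, uni))

    def test_independent_random_sets_center_on_zero(self):
        uni = sorted(f"g{i}" for i in range(60))
        rng = np.random.default_rng(0)
        values = []
        for _ in range(300):
            a = set(rng.choice(uni, 20, replace=False))
            b = set(rng.choice(uni, 20, replace=False))
            values.append(kappa(a, b, uni))
        assert abs(float(np.mean(values))) < 0.02

    def test_degenerate_expected_agreement(self):
        uni = {"A", "B"}
        assert kappa(uni, uni, uni) == 1.0
        assert kappa(set(), set(), uni) == 1.0
        assert kappa(uni, set(), uni) == 0.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            kappa({"A"}, {"A"}, set())


class TestGroupTerms:
    def _enrich(self, terms, query, universe=None, alpha=1.1):
        coll = collection_from(terms, universe)
        return coll, hypergeom_enrich(query, coll, alpha=alpha)

    def test_dissimilar_terms_stay_singletons(self):
        universe = {f"g{i}" for i in range(40)}
        terms = {"T1": {"g0", "g1"}, "T2": {"g20", "g21"}}
        coll, res = self._enrich(terms, {"g0", "g1", "g20"}, universe)
        grouped = group_terms(res, coll, kappa_min=0.4)
        assert grouped["group_id"].nunique() == 2

    def test_identical_terms_share_a_group(self):
        universe = {f"g{i}" for i in range(20)}
        terms = {"T1": {"g0", "g1", "g2"}, "T2": {"g0", "g1", "g2"}}
        coll, res = self._enrich(terms, {"g0", "g1"}, universe)
        grouped = group_terms(res, coll, kappa_min=0.4)
        assert grouped["group_id"].nunique() == 1
        assert grouped["group_label"].nunique() == 1

    def test_planted_three_cluster_structure_recovered(self):
        universe = {f"g{i}" for i in range(90)}
        blocks = [set(f"g{i}" for i in range(k * 30, k * 30 + 12)) for k in range(3)]
        terms = {}
        for k, block in enumerate(blocks):
            block = sorted(block)
            terms[f"A{k}"] = set(block[:10])
            terms[f"B{k}"] = set(block[2:12])  # overlaps A{k} heavily
        coll, res = self._enrich(terms, set(sorted(universe)[:30]), universe)
        grouped = group_terms(res, coll, kappa_min=0.4)
        groups = {row["term_id"]: row["group_id"] for _, row in grouped.iterrows()}
        for k in range(3):
            assert groups[f"A{k}"] == groups[f"B{k}"]
        assert len(set(groups.values())) == 3

    def test_group_label_is_most_significant_member(self):
        universe = {f"g{i}" for i in range(30)}
        terms = {"T1": {"g0", "g1", "g2", "g3"}, "T2": {"g0", "g1", "g2", "g3", "g4", "g5"}}
        coll, res = self._enrich(terms, {"g0", "g1", "g2", "g3"}, universe)
        grouped = group_terms(res, coll, kappa_min=0.3)
        best = res.iloc[0]["term_name"]
        assert (grouped["group_label"] == best).all()

    def test_no_significant_terms_rejected(self):
        coll = collection_from({"T1": {"A", "B"}})
        res = hypergeom_enrich({"A"}, coll, alpha=0.0)
        with pytest.raises(ValueError, match="significant"):
            group_terms(res, coll)


def test_gmt_round_trip(tmp_path):
    coll, _, _ = gen_genesets(seed=5, n_terms=10)
    from netpharm import io

    io.write_gmt(coll.terms, tmp_path / "sets.gmt")
    loaded = GeneSetCollection.from_gmt(tmp_path / "sets.gmt")
    assert loaded.terms == coll.terms
    # GMT carries no explicit background: the universe defaults to the union
    # of term genes unless passed separately
    assert loaded.universe == frozenset().union(*(g for _, g in coll.terms.values()))
    explicit = GeneSetCollection.from_gmt(tmp_path / "sets.gmt", universe=coll.universe)
    assert explicit.universe == coll.universe
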