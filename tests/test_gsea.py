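import numpy as np
import pandas as pd
import pytest

from linchk.gsea import (
    EnrichmentResult,
    RankedList,
    correlation_rank,
    enrichment_score,
    gsea_preranked,
    reduce_terms,
    semantic_similarity,
    term_matrix_filter,
)
from linchk.io import GeneSetCollection, OntologyDAG
from linchk.synth import make_coexpression

from oracles import running_sum_es


def ranked_from(genes, scores):
    return RankedList.from_scores(dict(zip(genes, scores)))


class TestCorrelationRank:
    def make_matrix(self, rng):
        y = rng.normal(5, 1, 20)
        data = {
            "LINC": y,
            "copy": y.copy(),
            "anti": -(y - y.mean()) + y.mean(),
            "noise": rng.normal(5, 1, 20),
        }
        return pd.DataFrame(data, index=[f"s{i}" for i in range(20)]).T

    def test_exact_copy_ranked_first(self, rng):
        m = self.make_matrix(rng)
        ranked = correlation_rank(m, "LINC", ["copy", "anti", "noise"])
        assert ranked.genes[0] == "copy"
        assert ranked.scores[0] == pytest.approx(1.0)

    def test_negated_profile_ranked_last(self, rng):
        m = self.make_matrix(rng)
        ranked = correlation_rank(m, "LINC", ["copy", "anti", "noise"])
        assert ranked.genes[-1] == "anti"
        assert ranked.scores[-1] == pytest.approx(-1.0)

    def test_constant_genes_dropped_with_warning(self, rng):
        m = self.make_matrix(rng)
        m.loc["flat"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            ranked = correlation_rank(m, "LINC", ["copy", "flat"])
        assert "flat" not in ranked.genes

    def test_planted_pathway_ranks_high(self):
        coex, sets, truth = make_coexpression(n_samples=60, seed=4)
        coding = [g for g in coex.gene_ids if not g.startswith("LINC_")]
        ranked = correlation_rank(coex, "LINC_PW00", coding)
        members = sets.genes("PW00")
        pct = [1 - ranked.genes.index(g) / len(ranked) for g in members]
        assert np.mean(pct) >= 0.90


class TestEnrichmentScore:
    def test_contiguous_top_hits_reach_one(self):
        genes = [f"g{i}" for i in range(10)]
        scores = [1.0] * 3 + [0.5] * 7
        assert enrichment_score(ranked_from(genes, scores), {"g0", "g1", "g2"}) == pytest.approx(1.0)

    def test_matches_running_sum_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 21))
            k = int(rng.integers(1, min(8, n - 1) + 1))
            genes = [f"g{i}" for i in range(n)]
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            gene_set = set(rng.choice(genes, k, replace=False))
            p = float(rng.choice([0.0, 1.0, 2.0]))
            es = enrichment_score(ranked_from(genes, scores), gene_set, weight_p=p)
            oracle = running_sum_es(genes, scores, gene_set, weight_p=p)
            if es != pytest.approx(oracle, abs=1e-12):
                # exactly tied positive/negative extremes: sign is arbitrary
                assert abs(es) == pytest.approx(abs(oracle), abs=1e-9)

    def test_unweighted_sign_flips_on_reversal(self, rng):
        n = 12
        genes = [f"g{i}" for i in range(n)]
        scores = np.linspace(1, -1, n)
        gene_set = {"g0", "g1", "g5"}
        es_fwd = enrichment_score(ranked_from(genes, scores), gene_set, weight_p=0.0)
        rev = ranked_from(genes[::-1], scores)  # same scores, reversed membership order
        es_rev = enrichment_score(rev, gene_set, weight_p=0.0)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        ranked = ranked_from(["a", "b", "c"], [3, 2, 1])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"x"})
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"a", "b", "c"})


class TestGseaPreranked:
    def collection(self, sets):
        coll = GeneSetCollection()
        for name, genes in sets.items():
            coll.sets[name] = ("", frozenset(genes))
        return coll

    def test_planted_set_beats_random_sets(self, rng):
        n = 200
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.normal(0, 0.3, n))[::-1]
        planted = set(genes[:20])
        sets = {"planted": planted}
        for j in range(5):
            sets[f"rand{j}"] = set(rng.choice(genes, 20, replace=False))
        res = gsea_preranked(
            ranked_from(genes, scores), self.collection(sets), n_perm=500, seed=1
        )
        by_name = {r.term: r for r in res}
        assert by_name["planted"].p_value < 0.01
        assert by_name["planted"].nes > 0
        assert by_name["planted"].fdr_q < 0.05

    def test_duplicate_set_under_two_names(self, rng):
        n = 100
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        members = set(genes[::5])
        res = gsea_preranked(
            ranked_from(genes, scores),
            self.collection({"one": members, "two": members}),
            n_perm=300,
            seed=0,
        )
        by_name = {r.term: r for r in res}
        assert by_name["one"].es == by_name["two"].es
        assert by_name["one"].nes == pytest.approx(by_name["two"].nes, abs=0.25)

    def test_deterministic_and_order_independent(self, rng):
        n = 80
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        sets = {f"S{j}": set(rng.choice(genes, 15, replace=False)) for j in range(4)}
        ranked = ranked_from(genes, scores)
        res1 = gsea_preranked(ranked, self.collection(sets), n_perm=200, seed=3)
        rev = self.collection(dict(reversed(list(sets.items()))))
        res2 = gsea_preranked(ranked, rev, n_perm=200, seed=3)
        assert {r.term: r.p_value for r in res1} == {r.term: r.p_value for r in res2}

    def test_no_eligible_set_rejected(self):
        ranked = ranked_from([f"g{i}" for i in range(30)], np.linspace(1, -1, 30))
        with pytest.raises(ValueError):
            gsea_preranked(ranked, self.collection({"big": {f"g{i}" for i in range(30)}}))


class TestTermMatrixFilter:
    def results_for(self, n_lincs, sig_in, term="T1"):
        out = {}
        for i in range(n_lincs):
            fdr = 0.01 if i < sig_in else 0.5
            out[f"L{i}"] = [EnrichmentResult(term, 0.5, 1.8, 0.01, fdr, 20)]
        return out

    def test_ceiling_convention_five_of_52_dropped(self):
        mat = term_matrix_filter(self.results_for(52, 5))
        assert mat.shape[0] == 0  # ceil(5.2) = 6 required

    def test_six_of_52_kept(self):
        mat = term_matrix_filter(self.results_for(52, 6))
        assert list(mat.index) == ["T1"]
        assert (mat.loc["T1"] == 1).sum() == 6

    def test_no_significant_terms_empty(self):
        mat = term_matrix_filter(self.results_for(10, 0))
        assert mat.empty

    def test_signs_encoded(self):
        res = {
            "L0": [EnrichmentResult("T1", -0.5, -1.9, 0.01, 0.01, 20)],
            "L1": [EnrichmentResult("T1", 0.5, 1.9, 0.01, 0.01, 20)],
        }
        mat = term_matrix_filter(res, min_lincRNA_fraction=0.5)
        assert mat.loc["T1", "L0"] == -1 and mat.loc["T1", "L1"] == 1


class TestSemanticSimilarity:
    def toy_dag(self):
        return OntologyDAG(
            parents={
                "R": [],
                "A": [("R", "is_a")],
                "B": [("R", "is_a")],
                "C": [("A", "is_a")],
                "D": [("A", "part_of")],
            },
            names={t: t for t in "RABCD"},
        )

    def test_self_similarity_unit(self):
        sim = semantic_similarity(self.toy_dag(), ["C", "B"])
        assert sim.loc["C", "C"] == 1.0

    def test_hand_propagated_s_values(self):
        # S_C = {C:1, A:.8, R:.64}; S_B = {B:1, R:.8}; shared {R}
        sim = semantic_similarity(self.toy_dag(), ["C", "B", "A", "D"])
        assert sim.loc["C", "B"] == pytest.approx((0.64 + 0.8) / (2.44 + 1.8))
        assert sim.loc["A", "C"] == pytest.approx((1 + 0.8 + 0.8 + 0.64) / (1.8 + 2.44))
        # part_of edge weight 0.6: S_D = {D:1, A:.6, R:.48}
        assert sim.loc["D", "C"] == pytest.approx((0.6 + 0.8 + 0.48 + 0.64) / (2.08 + 2.44))

    def test_symmetry_and_unknown_term(self):
        sim = semantic_similarity(self.toy_dag(), ["C", "D"])
        assert sim.to_numpy() == pytest.approx(sim.to_numpy().T)
        with pytest.raises(KeyError):
            semantic_similarity(self.toy_dag(), ["C", "nope"])


class TestReduceTerms:
    def sim_matrix(self):
        terms = ["a", "b", "c", "d"]
        m = np.array(
            [
                [1.0, 0.95, 0.1, 0.1],
                [0.95, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.9],
                [0.1, 0.1, 0.9, 1.0],
            ]
        )
        return pd.DataFrame(m, index=terms, columns=terms)

    def test_clusters_partition_terms(self):
        reps, clusters = reduce_terms(self.sim_matrix(), cut_height=0.5)
        assert set(clusters) == {"a", "b", "c", "d"}
        assert len(reps) == len(set(clusters.values())) == 2

    def test_representatives_deterministic(self):
        r1, _ = reduce_terms(self.sim_matrix(), seed=5)
        r2, _ = reduce_terms(self.sim_matrix(), seed=5)
        assert r1 == r2
        lowest, _ = reduce_terms(self.sim_matrix(), cut_height=0.5, seed=None)
        assert lowest == ["a", "c"]

    def test_output_size_monotone_in_cut_height(self):
        sizes = [
            len(reduce_terms(self.sim_matrix(), cut_height=h)[0])
            for h in (0.01, 0.5, 0.95)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_single_term(self):
        sim = pd.DataFrame([[1.0]], index=["only"], columns=["only"])
        assert reduce_terms(sim) == (["only"], {"only": 1})
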