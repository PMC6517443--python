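import numpy as np
import pytest

from linchk.classify import classify_lincRNAs
from linchk.synth import (
    make_coexpression,
    make_gene_models,
    make_methylation,
    make_sequences,
    make_survival,
    make_tissue_matrix,
    make_tumour_tables,
)

from oracles import dinuc_counts


class TestDeterminism:
    def test_tissue_matrix_bit_identical(self):
        m1, t1 = make_tissue_matrix(10, 10, 10, seed=42)
        m2, t2 = make_tissue_matrix(10, 10, 10, seed=42)
        assert m1.values.equals(m2.values)
        assert t1.gene_class == t2.gene_class

    def test_all_generators_seed_stable(self):
        assert make_sequences(3, 3, seed=5)[0] == make_sequences(3, 3, seed=5)[0]
        de1, cna1, _, _ = make_tumour_tables([f"G{i}" for i in range(10)], seed=5)
        de2, cna2, _, _ = make_tumour_tables([f"G{i}" for i in range(10)], seed=5)
        assert de1.equals(de2) and cna1.equals(cna2)
        s1, _ = make_survival(50, 2.0, seed=5)
        s2, _ = make_survival(50, 2.0, seed=5)
        assert s1.equals(s2)
        c1, _, _ = make_coexpression(n_samples=20, seed=5)
        c2, _, _ = make_coexpression(n_samples=20, seed=5)
        assert c1.values.equals(c2.values)

    def test_different_seeds_differ(self):
        m1, _ = make_tissue_matrix(5, 5, 5, seed=1)
        m2, _ = make_tissue_matrix(5, 5, 5, seed=2)
        assert not m1.values.equals(m2.values)


class TestTissueMatrix:
    def test_planted_classes_recovered(self):
        matrix, truth = make_tissue_matrix(50, 50, 100, 16, seed=1)
        labels = {c.gene_id: c.label for c in classify_lincRNAs(matrix)}
        hk_true = {g for g, c in truth.gene_class.items() if c == "HK"}
        ts_true = {g for g, c in truth.gene_class.items() if c == "TS"}
        hk_hits = sum(labels[g] == "HK" for g in hk_true)
        ts_hits = sum(labels[g] == "TS" for g in ts_true)
        assert hk_hits / len(hk_true) >= 0.95
        assert ts_hits / len(ts_true) >= 0.95

    def test_no_planted_hk_rarely_yields_hk_calls(self):
        false_hk_runs = 0
        for seed in range(100):
            matrix, _ = make_tissue_matrix(0, 10, 30, 16, seed=seed)
            labels = [c.label for c in classify_lincRNAs(matrix)]
            if any(l == "HK" for l in labels):
                false_hk_runs += 1
        assert false_hk_runs <= 1  # no HK call in >= 99% of seeds

    def test_impossible_parameterization_rejected(self):
        with pytest.raises(ValueError):
            make_tissue_matrix(5, 5, 5, n_tissues=3)
        with pytest.raises(ValueError):
            make_tissue_matrix(-1, 5, 5)


class TestSequences:
    def test_structured_flagged_and_lengths(self):
        seqs, truth = make_sequences(5, 7, length_range=(100, 150), seed=3)
        assert sum(truth.structured.values()) == 5
        assert all(100 <= len(s) <= 150 for s in seqs.values())

    def test_dinucleotide_bias_respected(self):
        bias = {a + b: 1.0 for a in "ACGT" for b in "ACGT"}
        bias["GC"] = 8.0
        bias["CG"] = 8.0
        seqs, _ = make_sequences(0, 40, length_range=(300, 300), dinuc_bias=bias, seed=7)
        counts: dict[str, int] = {}
        total = 0
        for s in seqs.values():
            for dn, c in dinuc_counts(s).items():
                counts[dn] = counts.get(dn, 0) + c
                total += c
        # GC/CG each requested at 8/30 of mass vs 1/30 for the rest
        assert counts["GC"] / total == pytest.approx(8 / 30, abs=0.03)
        assert counts["AT"] / total == pytest.approx(1 / 30, abs=0.02)

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            make_sequences(1, 1, length_range=(20, 60))


class TestTumourTables:
    def test_planted_events_separable(self):
        genes = [f"G{i:03d}" for i in range(60)]
        de, cna, focal, truth = make_tumour_tables(genes, seed=9)
        down = {g for g, ev in truth.tumour_events.items() if ev["down"]}
        # every planted-down gene has a qualifying DE row
        for g in down:
            sub = de[(de["gene_id"] == g) & (de["log2_fc"] < -1) & (de["q"] < 0.05)]
            assert len(sub) >= 1
        deleted = {g for g, ev in truth.tumour_events.items() if ev["deleted"]}
        frac = (cna == "homdel").mean(axis=1)
        for g in deleted:
            assert frac[g] >= 0.01 or truth.tumour_events[g]["focal"]
        clean = set(genes) - down - deleted
        assert (frac[sorted(clean)] < 0.01).all()

    def test_focal_regions_cover_planted_genes(self):
        genes = [f"G{i:03d}" for i in range(40)]
        lincs, _, _ = make_gene_models(genes, seed=9)
        de, cna, focal, truth = make_tumour_tables(genes, seed=9, annotations=lincs)
        focal_true = {g for g, ev in truth.tumour_events.items() if ev["focal"]}
        assert focal_true  # some planted
        span = {g.gene_id: g.span for g in lincs}
        for g in focal_true:
            assert any(
                span[g].overlaps(iv) for iv, _, t in focal if t == "del"
            )


class TestGeneModels:
    def test_proximal_fraction_planted(self):
        ids = [f"L{i}" for i in range(40)]
        lincs, coding, proximal = make_gene_models(ids, frac_proximal=0.1, seed=1)
        assert len(proximal) == 4
        from linchk.classify import exclude_proximal_lincRNAs

        kept = {g.gene_id for g in exclude_proximal_lincRNAs(lincs, coding)}
        assert kept == set(ids) - proximal


class TestMethylationAndCoexpressionAndSurvival:
    def test_methylation_groups_shifted(self):
        lincs, _, _ = make_gene_models([f"G{i}" for i in range(20)], seed=2)
        hk = {f"G{i}" for i in range(10)}
        betas, coords, _ = make_methylation(lincs, hk, n_samples=30, seed=2)
        hk_probes = [p for p in betas.index if p.split("_")[1] in hk]
        other = [p for p in betas.index if p.split("_")[1] not in hk]
        assert betas.loc[hk_probes].to_numpy().mean() < betas.loc[other].to_numpy().mean()

    def test_coexpression_correlation_near_target(self):
        coex, sets, _ = make_coexpression(n_samples=200, r=0.7, seed=8)
        vals = coex.values
        linc = vals.loc["LINC_PW00"]
        members = sorted(sets.genes("PW00"))
        rs = [np.corrcoef(linc, vals.loc[g])[0, 1] for g in members]
        assert np.mean(rs) == pytest.approx(0.7, abs=0.1)

    def test_survival_censoring_and_groups(self):
        records, truth = make_survival(n_patients=1000, hazard_ratio=2.0, seed=3)
        assert 0.3 <= records["event"].mean() <= 0.8
        high = [p for p, g in truth.hazard_group.items() if g == "high"]
        assert len(high) == pytest.approx(250, abs=2)
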