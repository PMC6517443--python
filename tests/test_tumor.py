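import warnings

import numpy as np
import pandas as pd
import pytest

from linchk.core import GeneAnnotation, GenomicInterval
from linchk.synth import make_tumour_tables
from linchk.tumors import (
    de_flags,
    focal_overlap,
    recurrent_deletion,
    refine_core_hk,
    simple_de,
)

from oracles import perbase_intersection


def de_rows(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tumour_type", "log2_fc", "q"])


class TestDeFlags:
    def test_fold_change_boundary_strict(self):
        flags = de_flags(de_rows([("G", "T1", -1.0, 0.01)]))
        assert not flags.loc["G", "down_any"]

    def test_down_when_past_both_thresholds(self):
        flags = de_flags(de_rows([("G", "T1", -1.1, 0.049)]))
        assert flags.loc["G", "down_any"] and flags.loc["G", "changed_any"]

    def test_q_boundary_strict(self):
        flags = de_flags(de_rows([("G", "T1", -3.0, 0.05)]))
        assert not flags.loc["G", "down_any"]

    def test_up_flag_symmetric(self):
        flags = de_flags(de_rows([("G", "T1", 1.2, 0.01), ("G", "T2", -0.2, 0.9)]))
        assert flags.loc["G", "up_any"] and not flags.loc["G", "down_any"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            de_flags(pd.DataFrame({"gene_id": ["G"], "log2_fc": [0.0]}))


class TestRecurrentDeletion:
    def table(self, n_homdel, n_total):
        cats = ["homdel"] * n_homdel + ["diploid"] * (n_total - n_homdel)
        return pd.DataFrame([cats], index=["G"], columns=[f"s{i}" for i in range(n_total)])

    def test_one_percent_boundary_inclusive(self):
        assert recurrent_deletion(self.table(10, 1000)).loc["G"]
        assert not recurrent_deletion(self.table(9, 1000)).loc["G"]

    def test_per_type_mode(self):
        # 2/100 homdel all in one type of 20 samples -> 10% there
        cats = ["homdel"] * 2 + ["diploid"] * 98
        table = pd.DataFrame([cats], index=["G"], columns=[f"s{i}" for i in range(100)])
        types = {f"s{i}": ("A" if i < 20 else "B") for i in range(100)}
        assert recurrent_deletion(table, min_fraction=0.05, per_type=types).loc["G"]
        assert not recurrent_deletion(table, min_fraction=0.05).loc["G"]


class TestFocalOverlap:
    def gene(self, start, end):
        return GeneAnnotation("G", "lincRNA", "+", [GenomicInterval("chr1", start, end, "+")])

    def test_abutting_region_is_no_hit(self):
        regions = [(GenomicInterval("chr1", 100, 200), "R", "del")]
        assert focal_overlap([self.gene(200, 300)], regions)["G"] == []

    def test_single_base_overlap_is_hit(self):
        regions = [(GenomicInterval("chr1", 100, 201), "R", "del")]
        assert focal_overlap([self.gene(200, 300)], regions)["G"] == ["R"]

    def test_amp_regions_ignored_for_deletion_calls(self):
        regions = [(GenomicInterval("chr1", 150, 250), "R", "amp")]
        assert focal_overlap([self.gene(200, 300)], regions)["G"] == []

    def test_matches_perbase_oracle(self, rng):
        for _ in range(30):
            x = rng.integers(0, 100, 2)
            y = rng.integers(0, 100, 2)
            g = self.gene(int(x.min()), int(x.max()) + 1)
            region = GenomicInterval("chr1", int(y.min()), int(y.max()) + 1)
            hit = bool(focal_overlap([g], [(region, "R", "del")])["G"])
            assert hit == (perbase_intersection([g.span], [region]) > 0)


class TestRefineCoreHk:
    def test_unflagged_gene_is_core(self):
        calls = refine_core_hk(
            ["G"],
            de_rows([("G", "T1", 0.0, 0.9)]),
            pd.DataFrame([["diploid"] * 10], index=["G"], columns=[f"s{i}" for i in range(10)]),
        )
        assert calls[0].core

    def test_single_tumour_type_down_breaks_core(self):
        rows = [("G", f"T{i}", 0.0, 0.9) for i in range(12)] + [("G", "T12", -2.0, 0.001)]
        calls = refine_core_hk(
            ["G"],
            de_rows(rows),
            pd.DataFrame([["diploid"] * 10], index=["G"], columns=[f"s{i}" for i in range(10)]),
        )
        assert not calls[0].core and calls[0].downregulated_any

    def test_adding_tumour_type_only_removes_genes(self):
        base = de_rows([("G", "T1", 0.0, 0.9)])
        extra = pd.concat([base, de_rows([("G", "T2", -1.5, 0.01)])])
        cna = pd.DataFrame([["diploid"] * 10], index=["G"], columns=[f"s{i}" for i in range(10)])
        core_before = {c.gene_id for c in refine_core_hk(["G"], base, cna) if c.core}
        core_after = {c.gene_id for c in refine_core_hk(["G"], extra, cna) if c.core}
        assert core_after <= core_before

    def test_planted_truth_recovery(self):
        genes = [f"G{i:03d}" for i in range(100)]
        de, cna, focal, truth = make_tumour_tables(genes, seed=3)
        calls = refine_core_hk(genes, de, cna)
        clean = {
            g for g, ev in truth.tumour_events.items() if not (ev["down"] or ev["deleted"])
        }
        core = {c.gene_id for c in calls if c.core}
        assert len(core & clean) / len(core) >= 0.95  # precision
        assert len(core & clean) / len(clean) >= 0.95  # recall


class TestSimpleDe:
    def test_null_false_positive_rate_controlled(self, rng):
        n_genes, n = 300, 6
        data = pd.DataFrame(
            rng.lognormal(1.0, 0.5, (n_genes, n)),
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n)],
        )
        labels = {f"s{i}": ("a" if i < 3 else "b") for i in range(n)}
        table = simple_de(data, labels)
        assert table["significant"].sum() <= 0.05 * n_genes

    def test_planted_fold_change_flagged(self, rng):
        base = rng.lognormal(2.0, 0.05, (1, 6))
        base[0, 3:] *= 4.0
        data = pd.DataFrame(base, index=["G"], columns=[f"s{i}" for i in range(6)])
        labels = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        table = simple_de(data, labels)
        assert bool(table.loc["G", "significant"])
        assert table.loc["G", "log2_fc"] == pytest.approx(2.0, abs=0.1)

    def test_constant_gene_excluded_with_warning(self):
        data = pd.DataFrame(
            [[2.0] * 6, [1, 2, 3, 4, 5, 6]], index=["const", "ok"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            table = simple_de(data, labels)
        assert "const" not in table.index and "ok" in table.index
        assert any("constant" in str(x.message) for x in w)

    def test_group_requirements(self):
        data = pd.DataFrame([[1, 2, 3]], index=["G"], columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError):
            simple_de(data, {"s0": "a", "s1": "a", "s2": "b"})
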