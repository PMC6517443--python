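"""End-to-end orchestration of the annotation pipeline.

Stages run in a fixed order: classify -> features -> structure ->
refine -> methylation -> function -> survival. Each stage writes a TSV
under the output directory and contributes funnel counts to a JSON
summary; every threshold used is logged, and a rerun with the same
config is bit-identical.

The demo mode generates all inputs synthetically (with planted ground
truth) and scores each stage against the truth, which is how the
pipeline is exercised without external cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import gsea as _gsea
from . import io as _io
from . import methylation as _meth
from . import structure as _struct
from . import survival as _surv
from . import synth as _synth
from . import tumors as _tum

log = logging.getLogger("linchk")


@dataclass
class PipelineConfig:
    """All sizes, thresholds and paths for one pipeline run.

    Threshold defaults equal the decision rules the pipeline is built
    around, so a bare run applies them unchanged.
    """

    seed: int = 7
    outdir: str = "linchk_out"
    # synthetic sizes
    n_hk: int = 50
    n_ts: int = 50
    n_bg: int = 100
    n_tissues: int = 16
    n_tumour_types: int = 13
    n_tumour_samples: int = 500
    n_meth_samples: int = 40
    n_coexpr_samples: int = 60
    n_pathways: int = 6
    pathway_size: int = 30
    n_patients: int = 400
    hazard_ratio: float = 2.0
    frac_down: float = 0.25
    frac_deleted: float = 0.15
    # stage thresholds
    detect_threshold: float = 0.5
    hk_min_fraction: float = 0.75
    hk_max_cv: float = 1.5
    ts_max_fraction: float = 0.25
    ts_min_cv: float = 3.5
    min_coding_distance: int = 1000
    n_shuffles: int = 200
    structure_fdr: float = 0.05
    fc_min: float = 2.0
    q_max: float = 0.05
    deletion_min_fraction: float = 0.01
    n_perm: int = 300
    gsea_fdr: float = 0.05
    min_lincRNA_fraction: float = 0.10
    cut_height: float = 0.85
    survival_quantile: float = 0.75

    def __post_init__(self) -> None:
        params = self.class_params()  # validates threshold bounds
        if self.n_shuffles < 19:
            raise ValueError("n_shuffles must be >= 19")
        if not (0 < self.survival_quantile < 1):
            raise ValueError("survival_quantile must be in (0, 1)")
        del params

    def class_params(self) -> _classify.HKClassParams:
        return _classify.HKClassParams(
            detect_threshold=self.detect_threshold,
            hk_min_fraction=self.hk_min_fraction,
            hk_max_cv=self.hk_max_cv,
            ts_max_fraction=self.ts_max_fraction,
            ts_min_cv=self.ts_min_cv,
            min_coding_distance=self.min_coding_distance,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate synthetic inputs, run all stages, score against truth.

    Returns the summary dict (also written to ``outdir/summary.json``)
    with a stage funnel, per-stage headline statistics and the planted
    clean-HK recall of the full filter cascade.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    log.info("run_pipeline seed=%d outdir=%s", seed, out)
    log.info("thresholds: %s", json.dumps(dataclasses.asdict(config), sort_keys=True))

    # ----- inputs with planted truth
    matrix, truth = _synth.make_tissue_matrix(
        config.n_hk, config.n_ts, config.n_bg, config.n_tissues, seed=seed
    )
    # order background genes first so the planted-proximal slots (first
    # 5% of the list) never consume a planted HK/TS gene
    linc_order = sorted(matrix.gene_ids, key=lambda g: (not g.startswith("BG"), g))
    lincs, coding, proximal = _synth.make_gene_models(
        linc_order, n_coding=20, frac_proximal=0.05, seed=seed
    )
    _io.write_matrix(matrix, out / "matrix.tsv")
    _io.write_gtf(lincs + coding, out / "genes.gtf")

    # ----- stage 1: classification
    params = config.class_params()
    calls = _classify.classify_lincRNAs(matrix, lincs, params, coding)
    cls_df = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "n_detected": c.profile.n_detected if c.profile else -1,
                "cv": c.profile.cv if c.profile else float("nan"),
                "label": c.label,
            }
            for c in calls
        ]
    ).set_index("gene_id")
    cls_df.to_csv(out / "classification.tsv", sep="\t")
    chk = [c.gene_id for c in calls if c.label == "HK"]
    ts = [c.gene_id for c in calls if c.label == "TS"]
    log.info("stage classify: %d cHK, %d TS", len(chk), len(ts))

    # ----- stage 2: features (synthetic tracks over the gene models)
    rng = np.random.default_rng(seed)
    anno_of = {g.gene_id: g for g in lincs}
    scores: dict[tuple[str, int], float] = {}
    snps: list[tuple[str, int]] = []
    repeats = []
    for g in lincs:
        for iv in g.exons:
            for pos in range(iv.start, iv.end, 3):  # sparse track
                scores[(iv.chrom, pos)] = float(rng.normal(0.1, 0.3))
            n_snp = rng.poisson(len(iv) * 0.02)
            snps.extend((iv.chrom, int(p)) for p in rng.integers(iv.start, iv.end, n_snp))
            if rng.random() < 0.3:
                mid = (iv.start + iv.end) // 2
                repeats.append(
                    (_io.GenomicInterval(iv.chrom, iv.start, mid), "SINE/Alu")
                )
    from .features import summarize_features

    feats = [
        summarize_features(anno_of[g], scores, snps, repeats) for g in chk + ts
    ]
    pd.DataFrame(
        [
            {
                "gene_id": f.gene_id,
                "mean_conservation": f.mean_conservation,
                "snp_density": f.snp_density,
                "alu_coverage": f.repeat_coverage.get("SINE/Alu", 0.0),
                "exonic_length": f.exonic_length,
            }
            for f in feats
        ]
    ).set_index("gene_id").to_csv(out / "features.tsv", sep="\t")
    log.info("stage features: %d genes summarised", len(feats))

    # ----- stage 3: structure permutation test over cHK sequences
    n_struct = max(len(chk) // 2, 1)
    seqs, seq_truth = _synth.make_sequences(
        n_struct, max(len(chk) - n_struct, 1), seed=seed
    )
    truth.update(seq_truth)
    struct_res = _struct.structure_test(
        seqs, n_shuffles=config.n_shuffles, seed=seed
    )
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "score": r.observed_score,
                "p": r.p_value,
                "q": r.q_value,
                "n_shuffles": r.n_shuffles,
            }
            for r in struct_res
        ]
    ).set_index("gene_id").to_csv(out / "structure.tsv", sep="\t")
    n_sig_struct = sum(r.q_value < config.structure_fdr for r in struct_res)
    log.info("stage structure: %d/%d significant at FDR<%.2f",
             n_sig_struct, len(struct_res), config.structure_fdr)

    # ----- stage 4: tumour refinement of the cHK set
    de_table, cna_table, focal, tum_truth = _synth.make_tumour_tables(
        chk,
        n_tumour_types=config.n_tumour_types,
        frac_down=config.frac_down,
        frac_deleted=config.frac_deleted,
        n_samples=config.n_tumour_samples,
        seed=seed,
        annotations=[anno_of[g] for g in chk],
    )
    truth.update(tum_truth)
    de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    cna_table.to_csv(out / "cna_table.tsv", sep="\t")
    core_calls = _tum.refine_core_hk(
        chk,
        de_table,
        cna_table,
        gene_annotations=[anno_of[g] for g in chk],
        focal_regions=focal,
        fc_min=config.fc_min,
        q_max=config.q_max,
        deletion_min_fraction=config.deletion_min_fraction,
    )
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "downregulated_any": c.downregulated_any,
                "deleted_recurrent": c.deleted_recurrent,
                "in_focal_deletion": c.in_focal_deletion,
                "core": c.core,
            }
            for c in core_calls
        ]
    ).set_index("gene_id").to_csv(out / "core_hk.tsv", sep="\t")
    core = [c.gene_id for c in core_calls if c.core]
    log.info("stage refine: %d/%d cHK are core", len(core), len(chk))

    # ----- stage 5: methylation comparison (HK vs TS promoters)
    meth_genes = [anno_of[g] for g in chk + ts]
    probe_betas, probe_coords, _ = _synth.make_methylation(
        meth_genes, set(chk), n_samples=config.n_meth_samples, seed=seed
    )
    gene_beta, n_probes = _meth.gene_level_beta(probe_betas, probe_coords, meth_genes)
    med_hk, med_ts, paired, unpaired = _meth.group_median_comparison(
        gene_beta, chk, ts
    )
    pd.DataFrame({"median_beta_HK": med_hk, "median_beta_TS": med_ts}).to_csv(
        out / "methylation.tsv", sep="\t", index_label="sample"
    )
    log.info("stage methylation: paired p=%.3g", paired.p_value)

    # ----- stage 6: function prediction for a few lincRNAs
    pathways = {f"PW{i:02d}": config.pathway_size for i in range(config.n_pathways)}
    coex, gene_sets, coex_truth = _synth.make_coexpression(
        n_samples=config.n_coexpr_samples, pathways=pathways, seed=seed
    )
    truth.update(coex_truth)
    coding_genes = [g for g in coex.gene_ids if not g.startswith("LINC_")]
    results_by_linc: dict[str, list] = {}
    for name in list(pathways)[:3]:
        linc = f"LINC_{name}"
        ranked = _gsea.correlation_rank(coex, linc, coding_genes)
        results_by_linc[linc] = _gsea.gsea_preranked(
            ranked, gene_sets, n_perm=config.n_perm, min_set=10, seed=seed
        )
    func_rows = [
        {"lincRNA": linc, "term": r.term, "es": r.es, "nes": r.nes,
         "p": r.p_value, "fdr": r.fdr_q, "direction": r.direction}
        for linc, rs in results_by_linc.items()
        for r in rs
    ]
    pd.DataFrame(func_rows).to_csv(out / "function.tsv", sep="\t", index=False)
    planted_hits = sum(
        any(r.term == truth.pathway_of_gene[linc] and r.fdr_q < config.gsea_fdr for r in rs)
        for linc, rs in results_by_linc.items()
    )
    term_matrix = _gsea.term_matrix_filter(
        results_by_linc, fdr_max=config.gsea_fdr,
        min_lincRNA_fraction=config.min_lincRNA_fraction,
    )
    term_matrix.to_csv(out / "term_matrix.tsv", sep="\t")
    log.info("stage function: planted term recovered for %d/%d lincRNAs",
             planted_hits, len(results_by_linc))

    # ----- stage 7: survival
    surv, surv_truth = _synth.make_survival(
        n_patients=config.n_patients, hazard_ratio=config.hazard_ratio, seed=seed
    )
    truth.update(surv_truth)
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    groups, curves, lr = _surv.survival_analysis(surv, q=config.survival_quantile)
    km_rows = []
    for gname, km in curves.items():
        for t, s in zip(km.times, km.survival):
            km_rows.append({"group": gname, "time": t, "survival": s})
    pd.DataFrame(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
    log.info("stage survival: log-rank p=%.3g", lr.p_value)

    # ----- funnel + truth scoring
    clean_hk = {
        g
        for g, cls in truth.gene_class.items()
        if cls == "HK"
        and not truth.tumour_events.get(g, {}).get("down", False)
        and not truth.tumour_events.get(g, {}).get("deleted", False)
    }
    recall = (
        len(clean_hk & set(core)) / len(clean_hk) if clean_hk else float("nan")
    )
    summary = {
        "seed": seed,
        "funnel": {
            "lincRNAs_input": len(lincs),
            "retained_after_proximity": len(lincs)
            - sum(c.label == "excluded_proximal" for c in calls),
            "candidate_HK": len(chk),
            "tissue_specific": len(ts),
            "core_HK": len(core),
        },
        "structure_significant": int(n_sig_struct),
        "structure_tested": len(struct_res),
        "methylation_paired_p": paired.p_value,
        "function_planted_term_recovered": int(planted_hits),
        "function_lincRNAs_tested": len(results_by_linc),
        "function_terms_kept": int(term_matrix.shape[0]),
        "survival_logrank_p": lr.p_value,
        "clean_hk_funnel_recall": recall,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True)
    return summary


def run_demo(seed: int = 7, outdir: str = "linchk_demo") -> dict:
    """One-command synthetic end-to-end run."""
    return run_pipeline(PipelineConfig(seed=seed, outdir=outdir))
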