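"""Stage 4: refine candidate housekeeping genes against tumour evidence.

A candidate survives as a 'core' housekeeping gene only if it is
(1) not significantly downregulated in any tumour type (|FC| > 2,
q < 0.05, both strict), (2) not recurrently homozygously deleted
(>= 1% of samples, inclusive), and (3) not inside any focal deletion
region. The rationale: loss of a gene that is genuinely required for
growth and viability should be selected against in tumours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneAnnotation, GenomicInterval, bh_fdr


@dataclass
class CoreHKCall:
    gene_id: str
    downregulated_any: bool
    deleted_recurrent: bool
    in_focal_deletion: bool

    @property
    def core(self) -> bool:
        return not (
            self.downregulated_any or self.deleted_recurrent or self.in_focal_deletion
        )


def de_flags(
    de_table: pd.DataFrame, fc_min: float = 2.0, q_max: float = 0.05
) -> pd.DataFrame:
    """Per-gene up/down/changed flags over all tumour types.

    down_any iff some tumour type has log2_fc < -log2(fc_min) AND
    q < q_max (both strict); up_any analogously with log2_fc > log2(fc_min).
    """
    need = ["gene_id", "tumour_type", "log2_fc", "q"]
    missing = [c for c in need if c not in de_table.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    thr = math.log2(fc_min)
    sig = de_table["q"].astype(float) < q_max
    lfc = de_table["log2_fc"].astype(float)
    df = pd.DataFrame(
        {
            "gene_id": de_table["gene_id"],
            "down": sig & (lfc < -thr),
            "up": sig & (lfc > thr),
        }
    )
    agg = df.groupby("gene_id").agg(down_any=("down", "any"), up_any=("up", "any"))
    agg["changed_any"] = agg["down_any"] | agg["up_any"]
    return agg


def recurrent_deletion(
    cna_table: pd.DataFrame, min_fraction: float = 0.01, per_type: dict | None = None
) -> pd.Series:
    """True where homozygous deletions occur in >= min_fraction of samples.

    Default pools all samples across tumour types; pass ``per_type``
    (sample -> tumour type) to require the fraction within any single
    type instead.
    """
    is_homdel = cna_table == "homdel"
    if per_type is None:
        frac = is_homdel.mean(axis=1)
        return frac >= min_fraction
    groups = pd.Series({s: per_type[s] for s in cna_table.columns})
    per = is_homdel.T.groupby(groups).mean().T
    return (per >= min_fraction).any(axis=1)


def focal_overlap(
    genes: list[GeneAnnotation],
    focal_regions: list[tuple[GenomicInterval, str, str]],
    region_type: str = "del",
) -> dict[str, list[str]]:
    """Region ids of the given type overlapping each gene span by >= 1 bp."""
    out: dict[str, list[str]] = {}
    for g in genes:
        sp = g.span
        hits = [
            rid
            for iv, rid, rtype in focal_regions
            if rtype == region_type and sp.overlaps(iv)
        ]
        out[g.gene_id] = hits
    return out


def refine_core_hk(
    chk_genes: list[str],
    de_table: pd.DataFrame,
    cna_table: pd.DataFrame,
    gene_annotations: list[GeneAnnotation] | None = None,
    focal_regions: list[tuple[GenomicInterval, str, str]] | None = None,
    fc_min: float = 2.0,
    q_max: float = 0.05,
    deletion_min_fraction: float = 0.01,
    missing_evidence: str = "pass",
) -> list[CoreHKCall]:
    """Apply the three tumour filters to candidate HK genes.

    ``missing_evidence``: 'pass' treats a gene absent from an evidence
    table as unflagged by that filter; 'exclude' drops it from the
    output entirely.
    """
    if missing_evidence not in ("pass", "exclude"):
        raise ValueError("missing_evidence must be 'pass' or 'exclude'")
    flags = de_flags(de_table, fc_min=fc_min, q_max=q_max)
    deleted = recurrent_deletion(cna_table, min_fraction=deletion_min_fraction)
    focal: dict[str, list[str]] = {}
    if gene_annotations is not None and focal_regions is not None:
        focal = focal_overlap(gene_annotations, focal_regions, region_type="del")

    out = []
    for gene in chk_genes:
        have_de = gene in flags.index
        have_cna = gene in deleted.index
        if missing_evidence == "exclude" and not (have_de and have_cna):
            continue
        out.append(
            CoreHKCall(
                gene_id=gene,
                downregulated_any=bool(flags.loc[gene, "down_any"]) if have_de else False,
                deleted_recurrent=bool(deleted.loc[gene]) if have_cna else False,
                in_focal_deletion=bool(focal.get(gene, [])),
            )
        )
    return out


def simple_de(
    matrix: pd.DataFrame,
    group_labels: dict[str, str],
    fc_min: float = 1.5,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression stand-in on FPKM-like values.

    Per gene: Welch t-test on log2(x+1), BH-corrected; fold change from
    linear group means. This is a deliberately simple test for
    abundance-scale synthetic data, not a count model; externally
    computed DE tables can be supplied anywhere one is consumed.
    Constant genes (no within-group variance anywhere) are excluded
    with a warning. Returns gene_id, log2_fc, p, q, significant.
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a_cols = [s for s in matrix.columns if group_labels[s] == groups[0]]
    b_cols = [s for s in matrix.columns if group_labels[s] == groups[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    la = np.log2(matrix[a_cols].to_numpy(dtype=float) + 1.0)
    lb = np.log2(matrix[b_cols].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(lb, la, axis=1, equal_var=False)
    keep = ~np.isnan(p)
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} constant gene(s) excluded from DE")
    genes = matrix.index.to_numpy()[keep]
    p = p[keep]
    mean_a = matrix.loc[genes, a_cols].mean(axis=1).to_numpy()
    mean_b = matrix.loc[genes, b_cols].mean(axis=1).to_numpy()
    eps = 1e-9
    log2_fc = np.log2((mean_b + eps) / (mean_a + eps))
    q = bh_fdr(p)
    sig = (np.abs(log2_fc) > math.log2(fc_min)) & (q < q_max)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "significant": sig,
        }
    ).set_index("gene_id")
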