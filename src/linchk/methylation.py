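"""Stage 5: promoter methylation aggregation and group comparison.

Array probes are collapsed to gene-level beta values by averaging all
probes falling in the promoter window (-2000 bp to +200 bp around the
strand-aware TSS). Gene groups (e.g. housekeeping vs tissue-specific)
are then compared by their per-sample median betas.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats as sps

from .core import GeneAnnotation, GenomicInterval, StatTestResult, wilcoxon_rank_sum


def promoter_window(
    gene: GeneAnnotation, upstream: int = 2000, downstream: int = 200,
    strand_aware: bool = True,
) -> GenomicInterval:
    """Promoter + gene-body-start window around the TSS, clipped at 0.

    '+' strand: [tss - upstream, tss + downstream); '-' strand the
    window is reflected through the TSS: [tss - downstream,
    tss + upstream). With ``strand_aware=False`` every gene is treated
    as '+'.
    """
    tss = gene.tss
    if strand_aware and gene.strand == "-":
        lo, hi = tss - downstream, tss + upstream
    else:
        lo, hi = tss - upstream, tss + downstream
    return GenomicInterval(gene.chrom, max(lo, 0), hi)


def gene_level_beta(
    probe_betas: pd.DataFrame,
    probe_coords: dict[str, tuple[str, int]],
    genes: list[GeneAnnotation],
    strand_aware: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean promoter-probe beta per gene per sample.

    ``probe_coords``: probe id -> (chrom, pos0); a probe contributes to
    a gene iff its position lies inside the half-open promoter window.
    Genes with zero probes are absent from the output (not zero-filled).
    Returns (gene x sample table, per-gene probe counts).
    """
    arr = probe_betas.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("beta values outside [0, 1]")
    rows = {}
    counts = {}
    for gene in genes:
        win = promoter_window(gene, strand_aware=strand_aware)
        probes = [
            pid
            for pid, (chrom, pos) in probe_coords.items()
            if chrom == win.chrom and win.start <= pos < win.end and pid in probe_betas.index
        ]
        if not probes:
            continue
        rows[gene.gene_id] = probe_betas.loc[probes].mean(axis=0)
        counts[gene.gene_id] = len(probes)
    if not rows:
        empty = pd.DataFrame(columns=probe_betas.columns)
        return empty, pd.Series(counts, name="n_probes", dtype=int)
    table = pd.DataFrame(rows).T
    table.columns = probe_betas.columns
    return table, pd.Series(counts, name="n_probes", dtype=int)


def group_median_comparison(
    table: pd.DataFrame, group_a_genes: list[str], group_b_genes: list[str]
) -> tuple[pd.Series, pd.Series, StatTestResult, StatTestResult]:
    """Per-sample median beta of each gene group, with a paired test.

    The same samples index both group medians, so the primary test is a
    paired two-sided Wilcoxon signed-rank across samples; an unpaired
    rank-sum is reported as secondary. Returns (medians_a, medians_b,
    paired_result, unpaired_result).
    """
    a = [g for g in group_a_genes if g in table.index]
    b = [g for g in group_b_genes if g in table.index]
    if not a or not b:
        raise ValueError("both gene groups must be represented in the table")
    med_a = table.loc[a].median(axis=0)
    med_b = table.loc[b].median(axis=0)
    diffs = (med_a - med_b).to_numpy(dtype=float)
    if (diffs == 0).all():
        paired = StatTestResult(0.0, 1.0, "wilcoxon-signed-rank")
    else:
        res = sps.wilcoxon(med_a, med_b, alternative="two-sided", zero_method="wilcox")
        paired = StatTestResult(float(res.statistic), float(res.pvalue), "wilcoxon-signed-rank")
    unpaired = wilcoxon_rank_sum(med_a, med_b)
    return med_a, med_b, paired, unpaired
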