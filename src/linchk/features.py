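"""Stage 2: exon-restricted sequence feature summaries.

Per-gene aggregation of per-base conservation scores, SNP density and
repeat-class coverage over the exon union, plus cross-species
orthologue calls from precomputed alignment hit tables (BLAST
outfmt-6-like; the alignment itself is upstream of this package).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    coefficient_of_variation,
    intersect_length,
    merge_intervals,
)


@dataclass
class FeatureSummary:
    gene_id: str
    mean_conservation: float
    snp_density: float  # SNPs per kb of exon
    repeat_coverage: dict[str, float]
    exonic_length: int


@dataclass
class OrthologueCall:
    query_gene: str
    species: str
    best_identity_pct: float
    is_orthologue: bool
    expressed_tissues: int
    cv_in_species: float


def exon_union(gene: GeneAnnotation) -> list[GenomicInterval]:
    """Deduplicated exon intervals (overlaps across transcripts merged)."""
    return merge_intervals(gene.exons)


def mean_exonic_conservation(
    gene: GeneAnnotation, scores: dict[tuple[str, int], float]
) -> float:
    """Mean per-base score over exonic positions that have a score.

    Bases without a score are skipped (tracks are sparse over masked
    repeats), never zero-filled. NaN with a warning if no exonic base
    is scored.
    """
    total = 0.0
    n = 0
    for iv in exon_union(gene):
        for pos in range(iv.start, iv.end):
            s = scores.get((iv.chrom, pos))
            if s is not None:
                total += s
                n += 1
    if n == 0:
        warnings.warn(f"gene {gene.gene_id}: no scored exonic bases")
        return math.nan
    return total / n


def snp_density(gene: GeneAnnotation, snp_positions) -> float:
    """SNPs per kb of exon: 1000 x (#SNPs in exon union) / exonic length.

    ``snp_positions``: iterable of (chrom, pos0) or of BED3 intervals
    (point positions taken as interval starts).
    """
    union = exon_union(gene)
    length = sum(len(iv) for iv in union)
    pts = []
    for item in snp_positions:
        if isinstance(item, GenomicInterval):
            pts.append((item.chrom, item.start))
        else:
            pts.append((item[0], int(item[1])))
    count = 0
    for chrom, pos in pts:
        for iv in union:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                count += 1
                break
    return 1000.0 * count / length


def repeat_coverage(
    gene: GeneAnnotation, repeats: list[tuple[GenomicInterval, str]]
) -> dict[str, float]:
    """Per-class fraction of the exon union covered by repeat elements.

    Intervals of a class are merged before intersecting, so overlapping
    annotations within a class are not double counted.
    """
    union = exon_union(gene)
    length = sum(len(iv) for iv in union)
    by_class: dict[str, list[GenomicInterval]] = {}
    for iv, cls in repeats:
        by_class.setdefault(cls, []).append(iv)
    return {
        cls: intersect_length(union, ivs) / length for cls, ivs in by_class.items()
    }


def summarize_features(
    gene: GeneAnnotation,
    scores: dict[tuple[str, int], float],
    snp_positions,
    repeats: list[tuple[GenomicInterval, str]],
) -> FeatureSummary:
    return FeatureSummary(
        gene.gene_id,
        mean_exonic_conservation(gene, scores),
        snp_density(gene, snp_positions),
        repeat_coverage(gene, repeats),
        sum(len(iv) for iv in exon_union(gene)),
    )


def summarize_orthologues(
    hit_table: pd.DataFrame,
    expression_by_species: dict[str, ExpressionMatrix] | None = None,
    identity_min: float = 30.0,
    detect_threshold: float = 0.5,
) -> list[OrthologueCall]:
    """Best-hit orthologue calls per (query, species) at >= identity_min.

    ``hit_table`` needs columns query, species, subject, identity_pct
    (outfmt-6-like layout). The identity cutoff is inclusive ("at
    least"). When species expression matrices are given, the subject
    gene's tissue CV and detected-tissue count are attached.
    """
    need = ["query", "species", "subject", "identity_pct"]
    missing = [c for c in need if c not in hit_table.columns]
    if missing:
        raise ValueError(f"hit table missing columns {missing}")
    ident = hit_table["identity_pct"].astype(float)
    if ((ident < 0) | (ident > 100)).any():
        raise ValueError("identity_pct outside [0, 100]")

    out = []
    for (query, species), grp in hit_table.groupby(["query", "species"], sort=True):
        best = grp.loc[grp["identity_pct"].astype(float).idxmax()]
        identity = float(best["identity_pct"])
        called = identity >= identity_min
        expressed, cv = 0, math.nan
        if called and expression_by_species and species in expression_by_species:
            mat = expression_by_species[species]
            subject = str(best["subject"])
            if subject in mat.values.index:
                tm = mat.tissue_means().loc[subject].to_numpy(dtype=float)
                expressed = int((tm > detect_threshold).sum())
                cv = coefficient_of_variation(tm)
        out.append(OrthologueCall(str(query), str(species), identity, called, expressed, cv))
    return out
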