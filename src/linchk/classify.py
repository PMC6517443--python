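"""Stage 1: housekeeping vs tissue-specific classification.

Genes are labelled from a multi-tissue expression matrix:

* HK (housekeeping candidate): detected (tissue mean > 0.5 FPKM, strict)
  in >= 75% of tissues AND coefficient of variation across tissue means
  < 1.5;
* TS (tissue-specific): detected in < 25% of tissues (strict) AND
  CV > 3.5 (strict);
* neither, otherwise.

lincRNAs closer than a minimum gap (default 1 kb, strict >) to any
protein-coding gene on the same chromosome are excluded up front, since
expression attribution near coding loci is unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DetectionProfile, ExpressionMatrix, GeneAnnotation


@dataclass
class HKClassParams:
    detect_threshold: float = 0.5  # FPKM; detected iff tissue mean strictly above
    hk_min_fraction: float = 0.75  # inclusive
    hk_max_cv: float = 1.5  # strict <
    ts_max_fraction: float = 0.25  # strict <
    ts_min_cv: float = 3.5  # strict >
    min_coding_distance: int = 1000  # bp, retained iff gap strictly greater
    log_scale_cv: bool = False  # compute CV on log2(x+1) tissue means

    def __post_init__(self) -> None:
        if not (0 < self.ts_max_fraction < self.hk_min_fraction <= 1):
            raise ValueError("need 0 < ts_max_fraction < hk_min_fraction <= 1")
        if not (self.hk_max_cv < self.ts_min_cv):
            raise ValueError("need hk_max_cv < ts_min_cv")


@dataclass
class HKClassification:
    gene_id: str
    profile: DetectionProfile | None
    label: str  # HK | TS | neither | excluded_proximal


def detection_profile(
    matrix: ExpressionMatrix, gene: str, params: HKClassParams | None = None
) -> DetectionProfile:
    """Tissue-level detection summary for one gene.

    Samples are first collapsed to per-tissue means; a tissue counts as
    detected iff its mean is strictly above the detection threshold. The
    CV is the sample CV over ALL tissue means (zeros included).
    """
    params = params or HKClassParams()
    if gene not in matrix.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    tm = matrix.tissue_means().loc[gene].to_numpy(dtype=float)
    return _profile_from_tissue_means(gene, tm, params)


def _profile_from_tissue_means(
    gene: str, tm: np.ndarray, params: HKClassParams
) -> DetectionProfile:
    n_detected = int((tm > params.detect_threshold).sum())
    vals = np.log2(tm + 1.0) if params.log_scale_cv else tm
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else math.nan
    return DetectionProfile(gene, tm.size, n_detected, mean, sd)


def exclude_proximal_lincRNAs(
    lincRNAs: list[GeneAnnotation],
    coding_genes: list[GeneAnnotation],
    min_distance: int = 1000,
) -> list[GeneAnnotation]:
    """Retain lincRNAs whose gap to the nearest coding gene span is > min_distance.

    The gap is between gene spans (min exon start to max exon end),
    strand-agnostic; overlap means gap 0. lincRNAs on chromosomes with
    no coding gene are retained.
    """
    coding_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in coding_genes:
        sp = g.span
        coding_by_chrom.setdefault(sp.chrom, []).append((sp.start, sp.end))
    retained = []
    for linc in lincRNAs:
        sp = linc.span
        spans = coding_by_chrom.get(sp.chrom)
        if not spans:
            retained.append(linc)
            continue
        gap = min(
            max(s - sp.end, sp.start - e, 0) for s, e in spans
        )
        if gap > min_distance:
            retained.append(linc)
    return retained


def _label(profile: DetectionProfile, params: HKClassParams) -> str:
    cv = profile.cv
    frac = profile.detection_fraction
    if frac >= params.hk_min_fraction and not math.isnan(cv) and cv < params.hk_max_cv:
        return "HK"
    if frac < params.ts_max_fraction and not math.isnan(cv) and cv > params.ts_min_cv:
        return "TS"
    return "neither"


def classify_lincRNAs(
    matrix: ExpressionMatrix,
    annotations: list[GeneAnnotation] | None = None,
    params: HKClassParams | None = None,
    coding_genes: list[GeneAnnotation] | None = None,
) -> list[HKClassification]:
    """Classify every gene in the matrix as HK / TS / neither.

    When annotations (lincRNAs) and coding_genes are supplied, the
    proximity prefilter runs first and excluded genes are reported with
    label ``excluded_proximal``. Genes present in the matrix without an
    annotation are classified on expression alone.
    """
    params = params or HKClassParams()
    if len(matrix.tissues) < 2:
        raise ValueError("need at least 2 tissues to classify")
    excluded: set[str] = set()
    if annotations is not None and coding_genes is not None:
        kept = {
            g.gene_id
            for g in exclude_proximal_lincRNAs(
                annotations, coding_genes, params.min_coding_distance
            )
        }
        excluded = {g.gene_id for g in annotations} - kept

    tms = matrix.tissue_means()
    out: list[HKClassification] = []
    for gene in matrix.gene_ids:
        if gene in excluded:
            out.append(HKClassification(gene, None, "excluded_proximal"))
            continue
        prof = _profile_from_tissue_means(
            gene, tms.loc[gene].to_numpy(dtype=float), params
        )
        out.append(HKClassification(gene, prof, _label(prof, params)))
    return out
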