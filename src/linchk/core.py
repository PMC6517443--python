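"""Shared domain types, interval arithmetic and generic statistics.

Everything downstream (classification, feature aggregation, the filter
cascade) is built on the small vocabulary defined here: half-open genomic
intervals, gene models with exon lists, a genes x samples expression
matrix with tissue labels, and a handful of statistics (coefficient of
variation, Benjamini-Hochberg FDR, rank-sum test) used across stages.

Coordinates are 0-based half-open everywhere inside the package; 1-based
inputs (GTF) are converted at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneAnnotation:
    """Gene model: biotype, strand and an ordered, disjoint exon list.

    ``tss`` is the strand-aware 5' end: first exon start on '+', last
    exon end on '-' (for '.' the leftmost coordinate is used).
    """

    gene_id: str
    biotype: str  # protein_coding | lincRNA | other
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"gene {self.gene_id} spans chromosomes {chroms}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id} has overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        if self.strand == "-":
            return self.exons[-1].end
        return self.exons[0].start

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


class ExpressionMatrix:
    """Genes x samples matrix of nonnegative abundances with tissue labels."""

    def __init__(self, values: pd.DataFrame, tissue_of_sample: Mapping[str, str]):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("NA values in expression matrix")
        if (arr < 0).any():
            raise ValueError("negative expression values")
        missing = [s for s in values.columns if s not in tissue_of_sample]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")
        self.values = values.astype(float)
        self.tissue_of_sample = {s: tissue_of_sample[s] for s in values.columns}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.tissue_of_sample[s], None)
        return list(seen)

    def tissue_means(self) -> pd.DataFrame:
        """Collapse samples to per-tissue means (genes x tissues)."""
        groups = pd.Series(
            [self.tissue_of_sample[s] for s in self.values.columns],
            index=self.values.columns,
        )
        out = self.values.T.groupby(groups).mean().T
        return out[self.tissues]  # keep first-appearance tissue order


@dataclass
class DetectionProfile:
    """Per-gene tissue detection summary and coefficient of variation."""

    gene_id: str
    n_tissues: int
    n_detected: int
    mean_expr: float
    sd_expr: float

    @property
    def detection_fraction(self) -> float:
        return self.n_detected / self.n_tissues

    @property
    def cv(self) -> float:
        """Sample CV; NaN when the mean is zero (undefined)."""
        if self.mean_expr <= 0:
            return math.nan
        return self.sd_expr / self.mean_expr


@dataclass
class StatTestResult:
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# statistics


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV: sd(ddof=1) / mean.

    Returns NaN (undefined) when the mean is zero or fewer than two
    values are given. Negative inputs are rejected: CV is only meaningful
    for nonnegative abundance-like data.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if (x < 0).any():
        raise ValueError("negative values")
    if x.size < 2:
        return math.nan
    m = x.mean()
    if m == 0:
        return math.nan
    return float(x.std(ddof=1) / m)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/abutting intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: i.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_length(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Total bases covered by both interval sets (each base once).

    Half-open semantics: abutting intervals share no base.
    """
    ma = merge_intervals(a)
    mb = merge_intervals(b)
    total = 0
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in mb:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for iv in ma:
        for jv in by_chrom_b.get(iv.chrom, ()):
            lo = max(iv.start, jv.start)
            hi = min(iv.end, jv.end)
            if hi > lo:
                total += hi - lo
    return total


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> StatTestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact enumeration for small tie-free samples, normal approximation
    with midrank tie correction otherwise (scipy's 'auto' policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return StatTestResult(float(res.statistic), float(min(res.pvalue, 1.0)), "wilcoxon-rank-sum")
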