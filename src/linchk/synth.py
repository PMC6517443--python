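"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its seed and emulates the
statistical structure of the cohorts the pipeline is designed for:

* multi-tissue abundance matrices with planted ubiquitous (HK),
  tissue-restricted (TS) and background genes (lognormal expression);
* transcript sequences with planted inverted-repeat stems vs
  dinucleotide-Markov random sequences;
* tumour differential-expression / copy-number / focal-region tables
  with planted down-regulation and deletion events;
* promoter methylation betas (Beta-distributed, HK promoters shifted
  low);
* pathway-driven co-expression from shared latent Gaussian factors;
* survival records with expression-dependent exponential hazards.

Noise families (lognormal expression, Beta methylation, exponential
survival, Gaussian latent factors) are chosen for support correctness;
abundances are FPKM-like, not count-derived.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneAnnotation, GenomicInterval
from .io import GeneSetCollection

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Planted ground truth; sufficient to score every downstream stage."""

    gene_class: dict[str, str] = field(default_factory=dict)  # HK | TS | background
    pathway_of_gene: dict[str, str] = field(default_factory=dict)
    tumour_events: dict[str, dict] = field(default_factory=dict)  # gene -> {down, deleted, focal}
    structured: dict[str, bool] = field(default_factory=dict)
    hazard_group: dict[str, str] = field(default_factory=dict)  # patient -> high | low

    def update(self, other: "SyntheticTruth") -> None:
        self.gene_class.update(other.gene_class)
        self.pathway_of_gene.update(other.pathway_of_gene)
        self.tumour_events.update(other.tumour_events)
        self.structured.update(other.structured)
        self.hazard_group.update(other.hazard_group)


def _rng(seed: int, key: str) -> np.random.Generator:
    h = hashlib.blake2b(f"{seed}:{key}".encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


# ---------------------------------------------------------------------------
# multi-tissue expression


def make_tissue_matrix(
    n_hk: int,
    n_ts: int,
    n_bg: int,
    n_tissues: int = 16,
    seed: int = 0,
    hk_baseline: float = 4.0,
    hk_noise_sd: float = 0.45,
    ts_peak: float = 100.0,
    bg_detect_prob: float = 0.3,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Multi-tissue matrix with planted HK / TS / background genes.

    HK genes: lognormal per-gene baseline (median ~4 FPKM) with mild
    per-tissue multiplicative noise, so the realised CV stays well
    below 1.5 and all tissues are detected. TS genes: one dominant
    tissue (plus up to two weakly detected ones), near-zero elsewhere,
    giving CV > 3.5 with probability >= 0.99. Background genes are
    detected in ~30% of tissues with high per-tissue variability, so
    they land in neither class (spurious HK calls are rare enough that
    a run without planted HK genes classifies none in >= 99% of seeds).
    """
    if min(n_hk, n_ts, n_bg) < 0:
        raise ValueError("gene counts must be >= 0")
    if n_tissues < 4:
        raise ValueError("need at least 4 tissues")
    rng = _rng(seed, "tissue_matrix")
    tissues = [f"tissue{i:02d}" for i in range(n_tissues)]
    rows, ids, truth = [], [], SyntheticTruth()

    for i in range(n_hk):
        gid = f"HK{i:04d}"
        base = rng.lognormal(np.log(hk_baseline), 0.5)
        vals = base * rng.lognormal(0.0, hk_noise_sd, n_tissues)
        rows.append(vals)
        ids.append(gid)
        truth.gene_class[gid] = "HK"

    for i in range(n_ts):
        gid = f"TS{i:04d}"
        k = int(rng.integers(1, 4))  # expressed in 1..3 of 16 (< 25%)
        vals = rng.uniform(0.0, 0.05, n_tissues)
        which = rng.choice(n_tissues, size=k, replace=False)
        vals[which[0]] = rng.lognormal(np.log(ts_peak), 0.5)
        for j in which[1:]:
            vals[j] = rng.lognormal(np.log(1.2), 0.3)
        rows.append(vals)
        ids.append(gid)
        truth.gene_class[gid] = "TS"

    for i in range(n_bg):
        gid = f"BG{i:04d}"
        on = rng.random(n_tissues) < bg_detect_prob
        vals = np.where(
            on, rng.lognormal(np.log(3.0), 1.0, n_tissues), rng.uniform(0.0, 0.05, n_tissues)
        )
        rows.append(vals)
        ids.append(gid)
        truth.gene_class[gid] = "background"

    values = pd.DataFrame(np.array(rows) if rows else np.empty((0, n_tissues)),
                          index=ids, columns=tissues)
    return ExpressionMatrix(values, {t: t for t in tissues}), truth


# ---------------------------------------------------------------------------
# gene models on a synthetic chromosome


def make_gene_models(
    linc_ids: list[str],
    n_coding: int = 20,
    frac_proximal: float = 0.0,
    seed: int = 0,
) -> tuple[list[GeneAnnotation], list[GeneAnnotation], set[str]]:
    """Lay lincRNAs and coding genes on a synthetic chromosome.

    Genes are spaced far apart (10 kb) so lincRNAs pass the 1 kb
    proximity filter, except a planted ``frac_proximal`` of lincRNAs
    placed 500 bp from a coding gene. Returns (lincRNAs, coding genes,
    ids of planted-proximal lincRNAs).
    """
    rng = _rng(seed, "gene_models")
    chrom = "chrS"
    pos = 10_000
    coding = []
    for i in range(n_coding):
        length = int(rng.integers(2_000, 5_000))
        coding.append(
            GeneAnnotation(
                f"PC{i:04d}", "protein_coding", "+",
                [GenomicInterval(chrom, pos, pos + length, "+")],
            )
        )
        pos += length + 10_000
    lincs, proximal = [], set()
    n_prox = int(round(frac_proximal * len(linc_ids)))
    for i, gid in enumerate(linc_ids):
        strand = "+" if rng.random() < 0.5 else "-"
        if i < n_prox and coding:
            host = coding[i % len(coding)].span
            start = host.end + 500  # gap 500 <= 1000: excluded by the filter
        else:
            start = pos
            pos += 10_000
        n_ex = int(rng.integers(1, 4))
        exons, cur = [], start
        for _ in range(n_ex):
            ex_len = int(rng.integers(200, 800))
            exons.append(GenomicInterval(chrom, cur, cur + ex_len, strand))
            cur += ex_len + int(rng.integers(300, 1_000))
        lincs.append(GeneAnnotation(gid, "lincRNA", strand, exons))
        if i < n_prox:
            proximal.add(gid)
    return lincs, coding, proximal


# ---------------------------------------------------------------------------
# sequences


def _markov_seq(length: int, trans: np.ndarray, init: np.ndarray, rng) -> str:
    out = np.empty(length, dtype="<U1")
    state = rng.choice(4, p=init)
    out[0] = _BASES[state]
    for i in range(1, length):
        state = rng.choice(4, p=trans[state])
        out[i] = _BASES[state]
    return "".join(out)


def _bias_to_chain(dinuc_bias: dict[str, float] | None) -> tuple[np.ndarray, np.ndarray]:
    if dinuc_bias is None:
        return np.full((4, 4), 0.25), np.full(4, 0.25)
    probs = np.zeros((4, 4))
    idx = {b: i for i, b in enumerate(_BASES)}
    for dn, p in dinuc_bias.items():
        probs[idx[dn[0]], idx[dn[1]]] = p
    if probs.sum() <= 0:
        raise ValueError("dinucleotide bias must have positive mass")
    probs /= probs.sum()
    marg = probs.sum(axis=1)
    marg = np.where(marg == 0, 1e-12, marg)
    trans = probs / marg[:, None]
    trans /= trans.sum(axis=1, keepdims=True)
    return trans, marg / marg.sum()


def make_sequences(
    n_structured: int,
    n_random: int,
    length_range: tuple[int, int] = (150, 300),
    dinuc_bias: dict[str, float] | None = None,
    seed: int = 0,
    stem_frac: float = 0.4,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Transcript sequences with planted inverted repeats vs Markov random.

    Structured sequences are built as arm + loop + reverse-complement
    arm + random tail, with total stem length ``stem_frac`` of the
    sequence (default 40%, comfortably above the 30% floor needed for
    the folding score to be extreme against the dinucleotide-shuffled
    null). Random sequences follow the first-order Markov chain implied
    by ``dinuc_bias`` (uniform by default).
    """
    lo, hi = length_range
    if lo < 40:
        raise ValueError("minimum sequence length is 40")
    if not (0.3 <= stem_frac <= 0.95):
        raise ValueError("stem_frac must lie in [0.3, 0.95]")
    rng = _rng(seed, "sequences")
    trans, init = _bias_to_chain(dinuc_bias)
    seqs: dict[str, str] = {}
    truth = SyntheticTruth()
    for i in range(n_structured):
        L = int(rng.integers(lo, hi + 1))
        arm = int(stem_frac * L) // 2
        loop = 5
        tail = max(L - 2 * arm - loop, 0)
        armseq = _markov_seq(arm, trans, init, rng)
        loopseq = _markov_seq(loop, trans, init, rng)
        tailseq = _markov_seq(tail, trans, init, rng) if tail else ""
        rc = "".join(_COMP[c] for c in reversed(armseq))
        sid = f"STRUCT{i:04d}"
        seqs[sid] = (armseq + loopseq + rc + tailseq)[:L]
        truth.structured[sid] = True
    for i in range(n_random):
        L = int(rng.integers(lo, hi + 1))
        sid = f"RAND{i:04d}"
        seqs[sid] = _markov_seq(L, trans, init, rng)
        truth.structured[sid] = False
    return seqs, truth


# ---------------------------------------------------------------------------
# tumour evidence


def make_tumour_tables(
    genes: list[str],
    n_tumour_types: int = 13,
    frac_down: float = 0.25,
    frac_deleted: float = 0.15,
    n_samples: int = 500,
    seed: int = 0,
    annotations: list[GeneAnnotation] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list, SyntheticTruth]:
    """DE table, CNA category table and focal deletions with planted events.

    The first ``frac_down`` of genes are planted down-regulated
    (log2 FC <= -1.2 with q < 0.05 in 1-3 tumour types), the next
    ``frac_deleted`` planted deleted (homozygous-deletion category in
    ~3% of samples; half of them additionally placed inside a focal
    deletion interval when annotations are given). Remaining genes are
    clean: |log2 FC| < 0.9, q >= 0.1, homdel rate 0.1%.
    """
    rng = _rng(seed, "tumour_tables")
    n = len(genes)
    n_down = int(round(frac_down * n))
    n_del = int(round(frac_deleted * n))
    down = set(genes[:n_down])
    deleted = set(genes[n_down : n_down + n_del])
    types = [f"TT{i:02d}" for i in range(n_tumour_types)]
    truth = SyntheticTruth()

    rows = []
    for g in genes:
        hot = set()
        if g in down:
            hot = set(rng.choice(n_tumour_types, size=int(rng.integers(1, 4)), replace=False))
        for ti, tt in enumerate(types):
            if ti in hot:
                lfc = -(1.2 + rng.exponential(0.8))
                q = rng.uniform(0.0, 0.045)
            else:
                lfc = float(np.clip(rng.normal(0.0, 0.2), -0.9, 0.9))
                q = rng.uniform(0.1, 1.0)
            rows.append((g, tt, lfc, q))
    de_table = pd.DataFrame(rows, columns=["gene_id", "tumour_type", "log2_fc", "q"])

    samples = [f"S{i:04d}" for i in range(n_samples)]
    cats = np.empty((n, n_samples), dtype=object)
    for gi, g in enumerate(genes):
        p_homdel = 0.03 if g in deleted else 0.001
        p = [p_homdel, 0.05, 0.85 - p_homdel, 0.07, 0.03]
        cats[gi] = rng.choice(
            ["homdel", "hetloss", "diploid", "gain", "amp"], size=n_samples, p=p
        )
    cna_table = pd.DataFrame(cats, index=genes, columns=samples)

    focal_regions: list = []
    focal_genes: set[str] = set()
    if annotations is not None:
        span_of = {a.gene_id: a.span for a in annotations}
        del_list = sorted(deleted)
        for j, g in enumerate(del_list):
            if j % 2 == 0 and g in span_of:  # half the deleted genes sit in focal dels
                sp = span_of[g]
                focal_regions.append(
                    (
                        GenomicInterval(sp.chrom, max(sp.start - 1000, 0), sp.end + 1000),
                        f"FOCAL_DEL{j:03d}",
                        "del",
                    )
                )
                focal_genes.add(g)
        # a couple of decoy amplification regions far away from all genes
        focal_regions.append((GenomicInterval("chrS", 1, 100), "FOCAL_AMP000", "amp"))

    for g in genes:
        truth.tumour_events[g] = {
            "down": g in down,
            "deleted": g in deleted,
            "focal": g in focal_genes,
        }
    return de_table, cna_table, focal_regions, truth


# ---------------------------------------------------------------------------
# methylation


def make_methylation(
    genes: list[GeneAnnotation],
    hk_gene_ids: set[str],
    n_samples: int = 40,
    seed: int = 0,
    low_shape: tuple[float, float] = (2.0, 10.0),
    high_shape: tuple[float, float] = (6.0, 4.0),
) -> tuple[pd.DataFrame, dict[str, tuple[str, int]], SyntheticTruth]:
    """Promoter probe betas with HK promoters shifted low.

    Each gene gets 3-8 probes uniformly inside its promoter window;
    probe betas are Beta-distributed: Beta(2, 10) (mean ~0.17) for HK
    promoters, Beta(6, 4) (mean ~0.6) for the rest.
    """
    from .methylation import promoter_window

    rng = _rng(seed, "methylation")
    samples = [f"M{i:03d}" for i in range(n_samples)]
    betas = {}
    coords: dict[str, tuple[str, int]] = {}
    truth = SyntheticTruth()
    for gene in genes:
        win = promoter_window(gene)
        a, b = low_shape if gene.gene_id in hk_gene_ids else high_shape
        for k in range(int(rng.integers(3, 9))):
            pid = f"probe_{gene.gene_id}_{k}"
            pos = int(rng.integers(win.start, win.end))
            coords[pid] = (win.chrom, pos)
            betas[pid] = rng.beta(a, b, n_samples)
        truth.gene_class.setdefault(
            gene.gene_id, "HK" if gene.gene_id in hk_gene_ids else "background"
        )
    table = pd.DataFrame(betas, index=samples).T
    return table, coords, truth


# ---------------------------------------------------------------------------
# co-expression


def make_coexpression(
    n_samples: int = 60,
    pathways: dict[str, int] | None = None,
    n_background: int = 150,
    r: float = 0.7,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GeneSetCollection, SyntheticTruth]:
    """Coding + lincRNA matrix driven by latent pathway factors.

    Each pathway has one lincRNA and ``pathways[name]`` coding genes
    all loading on a shared standard-Gaussian factor with loading
    sqrt(r), so the lincRNA-to-member Pearson correlation is ~``r``
    (default 0.7). Background coding genes are independent noise.
    Abundances are exponentiated with a small scale so linear-scale
    correlations stay close to the latent ones.
    """
    if pathways is None:
        pathways = {f"PW{i:02d}": 30 for i in range(8)}
    rng = _rng(seed, "coexpression")
    samples = [f"C{i:03d}" for i in range(n_samples)]
    load = np.sqrt(r)
    resid = np.sqrt(1.0 - r)
    rows, ids = [], []
    coll = GeneSetCollection()
    truth = SyntheticTruth()

    def expr(latent: np.ndarray) -> np.ndarray:
        return np.exp(np.log(5.0) + 0.4 * latent)

    for name, size in pathways.items():
        z = rng.normal(size=n_samples)
        linc = f"LINC_{name}"
        rows.append(expr(load * z + resid * rng.normal(size=n_samples)))
        ids.append(linc)
        members = []
        for k in range(size):
            gid = f"{name}_G{k:03d}"
            rows.append(expr(load * z + resid * rng.normal(size=n_samples)))
            ids.append(gid)
            members.append(gid)
            truth.pathway_of_gene[gid] = name
        truth.pathway_of_gene[linc] = name
        coll.sets[name] = (f"planted pathway {name}", frozenset(members))
    for k in range(n_background):
        gid = f"BGC{k:04d}"
        rows.append(expr(rng.normal(size=n_samples)))
        ids.append(gid)
    values = pd.DataFrame(np.array(rows), index=ids, columns=samples)
    return ExpressionMatrix(values, {s: s for s in samples}), coll, truth


# ---------------------------------------------------------------------------
# survival


def make_survival(
    n_patients: int = 400,
    hazard_ratio: float = 2.0,
    seed: int = 0,
    base_hazard: float = 1.0 / 1000.0,
    censor_hazard: float = 1.0 / 1000.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Survival records with expression-dependent exponential hazards.

    Expression is lognormal; patients above its 75th percentile form
    the 'high' group whose death hazard is multiplied by
    ``hazard_ratio``. Independent exponential censoring gives ~50%
    censoring at the defaults.
    """
    rng = _rng(seed, "survival")
    expr = rng.lognormal(np.log(3.0), 0.6, n_patients)
    thr = np.quantile(expr, 0.75)
    high = expr > thr
    hazard = base_hazard * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / censor_hazard, n_patients)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    patients = [f"P{i:04d}" for i in range(n_patients)]
    truth = SyntheticTruth()
    for pid, h in zip(patients, high):
        truth.hazard_group[pid] = "high" if h else "low"
    df = pd.DataFrame(
        {
            "patient_id": patients,
            "time": np.maximum(time, 1e-3),
            "event": event,
            "expression": expr,
        }
    )
    return df, truth
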