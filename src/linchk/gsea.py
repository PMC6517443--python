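"""Stage 6: co-expression-based function prediction via preranked GSEA.

For each lincRNA of interest, protein-coding genes are ranked by their
Pearson correlation to the lincRNA across samples; a weighted
Kolmogorov-Smirnov running statistic (enrichment score) is computed
for each gene set; significance comes from gene-label permutations of
the ranking (scores fixed, set membership randomized) with
sign-matched NES normalisation and a pooled-null FDR. Downstream, terms
recurrently significant across lincRNAs are kept and reduced to
non-redundant representatives using Wang-method semantic similarity on
the ontology DAG with average-linkage clustering and a tree cut.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .core import ExpressionMatrix
from .io import GeneSetCollection, OntologyDAG


@dataclass
class RankedList:
    """Genes sorted by descending score; ties broken by gene id."""

    genes: list[str]
    scores: np.ndarray  # aligned with genes, descending

    @classmethod
    def from_scores(cls, score_map: dict[str, float]) -> "RankedList":
        items = sorted(score_map.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls([g for g, _ in items], np.array([s for _, s in items], dtype=float))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    term: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    size: int

    @property
    def direction(self) -> int:
        return 1 if self.es >= 0 else -1


def correlation_rank(
    matrix: ExpressionMatrix | pd.DataFrame,
    lincRNA_gene: str,
    coding_genes: list[str],
    log_scale: bool = False,
) -> RankedList:
    """Rank coding genes by Pearson r to the lincRNA across samples.

    Constant genes (zero variance) are dropped with a warning. Default
    correlates linear abundances; ``log_scale`` switches to log2(x+1).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    if lincRNA_gene not in values.index:
        raise KeyError(f"unknown lincRNA {lincRNA_gene!r}")
    X = values.loc[coding_genes].to_numpy(dtype=float)
    y = values.loc[lincRNA_gene].to_numpy(dtype=float)
    if log_scale:
        X = np.log2(X + 1.0)
        y = np.log2(y + 1.0)
    if y.std() == 0:
        raise ValueError(f"lincRNA {lincRNA_gene!r} has constant expression")
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = Xc.std(axis=1)
    keep = sx > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} constant coding gene(s) dropped")
    r = (Xc[keep] @ yc) / (X.shape[1] * sx[keep] * y.std())
    r = np.clip(r, -1.0, 1.0)
    return RankedList.from_scores(
        {g: float(v) for g, v in zip(np.asarray(coding_genes)[keep], r)}
    )


def enrichment_score(
    ranked: RankedList, gene_set: set[str] | frozenset[str], weight_p: float = 1.0
) -> float:
    """Weighted KS enrichment score of a gene set against a ranking.

    Walking down the ranking, hits add |r_i|^p / sum_hits |r|^p and
    misses subtract 1 / (N - N_hits); the ES is the signed maximum
    deviation of the running sum from zero.
    """
    hits = np.array([g in gene_set for g in ranked.genes])
    n_hit = int(hits.sum())
    n = len(ranked)
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranking")
    w = np.abs(ranked.scores) ** weight_p
    w_hit = np.where(hits, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all hit scores zero: fall back to unweighted steps
        w_hit = hits.astype(float)
        denom = w_hit.sum()
    running = np.cumsum(w_hit / denom - (~hits) / (n - n_hit))
    return float(running[np.argmax(np.abs(running))])


def _es_many(
    order_w: np.ndarray, hit_idx_rows: np.ndarray, n: int, weight_p: float
) -> np.ndarray:
    """ES for many permuted hit-index sets against fixed ranked weights.

    ``order_w``: |score|^p per rank position; ``hit_idx_rows``:
    (n_perm, n_hit) integer array of hit positions per permutation.
    Deviation extremes occur at hit positions (just before/just after),
    so only those points are evaluated.
    """
    n_perm, k = hit_idx_rows.shape
    pos = np.sort(hit_idx_rows, axis=1)
    w = order_w[pos]
    denom = w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():  # unweighted fallback per spec of enrichment_score
        w[zero] = 1.0
        denom = w.sum(axis=1, keepdims=True)
    cum_hit = np.cumsum(w, axis=1) / denom
    j = np.arange(1, k + 1)
    miss_step = 1.0 / (n - k)
    # running sum just after hit m: cum_hit[m] - (pos[m] + 1 - (m+1)) * miss_step
    after = cum_hit - (pos + 1 - j) * miss_step
    # just before hit m: cum_hit[m-1] - (pos[m] - m) * miss_step
    before = np.concatenate([np.zeros((n_perm, 1)), cum_hit[:, :-1]], axis=1) - (
        pos - (j - 1)
    ) * miss_step
    cand = np.concatenate([after, before], axis=1)
    return cand[np.arange(n_perm), np.argmax(np.abs(cand), axis=1)]


def _child_seed(seed: int, key: str) -> int:
    h = hashlib.blake2b(f"{seed}:{key}".encode(), digest_size=8).digest()
    return int.from_bytes(h[:4], "big")


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    min_set: int = 15,
    max_set: int = 500,
    weight_p: float = 1.0,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Preranked GSEA over a gene-set collection.

    Null: membership labels permuted over the ranking (scores fixed),
    per-set child RNG keyed by set name so results are independent of
    iteration order. NES = ES / mean(|null ES| of matching sign);
    p-value from the matching-sign null tail with add-one correction;
    FDR by the pooled-NES procedure (fraction of pooled null NES at
    least as extreme, normalised by the fraction of observed NES at
    least as extreme, clipped to [0, 1]).
    """
    n = len(ranked)
    in_rank = set(ranked.genes)
    eligible = []
    for name in sets.names():
        size = len(sets.genes(name) & in_rank)
        if min_set <= size <= max_set and size < n:
            eligible.append((name, size))
    if not eligible:
        raise ValueError("no gene set within [min_set, max_set] intersects the ranking")

    w = np.abs(ranked.scores) ** weight_p
    obs_es = {}
    null_nes_pool = []
    obs_nes = {}
    pvals = {}
    for name, size in eligible:
        es = enrichment_score(ranked, sets.genes(name), weight_p)
        rng = np.random.default_rng(_child_seed(seed, name))
        # permute membership: draw `size` random rank positions per permutation
        hit_idx = np.argsort(
            rng.random((n_perm, n)), axis=1, kind="stable"
        )[:, :size]
        null = _es_many(w, hit_idx, n, weight_p)
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        if n_same == 0:
            mean_same = float(np.abs(null).mean()) or 1.0
            p = 1.0 / (n_perm + 1.0)
        else:
            mean_same = float(np.abs(null[same]).mean()) or 1.0
            p = (1.0 + float((np.abs(null[same]) >= abs(es)).sum())) / (n_same + 1.0)
        nes = es / mean_same
        # normalise each null sign tail by its own mean, as in the published procedure
        pos_mean = float(np.abs(null[null >= 0]).mean()) if (null >= 0).any() else 1.0
        neg_mean = float(np.abs(null[null < 0]).mean()) if (null < 0).any() else 1.0
        null_nes = np.where(null >= 0, null / (pos_mean or 1.0), null / (neg_mean or 1.0))
        obs_es[name] = (es, size)
        obs_nes[name] = float(nes)
        pvals[name] = min(p, 1.0)
        null_nes_pool.append(null_nes)

    pool = np.concatenate(null_nes_pool)
    all_obs = np.array(list(obs_nes.values()))
    results = []
    for name, size in eligible:
        es, sz = obs_es[name]
        nes = obs_nes[name]
        if nes >= 0:
            frac_null = float((pool >= nes).sum()) / max(float((pool >= 0).sum()), 1.0)
            frac_obs = float((all_obs >= nes).sum()) / max(float((all_obs >= 0).sum()), 1.0)
        else:
            frac_null = float((pool <= nes).sum()) / max(float((pool < 0).sum()), 1.0)
            frac_obs = float((all_obs <= nes).sum()) / max(float((all_obs < 0).sum()), 1.0)
        fdr = min(frac_null / frac_obs, 1.0) if frac_obs > 0 else 1.0
        results.append(EnrichmentResult(name, es, nes, pvals[name], fdr, sz))
    return results


def term_matrix_filter(
    results_by_lincRNA: dict[str, list[EnrichmentResult]],
    fdr_max: float = 0.05,
    min_lincRNA_fraction: float = 0.10,
) -> pd.DataFrame:
    """Term x lincRNA signed-significance matrix, recurrence-filtered.

    Cells are +1 / -1 for a significant (FDR < fdr_max) positive /
    negative association, else 0. Terms significant in fewer than
    ceil(min_lincRNA_fraction x n_lincRNAs) lincRNAs are dropped.
    """
    lincs = list(results_by_lincRNA)
    need = math.ceil(min_lincRNA_fraction * len(lincs))
    cells: dict[str, dict[str, int]] = {}
    for linc, results in results_by_lincRNA.items():
        for r in results:
            if r.fdr_q < fdr_max:
                cells.setdefault(r.term, {})[linc] = r.direction
    keep = [t for t, by_linc in cells.items() if len(by_linc) >= need]
    mat = pd.DataFrame(0, index=sorted(keep), columns=lincs, dtype=int)
    for t in keep:
        for linc, sign in cells[t].items():
            mat.loc[t, linc] = sign
    return mat


# ---------------------------------------------------------------------------
# Wang semantic similarity and redundancy reduction

_EDGE_WEIGHT = {"is_a": 0.8, "part_of": 0.6}


def _s_values(dag: OntologyDAG, term: str) -> dict[str, float]:
    """Wang S-values: semantic contribution of each ancestor to `term`."""
    s = {term: 1.0}
    # propagate upward; process terms by decreasing S so maxima settle
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for parent, rel in dag.parents.get(t, ()):
                cand = s[t] * _EDGE_WEIGHT[rel]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    return s


def semantic_similarity(dag: OntologyDAG, terms: list[str]) -> pd.DataFrame:
    """Pairwise Wang similarity matrix over the given terms.

    sim(A, B) = sum over shared ancestors of (S_A(t) + S_B(t)) divided
    by (SV(A) + SV(B)); symmetric with unit diagonal.
    """
    missing = [t for t in terms if t not in dag.parents]
    if missing:
        raise KeyError(f"terms not in ontology: {missing}")
    svals = {t: _s_values(dag, t) for t in terms}
    sv = {t: sum(svals[t].values()) for t in terms}
    m = np.eye(len(terms))
    for i, a in enumerate(terms):
        for j in range(i + 1, len(terms)):
            b = terms[j]
            shared = set(svals[a]) & set(svals[b])
            num = sum(svals[a][t] + svals[b][t] for t in shared)
            m[i, j] = m[j, i] = num / (sv[a] + sv[b])
    return pd.DataFrame(m, index=terms, columns=terms)


def reduce_terms(
    sim: pd.DataFrame,
    cut_height: float = 0.85,
    seed: int | None = 0,
) -> tuple[list[str], dict[str, int]]:
    """Cluster terms on distance 1 - similarity and pick one per cluster.

    Average-linkage hierarchical clustering, tree cut at ``cut_height``;
    the representative of each cluster is chosen by a seeded RNG
    (``seed=None`` selects the lexicographically smallest id instead).
    Returns (representatives, term -> cluster id).
    """
    terms = list(sim.index)
    if len(terms) == 1:
        return terms, {terms[0]: 1}
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for t, c in zip(terms, labels):
        clusters.setdefault(int(c), []).append(t)
    reps = []
    rng = np.random.default_rng(seed) if seed is not None else None
    for c in sorted(clusters):
        members = sorted(clusters[c])
        if rng is None:
            reps.append(members[0])
        else:
            reps.append(members[int(rng.integers(len(members)))])
    return reps, {t: int(c) for t, c in zip(terms, labels)}
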