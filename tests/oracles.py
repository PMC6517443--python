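"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: per-base set
membership for interval arithmetic, exhaustive structure enumeration
for folding, and a literal running-sum walk for the enrichment score.
"""

from __future__ import annotations

import numpy as np

_PAIRABLE = {
    ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G"),
}
MIN_LOOP = 3


def perbase_intersection(a, b) -> int:
    """Count bases covered by both interval sets via explicit membership."""
    cov_a = {(iv.chrom, p) for iv in a for p in range(iv.start, iv.end)}
    cov_b = {(iv.chrom, p) for iv in b for p in range(iv.start, iv.end)}
    return len(cov_a & cov_b)


def enumerate_max_pairs(seq: str) -> int:
    """Maximum nested WC/GU pairs by exhaustive search (n <= ~14).

    Enumerates every pairwise-compatible (disjoint or nested,
    non-crossing) subset of allowed pairs with >= MIN_LOOP unpaired
    bases inside each pair.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_LOOP + 1, n)
        if (seq[i], seq[j]) in _PAIRABLE
    ]

    def compatible(p, q):
        (i, j), (k, l) = p, q
        if j < k or l < i:  # disjoint
            return True
        if i < k and l < j:  # q nested in p
            return True
        if k < i and j < l:  # p nested in q
            return True
        return False

    best = 0

    def extend(chosen, start):
        nonlocal best
        best = max(best, len(chosen))
        if len(chosen) + (len(pairs) - start) <= best:
            return
        for idx in range(start, len(pairs)):
            p = pairs[idx]
            if all(compatible(p, q) for q in chosen):
                chosen.append(p)
                extend(chosen, idx + 1)
                chosen.pop()

    extend([], 0)
    return best


def running_sum_es(genes, scores, gene_set, weight_p=1.0) -> float:
    """Literal walk down the ranking accumulating hit/miss increments."""
    scores = np.asarray(scores, dtype=float)
    hits = [g in gene_set for g in genes]
    n, k = len(genes), sum(hits)
    whits = sum(abs(s) ** weight_p for s, h in zip(scores, hits) if h)
    running, extreme = 0.0, 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            running += (abs(s) ** weight_p / whits) if whits > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(extreme):
            extreme = running
    return extreme


def dinuc_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out
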