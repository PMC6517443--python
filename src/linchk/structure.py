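"""Folding-stability permutation test (Randfold-style).

A sequence is called "more structured than expected" when its folding
score is lower (more stable) than scores of dinucleotide-preserving
shuffles of itself. The shuffle keeps the full dinucleotide count
multiset, first and last base and length fixed (Altschul-Erickson
Eulerian-path construction), so the null controls for composition and
for the strong dinucleotide dependence of folding energies.

The default folding engine is a Nussinov base-pair maximisation DP
(Watson-Crick + GU wobble, minimum hairpin loop of 3 unpaired bases)
returning minus the maximum pair count, so that lower = more stable,
mirroring the sign convention of thermodynamic MFE. An ``external``
engine hook shells out to a user-configured folding command (e.g.
RNAfold) and parses a kcal/mol value.
"""

from __future__ import annotations

import hashlib
import math
import re
import subprocess
import warnings
from dataclasses import dataclass

import numpy as np

from .core import bh_fdr

ALPHABET = frozenset("ACGT")

# encoded as A=0, C=1, G=2, T/U=3
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
# Watson-Crick + GU wobble
_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}
MIN_LOOP = 3  # unpaired bases enclosed by any pair

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        if a and callable(a[0]):
            return a[0]
        return wrap


@njit(cache=True)
def _nussinov_maxpairs(s: np.ndarray) -> int:  # pragma: no cover - numba
    n = s.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                a = s[i]
                b = s[k]
                ok = (
                    (a == 0 and b == 3)
                    or (a == 3 and b == 0)
                    or (a == 1 and b == 2)
                    or (a == 2 and b == 1)
                    or (a == 2 and b == 3)
                    or (a == 3 and b == 2)
                )
                if ok:
                    left = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    cand = left + 1 + right
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return int(dp[0, n - 1])


def encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return np.array([_ENC[c] for c in seq], dtype=np.int8)


def fold_score(seq: str, engine: str = "nussinov", external_cmd: str | None = None) -> float:
    """Folding stability score; lower = more stable.

    ``nussinov``: -1 x maximum number of nested WC/GU pairs with a
    minimum hairpin loop of 3 unpaired bases (O(n^3) DP).
    ``external``: run ``external_cmd`` with the sequence on stdin and
    parse the last signed decimal number (kcal/mol) from its output.
    """
    if engine == "nussinov":
        s = encode(seq)
        if s.size < MIN_LOOP + 2:
            return 0.0
        return -float(_nussinov_maxpairs(s))
    if engine == "external":
        if not external_cmd:
            raise ValueError("external engine requires a folding command")
        out = subprocess.run(
            external_cmd, shell=True, input=seq + "\n", capture_output=True, text=True
        )
        if out.returncode != 0:
            raise RuntimeError(f"external folding command failed: {out.stderr[:200]}")
        nums = re.findall(r"-?\d+\.\d+", out.stdout)
        if not nums:
            raise RuntimeError("could not parse an energy from external engine output")
        return float(nums[-1])
    raise ValueError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random permutation preserving the exact dinucleotide count multiset.

    Treats the sequence as an Eulerian path in the dinucleotide
    multigraph; samples a random path with the same start and end
    vertices. First/last base, length and all adjacent-pair counts are
    preserved exactly.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    if len(s) < 3:
        return s
    first, last = s[0], s[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)

    verts = [v for v in edges if v != last]
    # Sample random "last exit" edges forming in-tree toward `last`
    # (Altschul & Erickson): retry until the chosen exits connect every
    # vertex with out-edges to the end vertex.
    for _ in range(10000):
        last_exit = {v: edges[v][rng.integers(len(edges[v]))] for v in verts}
        ok = True
        for v in verts:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to sample a valid Eulerian shuffle")

    pools: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in last_exit:
            rest.remove(last_exit[v])
        rng.shuffle(rest)
        if v in last_exit:
            rest.append(last_exit[v])
        pools[v] = rest

    out = [first]
    idx = {v: 0 for v in pools}
    cur = first
    for _ in range(len(s) - 1):
        nxt = pools[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class StructureTestResult:
    gene_id: str
    observed_score: float
    null_scores: np.ndarray
    p_value: float
    q_value: float
    n_shuffles: int


def _child_rng(seed: int, key: str) -> np.random.Generator:
    """Stable per-key child RNG so results don't depend on iteration order."""
    h = hashlib.blake2b(f"{seed}:{key}".encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


def structure_test(
    seqs: dict[str, str],
    n_shuffles: int = 1000,
    engine: str = "nussinov",
    seed: int = 0,
    external_cmd: str | None = None,
) -> list[StructureTestResult]:
    """One-sided (stability) permutation test per sequence, BH across genes.

    p = (1 + #{null <= observed}) / (n_shuffles + 1); smaller scores are
    more stable, so the lower tail is counted. Sequences shorter than 4
    bases are skipped with a warning.
    """
    if n_shuffles < 19:
        raise ValueError("need at least 19 shuffles for a p < 0.05 to be possible")
    results: list[StructureTestResult] = []
    for gene_id, seq in seqs.items():
        if len(seq) < 4:
            warnings.warn(f"sequence {gene_id} shorter than 4 bases: skipped")
            continue
        rng = _child_rng(seed, gene_id)
        obs = fold_score(seq, engine=engine, external_cmd=external_cmd)
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            null[i] = fold_score(
                dinucleotide_shuffle(seq, rng), engine=engine, external_cmd=external_cmd
            )
        p = (1.0 + float(np.sum(null <= obs))) / (n_shuffles + 1.0)
        results.append(StructureTestResult(gene_id, obs, null, p, math.nan, n_shuffles))
    if results:
        qs = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results
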