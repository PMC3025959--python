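"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles —
straightforward dynamic programs, direct summations and hand-coded
formulas — so the package implementation can be checked against an
independent route.  Nothing imports from oligochip.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from numba import njit

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    # N -> 4 never matches anything
    lut = {c: i for i, c in enumerate("ACGTN")}
    return np.array([lut[c] for c in seq], dtype=np.int8)


@njit(cache=True)
def _sw_dp(a, b, match, mismatch, gap):
    """Smith-Waterman with linear gaps; among score-optimal local
    alignments prefers more matching columns.  Returns
    (score, matches, columns) of the best cell."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    Mt = np.zeros((n + 1, m + 1), dtype=np.int64)   # matches on best path
    Cl = np.zeros((n + 1, m + 1), dtype=np.int64)   # columns on best path
    best = (0.0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            is_match = a[i - 1] == b[j - 1] and a[i - 1] != 4
            sub = match if is_match else mismatch
            # candidates: fresh start, left gap, up gap, diagonal
            sc, mt, cl = 0.0, 0, 0
            c_sc = H[i, j - 1] + gap
            if c_sc > sc or (c_sc == sc and Mt[i, j - 1] > mt):
                sc, mt, cl = c_sc, Mt[i, j - 1], Cl[i, j - 1] + 1
            c_sc = H[i - 1, j] + gap
            if c_sc > sc or (c_sc == sc and Mt[i - 1, j] > mt):
                sc, mt, cl = c_sc, Mt[i - 1, j], Cl[i - 1, j] + 1
            c_sc = H[i - 1, j - 1] + sub
            c_mt = Mt[i - 1, j - 1] + (1 if is_match else 0)
            if c_sc > sc or (c_sc == sc and c_mt >= mt):
                sc, mt, cl = c_sc, c_mt, Cl[i - 1, j - 1] + 1
            if sc <= 0.0:
                sc, mt, cl = 0.0, 0, 0
            H[i, j], Mt[i, j], Cl[i, j] = sc, mt, cl
            if sc > best[0] or (sc == best[0] and mt > best[1]):
                best = (sc, mt, cl)
    return best


def sw_stats(a: str, b: str, match: float = 1.0, mismatch: float = -1.03,
             gap: float = -2.11):
    """(score, matches, columns) of the best local alignment (one strand)."""
    return _sw_dp(_encode(a), _encode(b), match, mismatch, gap)


def sw_best_both_strands(a: str, b: str):
    fwd = sw_stats(a, b)
    rev = sw_stats(a, revcomp(b))
    return fwd if fwd[0] >= rev[0] else rev


def sw_edge_qualifies(a: str, b: str, min_identity: float, min_length: int) -> bool:
    """Does the best local alignment (either strand) reach the identity
    and length thresholds?"""
    score, matches, columns = sw_best_both_strands(a, b)
    if columns < min_length or columns == 0:
        return False
    return 100.0 * matches / columns >= min_identity


def sw_identity_over_probe(probe: str, target: str) -> float:
    """Identity % over probe length from the best local alignment of the
    probe against either target strand."""
    score, matches, _ = sw_best_both_strands(probe, target)
    return 100.0 * matches / len(probe)


@njit(cache=True)
def _lcs_dp(a, b):
    n, m = len(a), len(b)
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
            else:
                cur[j] = 0
        prev, cur = cur, prev
    return best


def lcs_brute(a: str, b: str) -> int:
    """Longest common substring by plain O(n·m) DP (one strand)."""
    return int(_lcs_dp(_encode(a), _encode(b)))


def lcs_both_strands(a: str, b: str) -> int:
    return max(lcs_brute(a, b), lcs_brute(a, revcomp(b)))


# ---------------------------------------------------------------------------
# Sequence composition
# ---------------------------------------------------------------------------

def _h(counts) -> float:
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values() if c)


def window_entropy(seq: str, window: int, dinucleotide: bool = False) -> list[float]:
    """Plain windowed entropy, or the first-order conditional entropy
    H(2-mers) − H(first window−1 bases) in dinucleotide mode."""
    out = []
    for i in range(len(seq) - window + 1):
        w = seq[i:i + window]
        if dinucleotide:
            h = _h(Counter(w[j:j + 2] for j in range(len(w) - 1))) - _h(Counter(w[:-1]))
            out.append(max(h, 0.0))
        else:
            out.append(_h(Counter(w)))
    return out


# Unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K) and
# duplex initiation terms, hand-transcribed for an independent Tm sum.
_NN_TABLE = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)


def nn_tm_hand(seq: str, na_mM: float = 25.0, oligo_nM: float = 50.0) -> float:
    """Tm by direct table summation: Tm = dH/(dS' + R ln C) − 273.15 with
    the entropic salt correction dS' = dS + 0.368·(N−1)·ln[Na+]."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        h, s = _INIT_AT if end in "AT" else _INIT_GC
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        d = seq[i:i + 2]
        if d not in _NN_TABLE:
            d = revcomp(d)
        h, s = _NN_TABLE[d]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM * 1e-3)
    r = 1.987
    c = oligo_nM * 1e-9
    return dh * 1000.0 / (ds + r * math.log(c)) - 273.15


# ---------------------------------------------------------------------------
# Secondary structure brute force
# ---------------------------------------------------------------------------

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def structure_brute(seq: str, min_loop: int = 3) -> tuple[int, int]:
    """(stem, selfdimer) by explicit enumeration of all substring pairs.

    A pairing of length L between positions a and b (a block read
    forward, its partner read backward) requires
    seq[a+k] complementary to seq[b-k] for k in 0..L-1.
    """
    n = len(seq)
    stem = 0
    dimer = 0
    for a in range(n):
        for b in range(n):
            L = 0
            while a + L < n and b - L >= 0 and _PAIR.get(seq[a + L]) == seq[b - L]:
                L += 1
                dimer = max(dimer, L)
                # unpaired bases strictly between the innermost pair
                if (b - (L - 1)) - (a + (L - 1)) - 1 >= min_loop:
                    stem = max(stem, L)
    return stem, dimer


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def bh_hand(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up by the textbook procedure."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = p[idx] * m / rank_from_top
        running_min = min(running_min, val)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


def fisher_two_sided_hand(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher p by summing hypergeometric pmfs no larger than
    the observed one (with the customary relative tolerance for float
    ties)."""
    from scipy.stats import hypergeom

    lo = max(0, n + K - N)
    hi = min(n, K)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    obs = pmf[support == k][0]
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


def lowess_hand(x: np.ndarray, y: np.ndarray, frac: float) -> np.ndarray:
    """Tricube-weighted local linear regression at each x (no robustness
    iterations)."""
    n = len(x)
    k = int(np.ceil(frac * n))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / np.maximum(h, 1e-300)) ** 3, 0, 1) ** 3
        X = np.column_stack([np.ones(n), x - x[i]])
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ y)
        out[i] = beta[0]
    return out


def average_linkage_brute(labels, dmat: np.ndarray):
    """O(n^3) average linkage with lexicographic tie-break, computing
    inter-cluster distances from the raw pairwise matrix each round."""
    clusters = {lab: [i] for i, lab in enumerate(labels)}
    merges = []
    node = 0
    while len(clusters) > 1:
        names = sorted(clusters)
        best = None
        for i, u in enumerate(names):
            for v in names[i + 1:]:
                d = np.mean([dmat[a, b] for a in clusters[u] for b in clusters[v]])
                cand = (d, u, v)
                if best is None or cand < best:
                    best = cand
        d, u, v = best
        name = f"node{node}"
        node += 1
        clusters[name] = clusters.pop(u) + clusters.pop(v)
        merges.append((u, v, float(d), len(clusters[name])))
    return merges
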