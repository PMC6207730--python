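"""Independent brute-force oracles used to validate the package's exact
algorithms. Each oracle is written as a direct enumeration or a plainly
different formulation from the implementation it checks."""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

_RNA_PAIR_E = {
    ("C", "G"): -3.0, ("G", "C"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def enumerate_fold_optimum(seq: str, min_loop: int = 3) -> float:
    """Minimum energy over ALL non-crossing pairings, by explicit recursive
    enumeration of complete structures (no memoised optimum recursion)."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    def region(i: int, j: int) -> list:
        """All pairing sets of region [i, j] as lists of (a, b) pairs."""
        if i > j:
            return [[]]
        out = []
        for rest in region(i + 1, j):
            out.append(rest)                       # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            e = _RNA_PAIR_E.get((seq[i], seq[k]))
            if e is None:
                continue
            for inner in region(i + 1, k - 1):
                for outer in region(k + 1, j):
                    out.append([(i, k)] + inner + outer)
        return out

    best = 0.0
    for structure in region(0, n - 1):
        energy = sum(_RNA_PAIR_E[(seq[a], seq[b])] for a, b in structure)
        best = min(best, energy)
    return best


_DNA_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def ir_best_score(
    seq: str,
    match: int = 3,
    mismatch: int = -3,
    gap: int = -7,
    min_loop: int = 3,
) -> int:
    """Maximum inverted-repeat local-alignment score of a sequence, by a
    plain quadratic dynamic program over (left position, right position)
    pairs with no windowing, span bookkeeping or traceback."""
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n == 0:
        return 0
    NEG = -(10 ** 9)
    best = 0
    H = [[NEG] * n for _ in range(n)]
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            pair = match if (_DNA_COMP[s[i]] == s[j] and s[i] != "N") else mismatch
            h = pair
            if i > 0 and j < n - 1 and H[i - 1][j + 1] > NEG:
                h = max(h, H[i - 1][j + 1] + pair)
            if i > 0 and H[i - 1][j] > NEG:
                h = max(h, H[i - 1][j] + gap)
            if j < n - 1 and H[i][j + 1] > NEG:
                h = max(h, H[i][j + 1] + gap)
            H[i][j] = h
            best = max(best, h)
    return best


_RNA_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def duplex_min_expectation(
    mirna: str,
    window: str,
    seed_lo: int = 2,
    seed_hi: int = 13,
    max_gaps: int = 2,
) -> float:
    """Minimal expectation over all <=``max_gaps``-gap antiparallel
    alignments, by memoised top-down recursion over (miRNA consumed,
    window-3'-side consumed, gaps used)."""
    m = mirna.upper().replace("T", "U")
    w = window.upper().replace("T", "U")[::-1]

    def col_pen(pos: int, state: str) -> float:
        base = {"match": 0.0, "gu": 0.5, "mm": 1.0, "gap": 2.0}[state]
        return base * 2 if seed_lo <= pos <= seed_hi else base

    @lru_cache(maxsize=None)
    def f(i: int, j: int, g: int) -> float:
        if i == len(m):
            return 0.0                       # trailing window bases free
        pos = i + 1
        best = float("inf")
        if j < len(w):
            a, b = m[i], w[j]
            if _RNA_COMP[a] == b:
                state = "match"
            elif (a, b) in (("G", "U"), ("U", "G")):
                state = "gu"
            else:
                state = "mm"
            best = min(best, col_pen(pos, state) + f(i + 1, j + 1, g))
        if g < max_gaps:
            best = min(best, col_pen(pos, "gap") + f(i + 1, j, g + 1))
            if 0 < i and j < len(w):
                best = min(best, col_pen(pos, "gap") + f(i, j + 1, g + 1))
        return best

    best = min(f(0, j0, 0) for j0 in range(len(w) + 1))
    f.cache_clear()
    return best


def mw_permutation_p(sample_a, sample_b) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group assignments,
    computing U directly from pairwise value comparisons."""
    pooled = list(sample_a) + list(sample_b)
    n_a = len(sample_a)
    n = len(pooled)

    def u_of(indices) -> float:
        a = [pooled[i] for i in indices]
        b = [pooled[i] for i in range(n) if i not in indices]
        u = 0.0
        for x in a:
            for y in b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    n_b = n - n_a
    u_obs = u_of(set(range(n_a)))
    stat_obs = min(u_obs, n_a * n_b - u_obs)
    count = 0
    total = comb(n, n_a)
    for idx in combinations(range(n), n_a):
        u = u_of(set(idx))
        if min(u, n_a * n_b - u) <= stat_obs + 1e-9:
            count += 1
    return min(1.0, count / total)
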