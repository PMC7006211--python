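"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: the
hypergeometric tail is exact integer arithmetic, and the local
alignment score is a direct three-matrix dynamic program.
"""

from __future__ import annotations

from math import comb

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact enumeration."""
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return num / comb(N, n)


def hypergeom_tail_table(N: int, K: int, n: int) -> list[tuple[int, float]]:
    """All (k, P(X >= k)) for one (N, K, n), via exact suffix sums."""
    k_lo = max(0, n + K - N)
    k_hi = min(n, K)
    pmf_num = [comb(K, j) * comb(N - K, n - j) for j in range(k_lo, k_hi + 1)]
    denom = comb(N, n)
    out = []
    suffix = 0
    for j in range(k_hi, k_lo - 1, -1):
        suffix += pmf_num[j - k_lo]
        out.append((j, suffix / denom))
    out.reverse()
    return out


def sw_score(
    a: str, b: str, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Smith-Waterman local score, BLOSUM62, gap of length L costs
    gap_open + gap_extend * L."""
    la, lb = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (left move)
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (up move)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, direct definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
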