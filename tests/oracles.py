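"""Independent reference implementations used only to cross-check the package.

These are deliberately written from scratch against the definitions, not by
calling the code under test: a plain-Python Gotoh dynamic program for local
affine-gap alignment scores, an arbitrary-precision E-value formula, and a
window-enumeration cluster finder.
"""

from __future__ import annotations

from decimal import Decimal, getcontext

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith–Waterman local alignment score, affine gaps (a gap of length L
    costs gap_open + L * gap_extend), full dynamic program over all cells."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to gap)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend
            )
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + s,
                Ix[i - 1][j - 1] + s,
                Iy[i - 1][j - 1] + s,
            )
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def evalue_decimal(S: float, m: int, n: int, lambda_: float, K: float) -> float:
    """E = K * m * n * exp(-lambda * S) evaluated with 50-digit arithmetic."""
    getcontext().prec = 50
    val = Decimal(K) * Decimal(m) * Decimal(n) * (-Decimal(lambda_) * Decimal(S)).exp()
    return float(val)


def enumerate_clusters(
    genes,
    span_bp: int,
    min_members: int = 2,
    max_members: int | None = None,
):
    """Left-to-right maximal-window chains over position-sorted genes.

    ``genes`` is a sequence of (start, end) tuples (already one chromosome,
    already the relevant class pool). Validity of every window [i, j] is
    established by direct enumeration; the chain then repeatedly takes the
    largest valid window at the earliest uncovered gene. Returns a list of
    index tuples for windows meeting ``min_members``; genes of smaller
    windows are skipped, as the chain always advances past its window.
    """
    order = sorted(range(len(genes)), key=lambda k: (genes[k][0], k))
    pos = [genes[k] for k in order]
    n = len(pos)

    def valid(i: int, j: int) -> bool:
        if max_members is not None and j - i + 1 > max_members:
            return False
        span = max(e for _, e in pos[i : j + 1]) - min(s for s, _ in pos[i : j + 1])
        return span <= span_bp

    out = []
    i = 0
    while i < n:
        j = i
        for k in range(i, n):
            if valid(i, k):
                j = k
            else:
                break
        if j - i + 1 >= min_members:
            out.append(tuple(order[i : j + 1]))
        i = j + 1
    return out
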