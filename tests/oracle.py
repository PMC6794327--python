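"""Independent brute-force oracles used only by the tests.

The affine-gap local alignment DP below is written directly from the
recurrences (three matrices, gap of length g costing open + g*extend)
and stays independent of the package's alignment backend.
"""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_affine_score(a: str, b: str, *, matrix=None, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    """Optimal Smith-Waterman score with affine gaps (exhaustive DP)."""
    matrix = matrix if matrix is not None else _BLOSUM62
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                                       Iy[i - 1][j - 1]))
            if M[i][j] > best:
                best = M[i][j]
    return best
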