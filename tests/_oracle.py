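"""Independent naive oracles used only by the test suite.

The full-matrix affine-gap local-alignment DP below is written from the
recurrences directly (Gotoh's three-matrix formulation with a zero floor)
and shares no code with the package's aligner.
"""

from __future__ import annotations

NEG = float("-inf")


def naive_local_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Optimal Smith-Waterman score; gap of length g costs open + (g-1)*extend."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]  # best ending in a match/mismatch or 0
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consuming b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)
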