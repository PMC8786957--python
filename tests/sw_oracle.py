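"""Independent brute-force Gotoh oracle used only by the test suite.

Written as a plain, unoptimised three-matrix dynamic program over Python
dicts, deliberately sharing no code with the package implementation.  It is
score-only: equality of the optimal local-alignment score is the property
being certified.
"""

from __future__ import annotations

NEG = float("-inf")


def local_align_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -4,
    gap_open: int = -6,
    gap_extend: int = -1,
) -> int:
    """Best Smith-Waterman score with affine gaps (gap of k costs open + k*extend)."""
    a, b = a.upper(), b.upper()
    m, n = len(a), len(b)
    best = 0
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                s = match
            else:
                s = mismatch
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend,
                          E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend,
                          F[i - 1][j] + gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
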