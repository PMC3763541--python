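"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the aligner oracle
is a full-matrix affine-gap dynamic program, the index oracle a naive
window scan, the quality oracle an explicit enumeration of windows.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_score_affine(
    target: str,
    query: str,
    match: int = 1,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> float:
    """Optimal local alignment score, affine gaps costing
    gap_open + L * gap_extend for a length-L gap. Full O(nm) matrices."""
    n, m = len(target), len(query)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (consumes query)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes target)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            s = match if target[i - 1] == query[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def scan_occurrences(subject: str, tile: str) -> list[int]:
    """All (overlapping) exact occurrence offsets of tile in subject."""
    k = len(tile)
    return [i for i in range(len(subject) - k + 1) if subject[i : i + k] == tile]


def scan_occurrences_fast(subject: str, tile: str) -> list[int]:
    """Same contract as scan_occurrences via repeated str.find (for large
    subjects); still independent of the package's k-mer index."""
    out = []
    pos = subject.find(tile)
    while pos != -1:
        out.append(pos)
        pos = subject.find(tile, pos + 1)
    return out


def any_window_below(qual, window: int, min_avg: float) -> bool:
    """Explicit enumeration of every sliding window (whole read if shorter)."""
    n = len(qual)
    if n == 0:
        return False
    w = min(window, n)
    return any(sum(qual[i : i + w]) / w < min_avg for i in range(n - w + 1))
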