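"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the local-alignment
oracle is a plain Gotoh dynamic program, and the column-classification
oracle enumerates the definition directly.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, match: int = 2, mismatch: int = -3,
                      gap_open: int = -5, gap_ext: int = -2) -> int:
    """Optimal local alignment score under affine gaps, where a gap of
    length L costs gap_open + L * gap_ext."""
    n, m = len(a), len(b)
    M = [[0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0, s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                                     Y[i - 1][j - 1], 0))
            X[i][j] = max(M[i - 1][j] + gap_open + gap_ext, X[i - 1][j] + gap_ext)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_ext, Y[i][j - 1] + gap_ext)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def classify_column(target_bases: dict[str, str]) -> tuple[str, str | None]:
    """Direct enumeration of the column classes over target rows."""
    vals = list(target_bases.values())
    if "-" in vals:
        return "gapped", None
    distinct = set(vals)
    if len(distinct) == 1:
        return "invariant", None
    if len(target_bases) >= 3 and len(distinct) == 2:
        for sp, base in target_bases.items():
            others = [v for o, v in target_bases.items() if o != sp]
            if len(set(others)) == 1 and base != others[0]:
                return "species_specific", sp
    if len(distinct) == 2:
        return "degenerate_ok", None
    return "other", None
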