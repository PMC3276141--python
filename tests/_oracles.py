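"""Independent brute-force oracles used to validate the alignment engine.

These enumerate every possible gapped alignment recursively, with no
dynamic programming and no shared code with the implementation they
check. Exponential, so only usable for short sequences — which is the
point.
"""

from __future__ import annotations


def oracle_global_score(
    a: str, b: str, match: float = 1, mismatch: float = -1, gap: float = -2
) -> float:
    """Best global alignment score by exhaustive path enumeration."""
    n, m = len(a), len(b)

    def rec(i: int, j: int) -> float:
        if i == n and j == m:
            return 0
        best = None
        if i < n and j < m:
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            best = rec(i + 1, j + 1) + s
        if i < n:
            v = rec(i + 1, j) + gap
            best = v if best is None else max(best, v)
        if j < m:
            v = rec(i, j + 1) + gap
            best = v if best is None else max(best, v)
        return best

    return rec(0, 0)


def oracle_local_score(
    a: str, b: str, match: float = 1, mismatch: float = -1, gap: float = -2
) -> float:
    """Best local score: max global score over all substring pairs, floored
    at zero (the empty local alignment)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(
                        best,
                        oracle_global_score(a[i1:i2], b[j1:j2], match, mismatch, gap),
                    )
    return best
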