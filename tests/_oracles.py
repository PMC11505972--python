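"""Independent brute-force oracles used to cross-check the implementation.

Everything in here is deliberately naive and shares no code path with the
package: alignment scoring is exhaustive enumeration over all monotone
alignment paths, and run detection is a direct window scan of the match
line.
"""

from __future__ import annotations

from itertools import product

GAP = "-"


def score_gapped_pair(
    gapped_a: str,
    gapped_b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Score an explicit gapped alignment: affine internal gaps, free end gaps.

    A gap run touching either end of the alignment costs nothing; an
    internal gap run of length L costs gap_open + (L - 1) * gap_extend.
    """
    assert len(gapped_a) == len(gapped_b)
    n = len(gapped_a)
    score = 0.0
    for a, b in zip(gapped_a, gapped_b):
        if a != GAP and b != GAP:
            score += match if a == b else mismatch
    for row in (gapped_a, gapped_b):
        i = 0
        while i < n:
            if row[i] == GAP:
                j = i
                while j < n and row[j] == GAP:
                    j += 1
                if i != 0 and j != n:  # internal run only
                    score -= gap_open + (j - i - 1) * gap_extend
                i = j
            else:
                i += 1
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as a (gapped_a, gapped_b) pair.

    Columns with gaps in both rows are never produced.  Exponential; only
    for short strings.
    """
    stack = [(0, 0, "", "")]
    while stack:
        i, j, ga, gb = stack.pop()
        if i == len(a) and j == len(b):
            yield ga, gb
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, ga + a[i], gb + b[j]))
        if i < len(a):
            stack.append((i + 1, j, ga + a[i], gb + GAP))
        if j < len(b):
            stack.append((i, j + 1, ga + GAP, gb + b[j]))


def best_score_bruteforce(a: str, b: str, **scoring) -> float:
    """Optimal global alignment score by exhaustive enumeration."""
    return max(score_gapped_pair(ga, gb, **scoring) for ga, gb in enumerate_alignments(a, b))


def naive_first_run(match_line: str, n: int) -> int | None:
    """First index i such that match_line[i:i+n] is n consecutive '|', else None."""
    target = "|" * n
    for i in range(len(match_line) - n + 1):
        if match_line[i : i + n] == target:
            return i
    return None


def ungapped_pos(gapped: str, col: int) -> int:
    """Number of residues of the row consumed strictly before alignment column col."""
    return sum(1 for c in gapped[:col] if c != GAP)
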