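"""Brute-force reference implementations used only by the tests.

Each oracle is deliberately naive — enumeration or linear scanning —
and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def concretizations(pattern: str) -> list[str]:
    """Every concrete DNA string matching an IUPAC pattern."""
    return ["".join(p) for p in itertools.product(*(IUPAC_SETS[s] for s in pattern))]


def brute_force_scan(seq: str, pattern: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (1-based start, min-Hamming) windows within the mismatch budget.

    Minimum is taken over every concretization of the pattern; a subject
    'N' never equals a concrete base, so it always counts as a mismatch.
    """
    concs = concretizations(pattern)
    m = len(pattern)
    out = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        d = min(sum(a != b for a, b in zip(window, c)) for c in concs)
        if d <= max_mismatches:
            out.append((i + 1, d))
    return out


def cursor_map(ref_row: str, position: int) -> int:
    """1-based alignment column of the position-th non-gap char of ref_row."""
    seen = 0
    for c, ch in enumerate(ref_row, start=1):
        if ch != "-":
            seen += 1
            if seen == position:
                return c
    raise ValueError("position beyond ungapped length")


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b) strings."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def affine_score(row_a: str, row_b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Score one alignment; a gap run of length L costs gap_open + L*gap_extend."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-":
            score -= gap_extend + (gap_open if not in_gap_a else 0.0)
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend + (gap_open if not in_gap_b else 0.0)
            in_gap_a, in_gap_b = False, True
        else:
            score += matrix[x, y]
            in_gap_a = in_gap_b = False
    return score


def best_alignment_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    return max(
        affine_score(ra, rb, matrix, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )
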