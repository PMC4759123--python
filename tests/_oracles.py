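"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: alignment scores come
from exhaustive enumeration of every global alignment (and, separately,
from Biopython's PairwiseAligner); SASA references come from closed-form
sphere/cap formulas and Biopython's Shrake-Rupley implementation.
"""

from __future__ import annotations

import math
from functools import lru_cache


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of ``a`` and ``b`` as (row_a, row_b).

    Moves are diagonal, up (gap in b) and left (gap in a); a gap is never
    aligned to a gap.
    """
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


def score_alignment(row_a: str, row_b: str, matrix, gap_open: float,
                    gap_extend: float, end_gaps_penalized: bool) -> float:
    """Score one explicit alignment under affine gap costs.

    A gap run of length L costs gap_open + (L-1)*gap_extend; runs lying
    entirely before the first or after the last residue of their row are
    free unless end gaps are penalized.
    """
    total = 0.0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            total += matrix.score(ca, cb)
    for row in (row_a, row_b):
        first = min(i for i, c in enumerate(row) if c != "-")
        last = max(i for i, c in enumerate(row) if c != "-")
        i = 0
        n = len(row)
        while i < n:
            if row[i] != "-":
                i += 1
                continue
            j = i
            while j < n and row[j] == "-":
                j += 1
            run = j - i
            is_end = j <= first or i > last
            if end_gaps_penalized or not is_end:
                total -= gap_open + (run - 1) * gap_extend
            i = j
    return total


def brute_force_best_score(a: str, b: str, matrix, gap_open: float,
                           gap_extend: float,
                           end_gaps_penalized: bool) -> float:
    return max(
        score_alignment(ra, rb, matrix, gap_open, gap_extend,
                        end_gaps_penalized)
        for ra, rb in enumerate_alignments(a, b)
    )


def two_sphere_sasa(r1: float, r2: float, d: float) -> float:
    """Closed-form accessible area of two probe-expanded spheres.

    Each sphere loses a spherical cap where the other overlaps it.
    """
    if d >= r1 + r2:
        return 4 * math.pi * (r1 * r1 + r2 * r2)
    total = 0.0
    for ra, rb in ((r1, r2), (r2, r1)):
        if d + ra <= rb:
            continue  # fully engulfed
        h = ra - (d * d + ra * ra - rb * rb) / (2 * d)
        total += 4 * math.pi * ra * ra - 2 * math.pi * ra * h
    return total


@lru_cache(maxsize=None)
def biopython_aligner(gap_open: float, gap_extend: float,
                      end_gaps_penalized: bool):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = \
        Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    if not end_gaps_penalized:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner
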