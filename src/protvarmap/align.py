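"""Global pairwise protein alignment with affine gap penalties.

A Gotoh-style dynamic program parameter-compatible with EMBOSS ``needle``:
BLOSUM62 scoring by default, gap open 10.0, gap extend 0.5, and end gaps
free unless ``end_gaps_penalized`` is set.  A gap of length ``L`` costs
``gap_open + (L - 1) * gap_extend`` — the first gapped column is charged
the opening penalty only.

Traceback ties are broken deterministically (diagonal over up over left),
which fixes the pairing but never the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AlignParams",
    "Alignment",
    "SubstitutionMatrix",
    "load_matrix",
    "matrix_score",
    "global_align",
    "AlphabetError",
]

GAP = "-"
_NEG = -1.0e18  # effectively -infinity, safe under addition
_TOL = 1e-9


class AlphabetError(ValueError):
    """A sequence letter is absent from the substitution matrix."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    name: str
    alphabet: str
    scores: np.ndarray  # square, symmetric

    def index(self, aa: str) -> int:
        i = self.alphabet.find(aa)
        if i < 0:
            raise AlphabetError(
                f"letter {aa!r} not in matrix {self.name} alphabet"
            )
        return i

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.index(a), self.index(b)])

    def encode(self, seq: str) -> np.ndarray:
        return np.array([self.index(c) for c in seq], dtype=np.intp)


def _parse_matrix_text(name: str, text: str) -> SubstitutionMatrix:
    rows: dict[str, list[float]] = {}
    alphabet: list[str] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if not alphabet:
            alphabet = fields
            continue
        rows[fields[0]] = [float(v) for v in fields[1:]]
    n = len(alphabet)
    m = np.zeros((n, n))
    for i, a in enumerate(alphabet):
        if a not in rows or len(rows[a]) != n:
            raise ValueError(f"matrix {name}: malformed row for {a!r}")
        m[i, :] = rows[a]
    if not np.array_equal(m, m.T):
        raise ValueError(f"matrix {name} is not symmetric")
    return SubstitutionMatrix(name, "".join(alphabet), m)


def load_matrix(name: str = "EBLOSUM62") -> SubstitutionMatrix:
    """Load a named matrix shipped with the package, in EMBOSS syntax."""
    text = resources.files("protvarmap.data").joinpath(name).read_text()
    return _parse_matrix_text(name, text)


def matrix_score(matrix: SubstitutionMatrix, aa1: str, aa2: str) -> float:
    """Symmetric substitution score lookup."""
    return matrix.score(aa1, aa2)


@dataclass(frozen=True)
class AlignParams:
    """Needle-compatible scoring parameters (gap_open >= gap_extend >= 0)."""

    matrix: SubstitutionMatrix = field(default_factory=load_matrix)
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_penalized: bool = False

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """(index into a, index into b) for residue-residue columns."""
        out = []
        i = j = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != GAP and cb != GAP:
                out.append((i, j))
            if ca != GAP:
                i += 1
            if cb != GAP:
                j += 1
        return out


# DP states; preference order for tie-breaks is M (diagonal), then X (up,
# gap in b), then Y (left, gap in a).
_M, _X, _Y = 0, 1, 2


def global_align(a: str, b: str, p: AlignParams | None = None) -> Alignment:
    """Optimal global alignment of protein sequences ``a`` and ``b``.

    Returns the maximum-score alignment under ``p``; with free end gaps
    (the default) leading and trailing gap runs cost nothing, matching
    ``needle``'s endweight=false behaviour.
    """
    if p is None:
        p = AlignParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sub = p.matrix.scores[np.ix_(p.matrix.encode(a), p.matrix.encode(b))]
    n, m = len(a), len(b)
    go, ge = p.gap_open, p.gap_extend
    end = p.end_gaps_penalized

    V = np.full((3, n + 1, m + 1), _NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    V[_M, 0, 0] = 0.0
    for i in range(1, n + 1):
        V[_X, i, 0] = (-(go + (i - 1) * ge)) if end else 0.0
        ptr[_X, i, 0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        V[_Y, 0, j] = (-(go + (j - 1) * ge)) if end else 0.0
        ptr[_Y, 0, j] = _Y if j > 1 else _M

    def best(cands: tuple[float, float, float]) -> tuple[float, int]:
        # first index wins ties -> diagonal-first determinism
        k = 0
        for t in (1, 2):
            if cands[t] > cands[k] + _TOL:
                k = t
        return cands[k], k

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            v, k = best((V[_M, i - 1, j - 1], V[_X, i - 1, j - 1],
                         V[_Y, i - 1, j - 1]))
            V[_M, i, j] = v + sub[i - 1, j - 1]
            ptr[_M, i, j] = k
            # vertical move consumes a[i-1]; free in the first/last column
            # of b when end gaps are unpenalized
            if not end and (j == m):
                v, k = best((V[_M, i - 1, j], V[_X, i - 1, j],
                             V[_Y, i - 1, j]))
            else:
                v, k = best((V[_M, i - 1, j] - go, V[_X, i - 1, j] - ge,
                             V[_Y, i - 1, j] - go))
            V[_X, i, j] = v
            ptr[_X, i, j] = k
            # horizontal move consumes b[j-1]
            if not end and (i == n):
                v, k = best((V[_M, i, j - 1], V[_X, i, j - 1],
                             V[_Y, i, j - 1]))
            else:
                v, k = best((V[_M, i, j - 1] - go, V[_X, i, j - 1] - go,
                             V[_Y, i, j - 1] - ge))
            V[_Y, i, j] = v
            ptr[_Y, i, j] = k

    score, state = best((V[_M, n, m], V[_X, n, m], V[_Y, n, m]))

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
        state = prev

    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     float(score))
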