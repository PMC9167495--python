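"""Global pairwise protein alignment (Needleman-Wunsch / Gotoh, affine gaps).

A deterministic end-to-end aligner used to pair up homologous domain regions
before codon back-threading, and to map sushi-domain key columns between
sequences.  Defaults are BLOSUM62 with gap open -11 / extend -1 (the opening
score applies to the first residue of a gap).  Ties are broken in a fixed
order — diagonal, then gap in ``b`` (up), then gap in ``a`` (left) — so the
same inputs always give the same alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e30  # effectively -inf without nan propagation


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __iter__(self):
        return iter((self.aligned_a, self.aligned_b))


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    index = {ch: i for i, ch in enumerate(alphabet)}
    return np.asarray(mat, dtype=float), index


def _encode(seq: str, index: dict[str, int], label: str) -> np.ndarray:
    try:
        return np.fromiter((index[ch] for ch in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-residue character {exc.args[0]!r} in sequence {label}") from None


def align_proteins_nw(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences with affine gaps.

    Gaps may follow gaps (the opening score is charged again when switching
    which sequence is gapped).  End gaps are penalized.  Raises ``ValueError``
    on empty sequences or characters absent from the substitution matrix.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    submat, index = _load_matrix(matrix)
    ea, eb = _encode(a, index, "a"), _encode(b, index, "b")
    n, m = len(a), len(b)
    # scores[i, j] = substitution score of a[i-1] vs b[j-1]
    scores = submat[np.ix_(ea, eb)]

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b: a-residue over '-'
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a: '-' over b-residue
    M[0, 0] = 0.0
    Ix[1:, 0] = gap_open + gap_extend * np.arange(n)
    Iy[0, 1:] = gap_open + gap_extend * np.arange(m)

    jidx = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(M[i - 1], np.maximum(Ix[i - 1], Iy[i - 1]))
        M[i, 1:] = prev_best[:-1] + scores[i - 1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + gap_open,
            Ix[i - 1, 1:] + gap_extend,
        )
        if i == 1:
            Ix[1, 0] = gap_open  # already set; keep row consistent
        # Iy within-row recurrence as a running max:
        #   Iy[i, j] = max_{k<j}( max(M,Ix)[i, k] + open + (j-1-k)*extend )
        base = np.maximum(M[i], Ix[i]) - jidx * gap_extend
        run = np.maximum.accumulate(base[:-1])
        Iy[i, 1:] = np.maximum(
            Iy[i, 1:], run + gap_open + (jidx[1:] - 1) * gap_extend
        )
    return _traceback(a, b, M, Ix, Iy, scores, gap_open, gap_extend)


def _traceback(a, b, M, Ix, Iy, scores, gap_open, gap_extend) -> PairwiseAlignment:
    i, j = len(a), len(b)
    # preference order on ties: M (diagonal) > Ix (up) > Iy (left)
    state = max(("M", "Ix", "Iy"), key=lambda s: ({"M": M, "Ix": Ix, "Iy": Iy}[s][i, j], s == "M", s == "Ix"))
    score = {"M": M, "Ix": Ix, "Iy": Iy}[state][i, j]
    out_a: list[str] = []
    out_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - scores[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if abs(mat[i, j] - target) <= tol:
                    state = s
                    break
        elif state == "Ix":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = Ix[i, j]
            i -= 1
            if abs(M[i, j] + gap_open - val) <= tol:
                state = "M"
            elif abs(Ix[i, j] + gap_extend - val) <= tol:
                state = "Ix"
            else:
                state = "Iy"
        else:  # Iy
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Iy[i, j]
            j -= 1
            if abs(M[i, j] + gap_open - val) <= tol:
                state = "M"
            elif abs(Ix[i, j] + gap_open - val) <= tol:
                state = "Ix"
            else:
                state = "Iy"
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score))


__all__ = ["PairwiseAlignment", "align_proteins_nw"]
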