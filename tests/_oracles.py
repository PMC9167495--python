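"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (exhaustive enumeration,
direct formulas) and deliberately shares no logic with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_FWD = dict(_TABLE.forward_table)
SENSE = sorted(c for c in _FWD if set(c) <= set("ACGT"))


# ---------------------------------------------------------------------------
# Pattern matching by exhaustive window enumeration


def _char_ok(element, ch: str) -> bool:
    from ctldcp.patterns import ElementKind

    if element.kind is ElementKind.ANY:
        return ch in AA20 or ch == "X"
    if ch == "X":
        return False
    if element.kind is ElementKind.EXCLUDE:
        return ch in AA20 and ch not in element.residues
    return ch in element.residues


def _can_match(elements, text: str) -> bool:
    """True if some repeat-count assignment makes the elements consume the
    whole text (recursive enumeration)."""
    if not elements:
        return text == ""
    el = elements[0]
    for r in range(el.repeat_min, el.repeat_max + 1):
        if r > len(text):
            break
        if all(_char_ok(el, text[i]) for i in range(r)):
            if _can_match(elements[1:], text[r:]):
                return True
        else:
            break  # a longer repeat would include the same failing char
    return False


def oracle_match(pattern, sequence: str) -> list[tuple[int, int]]:
    """All (start, end) 1-based closed hits, shortest per start, by trying
    every window length exhaustively."""
    hits = []
    n = len(sequence)
    for s in range(n):
        max_len = min(pattern.max_length, n - s)
        for length in range(pattern.min_length, max_len + 1):
            if _can_match(list(pattern.elements), sequence[s : s + length]):
                hits.append((s + 1, s + length))
                break
    return hits


# ---------------------------------------------------------------------------
# NG86 by direct enumeration


@lru_cache(maxsize=None)
def oracle_codon_sites(codon: str) -> float:
    """Synonymous sites of one codon; per position the fraction of non-stop
    single-nucleotide changes that preserve the amino acid."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            tot += 1
            if _FWD[mut] == _FWD[codon]:
                syn += 1
        if tot:
            s += syn / tot
    return s


@lru_cache(maxsize=None)
def oracle_pair_diffs(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over all shortest stop-free substitution pathways
    (all pathways if every one is blocked)."""
    positions = [p for p in range(3) if a[p] != b[p]]
    if not positions:
        return 0.0, 0.0
    valid_syn, all_syn = [], []
    for order in itertools.permutations(positions):
        cur = a
        syn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            elif cur not in _STOPS and _FWD[cur] == _FWD[nxt]:
                syn += 1
            cur = nxt
        all_syn.append(syn)
        if not blocked:
            valid_syn.append(syn)
    chosen = valid_syn or all_syn
    sd = sum(chosen) / len(chosen)
    return sd, len(positions) - sd


def oracle_ng86_counts(codons_a, codons_b) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for a retained-column codon alignment."""
    L = len(codons_a)
    S = 0.5 * (
        sum(oracle_codon_sites(c) for c in codons_a)
        + sum(oracle_codon_sites(c) for c in codons_b)
    )
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sd, nd = oracle_pair_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return S, 3 * L - S, Sd, Nd


# ---------------------------------------------------------------------------
# Global alignment score by exhaustive enumeration (short strings)


def oracle_global_score(a: str, b: str, submat, index, gap_open=-11.0, gap_extend=-1.0):
    """Maximum global alignment score over all alignments, enumerated
    recursively; the first residue of every gap costs gap_open."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        # prev: 'M' match, 'A' gap in b (a consumed), 'B' gap in a
        if i == len(a) and j == len(b):
            return 0.0
        candidates = []
        if i < len(a) and j < len(b):
            candidates.append(submat[index[a[i]], index[b[j]]] + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open
            candidates.append(cost + best(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open
            candidates.append(cost + best(i, j + 1, "B"))
        return max(candidates)

    return best(0, 0, "M")
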