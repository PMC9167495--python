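"""Standard genetic code helpers shared by the Ka/Ks estimators and simulators.

Translation table 1 only; terminal stop codons are expected to be stripped
upstream of any per-codon computation.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _STANDARD.forward_table if set(c) <= set(NUCLEOTIDES))
)
CODON_TO_AA: dict[str, str] = {c: _STANDARD.forward_table[c] for c in SENSE_CODONS}

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return (a in PURINES) == (b in PURINES)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS with the standard code; raises on length not a
    multiple of 3 or internal stops."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    protein = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at nucleotide {i + 1}")
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"unrecognized codon {codon!r} at nucleotide {i + 1}")
        protein.append(aa)
    return "".join(protein)


def strip_terminal_stop(cds: str) -> str:
    """Drop a trailing stop codon if present (no-op otherwise)."""
    cds = cds.upper()
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def codon_neighbors(codon: str):
    """Yield (position 0-2, new nucleotide, mutant codon) over all nine
    single-nucleotide neighbors, stops included."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, nt, codon[:pos] + nt + codon[pos + 1 :]


def back_translate(protein: str, rng) -> str:
    """Random synonymous back-translation of a protein (seeded rng)."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for aa in protein:
        choices = by_aa.get(aa)
        if not choices:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def reverse_translate_check(protein: str, cds: str) -> None:
    """Raise if the CDS does not translate exactly to the protein."""
    observed = translate_cds(strip_terminal_stop(cds))
    if observed != protein:
        for i, (p, o) in enumerate(zip(protein, observed)):
            if p != o:
                raise ValueError(
                    f"protein/CDS mismatch at residue {i + 1}: {p!r} vs {o!r}"
                )
        raise ValueError(
            f"protein/CDS length mismatch: {len(protein)} vs {len(observed)} residues"
        )


__all__ = [
    "NUCLEOTIDES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_TO_AA",
    "CODON_INDEX",
    "is_transition",
    "translate_cds",
    "strip_terminal_stop",
    "codon_neighbors",
    "back_translate",
    "reverse_translate_check",
]
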