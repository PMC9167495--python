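"""PROSITE-style motif patterns and EGF-like domain subtype classification.

The pattern dialect is the compact one used in domain annotation practice:
uppercase literal residues, ``x`` for any residue, bracketed residue classes
(``[GP]``), excluded classes (``{P}``), a repeat suffix ``(n)`` or ``(n,m)``
and optional ``-`` separators.  Three one-letter shorthands carry class
meaning by default: ``N`` = negatively charged or polar residue [DEQN],
``B`` = possibly beta-hydroxylated residue [DN], ``A`` = aromatic residue
[FYW].  Coordinates are 1-based closed intervals.

EGF-like subtypes follow the signature logic used for group XIV CTLDcps:

* EGF 1  — matches PS00022 ``CxCx(5)Gx(2)C``
* EGF 2  — matches PS01186 ``CxCx(2)[GP][FYW]x(4,8)C``
* cbEGF  — EGF 2 that additionally carries the calcium-binding signature
  PS01187 ``NxNNC-x(3,14)-C-x(3,7)-CxxBxxxxAxC-x(1,6)-C-x(8,13)-Cx``
* EGF_like — carries none of the above
* Tme5EGF — Thrombomodulin's fifth EGF; annotated upstream (CDD cl07616),
  never produced by sequence classification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: default one-letter class shorthands (overridable per parse call)
DEFAULT_SHORTHAND: dict[str, frozenset[str]] = {
    "N": frozenset("DEQN"),  # negatively charged or polar
    "B": frozenset("DN"),  # possibly beta-hydroxylated
    "A": frozenset("FYW"),  # aromatic
}


class PatternError(ValueError):
    """Malformed pattern text; carries the 1-based offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ElementKind(enum.Enum):
    LITERAL = "literal"
    ANY = "any"
    CLASS = "class"
    EXCLUDE = "exclude"


@dataclass(frozen=True)
class PatternElement:
    kind: ElementKind
    residues: frozenset[str]  # empty for ANY
    repeat_min: int = 1
    repeat_max: int = 1
    token: str = field(default="", compare=False)  # display form, e.g. shorthand letter

    def __post_init__(self):
        if self.repeat_min < 1 or self.repeat_max < self.repeat_min:
            raise ValueError(
                f"invalid repeat range ({self.repeat_min},{self.repeat_max})"
            )

    def matches_char(self, ch: str) -> bool:
        # 'X' (unknown residue) matches only the wildcard, never literals,
        # classes or exclusions — conservative.
        if self.kind is ElementKind.ANY:
            return ch in _AA_SET or ch == "X"
        if ch == "X":
            return False
        if self.kind is ElementKind.LITERAL or self.kind is ElementKind.CLASS:
            return ch in self.residues
        return ch in _AA_SET and ch not in self.residues  # EXCLUDE


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[PatternElement, ...]

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern must contain at least one element")

    @property
    def min_length(self) -> int:
        return sum(e.repeat_min for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.repeat_max for e in self.elements)


class EgfSubtype(enum.Enum):
    EGF1 = "EGF1"
    EGF2 = "EGF2"
    CBEGF = "cbEGF"
    EGF_LIKE = "EGF_like"
    TME5EGF = "Tme5EGF"


def parse_pattern(
    text: str,
    name: str = "",
    shorthand: dict[str, frozenset[str]] | None = None,
) -> MotifPattern:
    """Parse a compact pattern string into a :class:`MotifPattern`.

    Raises :class:`PatternError` naming the 1-based offending position on
    malformed bracket or repeat syntax.
    """
    if shorthand is None:
        shorthand = DEFAULT_SHORTHAND
    elements: list[PatternElement] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "-":
            i += 1
            continue
        start = i
        if ch == "x":
            kind, residues, token = ElementKind.ANY, frozenset(), "x"
            i += 1
        elif ch in "[{":
            closer = "]" if ch == "[" else "}"
            j = text.find(closer, i + 1)
            if j < 0:
                raise PatternError(f"unbalanced '{ch}'", i + 1)
            body = text[i + 1 : j]
            if not body or not set(body) <= _AA_SET:
                raise PatternError(f"invalid residue class '{body}'", i + 2)
            kind = ElementKind.CLASS if ch == "[" else ElementKind.EXCLUDE
            residues, token = frozenset(body), text[i : j + 1]
            i = j + 1
        elif ch.isalpha() and ch.isupper():
            if ch in shorthand:
                kind, residues = ElementKind.CLASS, shorthand[ch]
            elif ch in _AA_SET:
                kind, residues = ElementKind.LITERAL, frozenset(ch)
            else:
                raise PatternError(f"unknown residue code '{ch}'", i + 1)
            token = ch
            i += 1
        else:
            raise PatternError(f"unexpected character '{ch}'", i + 1)
        rep_min = rep_max = 1
        if i < n and text[i] == "(":
            j = text.find(")", i + 1)
            if j < 0:
                raise PatternError("unbalanced '('", i + 1)
            body = text[i + 1 : j]
            parts = body.split(",")
            try:
                if len(parts) == 1:
                    rep_min = rep_max = int(parts[0])
                elif len(parts) == 2:
                    rep_min, rep_max = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                raise PatternError(f"malformed repeat '({body})'", i + 1) from None
            if rep_min < 1 or rep_max < rep_min:
                raise PatternError(f"invalid repeat range '({body})'", i + 1)
            i = j + 1
        elements.append(
            PatternElement(kind, residues, rep_min, rep_max, token=token or text[start])
        )
    if not elements:
        raise PatternError("empty pattern", 1)
    return MotifPattern(name=name, elements=tuple(elements))


def render_pattern(pattern: MotifPattern) -> str:
    """Compact text form; ``parse_pattern(render_pattern(p))`` equals ``p``."""
    parts = []
    for e in pattern.elements:
        if e.token:
            tok = e.token
        elif e.kind is ElementKind.ANY:
            tok = "x"
        elif e.kind is ElementKind.LITERAL:
            tok = next(iter(e.residues))
        else:
            body = "".join(sorted(e.residues))
            tok = f"[{body}]" if e.kind is ElementKind.CLASS else f"{{{body}}}"
        if (e.repeat_min, e.repeat_max) != (1, 1):
            tok += (
                f"({e.repeat_min})"
                if e.repeat_min == e.repeat_max
                else f"({e.repeat_min},{e.repeat_max})"
            )
        parts.append(tok)
    return "".join(parts)


def _shortest_match_end(pattern: MotifPattern, seq: str, start: int) -> int | None:
    """Exclusive end offset of the shortest match beginning at 0-based ``start``,
    or None.  Reachability sweep over elements — no backtracking needed."""
    reachable = {start}
    for el in pattern.elements:
        nxt: set[int] = set()
        for p in reachable:
            run = 0
            limit = min(el.repeat_max, len(seq) - p)
            while run < limit and el.matches_char(seq[p + run]):
                run += 1
            for r in range(el.repeat_min, run + 1):
                nxt.add(p + r)
        if not nxt:
            return None
        reachable = nxt
    return min(reachable)


def match_pattern(pattern: MotifPattern, sequence: str) -> list[tuple[int, int]]:
    """All matches of ``pattern`` in ``sequence`` as 1-based closed intervals.

    Every start position with a match is reported; for variable repeats the
    shortest match at each start is returned.  Returns an empty list when
    nothing matches.
    """
    sequence = sequence.upper()
    hits = []
    last = len(sequence) - pattern.min_length
    for s in range(last + 1):
        end = _shortest_match_end(pattern, sequence, s)
        if end is not None:
            hits.append((s + 1, end))
    return hits


# ---------------------------------------------------------------------------
# Signature table and EGF subtype classification

DEFAULT_SIGNATURE_TEXT = """\
PS00022\tCxCx(5)Gx(2)C
PS01186\tCxCx(2)[GP][FYW]x(4,8)C
PS01187\tNxNNC-x(3,14)-C-x(3,7)-CxxBxxxxAxC-x(1,6)-C-x(8,13)-Cx
"""


def load_signature_table(path: str | Path | None = None) -> dict[str, MotifPattern]:
    """Load a name<TAB>pattern table; the three default EGF signatures when no
    path is given."""
    if path is None:
        lines = DEFAULT_SIGNATURE_TEXT.splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    table: dict[str, MotifPattern] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, text = line.partition("\t")
        if not text:
            raise ValueError(f"signature table line lacks a pattern: {line!r}")
        table[name] = parse_pattern(text.strip(), name=name)
    return table


DEFAULT_SIGNATURES = load_signature_table()


def classify_egf(
    sequence: str,
    flanked_sequence: str | None = None,
    signatures: dict[str, MotifPattern] | None = None,
) -> EgfSubtype:
    """Classify one EGF-like domain instance by its signature hits.

    ``sequence`` is the annotated EGF interval; PS00022 and PS01186 are tested
    on it directly.  The longer calcium-binding signature PS01187 may extend
    past a short annotated core, so it is tested on ``flanked_sequence``
    (the core padded by flanking protein residues) when provided.

    Precedence: cbEGF (PS01186 and PS01187) > EGF2 (PS01186) > EGF1 (PS00022)
    > EGF_like.  Tme5EGF is never produced here — it comes from upstream
    annotation (cl07616).
    """
    if not sequence:
        raise ValueError("empty EGF domain sequence")
    sig = signatures if signatures is not None else DEFAULT_SIGNATURES
    seq = sequence.upper()
    flanked = (flanked_sequence or sequence).upper()
    has_1186 = bool(match_pattern(sig["PS01186"], seq))
    if has_1186 and match_pattern(sig["PS01187"], flanked):
        return EgfSubtype.CBEGF
    if has_1186:
        return EgfSubtype.EGF2
    if match_pattern(sig["PS00022"], seq):
        return EgfSubtype.EGF1
    return EgfSubtype.EGF_LIKE


__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_SHORTHAND",
    "DEFAULT_SIGNATURES",
    "ElementKind",
    "EgfSubtype",
    "MotifPattern",
    "PatternElement",
    "PatternError",
    "classify_egf",
    "load_signature_table",
    "match_pattern",
    "parse_pattern",
    "render_pattern",
]
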