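"""Region segmentation of group XIV CTLDcps from anchor domain annotations.

Anchor domains (CTLD, EGF-like repeats, transmembrane segment) come from an
upstream domain-prediction hit table.  The derived extracellular regions
follow fixed rules: the sushi-like region is the interval between the CTLD
and the first EGF-like domain (or the transmembrane segment when the EGFs
are absent); the mucin-like region runs from the first residue after the
last EGF to the residue before the transmembrane segment; the cytotail runs
from after the transmembrane segment to the C-terminus.  In Thrombomodulin
the CTLD-to-first-EGF interval is labeled "hydrophobic stretch" instead of
"sushi-like".  Zero-length derived regions are reported as absent.  All
coordinates are 1-based closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import align_proteins_nw
from .patterns import EgfSubtype, classify_egf

logger = logging.getLogger(__name__)

#: anchor-name normalization (CD-Search short names on the left)
DEFAULT_NAME_MAP = {
    "CLECT": "CTLD",
    "CTLD": "CTLD",
    "CLECT_DC-SIGN_like": "CTLD",
    "TM": "TM",
    "TMhelix": "TM",
}
TME5_NAMES = {"cl07616", "TME5", "Tme5-EGF"}

#: sushi-fold key residue classes: conserved Cys, Trp, Gly, Pro
SUSHI_KEY_CLASSES = (frozenset("C"), frozenset("W"), frozenset("G"), frozenset("P"))


class AnnotationError(ValueError):
    pass


class ArchitectureError(ValueError):
    pass


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    name: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"{self.protein_id}/{self.name}: invalid interval ({self.start},{self.end})"
            )


@dataclass
class RegionSet:
    """Derived per-protein region partition (1-based closed intervals)."""

    protein_id: str
    family: str
    length: int
    ctld: tuple[int, int] | None = None
    sushi: tuple[int, int] | None = None
    sushi_label: str = "sushi-like"  # "hydrophobic stretch" for Thrombomodulin
    egfs: list[tuple[tuple[int, int], EgfSubtype | None]] = field(default_factory=list)
    mucin: tuple[int, int] | None = None
    tm: tuple[int, int] | None = None
    cytotail: tuple[int, int] | None = None

    def iter_regions(self):
        """Yield (label, start, end, subtype) N-to-C for present regions."""
        if self.ctld:
            yield ("CTLD", *self.ctld, None)
        if self.sushi:
            yield ("sushi", *self.sushi, None)
        for i, (interval, subtype) in enumerate(self.egfs, start=1):
            yield (f"EGF_{i}", *interval, subtype)
        if self.mucin:
            yield ("mucin", *self.mucin, None)
        if self.tm:
            yield ("TM", *self.tm, None)
        if self.cytotail:
            yield ("cytotail", *self.cytotail, None)

    def find(self, label: str) -> tuple[int, int] | None:
        for lab, start, end, _ in self.iter_regions():
            if lab == label:
                return (start, end)
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": self.protein_id,
                "region": label,
                "start": start,
                "end": end,
                "subtype": subtype.value if subtype else "",
            }
            for label, start, end, subtype in self.iter_regions()
        ]
        return pd.DataFrame(rows, columns=["protein_id", "region", "start", "end", "subtype"])


# ---------------------------------------------------------------------------
# Hit-table loading


_COLUMN_ALIASES = {
    "protein_id": {"protein_id", "query", "Query"},
    "name": {"name", "short name", "Short name", "short_name"},
    "start": {"start", "from", "From"},
    "end": {"end", "to", "To"},
    "source": {"source", "hit type", "Hit type"},
}


def load_domain_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[DomainAnnotation]:
    """Read a CD-Search-style hit table (TSV with header).

    Required columns: protein_id, name, start, end (CD-Search spellings such
    as Query/Short name/From/To are recognized; ``column_map`` overrides).
    Annotations are validated per protein (no overlapping anchors, start <=
    end) and returned sorted by (protein_id, start).
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty and df.columns.size == 0:
        return []
    df = df.fillna("")
    rename = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        if column_map and canonical in column_map:
            rename[column_map[canonical]] = canonical
            continue
        for col in df.columns:
            if col in aliases or col.lower() in aliases:
                rename[col] = canonical
                break
    df = df.rename(columns=rename)
    missing = {"protein_id", "name", "start", "end"} - set(df.columns)
    if missing:
        raise AnnotationError(f"domain table lacks columns: {sorted(missing)}")
    annotations = [
        DomainAnnotation(
            protein_id=row.protein_id,
            name=row.name,
            start=int(row.start),
            end=int(row.end),
            source=getattr(row, "source", "") or "",
        )
        for row in df.itertuples(index=False)
    ]
    annotations.sort(key=lambda a: (a.protein_id, a.start, a.end))
    errors = []
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)
    for pid, anns in by_protein.items():
        for prev, cur in zip(anns, anns[1:]):
            if cur.start <= prev.end:
                errors.append(
                    f"{pid}: {prev.name}({prev.start},{prev.end}) overlaps "
                    f"{cur.name}({cur.start},{cur.end})"
                )
    if errors:
        raise AnnotationError("overlapping anchors: " + "; ".join(errors))
    return annotations


def _anchor_kind(name: str, name_map: dict[str, str]) -> str:
    if name in TME5_NAMES:
        return "TME5"
    if name in name_map:
        return name_map[name]
    if "EGF" in name.upper():
        return "EGF"
    return "other"


def segment_protein(
    annotations: list[DomainAnnotation],
    protein_length: int,
    family: str = "other",
    sequence: str | None = None,
    flank: int = 10,
    name_map: dict[str, str] | None = None,
    signatures=None,
) -> RegionSet:
    """Derive the region partition of one protein from its anchor annotations.

    EGF subtypes are filled by signature classification when ``sequence`` is
    given (anchors named cl07616 become Tme5EGF directly); the calcium-binding
    signature is tested with ``flank`` residues of context on each side,
    clipped to the protein.  Raises :class:`ArchitectureError` on inconsistent
    anchor order (CTLD after the first EGF, or TM before the last EGF).
    """
    if name_map is None:
        name_map = DEFAULT_NAME_MAP
    anns = sorted(annotations, key=lambda a: a.start)
    for ann in anns:
        if ann.end > protein_length:
            raise AnnotationError(
                f"{ann.protein_id}/{ann.name}: end {ann.end} beyond protein length {protein_length}"
            )
    for prev, cur in zip(anns, anns[1:]):
        if cur.start <= prev.end:
            raise AnnotationError(
                f"overlapping anchors {prev.name}({prev.start},{prev.end}) / "
                f"{cur.name}({cur.start},{cur.end})"
            )
    ctlds = [a for a in anns if _anchor_kind(a.name, name_map) == "CTLD"]
    tms = [a for a in anns if _anchor_kind(a.name, name_map) == "TM"]
    egfs = [a for a in anns if _anchor_kind(a.name, name_map) in ("EGF", "TME5")]
    if len(ctlds) > 1 or len(tms) > 1:
        raise ArchitectureError("at most one CTLD and one TM anchor expected")
    ctld = ctlds[0] if ctlds else None
    tm = tms[0] if tms else None
    if ctld and egfs and ctld.start > egfs[0].start:
        raise ArchitectureError("CTLD lies after the first EGF-like domain")
    if tm and egfs and tm.end < egfs[-1].end:
        raise ArchitectureError("TM lies before the last EGF-like domain")

    pid = anns[0].protein_id if anns else ""
    rs = RegionSet(protein_id=pid, family=family, length=protein_length)
    if family == "Thrombomodulin":
        rs.sushi_label = "hydrophobic stretch"
    if ctld:
        rs.ctld = (ctld.start, ctld.end)
    if tm:
        rs.tm = (tm.start, tm.end)
        if tm.end < protein_length:
            rs.cytotail = (tm.end + 1, protein_length)

    def derived(lo: int, hi: int) -> tuple[int, int] | None:
        return (lo, hi) if lo <= hi else None  # zero-length -> absent

    if ctld:
        boundary = egfs[0].start if egfs else (tm.start if tm else None)
        if boundary is not None:
            rs.sushi = derived(ctld.end + 1, boundary - 1)
    if egfs and tm:
        rs.mucin = derived(egfs[-1].end + 1, tm.start - 1)

    for ann in egfs:
        if _anchor_kind(ann.name, name_map) == "TME5":
            subtype: EgfSubtype | None = EgfSubtype.TME5EGF
        elif sequence is not None:
            core = sequence[ann.start - 1 : ann.end]
            lo = max(1, ann.start - flank)
            hi = min(protein_length, ann.end + flank)
            flanked = sequence[lo - 1 : hi]
            subtype = classify_egf(core, flanked, signatures=signatures)
        else:
            subtype = None
        rs.egfs.append(((ann.start, ann.end), subtype))
    return rs


# ---------------------------------------------------------------------------
# Sushi key-residue check


@dataclass(frozen=True)
class KeyResidueCheck:
    column: int  # reference position, 1-based
    expected: frozenset[str]
    observed: str  # residue or '-' for a gap/truncation
    conserved: bool


@dataclass
class SushiCheckReport:
    reference_id: str
    key_columns: tuple[tuple[int, frozenset[str]], ...]
    checks: dict[str, tuple[KeyResidueCheck, ...]]
    calls: dict[str, str]  # id -> "has_sushi" | "lacks_sushi"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seq_id, checks in self.checks.items():
            for chk in checks:
                rows.append(
                    {
                        "sequence_id": seq_id,
                        "reference_column": chk.column,
                        "expected": "".join(sorted(chk.expected)),
                        "observed": chk.observed,
                        "conserved": chk.conserved,
                        "call": self.calls[seq_id],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "sequence_id", "reference_column", "expected",
                "observed", "conserved", "call",
            ],
        )


def check_sushi_residues(
    region_sequences: list[tuple[str, str]],
    reference_id: str,
    key_columns: list[tuple[int, frozenset[str] | str]],
    tolerance: int = 0,
) -> SushiCheckReport:
    """Check conservation of sushi-fold key residues against a reference.

    Each extracted sushi-region sequence is globally aligned to the reference
    and the configured key reference columns are mapped through the
    alignment; a residue is conserved when it belongs to the expected class,
    and a gap (deletion/truncation) counts as not conserved.  A sequence
    lacking more than ``tolerance`` key columns is called ``lacks_sushi``.
    """
    seqs = dict(region_sequences)
    if reference_id not in seqs:
        raise ValueError(f"reference {reference_id!r} not among sequences")
    ref = seqs[reference_id]
    columns = tuple(
        (int(pos), frozenset(cls)) for pos, cls in key_columns
    )
    for pos, _ in columns:
        if pos < 1 or pos > len(ref):
            raise ValueError(
                f"key column {pos} outside reference {reference_id!r} (length {len(ref)})"
            )
    checks: dict[str, tuple[KeyResidueCheck, ...]] = {}
    calls: dict[str, str] = {}
    for seq_id, seq in seqs.items():
        if seq_id == reference_id:
            mapped = {pos: ref[pos - 1] for pos, _ in columns}
        else:
            aln = align_proteins_nw(ref, seq)
            mapped = {}
            ref_pos = 0
            for ra, rb in zip(aln.aligned_a, aln.aligned_b):
                if ra != "-":
                    ref_pos += 1
                    mapped[ref_pos] = rb if rb != "-" else "-"
        seq_checks = tuple(
            KeyResidueCheck(
                column=pos,
                expected=cls,
                observed=mapped.get(pos, "-"),
                conserved=mapped.get(pos, "-") in cls,
            )
            for pos, cls in columns
        )
        checks[seq_id] = seq_checks
        lost = sum(1 for c in seq_checks if not c.conserved)
        calls[seq_id] = "lacks_sushi" if lost > tolerance else "has_sushi"
    return SushiCheckReport(reference_id, columns, checks, calls)


__all__ = [
    "AnnotationError",
    "ArchitectureError",
    "DEFAULT_NAME_MAP",
    "DomainAnnotation",
    "KeyResidueCheck",
    "RegionSet",
    "SUSHI_KEY_CLASSES",
    "SushiCheckReport",
    "check_sushi_residues",
    "load_domain_table",
    "segment_protein",
]
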