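"""Conserved-synteny comparison and gene-loss mechanism classification.

A synteny block is the set of gene-family occurrences within a fixed window
(default 20 Mbp in each direction) around an anchor gene on one chromosome.
Blocks are compared at the family-label level; a locus is considered
informative when at least ``min_families`` (default 15) syntenic families
are shared.  When a target family is absent from a genome, the fate of its
reference neighbors distinguishes two loss mechanisms: *locus-preserved
loss* (the neighborhood is intact, as for Clec14A in monotremes and
marsupials) and *chromosome disruption* (neighbors dispersed or lost, as
for CD248 in birds).  Strand is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 20_000_000
DEFAULT_MIN_FAMILIES = 15
DEFAULT_RETAINED_FRACTION = 0.5


class AnchorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    family: str
    chromosome: str
    start: int
    end: int
    species: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if not self.family:
            raise ValueError(f"{self.gene_id}: empty family label")


@dataclass
class SyntenyBlock:
    anchor: GeneRecord
    window_bp: int
    members: list[GeneRecord]

    @property
    def families(self) -> set[str]:
        return {g.family for g in self.members}


@dataclass
class SyntenyReport:
    shared_families: set[str]
    count: int
    meets_threshold: bool
    absence_call: str  # present | chromosome_disruption | locus_preserved_loss | indeterminate
    retained: int = 0
    relocated: int = 0
    missing: int = 0


def load_gene_table(path: str | Path, species: str = "") -> list[GeneRecord]:
    """Read a BED-like TSV (chromosome, start, end, gene_id, family[, species]);
    coordinates are 1-based closed."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"chromosome", "start", "end", "gene_id", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    return [
        GeneRecord(
            gene_id=row.gene_id,
            family=row.family,
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            species=getattr(row, "species", species) or species,
        )
        for row in df.itertuples(index=False)
    ]


def build_block(
    genes: list[GeneRecord],
    anchor_family: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    chromosome: str | None = None,
) -> SyntenyBlock:
    """Block of genes within ``window_bp`` of the single anchor-family gene.

    Raises :class:`AnchorError` when the anchor family is absent (a candidate
    gene loss — see :func:`classify_absence`) or ambiguous.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    candidates = [g for g in genes if g.family == anchor_family]
    if chromosome is not None:
        candidates = [g for g in candidates if g.chromosome == chromosome]
    if not candidates:
        raise AnchorError(f"anchor family {anchor_family!r} not found")
    if len(candidates) > 1:
        listing = ", ".join(f"{g.gene_id}@{g.chromosome}:{g.start}" for g in candidates)
        raise AnchorError(f"ambiguous anchor for {anchor_family!r}: {listing}")
    anchor = candidates[0]
    lo, hi = anchor.start - window_bp, anchor.end + window_bp
    members = sorted(
        (
            g
            for g in genes
            if g.chromosome == anchor.chromosome and g.end >= lo and g.start <= hi
        ),
        key=lambda g: (g.start, g.end, g.gene_id),
    )
    return SyntenyBlock(anchor=anchor, window_bp=window_bp, members=members)


def shared_families(
    a: SyntenyBlock, b: SyntenyBlock, min_families: int = DEFAULT_MIN_FAMILIES
) -> SyntenyReport:
    """Family-set intersection of two blocks (symmetric)."""
    shared = a.families & b.families
    return SyntenyReport(
        shared_families=shared,
        count=len(shared),
        meets_threshold=len(shared) >= min_families,
        absence_call="present",
    )


def classify_absence(
    target_family: str,
    reference_block: SyntenyBlock,
    query_genome: list[GeneRecord],
    retained_fraction_threshold: float = DEFAULT_RETAINED_FRACTION,
    window_bp: int | None = None,
    min_families: int = DEFAULT_MIN_FAMILIES,
) -> SyntenyReport:
    """Classify the mechanism behind the absence of ``target_family``.

    Each reference neighbor family is classified in the query genome as
    retained (present on the best candidate chromosome within one window of
    the candidate locus), relocated (present elsewhere) or missing.  The
    best candidate chromosome maximizes the number of neighbor families
    present (ties broken lexicographically); the candidate locus is the
    median start of neighbor genes on it.  Calls: ``locus_preserved_loss``
    when the retained fraction is at least the threshold,
    ``chromosome_disruption`` when the relocated-plus-missing fraction
    exceeds one minus the threshold, ``indeterminate`` otherwise (and always
    when the reference block is below ``min_families``).
    """
    window = reference_block.window_bp if window_bp is None else window_bp
    neighbors = sorted(reference_block.families - {target_family})
    if any(g.family == target_family for g in query_genome):
        return SyntenyReport(set(neighbors), len(neighbors), True, "present")
    if len(neighbors) < min_families:
        logger.warning(
            "classify_absence: only %d reference neighbor families (< %d); indeterminate",
            len(neighbors), min_families,
        )
        return SyntenyReport(set(neighbors), len(neighbors), False, "indeterminate")

    neighbor_set = set(neighbors)
    by_chrom: dict[str, set[str]] = {}
    for g in query_genome:
        if g.family in neighbor_set:
            by_chrom.setdefault(g.chromosome, set()).add(g.family)
    if not by_chrom:
        return SyntenyReport(
            set(), 0, False, "chromosome_disruption",
            retained=0, relocated=0, missing=len(neighbors),
        )
    best = min(by_chrom, key=lambda c: (-len(by_chrom[c]), c))
    locus = median(
        g.start for g in query_genome if g.chromosome == best and g.family in neighbor_set
    )
    lo, hi = locus - window, locus + window
    retained_set = {
        g.family
        for g in query_genome
        if g.chromosome == best and g.family in neighbor_set and g.end >= lo and g.start <= hi
    }
    present = {g.family for g in query_genome if g.family in neighbor_set}
    relocated = present - retained_set
    missing = neighbor_set - present
    n = len(neighbors)
    retained_frac = len(retained_set) / n
    displaced_frac = (len(relocated) + len(missing)) / n
    if retained_frac >= retained_fraction_threshold:
        call = "locus_preserved_loss"
    elif displaced_frac > 1 - retained_fraction_threshold:
        call = "chromosome_disruption"
    else:
        call = "indeterminate"
    return SyntenyReport(
        shared_families=retained_set,
        count=len(retained_set),
        meets_threshold=len(retained_set) >= min_families,
        absence_call=call,
        retained=len(retained_set),
        relocated=len(relocated),
        missing=len(missing),
    )


def shared_family_matrix(
    blocks: dict[str, SyntenyBlock], min_families: int = DEFAULT_MIN_FAMILIES
) -> pd.DataFrame:
    """Pairwise shared-family counts between named blocks."""
    names = sorted(blocks)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i:]:
            count = shared_families(blocks[a], blocks[b], min_families).count
            mat.loc[a, b] = mat.loc[b, a] = count
    return mat


__all__ = [
    "AnchorError",
    "DEFAULT_MIN_FAMILIES",
    "DEFAULT_RETAINED_FRACTION",
    "DEFAULT_WINDOW_BP",
    "GeneRecord",
    "SyntenyBlock",
    "SyntenyReport",
    "build_block",
    "classify_absence",
    "load_gene_table",
    "shared_families",
    "shared_family_matrix",
]
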