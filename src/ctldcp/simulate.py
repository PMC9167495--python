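"""Synthetic data generators for every pipeline stage.

Three generators cover the study conditions end to end without any external
downloads:

* :func:`simulate_architecture` — a modular CTLDcp coding sequence
  (signal-CTLD-sushi-EGFxk-mucin-TM-cytotail) whose EGF segments embed the
  signature of their planned subtype, so segmentation plus signature
  classification recovers the plan exactly.  EGF repeat counts default to
  the family architectures: CD93 five, Clec14A one, CD248 three,
  Thrombomodulin six.  The mucin segment is enriched (>= 50 %) in
  O-glycosylatable Ser/Thr/Pro residues.
* :func:`simulate_codon_evolution` — a Gillespie (exponential-waiting-time)
  codon substitution process with single-nucleotide changes, transition
  bias ``kappa``, per-region nonsynonymous weighting ``omega`` and stop
  codons rejected; both lineages evolve ``t/2`` from the ancestor, so the
  expected number of substitutions per codon along the pair path is ``t``.
* :func:`simulate_synteny_history` — a reference chromosome neighborhood and
  a derived genome that lost the target gene either with its neighborhood
  intact (locus-preserved loss) or dispersed (chromosome disruption).

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .architecture import DomainAnnotation
from .codons import (
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    back_translate,
    codon_neighbors,
    is_transition,
    translate_cds,
)
from .patterns import EgfSubtype
from .synteny import GeneRecord

# EGF cores carrying exactly the intended signature content.  Padding and all
# surrounding segments near EGF anchors are kept cysteine-free so no signature
# can arise across a segment boundary.
EGF1_CORE = "CACAAAAAGAAC"  # matches PS00022 only
EGF2_CORE = "CACAAGFAAAAC"  # matches PS01186 only
CBEGF_CORE = (  # matches PS01187, with a PS01186 match nested in its 3' half
    "DADD" + "C" + "AAA" + "C" + "AAA" + "C" + "AADAAAAFA" + "C" + "A" + "C"
    + "AAGFAAAA" + "C" + "A"
)
EGF_LIKE_CORE = "SAEAKALAEAGA"  # no signature (cysteine-free)

_CORES = {
    EgfSubtype.EGF1: EGF1_CORE,
    EgfSubtype.EGF2: EGF2_CORE,
    EgfSubtype.CBEGF: CBEGF_CORE,
    EgfSubtype.EGF_LIKE: EGF_LIKE_CORE,
    EgfSubtype.TME5EGF: EGF_LIKE_CORE,
}

_SIGNAL_ALPHABET = "ALVMFWS"
_CTLD_ALPHABET = "ADEFGHIKLNQRSTVWY"  # cysteine-free fill; see module docstring
_SUSHI_FILL = "AEIKLRSTV"
_MUCIN_STP = "STP"
_MUCIN_OTHER = "AGVEK"
_TM_ALPHABET = "AILVFM"
_CYTOTAIL_ALPHABET = "ADEGIKLNQRSTV"
_CYTOTAIL_MOTIF = "SDGYSEL"  # planted phospho-tyrosine consensus
_CYTOTAIL_MOTIF_OFFSET = 10  # 0-based offset of the motif within the cytotail

DEFAULT_OMEGAS = {
    "signal": 0.3,
    "CTLD": 0.1,
    "sushi": 0.1,
    "EGF": 0.1,
    "mucin": 2.0,
    "TM": 0.1,
    "cytotail": 0.3,
}


@dataclass(frozen=True)
class ArchitectureTemplate:
    family: str
    egf_plan: tuple[EgfSubtype, ...]
    signal_range: tuple[int, int] = (18, 24)
    ctld_range: tuple[int, int] = (125, 135)
    sushi_range: tuple[int, int] = (55, 65)
    egf_length: int = 40
    mucin_range: tuple[int, int] = (90, 120)
    tm_range: tuple[int, int] = (21, 25)
    cytotail_range: tuple[int, int] = (40, 50)
    omegas: dict = field(default_factory=lambda: dict(DEFAULT_OMEGAS))
    kappa: float = 2.0
    t: float = 0.3

    def __post_init__(self):
        for subtype in self.egf_plan:
            if self.egf_length < len(_CORES[subtype]):
                raise ValueError(
                    f"EGF segment length {self.egf_length} below the "
                    f"{subtype.value} core length {len(_CORES[subtype])}"
                )


DEFAULT_TEMPLATES: dict[str, ArchitectureTemplate] = {
    "CD93": ArchitectureTemplate(
        "CD93",
        (EgfSubtype.EGF2, EgfSubtype.CBEGF, EgfSubtype.CBEGF,
         EgfSubtype.EGF2, EgfSubtype.EGF2),
    ),
    "Clec14A": ArchitectureTemplate(
        "Clec14A", (EgfSubtype.EGF2,), mucin_range=(60, 80), cytotail_range=(30, 40)
    ),
    "CD248": ArchitectureTemplate(
        "CD248",
        (EgfSubtype.EGF2, EgfSubtype.CBEGF, EgfSubtype.EGF2),
        mucin_range=(150, 190),
    ),
    "Thrombomodulin": ArchitectureTemplate(
        "Thrombomodulin",
        (EgfSubtype.EGF_LIKE, EgfSubtype.EGF2, EgfSubtype.CBEGF,
         EgfSubtype.CBEGF, EgfSubtype.EGF2, EgfSubtype.TME5EGF),
    ),
}


@dataclass
class SimTruth:
    seed: int | None
    regions: list  # (label, start, end, subtype-or-None), 1-based closed
    omegas: dict
    kappa: float
    t: float
    events: list = field(default_factory=list)

    def find(self, label: str):
        for lab, start, end, _ in self.regions:
            if lab == label:
                return (start, end)
        return None


@dataclass
class SimulatedProtein:
    protein_id: str
    family: str
    protein: str
    cds: str
    annotations: list
    truth: SimTruth


def _rng_of(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _draw(rng, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _length(rng, rng_range: tuple[int, int]) -> int:
    lo, hi = rng_range
    return int(rng.integers(lo, hi + 1))


def _mucin(rng, n: int) -> str:
    """Ser/Thr/Pro-enriched stretch (60 % STP by construction)."""
    n_stp = int(math.ceil(0.6 * n))
    chars = [_MUCIN_STP[i] for i in rng.integers(0, 3, size=n_stp)]
    chars += [_MUCIN_OTHER[i] for i in rng.integers(0, len(_MUCIN_OTHER), size=n - n_stp)]
    order = rng.permutation(n)
    return "".join(chars[i] for i in order)


def _sushi(rng, n: int) -> str:
    """Sushi-like region with the conserved Cys/Trp/Gly/Pro key residues placed
    away from both ends (so EGF flank windows stay cysteine-free)."""
    if n < 30:
        raise ValueError("sushi region too short")
    chars = list(_draw(rng, _SUSHI_FILL, n))
    chars[11] = "C"
    chars[19] = "W"
    chars[29] = "G"
    if n > 37:
        chars[37] = "P"
    chars[n - 17] = "C"
    return "".join(chars)


def _cytotail(rng, n: int) -> str:
    chars = list(_draw(rng, _CYTOTAIL_ALPHABET, n))
    off = _CYTOTAIL_MOTIF_OFFSET
    chars[off : off + len(_CYTOTAIL_MOTIF)] = _CYTOTAIL_MOTIF
    return "".join(chars)


def simulate_architecture(
    template: ArchitectureTemplate,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    protein_id: str | None = None,
) -> SimulatedProtein:
    """One synthetic CTLDcp: protein, CDS, anchor annotations and truth.

    The CDS translates exactly to the protein; every EGF segment embeds the
    signature of its planned subtype (centered core, alanine padding) so
    signature classification recovers the plan.
    """
    rng = _rng_of(seed, rng)
    pid = protein_id or f"{template.family}_sim"
    segments: list[tuple[str, str, EgfSubtype | None]] = []  # (kind, seq, subtype)
    segments.append(("signal", _draw(rng, _SIGNAL_ALPHABET, _length(rng, template.signal_range)), None))
    segments.append(("CTLD", _draw(rng, _CTLD_ALPHABET, _length(rng, template.ctld_range)), None))
    segments.append(("sushi", _sushi(rng, _length(rng, template.sushi_range)), None))
    for subtype in template.egf_plan:
        core = _CORES[subtype]
        pad = template.egf_length - len(core)
        seq = "A" * (pad // 2) + core + "A" * (pad - pad // 2)
        segments.append(("EGF", seq, subtype))
    if template.egf_plan:
        segments.append(("mucin", _mucin(rng, _length(rng, template.mucin_range)), None))
    segments.append(("TM", _draw(rng, _TM_ALPHABET, _length(rng, template.tm_range)), None))
    segments.append(("cytotail", _cytotail(rng, _length(rng, template.cytotail_range)), None))

    protein_parts: list[str] = []
    regions: list = []
    annotations: list[DomainAnnotation] = []
    pos = 1
    egf_index = 0
    for kind, seq, subtype in segments:
        start, end = pos, pos + len(seq) - 1
        if kind == "EGF":
            egf_index += 1
            regions.append((f"EGF_{egf_index}", start, end, subtype))
            name = "cl07616" if subtype is EgfSubtype.TME5EGF else "EGF"
            annotations.append(DomainAnnotation(pid, name, start, end, source="simulated"))
        else:
            regions.append((kind, start, end, None))
            if kind == "CTLD":
                annotations.append(DomainAnnotation(pid, "CLECT", start, end, source="simulated"))
            elif kind == "TM":
                annotations.append(DomainAnnotation(pid, "TM", start, end, source="simulated"))
        protein_parts.append(seq)
        pos = end + 1
    protein = "".join(protein_parts)
    cds = back_translate(protein, rng)
    truth = SimTruth(
        seed=seed,
        regions=regions,
        omegas=dict(template.omegas),
        kappa=template.kappa,
        t=template.t,
    )
    return SimulatedProtein(pid, template.family, protein, cds, annotations, truth)


# ---------------------------------------------------------------------------
# Codon evolution

_NEIGHBORS: dict[str, tuple[tuple[str, bool, bool], ...]] = {}
for _codon in SENSE_CODONS:
    _NEIGHBORS[_codon] = tuple(
        (mut, is_transition(_codon[pos], nt), CODON_TO_AA[mut] != CODON_TO_AA[_codon])
        for pos, nt, mut in codon_neighbors(_codon)
        if mut not in STOP_CODONS
    )


def _mean_rate(kappa: float, omega: float) -> float:
    """Mean unnormalized substitution rate per codon over the 61 sense codons."""
    total = 0.0
    for codon in SENSE_CODONS:
        for _, ts, nonsyn in _NEIGHBORS[codon]:
            total += (kappa if ts else 1.0) * (omega if nonsyn else 1.0)
    return total / len(SENSE_CODONS)


def _omega_per_codon(n_codons: int, omega, regions) -> np.ndarray:
    if np.isscalar(omega):
        omegas = np.full(n_codons, float(omega))
    else:
        raise ValueError("omega must be scalar; use regions for per-region values")
    if regions:
        for start, end, w in regions:
            if w < 0:
                raise ValueError("omega must be non-negative")
            omegas[start - 1 : end] = float(w)
    return omegas


def evolve_lineage(
    cds: str,
    time: float,
    kappa: float,
    omega: float = 1.0,
    regions=None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> str:
    """Evolve one CDS lineage for ``time`` expected substitutions per codon
    (at the calibration composition) under the Gillespie codon process."""
    if time < 0 or kappa <= 0:
        raise ValueError("time must be >= 0 and kappa > 0")
    rng = _rng_of(seed, rng)
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    n_codons = len(cds) // 3
    omegas = _omega_per_codon(n_codons, omega, regions)
    if (omegas < 0).any():
        raise ValueError("omega must be non-negative")
    scale: dict[float, float] = {}
    weight_cache: dict[tuple[str, float], tuple[list[str], np.ndarray, float]] = {}
    out = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3].upper()
        if codon in STOP_CODONS or codon not in CODON_TO_AA:
            raise ValueError(f"invalid or stop codon {codon!r} at codon {i + 1}")
        w = float(omegas[i])
        if w not in scale:
            scale[w] = _mean_rate(kappa, w)
        norm = scale[w]
        elapsed = 0.0
        while True:
            key = (codon, w)
            cached = weight_cache.get(key)
            if cached is None:
                muts = [m for m, _, _ in _NEIGHBORS[codon]]
                weights = np.array(
                    [
                        (kappa if ts else 1.0) * (w if nonsyn else 1.0)
                        for _, ts, nonsyn in _NEIGHBORS[codon]
                    ]
                )
                total = float(weights.sum()) / norm
                probs = weights / weights.sum() if weights.sum() > 0 else weights
                cached = (muts, probs, total)
                weight_cache[key] = cached
            muts, probs, total_rate = cached
            if total_rate <= 0:
                break
            elapsed += rng.exponential(1.0 / total_rate)
            if elapsed > time:
                break
            codon = muts[rng.choice(len(muts), p=probs)]
        out.append(codon)
    return "".join(out)


def simulate_codon_evolution(
    cds: str,
    omega: float = 1.0,
    kappa: float = 2.0,
    t: float = 0.3,
    regions=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Evolve a pair of lineages ``t/2`` each from the ancestral CDS; the
    expected pairwise divergence is ``t`` substitutions per codon.

    ``regions`` optionally overrides ``omega`` per residue interval as a list
    of ``(start_aa, end_aa, omega)``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if not np.isscalar(omega) or omega < 0:
        raise ValueError("omega must be a non-negative scalar")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = _rng_of(seed, rng)
    a = evolve_lineage(cds, t / 2, kappa, omega, regions, rng=rng)
    b = evolve_lineage(cds, t / 2, kappa, omega, regions, rng=rng)
    return a, b


def omega_regions_from_truth(truth: SimTruth) -> list[tuple[int, int, float]]:
    """Per-region omega intervals for :func:`evolve_lineage` from a truth record
    (EGF_i labels share the 'EGF' omega)."""
    out = []
    for label, start, end, _ in truth.regions:
        kind = "EGF" if label.startswith("EGF_") else label
        out.append((start, end, truth.omegas[kind]))
    return out


@dataclass
class CohortMember:
    species: str
    family: str
    protein: str
    cds: str


@dataclass
class SimulatedCohort:
    ancestor: SimulatedProtein
    members: list[CohortMember]

    @property
    def annotations(self):
        return self.ancestor.annotations


def simulate_cohort(
    template: ArchitectureTemplate,
    n_species: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """A star-tree cohort: one ancestral protein per the template, each species
    lineage evolved ``t/2`` so any unordered pair has divergence ``t``."""
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = _rng_of(seed, rng)
    ancestor = simulate_architecture(template, rng=rng)
    regions = omega_regions_from_truth(ancestor.truth)
    members = []
    for i in range(n_species):
        cds = evolve_lineage(
            ancestor.cds, template.t / 2, template.kappa, regions=regions, rng=rng
        )
        members.append(
            CohortMember(
                species=f"sp{i + 1:02d}",
                family=template.family,
                protein=translate_cds(cds),
                cds=cds,
            )
        )
    return SimulatedCohort(ancestor=ancestor, members=members)


# ---------------------------------------------------------------------------
# Synteny histories


def simulate_synteny_history(
    n_families: int,
    mechanism: str,
    intensity: float = 0.8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    window_bp: int = 20_000_000,
    min_families: int = 15,
    target_family: str = "TARGET",
) -> tuple[list[GeneRecord], list[GeneRecord], SimTruth]:
    """Reference and derived genome tables with a known gene-loss mechanism.

    The derived genome always lacks the target family.  Under
    ``chromosome_disruption`` a fraction ``intensity`` of the neighbor
    families is deleted or relocated to other chromosomes; under
    ``locus_preserved_loss`` the neighborhood is untouched.
    """
    if mechanism not in ("chromosome_disruption", "locus_preserved_loss"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if not 0 < intensity <= 1:
        raise ValueError("intensity must be in (0, 1]")
    if n_families < min_families:
        raise ValueError(f"n_families must be >= {min_families}")
    rng = _rng_of(seed, rng)
    gene_len = 10_000
    center = 30_000_000
    reference: list[GeneRecord] = [
        GeneRecord(
            gene_id="TARGET_ref", family=target_family, chromosome="chr1",
            start=center, end=center + gene_len, species="reference",
        )
    ]
    neighbor_families = [f"fam{i + 1:02d}" for i in range(n_families)]
    for i, fam in enumerate(neighbor_families):
        offset = (i // 2 + 1) * 1_000_000 * (1 if i % 2 == 0 else -1)
        start = center + offset
        reference.append(
            GeneRecord(
                gene_id=f"{fam}_ref", family=fam, chromosome="chr1",
                start=start, end=start + gene_len, species="reference",
            )
        )
    other_chroms = ["chr2", "chr3", "chr4"]
    for chrom in other_chroms:
        for j in range(5):
            start = int(rng.integers(1_000_000, 50_000_000))
            reference.append(
                GeneRecord(
                    gene_id=f"bg_{chrom}_{j}", family=f"bg_{chrom}_{j}",
                    chromosome=chrom, start=start, end=start + gene_len,
                    species="reference",
                )
            )
    events: list = [("target_loss", target_family)]
    derived: list[GeneRecord] = []
    affected: set[str] = set()
    if mechanism == "chromosome_disruption":
        k = int(math.ceil(intensity * n_families))
        affected = set(
            neighbor_families[i]
            for i in rng.choice(n_families, size=k, replace=False)
        )
    for gene in reference:
        if gene.family == target_family:
            continue
        if gene.family in affected:
            if rng.random() < 0.5:
                events.append(("deletion", gene.family))
                continue
            chrom = other_chroms[rng.integers(len(other_chroms))]
            start = int(rng.integers(1_000_000, 50_000_000))
            events.append(("relocation", gene.family, chrom, start))
            derived.append(
                GeneRecord(
                    gene_id=gene.gene_id.replace("_ref", "_der"), family=gene.family,
                    chromosome=chrom, start=start, end=start + gene_len,
                    species="derived",
                )
            )
        else:
            derived.append(
                GeneRecord(
                    gene_id=gene.gene_id.replace("_ref", "_der"), family=gene.family,
                    chromosome=gene.chromosome, start=gene.start, end=gene.end,
                    species="derived",
                )
            )
    truth = SimTruth(
        seed=seed, regions=[], omegas={}, kappa=math.nan, t=math.nan,
        events=events,
    )
    truth.events.insert(0, ("mechanism", mechanism))
    return reference, derived, truth


# ---------------------------------------------------------------------------
# Phospho-site tables for the logo stage


def simulate_phospho_table(
    members: list[CohortMember],
    truth: SimTruth,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """NetPhos-style score rows for every tyrosine of a cohort; the planted
    cytotail consensus tyrosine scores high (>0.5), other tyrosines low."""
    import pandas as pd

    rng = _rng_of(seed, rng)
    tail = truth.find("cytotail")
    planted = None
    if tail is not None:
        y_off = _CYTOTAIL_MOTIF_OFFSET + _CYTOTAIL_MOTIF.index("Y")
        planted = tail[0] + y_off
    rows = []
    for member in members:
        for pos, residue in enumerate(member.protein, start=1):
            if residue != "Y":
                continue
            if pos == planted:
                score = float(rng.uniform(0.60, 0.95))
            else:
                score = float(rng.uniform(0.05, 0.45))
            rows.append(
                {
                    "protein_id": member.species,
                    "position": pos,
                    "residue": "Y",
                    "score": round(score, 3),
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "position", "residue", "score"])


__all__ = [
    "ArchitectureTemplate",
    "CBEGF_CORE",
    "CohortMember",
    "DEFAULT_OMEGAS",
    "DEFAULT_TEMPLATES",
    "EGF1_CORE",
    "EGF2_CORE",
    "EGF_LIKE_CORE",
    "SimTruth",
    "SimulatedCohort",
    "SimulatedProtein",
    "evolve_lineage",
    "omega_regions_from_truth",
    "simulate_architecture",
    "simulate_codon_evolution",
    "simulate_cohort",
    "simulate_phospho_table",
    "simulate_synteny_history",
]
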