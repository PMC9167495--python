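"""Pairwise Ka/Ks (dN/dS) estimation for domain-region codon alignments.

Two counting estimators are provided:

``ng86``
    Nei-Gojobori (1986) counting.  Synonymous site opportunity is computed
    per codon position as the fraction of non-stop single-nucleotide changes
    that are synonymous (mutations to stop codons are excluded from the
    denominator), averaged over the two sequences.  Codon pairs differing at
    several positions are resolved by averaging over all shortest
    substitution pathways, excluding pathways that pass through a stop
    codon; if every pathway is blocked the stop-free restriction is lifted
    for that pair.  Proportions are corrected with the Jukes-Cantor formula
    ``d = -(3/4) ln(1 - (4/3) p)``.

``yn00``
    An approximate counting method in the style of Yang-Nielsen (2000):
    codon frequencies follow the F3x4 model, the transition/transversion
    ratio kappa is estimated from fourfold-degenerate and nondegenerate
    sites with a Kimura two-parameter correction, and both site opportunities
    and pathway weights use the mutation-level weights
    ``kappa^(is_transition) * f_pos(target nucleotide)``.  Distances are
    obtained by inverting the K80 expected difference proportion at the
    estimated kappa, which reduces exactly to the Jukes-Cantor correction
    (and the whole estimator to NG86) when kappa = 1 and codon frequencies
    are uniform.

Ka/Ks is reported as NaN when dS is zero or undefined.  Coordinates are
1-based closed; the standard genetic code only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .alignment import align_proteins_nw
from .codons import (
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    codon_neighbors,
    is_transition,
    strip_terminal_stop,
    translate_cds,
)

logger = logging.getLogger(__name__)

_UNAMBIG = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Codon alignment construction


@dataclass(frozen=True)
class CodonAlignment:
    """Retained codon columns of a pairwise codon alignment.

    Columns containing a gap, an ambiguous nucleotide, or a stop codon in
    either sequence are dropped at construction and tallied in ``dropped``.
    """

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    retained_columns: tuple[int, ...]  # 1-based aligned-column indices
    dropped: dict = field(default_factory=dict)
    table_id: int = 1

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("unequal codon column counts")

    def __len__(self) -> int:
        return len(self.codons_a)


def map_protein_interval_to_cds(
    start: int, end: int, cds_length: int | None = None
) -> tuple[int, int]:
    """Map a 1-based closed residue interval to 1-based closed CDS coordinates
    (frame 0, initiator codon first)."""
    if start < 1 or end < start:
        raise ValueError(f"invalid residue interval ({start},{end})")
    nt_start, nt_end = 3 * (start - 1) + 1, 3 * end
    if cds_length is not None and nt_end > cds_length:
        raise ValueError(
            f"residue interval ({start},{end}) maps to nucleotide {nt_end}, "
            f"beyond CDS length {cds_length}"
        )
    return nt_start, nt_end


def backthread_codons(
    aligned_a: str, aligned_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Thread CDS codons through a gapped protein alignment.

    The ungapped proteins must translate exactly to their CDS (terminal stop
    codons are stripped first); a mismatch raises naming the first offending
    residue.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    cds_a, cds_b = strip_terminal_stop(cds_a), strip_terminal_stop(cds_b)
    for label, aligned, cds in (("a", aligned_a, cds_a), ("b", aligned_b, cds_b)):
        protein = aligned.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"sequence {label}: CDS length {len(cds)} != 3 x {len(protein)} residues"
            )
        for i, aa in enumerate(protein):
            codon = cds[3 * i : 3 * i + 3].upper()
            if set(codon) <= _UNAMBIG:
                if codon in STOP_CODONS:
                    continue  # internal stop: dropped (and reported) below
                if CODON_TO_AA[codon] != aa:
                    raise ValueError(
                        f"sequence {label}: residue {i + 1} ({aa!r}) does not match "
                        f"codon {codon!r}"
                    )
    cod_a: list[str] = []
    cod_b: list[str] = []
    retained: list[int] = []
    dropped = {"gap": 0, "ambiguous": 0, "stop": 0}
    ia = ib = 0
    for col, (ra, rb) in enumerate(zip(aligned_a, aligned_b), start=1):
        ca = cb = None
        if ra != "-":
            ca = cds_a[3 * ia : 3 * ia + 3].upper()
            ia += 1
        if rb != "-":
            cb = cds_b[3 * ib : 3 * ib + 3].upper()
            ib += 1
        if ca is None or cb is None:
            dropped["gap"] += 1
            continue
        if not (set(ca) <= _UNAMBIG and set(cb) <= _UNAMBIG):
            dropped["ambiguous"] += 1
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            dropped["stop"] += 1
            continue
        cod_a.append(ca)
        cod_b.append(cb)
        retained.append(col)
    for kind, count in dropped.items():
        if count:
            logger.warning("backthread: dropped %d %s codon column(s)", count, kind)
    return CodonAlignment(tuple(cod_a), tuple(cod_b), tuple(retained), dropped)


def codon_alignment_from_cds(cds_a: str, cds_b: str) -> CodonAlignment:
    """Column-wise codon alignment of two equal-length in-frame CDS (no indels)."""
    cds_a, cds_b = strip_terminal_stop(cds_a), strip_terminal_stop(cds_b)
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise ValueError("CDS pair must be equal length, multiple of 3")
    prot_a = translate_cds(cds_a)
    prot_b = translate_cds(cds_b)
    return backthread_codons(prot_a, prot_b, cds_a, cds_b)


# ---------------------------------------------------------------------------
# Results


@dataclass
class KaKsResult:
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    ratio: float  # NaN when dS is 0 or undefined
    kappa: float
    columns: int
    converged: bool = True

    @property
    def ratio_defined(self) -> bool:
        return math.isfinite(self.ratio)


# ---------------------------------------------------------------------------
# NG86


@lru_cache(maxsize=None)
def _ng86_codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (stop mutations excluded from the
    per-position denominator)."""
    s = 0.0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        syn = tot = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            tot += 1
            if CODON_TO_AA[mut] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s


@lru_cache(maxsize=None)
def _pathways(pair: tuple[str, str]):
    """All shortest substitution pathways between two sense codons.

    Each pathway is a tuple of steps ``(pos, from_nt, to_nt, is_syn)``;
    pathways passing through a stop codon are excluded unless every pathway
    is blocked, in which case all are kept.
    """
    c1, c2 = pair
    diff = [p for p in range(3) if c1[p] != c2[p]]
    valid, blocked = [], []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            syn = (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and CODON_TO_AA[cur] == CODON_TO_AA[nxt]
            )
            steps.append((pos, cur[pos], c2[pos], syn))
            cur = nxt
        (blocked if through_stop else valid).append(tuple(steps))
    return tuple(valid) if valid else tuple(blocked)


@lru_cache(maxsize=None)
def _ng86_pair_diffs(pair: tuple[str, str]) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged equally over pathways."""
    if pair[0] == pair[1]:
        return 0.0, 0.0
    paths = _pathways(pair)
    sd = sum(sum(1 for st in p if st[3]) for p in paths) / len(paths)
    ndiff = sum(1 for p in range(3) if pair[0][p] != pair[1][p])
    return sd, ndiff - sd


def _jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for one pairwise codon alignment."""
    L = len(aln)
    if L == 0:
        raise ValueError("codon alignment has no retained columns")
    S = 0.5 * (
        sum(_ng86_codon_sites(c) for c in aln.codons_a)
        + sum(_ng86_codon_sites(c) for c in aln.codons_b)
    )
    N = 3 * L - S
    Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sd, nd = _ng86_pair_diffs((ca, cb))
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    dS = _jukes_cantor(pS) if math.isfinite(pS) else math.nan
    dN = _jukes_cantor(pN) if math.isfinite(pN) else math.nan
    ratio = dN / dS if (math.isfinite(dS) and dS > 0 and math.isfinite(dN)) else math.nan
    return KaKsResult("NG86", S, N, Sd, Nd, pS, pN, dS, dN, ratio, 1.0, L)


# ---------------------------------------------------------------------------
# YN00-style estimator


def _f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Position-specific nucleotide frequencies (3 x 4, order TCAG) pooled over
    both sequences."""
    counts = np.zeros((3, 4))
    nt_index = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    for codon in itertools.chain(aln.codons_a, aln.codons_b):
        for pos, nt in enumerate(codon):
            counts[pos, nt_index[nt]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals


@lru_cache(maxsize=None)
def _degeneracy_class(codon: str, pos: int) -> str:
    """'4fold' if every non-stop change at pos is synonymous, '0fold' if every
    one is nonsynonymous, else 'other'."""
    aa = CODON_TO_AA[codon]
    syn = tot = 0
    for nt in NUCLEOTIDES:
        if nt == codon[pos]:
            continue
        mut = codon[:pos] + nt + codon[pos + 1 :]
        if mut in STOP_CODONS:
            continue
        tot += 1
        syn += CODON_TO_AA[mut] == aa
    if tot and syn == tot:
        return "4fold"
    if tot and syn == 0:
        return "0fold"
    return "other"


def _k80_kappa(P: float, Q: float) -> float | None:
    """Kappa from transition/transversion difference proportions (K80)."""
    x, y = 1 - 2 * P - Q, 1 - 2 * Q
    if x <= 0 or y <= 0:
        return None
    ts = -0.5 * math.log(x) + 0.25 * math.log(y)
    tv = -0.25 * math.log(y)
    if tv <= 0:
        return None
    return max(0.01, min(ts / tv, 99.0))


def estimate_kappa(aln: CodonAlignment) -> float:
    """Transition/transversion rate ratio from fourfold-degenerate and
    nondegenerate sites, K80-corrected per class and averaged with
    site-number weights.  Falls back to 1 when inestimable."""
    stats = {"4fold": [0, 0, 0], "0fold": [0, 0, 0]}  # sites, ts, tv
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        for pos in range(3):
            cls = _degeneracy_class(ca, pos)
            if cls == "other" or cls != _degeneracy_class(cb, pos):
                continue
            rec = stats[cls]
            rec[0] += 1
            if ca[pos] != cb[pos]:
                if is_transition(ca[pos], cb[pos]):
                    rec[1] += 1
                else:
                    rec[2] += 1
    estimates = []
    for sites, ts, tv in stats.values():
        if sites == 0:
            continue
        kap = _k80_kappa(ts / sites, tv / sites)
        if kap is not None:
            estimates.append((sites, kap))
    if not estimates:
        return 1.0
    total = sum(s for s, _ in estimates)
    return sum(s * k for s, k in estimates) / total


def _mutation_weight(pos: int, to_nt: str, kappa: float, from_nt: str, freqs) -> float:
    w = kappa if is_transition(from_nt, to_nt) else 1.0
    if freqs is not None:
        w *= freqs[pos][NUCLEOTIDES.index(to_nt)]
    return w


def _weighted_codon_sites(codon: str, kappa: float, freqs) -> float:
    """Synonymous site opportunity of one codon with kappa / nucleotide
    frequency weights (per position, normalized over non-stop changes)."""
    s = 0.0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        syn_w = tot_w = 0.0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            w = _mutation_weight(pos, nt, kappa, codon[pos], freqs)
            tot_w += w
            if CODON_TO_AA[mut] == aa:
                syn_w += w
        if tot_w > 0:
            s += syn_w / tot_w
    return s


def _weighted_pair_diffs(pair: tuple[str, str], kappa: float, freqs) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair with pathways weighted by the product of
    their step mutation weights."""
    if pair[0] == pair[1]:
        return 0.0, 0.0
    paths = _pathways(pair)
    weights, syn_counts = [], []
    for path in paths:
        w = 1.0
        syn = 0
        for pos, from_nt, to_nt, is_syn in path:
            w *= _mutation_weight(pos, to_nt, kappa, from_nt, freqs)
            syn += is_syn
        weights.append(w)
        syn_counts.append(syn)
    total_w = sum(weights)
    if total_w <= 0:
        weights = [1.0] * len(paths)
        total_w = float(len(paths))
    sd = sum(w * s for w, s in zip(weights, syn_counts)) / total_w
    ndiff = sum(1 for p in range(3) if pair[0][p] != pair[1][p])
    return sd, ndiff - sd


def _k80_distance(p: float, kappa: float) -> float:
    """Distance whose K80 expected difference proportion equals ``p`` at the
    given kappa; reduces exactly to Jukes-Cantor at kappa = 1."""
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0

    def expected(u: float) -> float:  # u = beta * t
        return 0.75 - 0.25 * math.exp(-4 * u) - 0.5 * math.exp(-2 * (kappa + 1) * u)

    if p >= 0.75:
        return math.nan
    hi = 1.0
    while expected(hi) < p:
        hi *= 2
        if hi > 1e6:
            return math.nan
    u = brentq(lambda x: expected(x) - p, 0.0, hi, xtol=1e-14, rtol=1e-14)
    return (kappa + 2) * u


def yn00(
    aln: CodonAlignment,
    kappa: float | None = None,
    codon_freqs: str = "f3x4",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> KaKsResult:
    """Approximate-counting Ka/Ks with transition/transversion bias and codon
    usage weighting (Yang-Nielsen 2000 style).

    ``kappa=None`` estimates kappa from the alignment; pass a value to fix it.
    ``codon_freqs`` is ``"f3x4"`` (position-specific nucleotide frequencies
    from the data) or ``"uniform"``.  The weighting uses the mutation-level
    model only, so the pass converges immediately; the loop guard remains for
    the degenerate case of numerically oscillating site counts.
    """
    L = len(aln)
    if L == 0:
        raise ValueError("codon alignment has no retained columns")
    if codon_freqs == "f3x4":
        freqs = tuple(tuple(row) for row in _f3x4_frequencies(aln))
    elif codon_freqs == "uniform":
        freqs = None
    else:
        raise ValueError(f"unknown codon frequency model {codon_freqs!r}")
    kap = estimate_kappa(aln) if kappa is None else float(kappa)
    if kap <= 0:
        raise ValueError("kappa must be positive")

    site_cache: dict[str, float] = {}

    def sites_of(codon: str) -> float:
        if codon not in site_cache:
            site_cache[codon] = _weighted_codon_sites(codon, kap, freqs)
        return site_cache[codon]

    converged = False
    prev_S = None
    S = Sd = Nd = 0.0
    from collections import Counter

    pair_counts = Counter(zip(aln.codons_a, aln.codons_b))
    for _ in range(max_iter):
        S = 0.5 * (
            sum(sites_of(c) for c in aln.codons_a)
            + sum(sites_of(c) for c in aln.codons_b)
        )
        Sd = Nd = 0.0
        for pair, count in pair_counts.items():
            sd, nd = _weighted_pair_diffs(pair, kap, freqs)
            Sd += count * sd
            Nd += count * nd
        if prev_S is not None and abs(S - prev_S) < tol:
            converged = True
            break
        prev_S = S
    else:  # pragma: no cover - weights are fixed, loop exits on 2nd pass
        logger.warning("yn00: site counts did not converge; returning last iterate")
    N = 3 * L - S
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    dS = _k80_distance(pS, kap) if math.isfinite(pS) else math.nan
    dN = _k80_distance(pN, kap) if math.isfinite(pN) else math.nan
    ratio = dN / dS if (math.isfinite(dS) and dS > 0 and math.isfinite(dN)) else math.nan
    return KaKsResult("YN00", S, N, Sd, Nd, pS, pN, dS, dN, ratio, kap, L, converged)


ESTIMATORS = {"ng86": ng86, "yn00": yn00}


# ---------------------------------------------------------------------------
# Cohort aggregation


def aggregate_domain_kaks(
    records,
    method: str = "yn00",
    families=None,
    regions=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-domain Ka/Ks over all unordered species pairs of a cohort.

    ``records`` is an iterable of objects (or dicts) with attributes
    ``species``, ``family``, ``protein`` (sequence), ``cds``, and ``region_set``
    (a :class:`~ctldcp.architecture.RegionSet`).  For every family x region
    label, region sub-sequences of each species pair are globally aligned,
    codon back-threaded and estimated.  Species lacking a region are skipped
    for it (logged).  Returns (long table, summary table); summaries carry
    the median and quartiles of defined ratios.
    """
    if method not in ESTIMATORS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(ESTIMATORS)}")
    estimator = ESTIMATORS[method]

    def get(rec, name):
        return rec[name] if isinstance(rec, dict) else getattr(rec, name)

    by_family: dict[str, list] = {}
    for rec in records:
        fam = get(rec, "family")
        if families is not None and fam not in families:
            continue
        by_family.setdefault(fam, []).append(rec)

    rows = []
    for fam in sorted(by_family):
        members = sorted(by_family[fam], key=lambda r: get(r, "species"))
        region_labels: list[str] = []
        for rec in members:
            for label, *_ in get(rec, "region_set").iter_regions():
                if label not in region_labels:
                    region_labels.append(label)
        if regions is not None:
            region_labels = [r for r in region_labels if r in regions]
        for label in region_labels:
            per_species = {}
            for rec in members:
                interval = get(rec, "region_set").find(label)
                if interval is None:
                    logger.warning(
                        "kaks: species %s lacks region %s of family %s; skipped",
                        get(rec, "species"), label, fam,
                    )
                    continue
                start, end = interval
                prot = get(rec, "protein")[start - 1 : end]
                nt_start, nt_end = map_protein_interval_to_cds(
                    start, end, len(strip_terminal_stop(get(rec, "cds")))
                )
                per_species[get(rec, "species")] = (
                    prot,
                    strip_terminal_stop(get(rec, "cds"))[nt_start - 1 : nt_end],
                )
            for sp_a, sp_b in itertools.combinations(sorted(per_species), 2):
                prot_a, cds_a = per_species[sp_a]
                prot_b, cds_b = per_species[sp_b]
                alignment = align_proteins_nw(prot_a, prot_b)
                aln = backthread_codons(
                    alignment.aligned_a, alignment.aligned_b, cds_a, cds_b
                )
                if len(aln) == 0:
                    logger.warning(
                        "kaks: no retained codon columns for %s/%s %s %s",
                        sp_a, sp_b, fam, label,
                    )
                    continue
                res = estimator(aln)
                rows.append(
                    {
                        "family": fam,
                        "region": label,
                        "species_a": sp_a,
                        "species_b": sp_b,
                        "method": res.method,
                        "S": res.S,
                        "N": res.N,
                        "Sd": res.Sd,
                        "Nd": res.Nd,
                        "dN": res.dN,
                        "dS": res.dS,
                        "ratio": res.ratio,
                        "kappa": res.kappa,
                        "columns_retained": res.columns,
                    }
                )
    long = pd.DataFrame(
        rows,
        columns=[
            "family", "region", "species_a", "species_b", "method",
            "S", "N", "Sd", "Nd", "dN", "dS", "ratio", "kappa",
            "columns_retained",
        ],
    )
    summaries = []
    if not long.empty:
        for (fam, label), grp in long.groupby(["family", "region"], sort=True):
            defined = grp["ratio"].dropna()
            summaries.append(
                {
                    "family": fam,
                    "region": label,
                    "n": int(defined.size),
                    "n_undefined": int(grp["ratio"].isna().sum()),
                    "median": defined.median() if defined.size else math.nan,
                    "q1": defined.quantile(0.25) if defined.size else math.nan,
                    "q3": defined.quantile(0.75) if defined.size else math.nan,
                }
            )
    summary = pd.DataFrame(
        summaries,
        columns=["family", "region", "n", "n_undefined", "median", "q1", "q3"],
    )
    return long, summary


__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "aggregate_domain_kaks",
    "backthread_codons",
    "codon_alignment_from_cds",
    "estimate_kappa",
    "map_protein_interval_to_cds",
    "ng86",
    "yn00",
]
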