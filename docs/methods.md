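# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the design decisions taken where several reasonable options existed.

## Pattern engine and EGF subtypes

Patterns use the compact motif dialect: uppercase literals, `x` for any
residue, bracketed classes, a repeat suffix `(n)` or `(n,m)`, optional `-`
separators, and three class shorthands — `N` = [DEQN] (negatively charged
or polar), `B` = [DN] (possibly β-hydroxylated), `A` = [FYW] (aromatic).
The shorthand table is an argument of `parse_pattern`, so patterns needing
literal Ala/Asn can supply an empty table.  Matching is a reachability
sweep over element offsets: all start positions are reported and, at each
start, the shortest-length match (sufficient for presence/absence
classification; overlapping starts are all kept).  The unknown residue `X`
matches only `x`, never literals, classes or exclusions — a deliberately
conservative rule so low-quality sequence can only lose, never gain, a
signature.

Subtype precedence is cbEGF (PS01186 + PS01187) > EGF 2 (PS01186) > EGF 1
(PS00022) > generic EGF-like.  The calcium-binding signature PS01187 spans
up to 52 residues and can exceed a tightly annotated EGF core, so it alone
is evaluated on the core padded with a configurable flank (default 10
residues each side, clipped to the protein).  Tme5-EGF is taken from
upstream annotation (cl07616), never inferred from sequence.

## Region segmentation

Anchors (CTLD, EGF-like repeats, TM) come from a hit table; derived
regions are pure interval arithmetic: sushi = (CTLD end + 1, first EGF
start − 1) — or up to the TM when a lineage has lost its EGF repeats —
mucin = (last EGF end + 1, TM start − 1), cytotail = (TM end + 1, protein
end).  Zero-length derived intervals are reported as absent rather than as
empty intervals.  The region upstream of the CTLD (signal peptide etc.) is
left unlabeled.  In Thrombomodulin the CTLD-to-EGF interval is labeled
"hydrophobic stretch" but participates in boundary computation exactly
like a sushi region.  Segmentation is invariant to annotation order and
validated against anchor overlap and out-of-range coordinates.

The sushi key-residue check aligns each extracted region to a designated
reference with the package's global aligner and maps configured reference
columns through the alignment; a gap at a key column counts as
non-conserved (loss by truncation and by substitution are treated alike).
Pairwise alignment to a reference was chosen over a multiple alignment: it
is deterministic, and presence/absence of fixed key columns does not
benefit from an MSA.  The key-column positions are configuration — the
conserved classes default to {C}, {W}, {G}, {P}, the residues that
stabilize the sushi fold.

## Pairwise alignment

Global (end-to-end) Needleman–Wunsch with Gotoh's affine-gap recursion;
BLOSUM62, gap open −11, extend −1 (the opening score is charged on the
first residue of a gap; gaps may follow gaps with a fresh opening charge).
Ties are broken diagonal > gap-in-b > gap-in-a, making alignments
deterministic.  Scores are verified in tests against exhaustive
enumeration on short strings and against Biopython's `PairwiseAligner` on
random pairs.

## Ka/Ks estimation

**NG86.**  Synonymous site opportunity is computed per codon position as
the fraction of non-stop single-nucleotide changes that preserve the amino
acid (mutations to stops are excluded from the denominator), summed over
positions and averaged over the two sequences, so S + N = 3L exactly.
Codon pairs differing at k positions are resolved by averaging over all k!
shortest pathways; pathways through stop codons are excluded, and in the
rare case that every pathway is blocked the restriction is lifted for that
pair.  Proportions are Jukes–Cantor corrected, d = −(3/4) ln(1 − 4p/3);
p ≥ 3/4 yields an undefined distance (reported as NaN, not raised).
ω = dN/dS is defined only when dS > 0.

**YN00-style.**  Codon frequencies follow F3×4 (position-specific
nucleotide frequencies pooled over both sequences; a uniform option
exists).  κ is estimated from fourfold-degenerate and nondegenerate sites:
per class, transition/transversion difference proportions are corrected
with the Kimura two-parameter formulas and the two per-class estimates are
combined with site-count weights (falling back to κ = 1 when saturated or
empty).  Site opportunities and pathway weights then use the
mutation-level weight κ^{is-transition} × f_pos(target nucleotide); because
selection (ω) is deliberately kept out of the weighting, the computation
converges in a single pass and — at κ = 1 with uniform frequencies —
collapses exactly onto NG86, a reduction asserted to 1e-6 in the tests.
Distances invert the K80 expected difference proportion at the estimated
κ (solved by Brent's method to 1e-14), which reduces exactly to the
Jukes–Cantor correction at κ = 1 and uses κ consistently with the site
counting.  This is an approximate-counting design in the Yang–Nielsen
spirit rather than a line-for-line port of the published iteration; its
accuracy is established by simulation (median ω recovery within 20 % at
ω ∈ {0.2, 1, 3}, κ = 2, t = 0.3 — in practice ~5 % for this method, with
the remaining bias residing in NG86's equal-rate assumption).

**Aggregation.**  For every family × region label, all unordered species
pairs are aligned on the region's protein sequence, codon back-threaded
(columns with a gap, ambiguous nucleotide or stop in either sequence are
dropped and tallied), and estimated.  Pairs are pooled globally (the
pooling key is configurable); undefined ratios are excluded from medians
and quartiles but counted.  Species lacking a region are skipped for that
region with a logged warning.  Codon columns, not nucleotide columns, are
the unit of gap filtering; the standard genetic code only, terminal stops
stripped before validation.

## Synteny

Blocks collect gene-family occurrences within a window (default 20 Mbp in
each direction, often the whole chromosome) around a single anchor gene;
an ambiguous anchor is an error, a missing anchor signals a candidate
loss.  Comparison is at the family-label level (family assignment is
input); strand is ignored; at least 15 shared families mark an informative
locus.  When a target family is absent, each reference neighbor is
classified in the query genome as retained (on the best candidate
chromosome — the one carrying most neighbors, ties lexicographic — within
one window of the median neighbor position), relocated, or missing.
Retained fraction ≥ 0.5 calls locus-preserved loss; relocated + missing
fraction > 0.5 calls chromosome disruption; the thresholds are
configurable because the underlying field practice is qualitative.

## Logos

Reliable phospho-sites are those matching the residue filter (tyrosine by
default) with score strictly greater than 0.5; duplicate (protein,
position) rows keep the maximal score.  Windows of width 2h+1 (default
h = 5) are padded at protein ends with a dedicated symbol excluded from
counts, keeping the matrix rectangular.  Information content per position
is R_i = log2 20 − H_i − e_n with the Schneider small-sample correction
e_n = (s − 1)/(2 n ln 2), s = 20, n = number of sequences; R is clipped at
zero, and a position with no non-pad observations is reported missing.
The correction is applied by default for the entropy rendering and not for
the probability rendering; both modes are available because upstream
plotting tools differ.

## Statistics

One-way fixed-effects ANOVA from the classical between/within mean
squares; zero within-group variance yields F = ∞, p = 0 when means differ
(F = 0, p = 1 otherwise) — the edge case is why the formulas are
implemented directly, with scipy supplying the F and studentized-range
distributions and tests cross-checking against `scipy.stats.f_oneway` and
statsmodels' Tukey HSD.  q = |mean_i − mean_j| / sqrt(MSW/2 (1/n_i +
1/n_j)) (Tukey–Kramer for unequal n).  p < 0.05 two-tailed is the reported
significance convention; p values never filter data rows.

## Synthetic data: what it emulates, and what it does not

`simulate_architecture` draws segment lengths from per-family ranges
(signal 18–24, CTLD 125–135, sushi 55–65, EGF 40, mucin 90–190 by family,
TM 21–25, cytotail 30–50 residues) with the family EGF plans
CD93 = (EGF2, cbEGF, cbEGF, EGF2, EGF2), Clec14A = (EGF2),
CD248 = (EGF2, cbEGF, EGF2), Thrombomodulin = (EGF-like, EGF2, cbEGF,
cbEGF, EGF2, Tme5).  EGF segments center a constructed signature core in
alanine padding, and all segments bordering EGFs are kept cysteine-free,
so a signature can never arise across a boundary; the mucin segment is 60 %
Ser/Thr/Pro (O-glycosylatable); the cytotail plants a fixed tyrosine
consensus used by the phospho stage.  CDS are random synonymous
back-translations.

`simulate_codon_evolution` is a Gillespie jump process per codon:
single-nucleotide changes at rate ∝ κ^{transition} × ω^{nonsynonymous},
changes creating stops rejected, rates normalized so one time unit equals
one expected substitution per codon at uniform sense-codon composition.
Divergence t is split symmetrically over the two lineages (star tree of
two), matching the pairwise estimators.  Default study conditions: ω = 0.1
for CTLD/sushi/EGF/TM, 2.0 for mucin, 0.3 for cytotail and the unlabeled
signal region; κ = 2; t = 0.3.

`simulate_synteny_history` places the target and 15 neighbor families at
1 Mb spacing around 30 Mb on one chromosome plus background chromosomes;
disruption deletes or relocates ⌈intensity × n⌉ neighbors (default
intensity 0.8, a strong disruption like a dismantled chromosome), while
locus-preserved loss removes only the target.

Not emulated: insertions/deletions within domains (alignment is tested
separately on constructed and random sequences), rate variation among
sites, selection on amino-acid properties, annotation noise in the domain
tables, and the neural-network phospho predictor itself (its score table
is an input).  Passing tests therefore demonstrate correctness of the
counting, segmentation and classification machinery under a clean codon
model — not robustness to misannotation or alignment error in real NCBI
data.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to
make the statistical checks stable: all 61×61 codon pairs plus 100–1000
random alignments for oracle equivalence, 200 replicates of 500-codon
pairs per ω setting for recovery, 100 simulated proteins per family
template for round-trips, 200 synteny histories, 50 four-species cohorts
for the selection contrast, and 20–25 proteins per family for the length
ANOVA.

## Known limitations

* The YN00-style estimator is an approximate-counting method; for
  publication-grade absolute dN/dS on real data, a maximum-likelihood
  codon model is the reference standard.
* Segmentation trusts the anchor annotations; it validates consistency but
  cannot recover from a missed CTLD or TM.
* Synteny classification assumes family labels are comparable across
  genomes (ortholog inference is out of scope).
* The logo small-sample correction uses the number of sequences, not the
  per-column non-pad count, so heavily padded edge columns are slightly
  over-corrected.
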