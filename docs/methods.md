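# Methods

This note records the models, conventions and numerical choices behind
`palmirna`, and what the synthetic benchmark does and does not establish.

## Folding model

Candidate precursors are folded with a compact surrogate energy model
rather than a full thermodynamic engine: pair energies G:C −3.0, A:U −2.0,
G:U −1.0 kcal/mol; −0.5 for every stacked pair (its directly enclosed
neighbour `(i+1, j−1)` also pairs); loop penalties per occurrence of
+3.0 (hairpin), +1.0 (bulge/internal) and +3.0 (multibranch); hairpin
loops span ≥ 3 nt; no pseudoknots; the exterior loop is free.
`score_structure` is the normative definition; the dynamic programme in
`fold` minimises it and is verified against exhaustive structure
enumeration for sequences up to 18 nt. Choices that the model leaves
open and how they were fixed:

* **Multibranch penalty.** No multiloop term was prescribed; it is set
  equal to the hairpin penalty (+3.0) so that spurious branching is
  discouraged, and the enumeration oracle uses the identical scoring
  function, so the DP/oracle agreement is exact rather than approximate.
* **Interior-loop bound.** The DP considers bulges/internal loops of at
  most 30 unpaired nt per side. Because the penalty is flat, larger loops
  are almost never optimal; sequences ≤ 18 nt (the oracle regime) cannot
  reach the bound at all.
* **Tie-breaks.** Traceback prefers stacking (longest helix), then the
  smallest 5′ index; folding is fully deterministic.
* **Pluggable backend.** `fold(seq, backend="vienna")` delegates to
  ViennaRNA when its bindings are importable; nothing in the package or
  tests depends on it. Absolute energies from the surrogate model are not
  comparable to laboratory ΔG values — the criteria thresholds
  (−15/−40 kcal/mol, MFEI 0.85) act on the surrogate scale, where the
  strongly paired planted hairpins clear them comfortably.

## Precursor excision and the hairpin criteria

Windows extend each alignment by 20/60/120/250 nt on both sides plus
asymmetric variants (read near either end), clipped to the contig and at
least 50 nt long. A window longer than a plausible precursor is not
itself the precursor: after folding, the precursor is the single-hairpin
subtree (outermost pair span) that encloses the top-count supporting tag.
A tag-bearing subtree with two or more terminal loops fails as "not a
single hairpin"; unrelated hairpins co-folded elsewhere in a wide window
are ignored. Accepted precursors must additionally lie within the
57–264 nt length range observed for plant pre-miRNAs.

"Errors" are unpaired nucleotides; a bulge is a maximal unpaired run on
one arm; a biased bulge has no opposing unpaired position between the
partners of its flanking pairs (runs at an arm end count as biased). The
per-bulge stem budget (≤ 12) applies to each bulge separately, not to
their sum. pm is the count-weighted fraction of supporting-tag
nucleotides on the stem arms (outside the terminal loop). All criteria
are pure threshold comparisons on measured values, so relaxing any
threshold can never turn a pass into a fail (property-tested).

Overlapping accepted candidates are deduplicated: candidates whose
precursor spans overlap by at least half the shorter span form one locus
(on either strand — a near-palindromic hairpin maps its own tags to both
strands and produces mirror duplicates), represented by the candidate
with duplex evidence, then the highest read support, then the lowest
MFEI and MFE. Read support is preferred over the bare (MFEI, MFE) key
because a one-arm sub-window can otherwise displace the duplex-bearing
precursor and silently drop one mature arm.

## Mapping rule

Ungapped, both strands, ≤ 1 mismatch restricted to tag offsets 0–15 and
exact beyond; all qualifying placements are reported and each seeds
precursor discovery; multi-mapping tags are not count-split. Candidate
placements come from a 16-mer index queried with the tag seed and its 48
single-substitution neighbours, which is exhaustive under this rule
(verified against a positionwise scanner on multi-kb genomes).

## Differential expression

Size factors follow the median-of-ratios construction with rows
containing any zero excluded from the median. With one library per
condition the dispersion cannot be estimated and is supplied as
φ = BCV² (default 0.2² = 0.04). The exact test scales counts to
pseudo-counts (count / s, rounded half-up), conditions on their sum n,
and sums the probabilities of all splits of n no more probable than the
observed one, under independent NB(n/2, φ) marginals for both groups;
φ = 0 degrades to the Poisson/binomial case. This mirrors the
quantile-adjusted exact-test construction used by count-based DE tools;
the division-plus-rounding pseudo-count step is an approximation of
their quantile adjustment and is the package's testable core. Reported
fold changes are ratios of normalised counts with a +0.5 stabiliser.
Significance is the conjunction p < 0.05 and BH-FDR < 0.05, since the
two thresholds are always cited together for this design. BH adjustment
is delegated to statsmodels; an independent textbook step-up
implementation lives in the test-suite.

Complete-linkage clustering (for heatmap ordering) is implemented
directly with Lance–Williams max-updates and a deterministic smallest-
member-index tie-break — the tie-break contract is why a library routine
is not used; scipy's implementation serves as a cross-check in tests.
Distances are Euclidean on log2(n+1), configurable. qPCR fold changes
use 2^(−ΔΔCt).

## Target scanning

Sites are scored ungapped over windows of miRNA length (end gaps scored
when lengths differ by ≤ 4 nt): Watson–Crick 0, G:U 0.5, mismatch 1,
gap 2, doubled at miRNA positions 2–13. Expectation ≤ 3 reports a hit;
non-overlapping hits are selected greedily by ascending expectation then
leftmost position. The position 9–11 central window decides
translational inhibition vs cleavage. Target-site accessibility (UPE ≤
25) is recorded in the parameter set but never computed or filtered on —
a documented limitation.

## Synthetic-data generator

The generator emulates the four-library design: a random genome (GC 0.45
by default) with planted MIR loci and rRNA/tRNA/snoRNA/snRNA loci;
libraries of unequal depth (6,200–8,000 reads at desk scale) composed of
~35 % miRNA reads, 20 % ncRNA windows and unmappable background whose
lengths follow 21- and 24-nt-peaked weights; reads are insert + 3′
adaptor truncated to 36 nt. Hairpins are built constructively (lower
stem, mature, upper stem, A/C loop, reverse-complement arm, optional 1–3
nt bulge in the lower 3′ stem) and validated by folding, so planted loci
pass the criteria and carry a 2-nt-overhang duplex by construction; the
3p mature is placed by the duplex geometry. Counts are NB with
variance μ + φμ² (φ per library design; φ = 0 rounds the expectation
deterministically). Per-locus abundances are normalised lognormal(0, 0.8)
draws fixed by a master seed; the default fixture plants its 4-fold NaCl
responses on the two most abundant loci so the differential loci sit
well above 100 expected reads, matching the power conditions the DE
stage is specified for. Identical seeds give byte-identical FASTQ.

What the generator does **not** emulate: sequencing errors beyond an
optional uniform substitution rate (default 0), quality-score realism,
5′ adaptors, 24-nt heterochromatic siRNA biogenesis, genome repeats and
multi-locus families beyond what random placement yields. Passing the
synthetic benchmark therefore demonstrates the correctness of the
pipeline's logic under its stated model, not performance on real
sequencing data with contamination, assembly gaps or atypical hairpins.

## Problem sizes

Desk-scale defaults — 50 kb genome, 10 loci, ~29k reads across four
libraries, 200-seed Monte-Carlo calibrations, 10,000-rep null
simulations — were chosen so the full analysis and its verification run
in a few minutes on one core while every stage still faces non-trivial
inputs (multi-mapping palindromic arms, adjacent loci, ncRNA
contamination, unmappable background).

## Known limitations

* The surrogate energy scale is not thermodynamic; criteria values are
  only meaningful relative to it.
* Novel-miRNA serials depend on candidate order (deterministic per run).
* With single libraries per condition the dispersion is assumed, never
  estimated; power statements are conditional on φ = 0.04.
* The exact test's BH correction makes power depend on how many true
  positives share the matrix; the calibration reports the fixture design
  (20 arm rows, 2 planted responses).
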