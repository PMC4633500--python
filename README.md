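# palmirna

Genome-wide miRNA discovery and salt-stress expression analysis for a
four-library small-RNA sequencing design (leaf/root × control/NaCl), as
used to characterise the date-palm (*Phoenix dactylifera* L.) miRNAome.
The package re-implements the full desk-scale pipeline — read filtering,
tag collapsing, structural-ncRNA removal, seed-restricted genome mapping,
hairpin-precursor folding and filtering, conserved/variant/novel
classification, fixed-dispersion differential expression, and plant-style
target prediction — and ships a synthetic-data generator so every stage is
testable against known ground truth without any downloads.

## What it computes

**Discovery.** 18–25 nt unique tags are mapped ungapped to the genome
(≤ 1 mismatch, confined to the first 16 nt of the tag). Windows around
each alignment are folded and a candidate precursor must satisfy the full
hairpin rule set: stem ≥ 16 bp, ΔG ≤ −15 kcal/mol, hairpin ≥ 50 nt,
terminal loop ≤ 350 nt, per-bulge error budgets in stem (≤ 12) and mature
region (≤ 8 / biased ≤ 4, ≤ 2 bulges), mature pairing ≥ 12 bp, ≥ 80 % of
supporting small-RNA nucleotides on the stem, ≥ 10 supporting reads, and
the stringent cut-offs MFE ≤ −40 kcal/mol and

MFEI = (|MFE| / L × 100) / GC% ≥ 0.85.

A 5p/3p duplex with exactly 2-nt 3′ overhangs, when present, corroborates
the candidate. Matures are classified against a miRBase-style catalogue:
0 mismatches → conserved, 1–2 → variant (1–3 behind a switch), no match →
novel if supported by ≥ 10 reads.

**Expression.** Counts are normalised by median-of-ratios size factors

s_j = median_i [ c_ij / (∏_k c_ik)^(1/m) ],

and each NaCl-vs-control pair is tested with a two-sided negative-binomial
exact conditional test at fixed dispersion φ = BCV² = 0.2² = 0.04
(variance μ + φμ²), BH-adjusted; a miRNA is salt-responsive when both
p < 0.05 and FDR < 0.05.

**Targets.** Transcripts are scanned for complementary sites scored per
position (Watson–Crick 0, G:U 0.5, mismatch 1, gap 2; doubled at miRNA
positions 2–13); sites with expectation ≤ 3 are reported, and any
non-Watson–Crick position facing miRNA positions 9–11 marks the hit as
translational inhibition rather than cleavage.

## Worked example

```
python analysis/01_simulate.py           # synthetic four-library bundle
python analysis/02_run_pipeline.py       # discovery + classification
python analysis/03_differential_expression.py
python analysis/04_predict_targets.py
```

The default bundle plants 10 MIR loci (conserved/variant/novel cycling)
in a 50 kb genome with 5 ncRNA loci and four libraries of 6,200–8,000
reads; 4-fold NaCl responses are planted on the most abundant locus. The
run prints:

```
accepted precursors: 15 (10 with 5p/3p duplex)
10/10 planted loci recovered with the correct class

significant calls in the pipeline run: 6/40
   pda-miR172a_1mm  leaf_nacl_vs_leaf_control  log2FC  1.63  FDR 0.0008
   pda-miR172a_1mm  root_nacl_vs_root_control  log2FC  2.05  FDR 0.0000
   ...
Monte-Carlo calibration over 200 re-simulated library sets:
  power for planted 4-fold loci: 96.2% (400 checks)
  false-call rate for unchanged loci: 0.72% (6800 checks)
```

i.e. every planted precursor passes the hairpin criteria and is classified
correctly, the planted 4-fold salt responses are called significant in
both tissues (with the correct sign), and the exact test at φ = 0.04 is
well calibrated.

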