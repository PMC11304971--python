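# sexscaff

Coverage-based identification of sex-chromosome scaffolds, implemented as a
tested, fully synthetic-data-driven pipeline.

When a genome assembly is built from a heterogametic (XY) individual, its
contigs are a mixture of autosomal sequence, collapsed haplotype duplicates,
X-linked and Y-linked sequence, and the pseudoautosomal region (PAR) that
still recombines between X and Y. Resequencing one male and one female and
comparing their mapping depth separates these classes: relative to the
expected full depth, autosomes and the PAR show 100% coverage in both sexes,
haplotype duplicates 50% in both, the X 50% in males and 100% in females,
and the Y 50% in males and ~0% in females. `sexscaff` implements this logic
for assembly curation — the same scheme used to assemble a distinct X
(pseudo-chromosome) and a Y-linked scaffold for the nine-spined stickleback —
together with the downstream population-genetic checks.

## What it computes

- **Depth model.** Window depths (default 10 kb windows) per sex are fitted
  with a three-component mixture: two Gaussians with means anchored at 50%
  and 100% of the base depth (≈100×), plus a zeta (discrete power-law)
  component for outlier windows near 0% or far above 100%. A 4-state HMM
  (ZERO/HALF/FULL/EXCESS, symmetric persistence 0.99) is decoded by Viterbi.
- **Region calls.** Per-window male/female state pairs map to
  AUTOSOME/HAPLOTYPE/X/Y calls by the rule table above; AUTOSOME calls on
  X-linked contigs are re-labelled PAR; X/PAR and Y regions are emitted as
  0 cM linkage-map markers for the X-linked (LG12) and Y-linked (LG22)
  groups.
- **Depth utilities.** Breadth of coverage N/G, iterative (3-round)
  proportional depth normalization, and contig split-point detection
  (depth dropping below 30 between two regions above 30).
- **Population genetics.** VCFtools-style genotype/site filters
  (GQ ≥ 20, QUAL ≥ 30, mean depth in [3, 35], MAF ≥ 0.05, call rate ≥ 0.2,
  interval exclusion); nucleotide diversity π in 100 kb windows with mixed
  ploidy — haploid male calls in the sex-linked region (SLR) and on the Y
  contribute one allele copy, diploid calls two:
  π_site = n/(n−1) · (1 − Σ p_a²); paired t / Wilcoxon signed-rank
  compartment comparisons with Shapiro–Wilk test choice; the neutral
  equilibrium expectations π_X = ¾ π_A and π_Y = ¼ π_A.
- **Forward Wright–Fisher simulator** with separate sexes and X/Y/autosomal
  transmission, verifying those ¾ and ¼ expectations by simulation.
- **Assembly statistics.** N50, totals, per-linkage-group contig counts, gap
  (N-run) counts, and percent-change / count-ratio arithmetic for comparing
  assembly versions.

Every stage runs against the built-in synthetic-data generator
(`sexscaff.synthetic_data`), which produces contig sets with known truth
labels, overdispersed male/female depth tracks, and ploidy-correct variant
tables — no sequencing data is required.

## Worked example

```
$ sexscaff run-all --seed 11 --outdir run1
AUTOSOME: 1.0
HAPLOTYPE: 1.0
PAR: 1.0
UNCLASSIFIED: 1.0
X: 1.0
Y: 1.0
```

This simulates a 50-contig genome (30 autosomal, 5 haplotype, 4 X, 5 Y,
2 X+PAR, 4 repeat-outlier contigs) at 100× base depth with window-depth
standard deviation 5, runs the full classification, and prints per-class
window recall — 1.0 for every class at this noise level. The run directory
contains the depth tracks, fitted models (`model_male.yaml`), region calls
(`calls.bed`), linkage markers (`markers.txt`), the confusion matrix against
the generator truth (`confusion.tsv`), filtered variants, windowed π
(`pi_windows.tsv`) and assembly statistics; `summary.yaml` records the
config hash and seed, and a rerun with the same seed is byte-identical.

The Wright–Fisher check:

```
$ sexscaff wfsim --seed 1
pi_A=0.4045+-0.0048
pi_X/pi_A=0.7317+-0.0122 (expected 0.75)
pi_Y/pi_A=0.2466+-0.0043 (expected 0.25)
```

With 50 breeding males and 50 females, X-linked and Y-linked diversity land
within Monte-Carlo error of ¾ and ¼ of the autosomal level, as expected at
neutral equilibrium.

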