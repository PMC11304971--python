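# Methods

This note documents the models, defaults and design choices behind
`sexscaff`, and what the synthetic-data tests do and do not demonstrate.

## Depth classification model

Window depths are treated as draws from a per-sex mixture with three
components: a Gaussian centred near 50% of the base depth (one sequence
copy where the assembly holds the collapsed or sex-linked representation),
a Gaussian near 100% (two copies), and a zeta-distributed outlier component
covering windows near 0% or far above 100% (unmappable or collapsed-repeat
sequence). The zeta pmf P(k) ∝ k^(−s) is evaluated at k = ⌊depth⌋ + 1, so
its mass is highest at zero depth and decays polynomially — it therefore
dominates the Gaussians both near zero and in the far right tail, which is
exactly the "about 0% or over 100%" outlier regime.

Fitting is by EM. The Gaussian means start at 0.5× and 1.0× the base depth
and are clipped to ±20% of those anchors at each M-step; this prevents
label switching on skewed inputs while leaving room for real shifts (e.g.
GC or mappability bias in the 50% cluster). The zeta exponent is
re-estimated each M-step by bounded scalar maximum likelihood
(s ∈ [1.05, 8]) on the responsibility-weighted windows. Standard deviations
are floored at 0.5× depth units to avoid collapse. Convergence is declared
when the log-likelihood gain drops below 1e−6 (default), and the full
likelihood trace is retained so monotonicity is testable. All-identical
input returns a degenerate single-component model flagged as such.

### HMM

Segmentation uses a 4-state hidden Markov model — ZERO, HALF, FULL,
EXCESS — decoded with Viterbi. ZERO and EXCESS share the fitted zeta
emission, split at 150% of base depth (ZERO only emits below it, EXCESS
only above); HALF and FULL use the fitted Gaussians. Transitions are
symmetric: self-transition probability `persistence` (default 0.99),
remaining mass uniform over the other three states. At 10 kb windows,
0.99 persistence corresponds to an expected segment length of about 1 Mb,
matching the scale at which sex-linked blocks alternate with the PAR.
The initial distribution is uniform. Correctness of the decoder is checked
against exhaustive enumeration of all 4^T paths on short tracks rather
than against another HMM library, because the split-zeta emission law is
not expressible in standard packages.

## Sex-combination rules and PAR

Per-window male/female state pairs map to calls:
(FULL, FULL) → AUTOSOME, (HALF, HALF) → HAPLOTYPE, (HALF, FULL) → X,
(HALF, ZERO) → Y; any pair involving EXCESS, and every remaining pair, is
UNCLASSIFIED rather than forced into a class — such windows are candidate
repeats or collapsed duplications and need independent evidence. "Female
0%" for the Y is operationalised as the ZERO HMM state, not literally zero
depth. Adjacent windows with the same call merge into maximal regions
(1-based inclusive coordinates; BED output is 0-based half-open).

The PAR shows (FULL, FULL) like an autosome and cannot be separated by
coverage alone; it is recognised positionally. `separate_par` relabels
AUTOSOME calls as PAR on contigs named in an explicit X-linkage evidence
set (contigs carrying X calls, or contigs with prior linkage-map
assignment to the X chromosome group). X and PAR regions are emitted as
markers for the X-linked group (LG12), Y regions for the Y-linked group
(LG22), one marker per 10 kb by default, all at map position 0 cM — a
coverage-derived region carries no internal recombination information, so
a single map position is the honest encoding for downstream anchoring.

## Depth utilities

- **Breadth of coverage** is N/G (covered sites over region length).
- **Iterative normalization** performs proportional bias correction: each
  round divides every window by its depth relative to the 10%-trimmed track
  mean (or by a supplied mappability bias on the first round) and rescales
  to preserve the global mean. Three rounds are the default and reach a
  fixed point — a fourth round changes windows by < 1e−6 relative. The
  self-estimated variant assumes the underlying signal is uniform apart
  from multiplicative window biases; it deliberately flattens genuine
  copy-number structure, so the classification stage of the pipeline
  consumes raw depth and normalization is exposed as its own stage for
  mappability-dominated tracks.
- **Split detection** reports one candidate per maximal run of windows
  below the threshold (default 30, an absolute depth appropriate to ~100×
  data and configurable) flanked on both sides by at least one window
  above it; runs touching contig edges are not splits. The reported
  position is the first base of the first sub-threshold window.

## Nucleotide diversity with mixed ploidy

π is estimated per site as the unbiased pooled heterozygosity
n/(n−1) · (1 − Σ p_a²) = 2x(n−x)/(n(n−1)) over the allele copies present
after ploidy resolution: haploid male calls inside the sex-linked region
or on the Y contribute one copy, diploid calls two, missing genotypes
none, so n varies by site. On complete data this equals the mean pairwise
difference over all copy pairs, which is the oracle the tests use. Window
π sums per-site values over a 100 kb window and divides by the window's
true length; terminal windows shorter than 100 kb use their own length
and are flagged, as are windows with no callable copies. Whether to
average π across windows or weight by sites is left to the caller; the
compartment comparisons use window means (the primary convention here).

Filters follow the VCFtools conventions: GQ below threshold masks the
genotype; sites fail on QUAL, mean depth over the samples carrying the
region, minor-allele frequency, call rate (kept when ≥ the `max_missing`
value — the flag's name inverts its meaning) or interval exclusion. Site
rules are evaluated jointly on the masked table, so the surviving set is
order-independent by construction (and tested as such). Compartment
comparisons pair per-population means and pick the paired t-test when
Shapiro–Wilk does not reject normality of the differences at 0.05,
otherwise the Wilcoxon signed-rank test; constant nonzero differences
fall back to the signed-rank with a warning since the t statistic is
undefined at zero variance.

## Synthetic data

The generator defines the conditions everything is tested under:

- **Layout**: contigs drawn uniformly in a length range (default
  100–400 kb for the 50-contig evaluation genome) with per-window truth
  labels; a PAR-requested contig carries an X-linked block (~60% of
  windows) followed by a PAR block, and defines the layout's SLR/PAR
  intervals.
- **Depth**: expected window depth is base_depth × m(class, sex) with
  m ∈ {0, 0.5, 1}; base depth defaults to 100× (linked-read scale). Noise
  is gamma with variance dispersion² · (mean/base), i.e. σ = dispersion at
  full coverage with Poisson-like scaling below; dispersion defaults to 5
  (σ = 5% of base). A gamma law was chosen as the continuous analogue of
  overdispersed molecule counts because window depths are averages, not
  integers; the true variance of per-window unique-molecule counts is a
  free parameter of the emulation. Outlier windows are 50/50 near-zero
  (gamma, mean 2% of base) or zeta-tailed above 150% of base (s = 2.5).
- **Variants**: segregating sites are placed at rate π·a_n per bp with
  derived counts from the neutral frequency spectrum P(i) ∝ 1/i, giving
  expected per-site heterozygosity exactly π; males are haploid on X/Y
  sites, females absent from Y sites; GQ/DP/QUAL fields are simulated so
  filters are exercisable. π targets must be < 0.01 (small-diversity
  placement model).
- **Wright–Fisher**: unlinked loci, each with an independent pedigree
  realization, simulated forward for `n_generations` (default 2000 =
  10 × the autosomal pairwise coalescent scale at N = 100) recording which
  parental copy every offspring copy descends from; autosomal copies are
  transmitted biparentally, X copies one from the mother always plus the
  father's X to daughters, Y copies patrilineally. Pairwise coalescence
  times of 16 sampled copies are read off the recorded ancestry and
  pairwise differences drawn Poisson(2μT) under infinite sites
  (μ = 10⁻³/locus/generation default). Per-locus π is the mean pairwise
  difference; compartment means carry Monte-Carlo standard errors over
  loci, and ratio SEs propagate by the delta method. Pairs not coalesced
  within the run are capped at T = G (probability ≈ e^(−10) at the
  defaults; negligible). The simulation is vectorised across loci in
  chunks of 64 to bound memory.

What passing tests show — and do not: the generator produces clean
multiplicative depth classes with independent window noise; real
linked-read data adds mappability structure, GC bias, segmental
duplications and UMI saturation, so the ≥ 99% recovery figures are a
correctness statement about the method, not an accuracy forecast for real
genomes. Likewise the variant tables have no linkage disequilibrium or
sequencing-error model beyond the quality fields.

## Assembly statistics

N50 is the length of the shortest sequence in the smallest set of longest
sequences covering half the total (checked against sort-and-accumulate).
Gaps are maximal runs of N of any length (counting runs, not bases; the
per-base alternative is a one-line change). Percent changes are
(new − old)/old × 100 rounded half-up to 2 decimals, and count ratios
round half-up at the requested precision — half-up matching how such
tables are conventionally printed. Comparison tables should be computed
from raw counts; rows derived from already-rounded percentages are not
reproducible from counts and are excluded from the package's recomputed
set.

## Pipeline and reproducibility

`run_pipeline` executes simulate → depth (round-trip through TSV) →
per-sex model fit → segment/classify/PAR/markers → variants/filters/π →
assembly stats, writing text outputs plus `summary.yaml` with the config
hash. Stage seeds are derived from the master seed by hashing the stage
name, so stages can be re-run in isolation; identical config and seed give
byte-identical run directories. Problem sizes in the bundled evaluation
(50 contigs, ~12 Mb, 2000 loci per Wright–Fisher compartment) were chosen
so a full run completes in about a minute on one core while keeping
Monte-Carlo errors small enough for the ¾/¼ checks.

## Known limitations

- PAR recognition requires external X-linkage evidence; coverage alone
  cannot distinguish PAR from autosome.
- The self-normalization assumes bias-only variation; do not apply it
  before classification.
- The zeta outlier component shares one exponent for the near-zero and
  excess arms; strongly asymmetric outlier regimes would need two.
- The Wright–Fisher model is neutral and unlinked; it verifies equilibrium
  expectations, not selection or recombination effects on sex-linked
  diversity.
- Indels are not modelled; the variant machinery is biallelic-SNP only.
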