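# Methods

## The generative model

The simulator produces population-level BrdU incorporation for synchronized
cells released into S-phase. Its assumptions:

- **Firing times.** Origin *o* fires at time T_o ~ Normal(μ_o, σ), truncated
  at 0, independently across cells and origins. μ is the origin's
  characteristic firing time (minutes after release; the T_Rep timing source
  for quartile analyses), σ the cell-to-cell dispersion.
- **Forks.** Both forks from a fired origin move at constant speed *v*
  (bp/min). Position *x* is replicated by harvest time t_h through origin
  *o* in the fraction of cells f_o(x) = P(T_o ≤ t_h − |x − mid(o)|/v).
- **Passive replication.** Origins act as independent rescuers:
  replicated(x) = 1 − Π_o (1 − f_o(x)). This is an approximation — it
  ignores the correlation that a fork which passively replicates a dormant
  origin also suppresses its own firing — but it reproduces the qualitative
  dormancy behavior deterministically, which is what desk-scale testing
  needs.
- **Sequencing.** A library of given depth draws fragment start bins from a
  multinomial over the expected density (replicated fraction plus a uniform
  background of `background_rate` fragments per kb), with a uniform offset
  inside the bin and fixed fragment length. Strand is ignored throughout:
  BrdU incorporation is strandless.
- **rif1Δ.** A designated subset of late origins ("regulated", the ground
  truth) has μ reduced by Δ in the mutant; nothing else differs.

### HU as a harvest-time cutoff

HU depletes dNTPs. The model represents this entirely through the regime
parameters, with no explicit checkpoint mechanism: forks crawl
(`hu_fork_speed` = 50 bp/min, roughly a 30-fold slowdown of the ~1.5 kb/min
unperturbed speed) and the firing program dilates by `hu_time_scale` = 2, so
an origin with characteristic time μ fires near 2μ minutes after release
into HU. With μ_early = 10, μ_late = 35 and harvest at t_h = 45 min, early
origins (effective 20 min) fire well before harvest while late origins
(effective 70 min) essentially never do — the HU phenotype in which
incorporation is inversely related to T_Rep. Regulated origins in *rif1Δ*
(μ = 15, effective 30 min) fire inside the window. The two HU-specific
parameters are the package's own modeling choice: a single harvest cutoff
with unscaled times and fast forks cannot simultaneously silence late
origins (35 < 45 min) and keep early-origin BrdU domains local
(45 min × 1.5 kb/min ≈ 50 kb of spread would passively replicate every
origin window and erase all strain contrast). Both are config-exposed.

### Default design

| parameter | default | why |
| --- | --- | --- |
| genome | 16 chromosomes × 600 kb | the organism's chromosome count at roughly half-scale lengths |
| origins | 288, ≥20 kb apart | ~1 per 33 kb, matching real origin density and the called-origin scale |
| early fraction | 0.5 | half early (μ=10), half late (μ=35) |
| regulated late fraction | 0.75 | most late origins are Rif1-regulated |
| Δ | 20 min | advance of regulated origins in *rif1Δ* |
| σ | 4 min | conventional firing-time dispersion |
| HU arm | t_h=45 min, v=50 bp/min, scale 2, depth 2×10⁵ ×2 reps | see above |
| timepoint arms | t_h ∈ {25, 35} min, v=1500 bp/min, depth 10⁶ | unperturbed S-phase; deeper coverage emulates the dense tiling-array profiles these arms stand in for |
| background | 0.05 fragments/kb | low uniform IP background |

The timepoint arms need the deeper libraries because their signal spreads
over most of the genome (forks travel tens of kb), leaving ~1 fragment per
50 bp bin at sequencing depth — too noisy for a stable cross-strain scale
anchor (below).

## Analysis choices

- **Coordinates.** 0-based half-open everywhere internally; the origin-table
  reader performs the single 1-based→0-based conversion (OriDB dialect).
- **Binning.** Fragments are assigned to the bin containing their midpoint:
  conserves counts exactly and never splits a fragment across bins.
- **Median smoothing.** A 1 kb window over 50 bp bins is even (20 bins); the
  smoother uses the symmetric 21-bin window so it is centered and unbiased.
  At chromosome ends the window shrinks instead of padding — no invented
  signal at telomeres, where the biology of interest lives.
- **Quantile normalization** applies within a strain's replicates only.
  Ties (ubiquitous in count data) receive the mean reference value over
  their tied rank span, so tied bins stay tied.
- **Cross-strain track comparison.** Equal-depth libraries are zero-sum: the
  deregulated late origins add ~40% signal mass to the *rif1Δ* library, so
  equal-total scaling (or none) would depress every unchanged region of the
  mutant track. `tracks.match_scale` instead anchors on bins that are
  high-signal in *both* tracks (each above its own 75th positive
  percentile — in practice the plateaus of early origins, which the mutation
  does not touch) and uses their summed-signal ratio. The selection is
  deliberately symmetric: thresholding on one track's noisy values alone
  inflates its conditional mean and biases the factor.
- **Peak calling** consumes raw pooled replicate counts (the Poisson model
  needs counts, and the replicates are pooled rather than intersected — the
  documented choice). The scoring window is the 1 kb origin window; the
  local rate is the maximum of the genome-wide, 5 kb and 10 kb window rates
  (windows truncated at chromosome ends). P(X ≥ k) is accumulated in log
  space; bins with k ≤ λ are skipped when the significance threshold is
  ≤ 0.25, since the Poisson median sits within one count of λ. Significant
  bins merge across gaps ≤ 500 bp; the summit is the max-count bin. No
  multiple-testing correction at this stage — FDR control happens at the
  origin level.
- **Differential testing.** The origin set is the union of origins called in
  either strain. Counts are 1 kb-window midpoint counts per replicate.
  Normalization default is median-of-ratios size factors computed on the
  count matrix, with one refinement pass that re-estimates the factors on
  origins whose first-pass |log2 fold| < 1: when ~40% of tested origins are
  strongly changed in one direction, the plain median lands in the tail of
  the unchanged block and the residual shift (a few percent, but systematic)
  is large enough for deep counts to flag every unchanged origin. Plain
  library-size normalization is kept as an option but is composition-biased
  here for the same reason. The test is an exact conditional two-group test:
  scaled counts pooled per strain, the split of the pooled total evaluated
  under NB(φ) group sums with the pooled mean (binomial when φ = 0), and the
  two-sided p the total probability of splits no more probable than the
  observed one. φ is a single method-of-moments estimate pooled across
  origins — 2-vs-2 designs cannot support per-origin dispersions. All-zero
  origins get p = 1 by convention.
- **Quartiles.** Stable sort by (T_Rep, name); four contiguous rank blocks
  with earlier quartiles taking the remainder (sizes differ by ≤1). The name
  tie-break matters because the simulation assigns only two distinct μ
  values.
- **Landscape statistics.** Edge-gap interval distance (0 on overlap,
  half-open semantics; abutting intervals do not overlap). "Within 20 kb" is
  ≤ 20 kb, measured from the origin midpoint; telomere landmarks are the two
  chromosome-end coordinates. Mean-CEN-distance comparisons exclude
  pericentric and subtelomeric origins first and use Welch (unequal-variance)
  two-sided t-tests; two identical degenerate samples give p = 1 by
  convention, classes with n < 2 are flagged and skipped. Binding-site
  overlap uses ≥1 bp intersection of the 1 kb origin window with the site
  window (whole interval for ORFs, the 1 kb nearest the naming gene for
  intergenics), optionally excluding subtelomeric origins.

## What the synthetic design does and does not show

The generator reproduces the features the pipeline's inferences rest on:
timing-dependent HU incorporation, passive replication of dormant origins,
replicate noise, background, and a known regulated set. Passing tests
demonstrate that the pipeline recovers a planted timing effect of realistic
size at realistic depth, controls its FDR under the null, and that every
interval/statistical primitive matches an independent oracle.

They do not establish performance on real libraries: the model has no GC or
mappability bias, no IP-efficiency variation, uniform fragment length, no
repetitive sequence (the subtelomeric regions that motivate sequencing over
arrays are exactly the hard case), a common dispersion rather than
origin-specific variability, and origins placed independently of
centromeres and telomeres — so the landscape tables over synthetic data
exercise the machinery but carry no positional biology. The checkpoint is
represented only through the effective HU time scale, not as a mechanism.

## Problem sizes and runtime

Default runs use the design above: simulation plus the full HU analysis in
a few seconds, the timepoint arms in ~10 s; the complete test suite and the
acceptance script each finish in well under a minute on one CPU.
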