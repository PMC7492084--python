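# Methods

This note documents the models and conventions barrelkit implements,
the parameters that matter with their defaults, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the underlying procedure admits more than one reading.

## Barrel–septa contrast

A tissue section is measured through three ROI groups: barrel ROIs
(the 5–6 selected barrel hollows), one enclosing ROI covering those
barrels plus the surrounding septa up to the edges of adjacent barrels,
and 0–3 background ROIs placed in low-signal territory adjacent to the
barrel field.

* **Septa intensity is defined on integrated intensities.**  The septa
  mean is `(enclosing_sum − Σ barrel_sums) / (enclosing_area − Σ
  barrel_areas)`.  Subtracting ROI *means* directly would be
  dimensionally inconsistent whenever ROI areas differ; working in
  integrated intensity makes the decomposition exact:
  `enclosing_sum = septa_sum + Σ barrel_sums` holds identically, and the
  test suite asserts it on every synthetic section.
* **Contrast** is `(barrel − septa)/(barrel + septa)` on mean
  intensities, with the barrel mean area-weighted across barrel ROIs.
  It lies in [−1, 1] for non-negative intensities, is invariant to
  multiplying the image by a positive scalar, and needs no background
  correction because it is a ratio.  An optional
  `background_subtract_contrast` flag subtracts the background mean from
  both terms first; it is off by default.
* **Background normalization** divides by the arithmetic mean of the
  background-ROI means.  Division (rather than subtraction) is chosen
  because the normalized intensities are reported as fold-like
  quantities; the number of background ROIs used (0–3) is recorded with
  the measurement.
* **Aggregation** is the arithmetic mean over sections per animal,
  grouped by genotype and age; the convention is two sections per
  animal, and any other count triggers a warning, not an error.
* ROIs are accepted as boolean masks, 16-bit label masks, or JSON
  polygons; polygons are rasterized with scikit-image's polygon fill,
  which includes pixels whose centers fall inside the polygon.

## Puncta per cell

Each RNA punctum is assigned to the cell centroid at minimum Euclidean
distance (k-d tree, with exact ties resolved to the smallest `cell_id`
so results are order-independent).  There is no maximum assignment
distance by default — every punctum is counted — but a `max_distance`
cap is available.  Cells receiving no punctum contribute zero to the
mean.  Means are taken per layer per image, then per animal, in that
order, so images with different cell counts weigh equally within an
animal.

## PWM scanning with exact p-values

A PWM of per-position base probabilities is regularized with a
pseudocount (`(p + pc/4)/(1 + pc)`, default pc = 0.001) and converted to
a log2-odds matrix against a 0-order background.  Window scores are the
sum of per-position entries, in bits.

* **Exact thresholding.**  Scores are discretized on a fixed grid of
  10⁻⁴ bits with *floor* rounding; the null distribution of the
  integerized window score is computed exactly by convolving the four
  background-weighted per-column score distributions.  The scan
  threshold is the smallest achievable score whose exact tail
  probability is ≤ α (default α = 10⁻⁴, the conventional FIMO default).
  Floor rounding is conservative: reported tails are upper bounds, so
  discretization can never admit a window the exact score would have
  rejected.  When no word attains the α tail (e.g. any K = 1 motif at
  α = 10⁻⁴, where the best tail is 0.25), the threshold is placed one
  grid step above the maximum score and a warning is issued; such scans
  return no hits.
* **Zero probabilities.**  With pseudocount 0, log2(0) entries are
  clamped to a −64 bit floor so the dynamic program stays finite; any
  window using such a base is effectively unreachable.  A positive
  pseudocount (the default) avoids the issue entirely.
* **Both strands.**  Reverse-strand hits are scored with the
  reverse-complemented matrix against its own null distribution and
  reported in forward coordinates.  For a strand-symmetric background
  the two distributions coincide; for a composition background the
  per-strand treatment preserves the reflection invariance (scanning a
  sequence and its reverse complement yields the same instances mapped
  through coordinate reflection), which the suite asserts.
* Windows containing N are skipped rather than scored with imputed
  bases.

## Two-scanner cross-validation

The cross-validation contract needs two instance sets over a common
coordinate scheme.  The two scanners are realized as two configurations
of the same engine — scanner A scores against a uniform background,
scanner B against the pooled base composition of the scanned sequences —
since reproducing two external programs bit-for-bit is neither possible
nor required by the contract.

Matching keeps an instance from set A when a partner in set B lies on
the same chromosome and strand with |Δstart| ≤ 1 **and** |Δend| ≤ 1.
Matching is one-to-one and greedy in ascending coordinate order, and
retained instances keep A's coordinates.  Two readings are configurable
because the underlying procedure does not pin them down: strand
agreement can be relaxed (`require_strand=False`), and the AND over
start/end differences can be relaxed to OR (`criterion="or"`).  The
strict AND-with-strand default is the more conservative choice.
Palindromic motifs legitimately fire on both strands at one locus; both
instances are kept, with deduplication left to the consumer.

## Control regions and enrichment

* **Shuffling.**  Each input region yields one control of identical
  length, placed uniformly at random over *all* admissible start
  positions genome-wide — positions whose whole extent avoids assembly
  gaps.  Controls may overlap each other (as bedtools-style shuffling
  allows).  The suite verifies exact length conservation, zero gap
  overlap, and chi-square uniformity over admissible starts.
* **Containment.**  A region "contains" a motif when at least one
  cross-validated instance lies fully within it.
* **Near TSS.**  A region is "near" a gene when its midpoint lies within
  ±window of the TSS.  The midpoint convention is symmetric and robust
  to region length; an any-overlap rule is available behind a flag.
  TSS strand is ignored (windows are symmetric) since no directional
  rule is implied by the procedure.  The default window list is
  {1, 5, 10, 25, 50} kb; all windows are evaluated and reported, and a
  motif is "reported" when the dual criterion holds at any window.
* **Dual reporting rule.**  Test 1: ATAC peaks near any DEG TSS versus
  control regions near any DEG TSS (the same proximity rule on both
  sides keeps the comparison like-for-like; using all controls as the
  denominator is available via `restrict_controls=False`), with/without
  the motif.  Test 2: DEGs versus control genes, having/not having at
  least one nearby motif-containing ATAC peak.  The motif is reported
  only when both two-sided Fisher p-values are below 0.03.  The
  conjunction makes the rule conservative: its type-I rate is well below
  0.03, which the calibration simulations confirm.  No multiple-testing
  correction is applied across motifs — the dual rule itself is the
  false-positive control, replicated as-is.
* **Control genes** are those expressed strictly above 5 TPM in every
  (age, genotype) condition and never differential at any age.

## Classical statistics

* **Fisher exact test** (two-sided) follows the probability-mass
  convention: the p-value sums hypergeometric probabilities of all
  tables with the observed margins that are no more probable than the
  observed table, with a 1 + 10⁻⁷ relative tolerance when comparing
  table probabilities (the convention of R's `fisher.test`, in which
  these analyses are conventionally run).  The odds ratio is the sample
  odds ratio `(a·d)/(b·c)`; the Haldane–Anscombe 0.5 correction applies
  to the odds ratio only when a cell is zero, never to the p-value.
* **t-test** defaults to Welch (unequal variances) with Satterthwaite
  degrees of freedom — the default of the same environment — with the
  pooled-variance test behind a flag.
* **ANOVA**: one-way uses the classical between/within decomposition;
  two-way uses Type II sums of squares (via OLS), appropriate for the
  unbalanced designs typical of animal cohorts (N = 4–6 per cell) and
  identical to the classical decomposition when balanced.  The
  interaction is tested only when every occupied cell has ≥ 2
  observations; empty cells are an error naming the cells.  Degenerate
  all-equal data reports F = 0, p = 1.
* **Benjamini–Hochberg** adjustment is the step-up procedure with
  cumulative-minimum enforcement, preserving input order.
* **DEG rule**: differential iff |log2 fold change| ≥ 1 (fold change
  cutoff of 2) AND adjusted p strictly < 0.01, with direction from the
  sign of the fold change.

## Synthetic-data generators

The generators reproduce the *statistical structure* each analysis
assumes, not the biology:

* **Barrel images** are discs on a square (optionally hexagonal) grid:
  barrel intensity on a septa field inside the barrel-field rectangle,
  background outside, i.i.d. Gaussian noise added *before* a Gaussian
  blur (the order fixes what "recovery within tolerance" means).  Discs
  make the true contrast analytically known; real barrels are irregular
  and brighter toward their centers, so recovery on these images bounds
  only the pipeline's arithmetic, not segmentation quality.  Defaults:
  5×5 grid, disc radius 30 px, spacing 72 px, intensities 200/100/10,
  chosen so that barrels are well resolved relative to the default 1 px
  blur — the blur's partial-volume bias on contrast scales as
  2σ/r (≈ 0.016 of the contrast at the defaults), mirroring real
  acquisitions where the PSF is a few µm against ~300 µm barrels.
* **Genome fixtures** use i.i.d. nucleotides with a symmetric GC split
  (pA = pT, pC = pG; default GC 0.42), the simplest model consistent
  with a 0-order scanning background; real genomes have higher-order
  structure and repeats that this does not emulate.  Gaps are written
  both as N runs in the FASTA and as a BED file, and the two are tested
  to agree.  Peaks avoid gaps and each other; planted sites are the PWM
  consensus on a uniform strand at a uniform offset, and always rescan
  above the 10⁻⁴ threshold.
* **Expression tables** plant a configurable fraction of L4-marked
  genes as down-regulated and L5-marked genes as up-regulated with the
  stated effect size and a tiny adjusted p, over background differential
  rates applied uniformly to all genes; null genes carry Gaussian
  log-fold-change noise and uniform adjusted p-values.  Defaults echo
  the observed structure in this literature: 102 L4 and 240 L5 genes in
  a 5,000-gene universe, 26% / 19% responsive fractions, 1% / 2%
  background down/up rates, |LFC| effect 2.0.  Uniform null padj is an
  idealization — real moderated-test p-values are correlated across
  genes — so null calibration results speak to the test arithmetic, not
  to RNA-seq dependence structure.
* **Puncta datasets** place cell centroids uniformly within equal-height
  layer bands and draw per-cell counts from a Poisson with the layer's
  rate, scattering puncta within one cell radius; real images have
  segmentation errors and spatially clustered cells that this omits.
* **The enrichment fixture** is coordinate-level: one peak near each
  gene's TSS on a 10 Mb chromosome (1,200 genes, 200 of them DEGs),
  shuffled controls, and motif *instances* planted at 50% in peaks near
  DEG TSSs and 5% everywhere else (controls carry the background rate
  everywhere, being shuffled background).  Planting instances rather
  than sequences isolates the enrichment statistics from the scanner,
  which is tested separately against its own oracles.

## Problem sizes and runtimes

The test and acceptance workloads use desk-scale sizes chosen as the
smallest that make the statistical assertions sharp: 20 seeds for
contrast recovery, 10 kb sequences for scanner/oracle equivalence,
exhaustive enumeration to 4⁶ words and all 2×2 tables to n = 40, 10,000
shuffles for uniformity, 100 fixture replicates for power/calibration of
the dual rule, 2,000 simulations for Welch calibration, and 200 seeds
for null layer-overrepresentation.  The full suite runs in about two
minutes on one core.

## Known limitations

* The scanner pair (uniform vs composition background) emulates the
  *contract* of cross-validation between two independent programs, not
  any particular external tool's scoring quirks.
* Exact p-value DP cost grows with K and with the score range in grid
  units; motifs longer than ~20 positions with extreme pseudocount-free
  probabilities can become memory-heavy (the −64 bit clamp bounds this).
* The two-way ANOVA covers crossed fixed effects only — no mixed models,
  no post hoc corrections.
* Genome fixtures do not simulate reads, duplication structure, or
  repeat families; enrichment conclusions on them validate the
  statistics, not peak calling.
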