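# Methods

This note documents the statistical model behind `tilemeth`, the design
decisions taken where several reasonable choices existed, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Data model

A single-cell bisulfite library is represented as a set of per-cytosine
calls `(chromosome, position, context, methylated reads, unmethylated
reads)` in the Bismark cytosine-report dialect. On read, the two strands of
a CpG dyad are merged onto the forward-strand C (the reverse-strand record
at `p` folds into `p − 1`, counts summed). Merging is the default because
per-site depth in single-cell pBAT data is near 1x and the downstream
statistics count "CpG sites" without strand qualification; it can be
disabled (`strand_merge=False`) for strand-resolved analyses. Internally all
coordinates are 0-based half-open; cytosine-report positions stay 1-based,
matching the emitting tools.

Mapping efficiency is metadata carried on the sample sheet, not recomputed:
read trimming and alignment are upstream of this package.

## QC

Inclusion requires mapping efficiency ≥ 0.10 (inclusive) and covered CpG
count > 10⁶ (strict), exactly as the thresholds are worded; both are
parameters so reduced-scale data can be filtered proportionally. The
conversion rate is the pooled ratio `Σ unmethylated / Σ total` over lambda
spike-in calls, which makes it invariant to batching. Global methylation per
context is the unweighted mean of per-site fractions rather than a
pooled-read ratio; at ~1x depth the two coincide, and the per-site mean is
the same statistic used for tiles.

## Tiling and quantification

CpG density varies over orders of magnitude along mammalian genomes, so
fixed-bp windows confound methylation with CpG density. Tiles are therefore
runs of 100 consecutive reference CpGs per chromosome; the trailing
remainder forms one `partial` tile that is quantified but excluded from
differential testing (its smaller CpG count would change the test's
resolution). A tile's genomic extent runs from its first CpG's C to one past
its last CpG's G, so adjacent tiles never overlap and every CpG belongs to
exactly one tile.

The tile level of a cell is the mean per-site methylation fraction over the
covered CpGs; an uncovered (tile, cell) entry is missing, never zero. The
same per-site mean is used for arbitrary region sets (CpG-island classes,
imprinting-control-region stand-ins, repeats) and for the metagene profile
(gene bodies scaled into 60 bins, 15-kb flanks in 30 fixed-width bins each;
bin counts are plotting granularity, not inference).

Promoters are strand-aware windows −1500/+500 bp around each TSS, kept only
when they contain strictly more than 8 reference CpGs.

## Differential methylation

For one treatment-versus-control pair, *informative* tiles must cover ≥ 5
CpGs in ≥ 2 cells in each group separately. The per-sample interpretation of
"covers" (each qualifying cell individually covers ≥ 5 CpGs) is the stricter
of the two readings and is the default; both thresholds are parameters.

The reported effect size is `100 × (mean of treatment-cell fractions − mean
of control-cell fractions)` — each oocyte is the biological replicate. The
default p-value is an exact two-sided Fisher test on the 2×2 table of
methylated/unmethylated read counts pooled within groups, computed from the
hypergeometric log-pmf with the conventional `1 + 1e-7` relative tolerance
for tail ties; it is exact at the low, uneven coverage where asymptotic
tests misbehave, and is verified in the test suite against an independent
exact-tail computation over an exhaustive sweep of small tables. A
`logistic` alternative (binomial GLM of per-sample counts on group,
likelihood-ratio p) mirrors the multi-sample logistic mode of count-based
DMR callers; it falls back to the exact test when the GLM cannot be fitted.
Multiple testing uses Benjamini–Hochberg over all tested tiles (standard
step-up, p = 1 tiles kept in the denominator). Significance requires
`q < 0.05` and `|difference| > 20` percentage points; direction is `hyper`
when the treatment mean is higher.

Two false-positive controls reflect the small group sizes:

1. **Label randomization.** The entire procedure — informative-tile filter
   included — is re-run under sample-label shuffles that preserve group
   sizes, excluding the identity assignment and its mirror. Permutations are
   drawn uniformly from the enumerated label assignments (or rejection-
   sampled when the space is large), seeded. The observed count sitting
   inside the permutation distribution flags a comparison as unreliable on
   its own.
2. **Recurrence consensus.** A tile is a consensus DMR only when significant
   with the *same direction* in at least 2 of the 3 dose-versus-control
   comparisons of one hormone. Direction consistency is required because
   hyper- and hypo-DMRs are reported separately; a direction conflict
   excludes the tile. Comparisons must share one tile universe (in practice,
   the intersection of their informative sets).

Annotation assigns each tile's midpoint to promoter > gene body > other (in
that precedence) and reports nearest-TSS distance, strand-ignored; tiles on
chromosomes without genes get infinite distance.

## Variability and correlation

Within-group variability is the sample SD (ddof = 1) of a tile's fractions
across a group's cells, missing below two observations. Summaries follow the
analysis conventions: a seeded random sample of up to 10,000 tiles;
CGI-overlapping tiles stratified by group-mean level into low (< 0.2),
medium, and high (> 0.8) — the 0.2/0.8 cutoffs quantify an otherwise
qualitative high/medium/low split; and the nearest-TSS distances of the
top-10,000 most variable tiles with the fraction beyond 10 kb. Binomial
sampling alone makes the medium stratum the most variable (site-level
variance `p(1−p)` peaks at 0.5), which the generator reproduces.

Sample similarity is Pearson correlation over tile levels with pairwise-
complete observations (≥ 3 complete pairs per entry); samples with undefined
correlations are dropped from clustering with a warning. Clustering is
average linkage on `1 − r` — the linkage is a free choice; average linkage
is the least surprising for correlation heatmaps. Intra/inter comparisons
partition the off-diagonal pairs by shared group label.

## Synthetic generator

The generator emulates the *structure* the analysis assumes, not any real
genome:

- **CpG map.** Inter-CpG gaps are `1 + Geometric(1/(mean − 1))` (integers
  ≥ 2, stated mean), giving the uneven spacing that motivates CpG-count
  tiling.
- **Methylation domains.** Alternating blocks of 200 CpGs: even blocks
  hypermethylated (default 0.85, gene-body-like), odd blocks hypomethylated
  (default 0.10, intergenic-like), with every 5th odd block at an
  intermediate level (0.50) so partially methylated domains — and hence a
  populated medium CGI stratum — exist. The layout is deterministic so the
  annotation generator can place genes on hypermethylated blocks and CGIs on
  both kinds independently of the methylome seed.
- **Coverage.** Per-CpG Bernoulli capture (default 0.22, the order of a few
  million covered CpGs out of ~20 million at genome scale) at read depth 1,
  matching near-haploid single-cell pBAT coverage; optional geometric extra
  depth.
- **Errors.** Conversion failure (default 0.005) flips unmethylated calls to
  methylated-looking; over-conversion (default 0.002) flips the other way,
  applied as independent bit-flips on the true state. Lambda spike-in calls
  are drawn with a configurable conversion rate (default 0.995). Non-CG
  contexts are an optional low-rate channel (default off, level 0.01) since
  they feed only global QC summaries.
- **Planted effects.** Each "profile" (e.g. the three doses of one hormone)
  receives a disjoint set of full tiles shifted by ±Δ (default 40 percentage
  points, half up from hypomethylated blocks, half down from hypermethylated
  ones, clipped to [0, 1]). The returned truth table enables recall/precision
  scoring. The default eight-group design mirrors a superovulation study:
  natural and hCG-only controls plus 5/50/200 IU FSH and hMG groups, six
  cells each (seven in the highest hMG dose).

It does **not** emulate read-level artifacts (PCR duplicates, chimeras,
mapping bias), chromosome-scale copy-number structure, genuine sequence
context, or biological between-cell heterogeneity beyond binomial sampling.
Passing tests therefore demonstrate the correctness and calibration of the
*procedure* under its assumed sampling model, not properties of any real
dataset; real-data headline numbers additionally depend on the genome and
libraries used.

## Problem sizes and numerical conventions

Tests and the acceptance script scale the genome down so the full pipeline
runs in minutes: maps of 10⁴–5×10⁵ CpGs (up to 5,000 tiles), 2–8 groups of
6–7 cells, 10–20 replicate seeds for stochastic checks, 20 label
permutations per randomization. These sizes keep Monte-Carlo error small
relative to the margins asserted (e.g. binomial SE on a tile mean at 300
pooled reads ≈ 2–3 percentage points against a planted 40-point effect).

All randomness flows through `numpy.random.default_rng` seeds carried in
`SimDesign` or passed explicitly; identical seeds give byte-identical
outputs. Exact-test ties use the `1 + 1e-7` relative tolerance; SD uses
ddof = 1; quantile intervals for the randomization check are inclusive.
Degenerate inputs (empty call sets, single-sample groups, zero informative
tiles, all-identical counts) return defined results or typed errors
(`InvalidParameterError`, `ValidationError`, `InsufficientDataError`,
`ParseError`) rather than silent NaNs.

## Known limitations

- The q-value method is Benjamini–Hochberg; it does not reproduce the SLIM
  q-values of methylKit bit-for-bit, so DMR lists can differ at the margin
  for data processed with that package.
- The pooled Fisher test ignores between-cell overdispersion; the logistic
  option shares this limitation. With six cells per group a random-effects
  test would be poorly identified, which is exactly why the randomization
  and recurrence controls exist.
- Whether the 20-point difference threshold should apply to the pooled or
  the mean-of-cells difference is ambiguous in general; the mean-of-cells
  convention used here treats cells as replicates.
- Label randomization permutes within the two compared groups; resampling
  across all eight groups is a plausible alternative and is not implemented.
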