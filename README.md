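# tilemeth

Single-cell bisulfite methylome analysis over CpG-count tiles: per-cell QC,
100-CpG genome tiling, differential methylation calling with
label-randomization false-positive control and a recurrence-based consensus
rule, and methylome variability/correlation statistics — plus a synthetic
single-cell methylome generator so every stage can be verified against
planted ground truth.

## The problem

Mature oocytes carry a distinctive DNA methylation landscape: hypermethylated
transcribed gene bodies over a largely unmethylated intergenic background.
Whether hormone-stimulated ovulation (superovulation with FSH/hMG at
different doses) perturbs this landscape is an epigenetic-safety question
that can only be addressed at the single-cell level, because each oocyte is
one cell. Single-cell post-bisulfite (pBAT) libraries, however, are sparse —
on the order of a few million CpGs covered at ~1x per cell out of >20
million — so the analysis must aggregate, filter and control false positives
carefully. `tilemeth` implements that analysis for anyone working with
Bismark-style cytosine reports from sparse single-cell libraries.

## Method

- **QC.** A cell is kept when mapping efficiency ≥ 10% and it covers
  strictly more than 10⁶ CpG sites. Bisulfite conversion is estimated from
  unmethylated lambda spike-in DNA as
  `#unmethylated C calls / #total C calls`.
- **Tiling.** Because CpGs are unevenly spaced, the genome is partitioned
  into non-overlapping tiles of 100 consecutive CpGs. A tile's level in a
  cell is the mean of per-site methylation fractions, `m̄ = (1/k) Σ mᵢ/nᵢ`.
- **Differential methylation.** For one treatment-vs-control pair, only
  *informative* tiles (≥ 5 covered CpGs in ≥ 2 cells per group) are tested.
  The default test is an exact two-sided Fisher test on pooled
  methylated/unmethylated read counts; a binomial-GLM likelihood-ratio test
  is available. Benjamini–Hochberg q-values are computed over all tested
  tiles, and a tile is a DMR when `q < 0.05` and the group-mean difference
  exceeds 20 percentage points.
- **False-positive control.** Re-running the whole procedure under shuffled
  sample labels yields DMR counts comparable to the real labels at these
  sample sizes, so single-comparison calls are unreliable. The *consensus*
  rule therefore keeps only tiles significant with a consistent direction in
  at least two of the three dose-vs-control comparisons of one hormone.
- **Annotation and variability.** Tiles are classed promoter / gene body /
  other at their midpoint (promoters: −1500/+500 bp of a TSS with > 8 CpGs)
  with nearest-TSS distances; variability is the within-group SD of tile
  levels, stratified by CpG-island methylation class; sample similarity is
  pairwise-complete Pearson correlation clustered with average linkage on
  `1 − r`.

The synthetic generator (`tilemeth.simulate`) emulates the assumed data
structure — domain-structured bimodal methylation, Bernoulli per-CpG capture
at depth 1, conversion-error bit-flips, planted group-specific DMRs — and
returns the planted truth for recovery testing.

## Worked example

```python
import tilemeth as tm

cpg_map = tm.generate_genome_cpg_map(n_chroms=2, cpgs_per_chrom=20_000,
                                     mean_gap_bp=100, seed=1)
annotation = tm.generate_gene_annotation(cpg_map, n_genes=10, seed=2)

design = tm.SimDesign(
    groups=(
        tm.GroupSpec("natural", "", 6, None),
        tm.GroupSpec("FSH5", "5IU", 6, "FSH"),
        tm.GroupSpec("FSH50", "50IU", 6, "FSH"),
        tm.GroupSpec("FSH200", "200IU", 6, "FSH"),
    ),
    seed=3, n_planted_per_profile=10, capture_prob=0.4,
)
samples, truth = tm.simulate_methylomes(cpg_map, annotation, design)
matrix = tm.tile_methylation(tm.make_tiles(cpg_map), samples, cpg_map)
print(tm.pairwise_dmr(matrix, "FSH5", "natural").summary())
```

prints

```
Pairwise differential methylation
==============================================
treatment:        FSH5
control:          natural
test:             fisher_pooled
informative tiles 400
thresholds:       q < 0.05, |diff| > 20.0 pp
DMRs:             10 (5 hyper / 5 hypo)
```

All 10 planted tiles (5 shifted up by 40 percentage points, 5 down) are
called with the correct sign and nothing else. Fitting the other two doses
on the shared informative set and applying the recurrence rule:

```python
results = [tm.PairwiseDMR(matrix, t, "natural").fit()
           for t in ("FSH5", "FSH50", "FSH200")]   # use a shared tile_subset
consensus = tm.consensus_dmrs(results, min_recurrence=2)
print(consensus.summary())
# Consensus DMRs over ['FSH5', 'FSH50', 'FSH200'] (recurrence >= 2):
#   10 tiles (5 hyper / 5 hypo)
```

while shuffling the sample labels collapses the signal
(`tm.randomized_combinations(matrix, "FSH5", "natural", n_perm=20, seed=4)`
observed 10 DMRs against a shuffled-label median of 0), showing that the
recovered tiles are driven by the group structure and not by sparsity
artifacts.

The same pipeline is scriptable from a shell via the `tilemeth` command
(`simulate`, `validate`, `qc`, `tile`, `regions`, `dmr`, `dmr-consensus`,
`dmr-null`, `variability`, `correlate`).

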