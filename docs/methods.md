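# Methods

This note documents the models, estimators and numerical choices behind
`bcellomics`, and what the simulator does and does not emulate.

## The simulated study

The generator emulates a two-genotype (Dnmt3-sufficient "WT" /
-deficient "KO"), three-cell-type (naive B → germinal-center B →
bone-marrow plasma cell), three-replicate design. Its defaults encode
the study's structure:

* **Genome.** One chromosome (default 2 Mb) of uniform-ACGT sequence
  (25% each base, matching the motif-scan background), 150
  non-overlapping genes of 2–6 kb with 2–5 exons, 16 of them
  immunoglobulin segments (IgM/IgD/IgG/IgA constant classes and IgV
  variable segments), 40 enhancer intervals of 1 kb, and 200 instances
  per motif of near-consensus PWMs (AP-1 `TGACTCA`, an octamer
  `ATGCAAAT`) implanted verbatim (reverse-complemented on the − strand).
  The CpG map is recomputed from the final sequence, so implantation and
  CpG coordinates are always consistent. Gene and peak placement uses
  Dirichlet-gap packing, which errors out explicitly when the requested
  content cannot fit.
* **Methylation.** Per-site baselines π ~ Beta(8, 2) (mean 0.8, the
  high-methylation genome background); coverage ~ NB(mean 30, size 10),
  the middle of the study's 10–50× range; counts are beta-binomial with
  dispersion φ = 0.02. Differentiated cell types lose Δ = 0.4 at 10% of
  sites in both genotypes (activation-driven demethylation is
  Dnmt3-independent) and gain Δ = 0.4 at 2% of sites only in the
  sufficient genotype (de novo methylation requires Dnmt3). Hyper sites
  are drawn preferentially from the spans of Dnmt3-dependent repressed
  genes, which is what produces the negative methylation–expression
  correlation downstream. Options place hypo sites near a chosen motif
  (within 50 bp) or inside enhancers, and a promoter-hypomethylation
  mode implants a V-shaped dip (deepest at the TSS, ±500 bp) at the
  top expression quartile, ranking genes on the FPKM (length-normalized)
  scale used by the downstream stratification.
* **Expression.** Relative gene abundances are lognormal (σ = 1);
  each cell type's Ig budget (4.0% naive, 2.7% germinal-center, 47.4%
  plasma cell; 1%/79%/70% class-switched) is carved out of the
  transcriptome and split over constant classes (75%) and V segments
  (25%, Dirichlet usage). Counts are NB with dispersion 0.1
  (BCV ≈ 0.32) for ordinary genes and 0.01 for Ig genes — the Ig budget
  is a cell-state property, far more stable than gene-level biological
  variability, and a handful of dominant constant-region genes at
  BCV 0.32 would make the budget swing by several percent. 10% of genes
  are repressed 4-fold upon differentiation and 3% induced; half the
  repressed set is Dnmt3-dependent and fails to repress in the KO
  (single-genotype designs have no perturbation arm, so there the
  effects track differentiation alone).
* **ATAC.** Cut sites are generated directly as 5′ start bases (the
  footprint statistic consumes nothing else). A FRiP-fraction of each
  sample's reads (default 0.15 of 400k) is multinomial over peaks with
  lognormal weights and per-sample gamma noise (dispersion 0.05);
  background reads land uniformly outside peaks, which makes the
  realized FRiP match the design value by construction. The default
  depth gives ~60 in-peak reads per peak, the per-peak coverage of a
  typical ATAC study (~20 M reads over ~50k peaks). Peaks are centered
  on bound-motif instances where available; inside those, draws within
  ±10 bp of the motif center are accepted with probability equal to the
  depletion factor (rejection sampling, each read settles exactly once),
  carving a footprint whose center/flank rate ratio equals the factor.
  5% of peaks are 4-fold more accessible in the affected groups.

Everything is a deterministic function of the design's seed
(`numpy` `SeedSequence` substreams per data type); identical seeds give
byte-identical files.

**What the simulator does not emulate:** read-level artifacts (FASTQ,
alignment, bisulfite conversion failure, PCR duplicates), CpG islands
and genomic sequence composition, spatial correlation of methylation
along the genome, fragment-length structure of ATAC, trans effects
between loci beyond the implanted couplings. Passing tests therefore
demonstrate the statistics behave correctly under the stated models,
not that real libraries satisfy those models.

## Differential methylation

Per CpG, methylated counts are beta-binomial: Var(m) = c·π(1−π)(1+(c−1)φ).
Group means are pooled (coverage-weighted) proportions. The test
statistic is the difference of arcsin√μ between groups; by the delta
method its variance is Σc(1+(c−1)φ)/(4S²) per group — independent of
the unknown proportion, which is the point of the transform. Two-sided
p from the normal reference; effect sizes (Δme) are reported on the raw
proportion scale because the 20% threshold lives there.

The dispersion is method-of-moments with an exact small-sample
correction: residuals around the fitted group mean carry coefficients
w_j = (1−c_j/S)² + (Q−c_j²)/S² on their variances (S, Q the group's
coverage sum and sum of squares). Without this, the estimator loses a
degree of freedom and collapses to zero at n = 3, which inflates the
Wald statistic by √(n/(n−1)). Per-site estimates are then shrunk toward
the genome-wide **mean** of the corrected estimates with weight
2/n_reps. The mean, not the median, because clipping at zero skews the
per-site sampling distribution: on calibration simulations the median
sat at roughly half the true dispersion while the mean was nearly
unbiased, and a median target left the null visibly anti-conservative.
With these choices the null p-values are uniform at n = 3/group and
30× coverage.

Sites are filtered at 10× pooled coverage per group before testing;
the stricter per-sample filter is used for heat-map/PCA-style summaries.
Sites with zero pooled coverage in a group are excluded and counted in
a log line.

## Differential expression and accessibility

One NB Wald test serves both data types; only the offsets differ (total
counts for RNA, reads-in-peaks for ATAC — the latter keeps the test
consistent with RPM normalization). Group abundances are pooled
estimates q_g = Σy/Σs; the moment dispersion uses the same exact
residual-coefficient correction as above, pooled over groups, then is
shrunk 50/50 toward a trend over mean expression (bin means over 20
quantile bins, linearly interpolated — means, not medians, for the same
clipping-skew reason). Fold changes come from prior-count-shrunken
pooled means (prior 0.5).

The Wald statistic is referred to a t distribution with per-feature
degrees of freedom 3(n₁+n₂−2)/share², where share = αμ/(1+αμ) is the
dispersion term's share of the NB variance. Rationale: only the αμ²
term of Var = μ+αμ² carries estimation noise, so Poisson-dominated
(low-count) features are essentially normal, while
dispersion-dominated features behave like a t with the moderated
dispersion's effective degrees of freedom — the factor 3 reflecting the
~4-fold variance reduction of the 50/50 trend moderation, validated on
null simulations of both the RNA regime (mean ~100–200, α = 0.1) and
the ATAC regime (mean ~60, α = 0.05). A flat reference in either
direction fails one regime or the other.

Thresholds follow the study: DEGs at BH FDR ≤ 0.05 with 2-fold change
after keeping genes above 1 FPKM (strict) in at least two samples (the
stricter FDR ≤ 0.01 variant used for some displays is a parameter);
DARs at FDR ≤ 0.01 with 2-fold, on QC-passing samples only (FRiP within
the closed interval [0.05, 0.25]).

## K-means programs

Lloyd's algorithm on row-z-scored matrices, best of n_start random
initializations (centroids seeded from data rows) by within-cluster sum
of squares, deterministic given the seed. The per-iteration objective
is asserted non-increasing; empty clusters are re-seeded at the
worst-fit point. Hand-written rather than delegated so the objective
trace is inspectable; scikit-learn's KMeans serves as an independent
optimum check in the tests. Defaults mirror the study's settings
(50 iterations / 100 starts for expression, 1000/100 for accessibility).

## Motif scanning and enrichment

PWMs are probability matrices scored as Σ log₂((p+10⁻³)/bg) with a
uniform background; both strands are scanned (the − strand by scoring
the reverse-complement matrix on the + sequence, so reported starts are
always leftmost-genomic) and windows containing non-ACGT bases are
skipped. The hit threshold defaults to 80% of each motif's maximum
attainable score — a per-motif cutoff in the spirit of curated motif
libraries without depending on one. Overlapping hits are kept.

Enrichment near DML forms, per motif, the 2×2 table {DML, non-DML
universe} × {within 50 bp of a hit (inclusive, distance to the nearest
hit base), not}, with the universe = all tested CpGs; cluster
enrichment tests {in cluster, other regions} × {≥ 1 hit, none}. Both
use Fisher's exact test (two-sided by the probability-mass-at-most-
observed rule; sample OR = ad/bc, with a Haldane–Anscombe-corrected OR
reported alongside since perfect separations are routine) and BH
correction. One calibration caveat is inherent to exact tests: their
discrete p-values are only near-uniform under permutation when the
table entries are large, so the permutation-calibration check is run at
a scale (≈8k proximal of 20k universe sites, 4k permuted labels) where
discreteness is negligible; at small counts the discrete p is
conservative, never liberal.

## Footprinting

Only the base at which each read began is counted. The motif center is
start + ⌊L/2⌋; offsets are read − center for + instances and mirrored
for − instances, aggregated over instances and samples, with rates per
million total reads (the normalization denominator the reads-in-peaks
convention does not specify; documented choice). The footprint depth
statistic is the mean rate at |offset| ≤ 5 over the mean in the
50–100 bp flank band; the profile minimum is located after a 21-bp
moving-average smooth because a flat-bottomed well has no unique
pointwise minimum. No Tn5 +4/−5 shift is applied by default (available
as an option); windows truncated at chromosome ends are flagged.

## Integration statistics

* **Closest gene**: nearest gene-span boundary (distance 0 inside the
  span), ties to the lexicographically smaller gene id, signed
  upstream(−)/downstream(+) in gene orientation; a TSS-anchored variant
  is available.
* **DML × DEG overlap**: gene-level hypergeometric upper tail with
  expected overlap DE/G; "DML-proximal" in the pipeline means a DML
  inside the gene span.
* **Meta-gene profiles**: CpGs mapped to their closest gene's grid —
  50 upstream-flank bins (absolute bp), 100 body bins (span fraction),
  50 downstream bins — strand-flipped for − genes; genes stratified
  into quartiles of mean FPKM; bin means smoothed by a tricube-weighted
  local quadratic over a span-0.1 fraction of grid points (an explicit
  loess-equivalent; exact numerical equality with any particular loess
  implementation is not claimed). Sparse windows degrade to weighted
  means, empty stretches are linearly interpolated, and a constant
  signal is reproduced exactly.
* **Accessibility at DML**: reads whose 5′ base equals the cytosine
  position exactly, per million total reads, with group means.
* **Enhancer overlap**: Fisher on {DML, non-DML} × {inside a half-open
  enhancer interval, not}.
* **Correlation**: Spearman ρ with average-rank ties and the
  large-sample t approximation for significance (the study's
  description of the significance computation is ambiguous; the
  standard approximation is used).
* **PCA**: SVD of feature-centered data, sample scores U·S, variance
  fractions σ²ᵢ/Σσ² summing to one.

## Pipeline

`run_all` executes simulate → DML → DEG/Ig → ATAC QC + DAR + clustering
→ motif scan/enrichment → footprints → integration from a single JSON
config, writing TSV/BED/FASTA/GTF/JSON artifacts and a manifest of
SHA-256 checksums. Contrasts default to first-genotype
naive-vs-terminal for methylation/expression and WT-vs-KO in the
terminal cell type for accessibility. All timings go to the log, never
into checksummed files, so fixed-seed runs are checksum-identical.

## Problem sizes

Tests and the acceptance script run the calibration and recovery
checks at 10⁴ CpGs, 5×10³ genes (16 Mb toy chromosome, 1–3 kb genes)
and 2×10³ peaks with 3 replicates per group, and the end-to-end demo on
a 1 Mb genome with 2 replicates — sizes chosen so the whole suite
completes in a few minutes on one CPU while keeping every Monte-Carlo
margin comfortably away from its threshold.

## Known limitations

* No spatial smoothing across neighboring CpGs and no region (DMR)
  merging; single-CpG resolution only.
* The NB test is a Wald approximation, not edgeR's exact conditional
  test or quasi-likelihood F — tool-level numerical equality is not
  claimed, only matching operating characteristics (calibration, power
  at the stated thresholds).
* Total-count normalization (no TMM); composition effects from heavy
  asymmetric differential signal shift log-fold-changes of null
  features slightly.
* The exact-test discreteness caveat above applies to any enrichment
  run with few DML.
* The simulator's independence assumptions (sites, genes, peaks) make
  power estimates optimistic relative to correlated real data.
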