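# bcellomics

Integrative RRBS + RNA-seq + ATAC-seq analysis of B-cell terminal
differentiation, with a ground-truth tri-omic simulator.

During the germinal-center reaction and plasma-cell differentiation, B
cells lose DNA methylation at over a hundred thousand CpGs, while the de
novo methyltransferases Dnmt3a/Dnmt3b add methylation at a much smaller
set of loci. `bcellomics` implements the statistical pipeline used to
show that this de novo methylation represses the plasma-cell chromatin
and expression program:

* **Differential methylation** — per-CpG beta-binomial model on bisulfite
  counts. Group means are pooled proportions μ<sub>g</sub> = Σm/Σc; a
  Wald test on arcsin√μ (variance-stabilized, so the null variance is
  free of μ) with moment dispersions φ̂ shrunk toward the genome-wide
  mean. Calls require BH FDR ≤ 0.05 and |Δme| ≥ 20% after a 10×-coverage
  filter.
* **Differential expression / accessibility** — negative-binomial Wald
  test with offsets (library size for genes, reads-in-peaks for ATAC
  peaks), bias-corrected moment dispersion shrunk 50/50 toward a mean
  trend, and a Satterthwaite-style t reference. DEGs: FDR ≤ 0.05 and
  2-fold after an FPKM > 1 (≥ 2 samples) filter. DARs: FDR ≤ 0.01 and
  2-fold. ATAC signal is normalized as RPM = reads × 10⁶ / reads-in-peaks
  (Σ<sub>peaks</sub> RPM = 10⁶ per sample), with samples outside 5–25%
  FRiP removed.
* **Motifs and footprints** — genome-wide PWM scanning (log₂-odds, both
  strands), Fisher-exact enrichment of motifs within 50 bp of DML and
  within K-means clusters of differential regions, and cut-site
  footprinting that counts only the base where each ATAC read began,
  mirrored onto motif orientation.
* **Integration** — closest-gene annotation of CpGs, hypergeometric
  DML × DEG overlap (expected = DE/G), meta-gene methylation profiles
  stratified by expression quantile with loess-like span-0.1 smoothing,
  accessibility exactly at differentially methylated cytosines,
  enhancer-overlap odds ratios, Spearman Δme–Δexpression correlation,
  and PCA with percent variance explained.
* **Simulator** — a toy genome with gene models, implanted transcription
  factor motifs, enhancers and a CpG map, plus beta-binomial RRBS counts,
  NB expression (including the immunoglobulin transcript budget: 4% of
  mRNA in naive B cells, 2.7% in germinal-center B, 47.4% in plasma
  cells, with 79%/70% class-switched) and ATAC cut sites with peaks,
  footprints and accessibility gains — all with truth tables so every
  caller can be scored.

## Worked example

```python
from bcellomics import (SimDesign, generate_genome, simulate_methylation,
                        filter_coverage, test_dml, call_dml)

design = SimDesign(seed=1)            # 2 genotypes x 3 cell types x 3 reps
layout, _ = generate_genome(design)
meth, truth = simulate_methylation(layout, design)

tested = filter_coverage(meth, min_cov=10, scope="per_group")
called = call_dml(test_dml(tested, ("WT_nB", "WT_BMPC")))
print(called.attrs["summary"])
```

prints

```
{'n_dml': 1181, 'n_hypo': 964, 'n_hyper': 217}
```

— of 10,000 simulated CpGs, 1,181 are called differentially methylated
between naive B cells and plasma cells: 964 lose methylation on
differentiation and 217 gain it (the Dnmt3-dependent de novo set).
Scored against the generator's truth table this run has 95.7%
sensitivity at a realized false-discovery proportion of 0.028.

The `examples/` directory holds one short script per capability
(simulation, DML, DEG + Ig repertoire, ATAC + footprinting, motif
enrichment, integration, full pipeline). The pipeline also has a thin
CLI:

```bash
bcellomics run --config examples/demo_config.json --out demo_out
```

which writes every stage's outputs plus a checksum manifest and summary
(deterministic for a fixed seed).

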