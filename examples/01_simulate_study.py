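"""Generate the synthetic B-cell differentiation study.

Builds a toy genome (genes, CpG map, enhancers, implanted TF motifs) and
tri-omic data for 2 genotypes x 3 cell types x 3 replicates: bisulfite
CpG counts, gene-level RNA counts and ATAC cut sites, each with a
ground-truth table.
"""

from bcellomics import SimDesign, generate_genome, simulate_atac, \
    simulate_expression, simulate_methylation

design = SimDesign(seed=1)
layout, sequences = generate_genome(design)
print(f"genome: {design.chrom} of {design.chrom_length:,} bp, "
      f"{len(layout.genes)} genes, "
      f"{len(layout.cpg_positions[design.chrom]):,} CpGs, "
      f"{len(layout.motif_truth)} implanted motif instances")

meth, meth_truth = simulate_methylation(layout, design)
n_spiked = int((meth_truth["is_hypo"] | meth_truth["is_hyper"]).sum())
print(f"RRBS: {meth.n_sites:,} CpG sites x {len(meth.samples)} samples, "
      f"{n_spiked} differential loci implanted "
      f"({int(meth_truth['is_hypo'].sum())} hypo on differentiation, "
      f"{int(meth_truth['is_hyper'].sum())} de novo gains)")

expr, expr_truth = simulate_expression(layout, design)
print(f"RNA: {expr.counts.shape[0]} genes x {expr.counts.shape[1]} samples, "
      f"mean library {expr.library_size.mean():,.0f} reads")

cuts, peaks, atac_truth = simulate_atac(layout, design)
print(f"ATAC: {len(peaks)} peaks, {len(cuts.table):,} cut sites, "
      f"{int(atac_truth['is_da'].sum())} differentially accessible peaks, "
      f"{int(atac_truth['has_footprint'].sum())} peaks with a TF footprint")
# Every downstream example starts from exactly these objects; the truth
# tables let each caller be scored for sensitivity and false discoveries.
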