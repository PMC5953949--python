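"""Cross-omic integration: closest-gene annotation, DML x DEG overlap,
meta-gene methylation by expression, accessibility at DML, enhancer
overlap, and the methylation-expression correlation.
"""

from bcellomics import SimDesign, accessibility_at_sites, annotate_closest_gene, \
    call_deg, call_dml, compute_fpkm, dml_deg_overlap, enhancer_overlap, \
    filter_coverage, filter_expressed, generate_genome, correlate_changes, \
    metagene_methylation, pca_summary, simulate_atac, simulate_expression, \
    simulate_methylation, test_deg, test_dml

design = SimDesign(seed=1)
layout, _ = generate_genome(design)
meth, _ = simulate_methylation(layout, design)
expr, _ = simulate_expression(layout, design)
cuts, peaks, _ = simulate_atac(layout, design)

tested = filter_coverage(meth, 10, "per_group")
dml_tab = call_dml(test_dml(tested, ("WT_nB", "WT_BMPC")))
dml = dml_tab.loc[dml_tab["is_dml"], ["chrom", "pos"]]
fpkm = compute_fpkm(expr)
deg_tab = call_deg(test_deg(expr, design.sample_groups, ("WT_nB", "WT_BMPC"),
                            genes=filter_expressed(fpkm)))

ann = annotate_closest_gene(dml, layout)
uni_ann = annotate_closest_gene(tested.sites, layout)
dml_genes = set(ann.loc[ann["distance"] == 0, "gene_id"])
deg_genes = set(deg_tab.loc[deg_tab["is_deg"], "gene"])
ov = dml_deg_overlap(dml_genes, deg_genes,
                     set(uni_ann["gene_id"]) | dml_genes | deg_genes)
print(f"{ov.observed} genes carry both a DML and differential expression "
      f"(expected {ov.expected:.1f}, fold {ov.fold:.2f}, P = {ov.p:.3g})")

enh = enhancer_overlap(dml, tested.sites, layout.enhancers)
print(f"DML vs enhancers: OR {enh['odds_ratio_haldane']:.1f}, P = {enh['p']:.2e}")

acc = accessibility_at_sites(cuts, dml, design.sample_groups)
print(f"accessibility at DML cytosines (reads/M): "
      f"WT BMPC {acc['mean_WT_BMPC'].mean():.2f} vs "
      f"KO BMPC {acc['mean_KO_BMPC'].mean():.2f}")

merged = ann.merge(dml_tab[["chrom", "pos", "delta_me"]], on=["chrom", "pos"]) \
            .merge(deg_tab[["gene", "log2fc"]], left_on="gene_id", right_on="gene")
rho, p = correlate_changes(merged["delta_me"], merged["log2fc"])
print(f"Spearman rho(delta methylation, delta expression) = {rho:.2f} "
      f"(P = {p:.2g}, n = {len(merged)})")
# A negative rho reproduces the study's inverse coupling: loci gaining
# methylation sit at genes being repressed.

per = filter_coverage(meth, 10, "per_sample")
msites = per.sites.copy()
msites["meth"] = per.methylated.sum(axis=1) / per.coverage.sum(axis=1)
prof = metagene_methylation(msites, layout, fpkm)
tss = prof[(prof["grid"] == 50)]
print("methylation at the TSS by expression stratum (1=low, 4=high): " +
      ", ".join(f"{int(r['stratum'])}: {r['methylation']:.2f}"
                for _, r in tss.iterrows()))

import pandas as pd
mfrac = pd.DataFrame(per.methylated / per.coverage.clip(min=1),
                     columns=per.samples)
pca = pca_summary(mfrac)
print(f"methylation PCA: PC1 explains {pca['percent_variance'][0]:.1f}%, "
      f"PC2 {pca['percent_variance'][1]:.1f}%")
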