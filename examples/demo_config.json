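{
 "alpha_dar": 0.01,
 "alpha_deg": 0.05,
 "alpha_dml": 0.05,
 "contrast_atac": null,
 "contrast_expr": null,
 "contrast_meth": null,
 "delta_me": 0.2,
 "design": {
  "atac_dispersion": 0.05,
  "bound_motifs": [
   "AP1"
  ],
  "celltypes": [
   "nB",
   "GCB",
   "BMPC"
  ],
  "chrom": "chr1",
  "chrom_length": 1000000,
  "couple_hyper_to_repressed": true,
  "coverage_mean": 30.0,
  "coverage_size": 10.0,
  "da_fold": 4.0,
  "dnmt3_dependent_frac": 0.5,
  "enhancer_width": 1000,
  "exons_per_gene": [
   2,
   5
  ],
  "expr_dispersion": 0.1,
  "expr_log_sd": 1.0,
  "fold_change": 4.0,
  "footprint_depletion": 0.2,
  "footprint_halfwidth": 10,
  "frac_da": 0.05,
  "frac_down": 0.1,
  "frac_hyper": 0.02,
  "frac_hypo": 0.1,
  "frac_up": 0.03,
  "frip": 0.15,
  "frip_overrides": {},
  "gene_span_range": [
   2000,
   6000
  ],
  "genotypes": [
   "WT",
   "KO"
  ],
  "hypo_in_enhancer_frac": 0.3,
  "hypo_near_motif": null,
  "hypo_near_window": 50,
  "ig_dispersion": 0.01,
  "ig_fraction": {
   "BMPC": 0.474,
   "GCB": 0.027,
   "nB": 0.04
  },
  "ig_genes": {
   "IgA": 2,
   "IgD": 1,
   "IgG": 3,
   "IgM": 2,
   "IgV": 8
  },
  "library_size_cv": 0.1,
  "library_size_mean": 1000000.0,
  "meth_baseline": [
   8.0,
   2.0
  ],
  "meth_delta": 0.4,
  "meth_dispersion": 0.02,
  "motifs": {
   "AP1": "TGACTCA",
   "OCT2": "ATGCAAAT"
  },
  "n_cpg_sites": 5000,
  "n_enhancers": 40,
  "n_genes": 100,
  "n_motif_instances": 100,
  "n_peaks": 500,
  "n_reps": 2,
  "peak_width": 200,
  "promoter_hypo_top_stratum": false,
  "promoter_window": 500,
  "reads_per_sample": 100000,
  "seed": 11,
  "switched_fraction": {
   "BMPC": 0.7,
   "GCB": 0.79,
   "nB": 0.01
  }
 },
 "enrich_window": 50,
 "fc_dar": 2.0,
 "fc_deg": 2.0,
 "footprint_halfwidth": 100,
 "frip_bounds": [
  0.05,
  0.25
 ],
 "k_clusters": 4,
 "metagene_span": 0.1,
 "min_cov": 10,
 "min_fpkm": 1.0,
 "min_fpkm_samples": 2
}
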