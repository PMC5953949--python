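"""End-to-end orchestration: simulate -> differential calls -> motif scan /
enrichment -> footprinting -> integration, with a checksum manifest."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import atac as atacmod
from . import exprdiff, integrate, io, methdiff, motif as motifmod
from .simulate import SimDesign, consensus_pwm, generate_genome, simulate_atac, \
    simulate_expression, simulate_methylation

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Thresholds and contrasts for a full run; round-trips to JSON."""

    design: SimDesign = field(default_factory=SimDesign)
    min_cov: int = 10
    alpha_dml: float = 0.05
    delta_me: float = 0.20
    alpha_deg: float = 0.05
    fc_deg: float = 2.0
    alpha_dar: float = 0.01
    fc_dar: float = 2.0
    frip_bounds: tuple[float, float] = (0.05, 0.25)
    min_fpkm: float = 1.0
    min_fpkm_samples: int = 2
    enrich_window: int = 50
    footprint_halfwidth: int = 100
    metagene_span: float = 0.1
    k_clusters: int = 4
    # contrasts: (reference group, test group); None -> derived from design
    contrast_meth: tuple[str, str] | None = None
    contrast_expr: tuple[str, str] | None = None
    contrast_atac: tuple[str, str] | None = None

    def validate(self) -> None:
        self.design.validate()
        for a in (self.alpha_dml, self.alpha_deg, self.alpha_dar):
            if not 0 < a < 1:
                raise ValueError("alpha thresholds must be in (0, 1)")
        if not 0 <= self.delta_me <= 1:
            raise ValueError("delta_me must be in [0, 1]")
        lo, hi = self.frip_bounds
        if not 0 <= lo < hi <= 1:
            raise ValueError("bad FRiP bounds")

    def resolved_contrasts(self) -> dict[str, tuple[str, str]]:
        d = self.design
        groups = d.groups
        first_gt = d.genotypes[0]
        diff = (f"{first_gt}_{d.celltypes[0]}", f"{first_gt}_{d.celltypes[-1]}")
        if len(d.genotypes) > 1:
            geno = (f"{d.genotypes[0]}_{d.celltypes[-1]}",
                    f"{d.genotypes[-1]}_{d.celltypes[-1]}")
        else:
            geno = diff
        out = {
            "meth": self.contrast_meth or diff,
            "expr": self.contrast_expr or diff,
            "atac": self.contrast_atac or geno,
        }
        for k, (a, b) in out.items():
            if a not in groups or b not in groups:
                raise ValueError(f"unknown group in contrast {k}: {(a, b)}")
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = self.design.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["design"] = SimDesign.from_dict(d.get("design", {}))
        for k in ("frip_bounds", "contrast_meth", "contrast_expr", "contrast_atac"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage into ``out_dir``; returns the manifest dict
    (also written as ``manifest.json``) with per-file checksums and the
    summary report."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    contrasts = config.resolved_contrasts()
    summary: dict = {"contrasts": {k: list(v) for k, v in contrasts.items()}}
    t0 = time.time()
    current = {"stage": "init"}

    def _stage(name):
        current["stage"] = name
        log.info("[%6.1fs] stage %s", time.time() - t0, name)

    try:
        # ---------------------------------------------------- simulate
        _stage("simulate")
        layout, seqs = generate_genome(design)
        io.write_fasta(out / "genome.fa", seqs)
        io.write_gtf(out / "genes.gtf", layout)
        io.write_bed6(out / "enhancers.bed", layout.enhancers)
        io.write_bed6(out / "motif_truth.bed", layout.motif_truth.rename(
            columns={"motif_id": "name"}).assign(
            end=lambda df: df["start"] + df["name"].map(
                {k: len(v) for k, v in design.motifs.items()})))
        pwms = [motifmod.MotifModel(mid, consensus_pwm(cons))
                for mid, cons in design.motifs.items()]
        motifmod.write_jaspar(out / "motifs.jaspar", pwms)

        meth, meth_truth = simulate_methylation(layout, design)
        cov_dir = out / "coverage"
        cov_dir.mkdir(exist_ok=True)
        for s in meth.samples:
            io.write_bismark_cov(cov_dir / f"{s}.cov", meth, s)
        meth_truth.to_csv(out / "truth_methylation.tsv", sep="\t", index=False)

        expr, expr_truth = simulate_expression(layout, design)
        io.write_count_matrix(out / "gene_counts.tsv", expr)
        expr_truth.to_csv(out / "truth_expression.tsv", sep="\t")

        cutsites, peaks, atac_truth = simulate_atac(layout, design)
        io.write_cutsites(out / "cutsites.tsv", cutsites)
        io.write_bed6(out / "peaks.bed", peaks)
        atac_truth.to_csv(out / "truth_atac.tsv", sep="\t", index=False)

        # --------------------------------------------------------- dml
        _stage("dml")
        tested = methdiff.filter_coverage(meth, config.min_cov, scope="per_group")
        dml_rec = methdiff.test_dml(tested, contrasts["meth"])
        dml_tab = methdiff.call_dml(dml_rec, config.alpha_dml, config.delta_me)
        dml_tab.to_csv(out / "dml.tsv", sep="\t", index=False)
        dml_bed = dml_tab[dml_tab["is_dml"]].copy()
        dml_bed["start"] = dml_bed["pos"]
        dml_bed["end"] = dml_bed["pos"] + 1
        dml_bed["name"] = dml_bed["direction"]
        dml_bed["score"] = np.round(-np.log10(np.maximum(dml_bed["fdr"], 1e-300)), 3)
        io.write_bed6(out / "dml.bed", dml_bed)
        summary["dml"] = dml_tab.attrs["summary"] | {"n_tested": int(len(dml_tab))}

        # --------------------------------------------------------- deg
        _stage("deg")
        fpkm = exprdiff.compute_fpkm(expr)
        expressed = exprdiff.filter_expressed(fpkm, config.min_fpkm,
                                              config.min_fpkm_samples)
        deg_rec = exprdiff.test_deg(expr, design.sample_groups, contrasts["expr"],
                                    genes=expressed)
        deg_tab = exprdiff.call_deg(deg_rec, config.alpha_deg, config.fc_deg)
        deg_tab.to_csv(out / "deg.tsv", sep="\t", index=False)
        n_up = int((deg_tab["is_deg"] & (deg_tab["log2fc"] > 0)).sum())
        n_down = int((deg_tab["is_deg"] & (deg_tab["log2fc"] < 0)).sum())
        summary["deg"] = {"n_tested": int(len(deg_tab)), "n_deg": n_up + n_down,
                          "n_up": n_up, "n_down": n_down}

        deg_genes = deg_tab.loc[deg_tab["is_deg"], "gene"]
        if len(deg_genes) >= config.k_clusters:
            z = np.log2(fpkm.loc[deg_genes] + 1)
            assign, means = exprdiff.kmeans_programs(
                z, config.k_clusters, max_iter=50, n_start=100, seed=design.seed)
            assign.to_csv(out / "deg_clusters.tsv", sep="\t")
        rep = exprdiff.ig_repertoire(expr, layout, design.sample_groups)
        io.write_json(out / "ig_repertoire.json", rep)
        summary["ig"] = rep.get("groups", {})

        # -------------------------------------------------------- atac
        _stage("atac")
        pk_counts = atacmod.reads_in_peaks(cutsites, peaks)
        qc = atacmod.qc_frip(pk_counts.attrs["frip"], *config.frip_bounds)
        qc.to_csv(out / "atac_qc.tsv", sep="\t", index=False)
        passing = qc.loc[qc["pass"], "sample"].tolist()
        failing = qc.loc[~qc["pass"], "sample"].tolist()
        summary["atac_qc"] = {"n_pass": len(passing), "failed_samples": failing}
        pk_pass = pk_counts[passing]
        pk_pass.attrs = dict(pk_counts.attrs)
        cm_atac = atacmod.peak_count_matrix(pk_pass)
        rpm = atacmod.rpm_normalize(
            cm_atac.counts, cm_atac.library_size.reindex(passing).to_numpy())
        rpm.to_csv(out / "peak_rpm.tsv", sep="\t")
        dar_design = {s: g for s, g in design.sample_groups.items() if s in passing}
        dar_rec = atacmod.test_dar(cm_atac, dar_design, contrasts["atac"])
        dar_tab = atacmod.call_dar(dar_rec, config.alpha_dar, config.fc_dar)
        dar_tab.to_csv(out / "dar.tsv", sep="\t", index=False)
        n_open = int((dar_tab["is_dar"] & (dar_tab["log2fc"] > 0)).sum())
        n_closed = int((dar_tab["is_dar"] & (dar_tab["log2fc"] < 0)).sum())
        summary["dar"] = {"n_tested": int(len(dar_tab)), "n_dar": n_open + n_closed,
                          "n_more_accessible": n_open, "n_less_accessible": n_closed}

        dar_names = dar_tab.loc[dar_tab["is_dar"], "name"]
        cluster_regions: dict[int, pd.DataFrame] = {}
        if len(dar_names) >= config.k_clusters:
            assign, _means = exprdiff.kmeans_programs(
                np.log2(rpm.loc[dar_names] + 1), config.k_clusters,
                max_iter=1000, n_start=100, seed=design.seed)
            assign.to_csv(out / "dar_clusters.tsv", sep="\t")
            pk_idx = peaks.set_index("name")
            for cl in sorted(assign.unique()):
                members = assign.index[assign == cl]
                cluster_regions[int(cl)] = pk_idx.loc[members].reset_index()

        # ------------------------------------------------- motif scan
        _stage("motif")
        hits = motifmod.scan_motifs(seqs, pwms)
        hits_bed = hits.rename(columns={"motif_id": "name"})
        io.write_bed6(out / "motif_hits.bed", hits_bed)
        universe = tested.sites
        dml_sites = dml_tab.loc[dml_tab["is_dml"], ["chrom", "pos"]]
        if len(dml_sites):
            enr = motifmod.enrich_near_dml(hits, dml_sites, universe,
                                           config.enrich_window)
            enr.to_csv(out / "motif_enrichment_dml.tsv", sep="\t", index=False)
            summary["motif_enrichment_top"] = enr.iloc[0]["motif_id"] if len(enr) else None
        if cluster_regions:
            enr_cl = motifmod.enrich_in_regions(hits, cluster_regions,
                                                peaks.assign(name=peaks["name"]))
            enr_cl.to_csv(out / "motif_enrichment_clusters.tsv", sep="\t", index=False)

        # --------------------------------------------------- footprint
        _stage("footprint")
        for mid in design.bound_motifs:
            mhits = hits[hits["motif_id"] == mid]
            if mhits.empty:
                continue
            prof = atacmod.footprint(cutsites, mhits, w=config.footprint_halfwidth,
                                     samples=passing, chrom_sizes=layout.chrom_sizes)
            prof.to_frame().to_csv(out / f"footprint_{mid}.tsv", sep="\t", index=False)
            summary.setdefault("footprint", {})[mid] = {
                "center_flank_ratio": prof.center_flank_ratio(),
                "n_instances": prof.n_instances,
            }

        # --------------------------------------------------- integrate
        _stage("integrate")
        ann = integrate.annotate_closest_gene(dml_sites if len(dml_sites) else universe,
                                              layout)
        ann.to_csv(out / "dml_annotated.tsv", sep="\t", index=False)
        universe_ann = integrate.annotate_closest_gene(universe, layout)
        if len(dml_sites) and len(deg_genes):
            # a gene is DML-proximal when a DML lies within its span
            dml_prox = set(ann.loc[ann["distance"] == 0, "gene_id"])
            ov = integrate.dml_deg_overlap(
                dml_prox, set(deg_genes),
                set(universe_ann["gene_id"]) | dml_prox | set(deg_genes))
            io.write_json(out / "overlap.json", ov.to_dict())
            summary["overlap"] = ov.to_dict()
        # meta-gene profile of the reference group's mean methylation
        ref_group = contrasts["meth"][0]
        per_sample = methdiff.filter_coverage(meth, config.min_cov, scope="per_sample")
        ref_cols = [j for j, s in enumerate(per_sample.samples)
                    if per_sample.design[s] == ref_group]
        msites = per_sample.sites.copy()
        cov_ref = per_sample.coverage[:, ref_cols].sum(axis=1)
        met_ref = per_sample.methylated[:, ref_cols].sum(axis=1)
        msites["meth"] = np.where(cov_ref > 0, met_ref / np.maximum(cov_ref, 1), np.nan)
        msites = msites.dropna(subset=["meth"]).reset_index(drop=True)
        prof = integrate.metagene_methylation(msites, layout, fpkm,
                                              span=config.metagene_span)
        prof.to_csv(out / "metagene.tsv", sep="\t", index=False)
        if len(dml_sites):
            acc = integrate.accessibility_at_sites(cutsites, dml_sites,
                                                   design.sample_groups)
            acc.to_csv(out / "dml_accessibility.tsv", sep="\t", index=False)
        enh = integrate.enhancer_overlap(
            dml_sites if len(dml_sites) else universe.iloc[:1], universe,
            layout.enhancers)
        io.write_json(out / "enhancer_overlap.json", enh)
        summary["enhancer_overlap"] = {"odds_ratio": enh["odds_ratio"], "p": enh["p"]}
        # delta-methylation vs delta-expression correlation over annotated DML
        if len(dml_sites) and len(deg_tab):
            merged = ann.merge(
                dml_tab[["chrom", "pos", "delta_me"]], on=["chrom", "pos"]
            ).merge(deg_tab[["gene", "log2fc"]], left_on="gene_id", right_on="gene")
            if len(merged) >= 4 and merged["delta_me"].std() > 0 \
                    and merged["log2fc"].std() > 0:
                rho, p = integrate.correlate_changes(merged["delta_me"],
                                                     merged["log2fc"])
                summary["spearman_dme_dexpr"] = {"rho": rho, "p": p,
                                                 "n_pairs": int(len(merged))}
        # PCA of per-sample methylation on the per-sample-covered set
        mfrac = per_sample.methylated / np.maximum(per_sample.coverage, 1)
        pca = integrate.pca_summary(pd.DataFrame(mfrac, columns=per_sample.samples))
        summary["pca_meth_percent_variance"] = [
            round(float(x), 4) for x in pca["percent_variance"][:3]]
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {current['stage']}: {exc}") from exc

    io.write_json(out / "summary.json", summary)
    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json"
                   and not p.name.endswith(".fai"))
    manifest = {
        "config": config.to_dict(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        "summary": summary,
    }
    io.write_json(out / "manifest.json", manifest)
    return manifest
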