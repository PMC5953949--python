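"""Ground-truth tri-omic simulator.

Generates a toy genome plus RRBS-like CpG counts, RNA-seq-like gene counts
and ATAC-seq-like cut sites emulating a two-genotype (Dnmt3-sufficient /
-deficient), multi-cell-type (naive B -> germinal-center B -> bone-marrow
plasma cell) B-cell differentiation study:

* differentiated cell types lose methylation at ~10% of CpGs in both
  genotypes, and gain methylation at a smaller set only in the sufficient
  genotype (de novo methylation requires Dnmt3);
* a cluster of genes is repressed upon differentiation, and a
  Dnmt3-dependent subset fails to be repressed in the deficient genotype;
* immunoglobulin genes carry a cell-type-specific share of all transcripts
  with a cell-type-specific class-switched fraction;
* ATAC cut sites are enriched inside peaks (a target fraction of reads in
  peaks), with transposition depleted around bound motif instances
  (footprints), and a subset of peaks more accessible in the affected
  groups.

Every dataset comes with a truth table so downstream callers can be scored
for sensitivity and false-discovery proportion.  All outputs are functions
of ``design.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CountMatrix, CutSiteSet, Gene, GenomeLayout, MethCountTable

__all__ = [
    "SimDesign",
    "generate_genome",
    "simulate_methylation",
    "simulate_expression",
    "simulate_atac",
    "consensus_pwm",
]

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimDesign:
    """Parameters of the simulated study.

    Groups are the product genotype x cell type; the first cell type is the
    undifferentiated reference, the first genotype the unperturbed one.
    Differentiation effects (hypomethylation, gene repression) apply to all
    differentiated cell types; perturbation-dependent effects (methylation
    gain, repression failure, accessibility gain) distinguish the last
    genotype.
    """

    seed: int = 0
    genotypes: tuple[str, ...] = ("WT", "KO")
    celltypes: tuple[str, ...] = ("nB", "GCB", "BMPC")
    n_reps: int = 3

    # genome
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    n_genes: int = 150
    gene_span_range: tuple[int, int] = (2_000, 6_000)
    exons_per_gene: tuple[int, int] = (2, 5)
    ig_genes: dict = field(
        default_factory=lambda: {"IgM": 2, "IgD": 1, "IgG": 3, "IgA": 2, "IgV": 8}
    )
    motifs: dict = field(
        default_factory=lambda: {"AP1": "TGACTCA", "OCT2": "ATGCAAAT"}
    )
    n_motif_instances: int = 200
    n_enhancers: int = 40
    enhancer_width: int = 1_000

    # methylation (beta-binomial RRBS counts)
    n_cpg_sites: int = 10_000
    meth_baseline: tuple[float, float] = (8.0, 2.0)  # Beta(a, b), mean 0.8
    meth_dispersion: float = 0.02
    coverage_mean: float = 30.0
    coverage_size: float = 10.0
    frac_hypo: float = 0.10
    frac_hyper: float = 0.02
    meth_delta: float = 0.4
    hypo_near_motif: str | None = None  # draw hypo sites within 50 bp of this motif
    hypo_near_window: int = 50
    hypo_in_enhancer_frac: float = 0.3
    # draw hyper (de novo) sites from the spans of Dnmt3-dependent repressed
    # genes, coupling methylation gain to program repression
    couple_hyper_to_repressed: bool = True
    promoter_hypo_top_stratum: bool = False  # promoter demethylation, top-expressed genes
    promoter_window: int = 500

    # expression (negative-binomial gene counts)
    library_size_mean: float = 1_000_000.0
    library_size_cv: float = 0.1
    expr_log_sd: float = 1.0
    expr_dispersion: float = 0.1
    # Ig transcript budget is a stable cell-state property: the dominant
    # constant-region genes vary far less than ordinary genes
    ig_dispersion: float = 0.01
    frac_down: float = 0.10
    frac_up: float = 0.03
    fold_change: float = 4.0
    dnmt3_dependent_frac: float = 0.5  # share of repressed genes that need Dnmt3
    ig_fraction: dict = field(
        default_factory=lambda: {"nB": 0.040, "GCB": 0.027, "BMPC": 0.474}
    )
    switched_fraction: dict = field(
        default_factory=lambda: {"nB": 0.01, "GCB": 0.79, "BMPC": 0.70}
    )

    # ATAC (cut sites + peaks)
    n_peaks: int = 1_000
    peak_width: int = 200
    # default depth gives ~60 in-peak reads per peak (frip * reads /
    # n_peaks), matching a typical ATAC study's per-peak coverage
    reads_per_sample: int = 400_000
    frip: float = 0.15
    frip_overrides: dict = field(default_factory=dict)  # per-sample FRiP targets
    atac_dispersion: float = 0.05
    frac_da: float = 0.05
    da_fold: float = 4.0
    footprint_depletion: float = 0.2
    footprint_halfwidth: int = 10
    bound_motifs: tuple[str, ...] = ("AP1",)

    def validate(self) -> None:
        for name in ("frac_hypo", "frac_hyper", "frac_down", "frac_up", "frac_da",
                     "frip", "footprint_depletion", "dnmt3_dependent_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("meth_dispersion", "expr_dispersion", "coverage_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.celltypes) < 1 or self.n_reps < 1:
            raise ValueError("need at least one cell type and one replicate")

    # -- group bookkeeping ------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return [f"{gt}_{ct}" for gt in self.genotypes for ct in self.celltypes]

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.groups for r in range(self.n_reps)]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}

    def split_group(self, group: str) -> tuple[str, str]:
        for gt in self.genotypes:
            if group.startswith(gt + "_"):
                return gt, group[len(gt) + 1:]
        raise KeyError(group)

    def is_differentiated(self, group: str) -> bool:
        return self.split_group(group)[1] != self.celltypes[0]

    def is_affected(self, group: str) -> bool:
        """Groups carrying perturbation-dependent effects: differentiated
        cell types of the last (perturbed) genotype.  A single-genotype
        design has no perturbation arm, so nothing is affected."""
        if len(self.genotypes) < 2:
            return False
        gt, ct = self.split_group(group)
        return ct != self.celltypes[0] and gt == self.genotypes[-1]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimDesign":
        d = dict(d)
        for k in ("genotypes", "celltypes", "gene_span_range", "exons_per_gene",
                  "bound_motifs", "meth_baseline"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


# ------------------------------------------------------------------ helpers

def _pack_intervals(rng: np.random.Generator, low: int, high: int,
                    widths: np.ndarray) -> np.ndarray:
    """Place non-overlapping intervals of the given widths in [low, high)
    with Dirichlet-distributed gaps.  Returns start positions."""
    widths = np.asarray(widths, dtype=int)
    free = (high - low) - int(widths.sum())
    if free < len(widths) + 1:
        raise ValueError(
            f"infeasible packing: {len(widths)} intervals of total width "
            f"{int(widths.sum())} bp do not fit in {high - low} bp"
        )
    gaps = np.floor(rng.dirichlet(np.ones(len(widths) + 1)) * free).astype(int)
    starts = low + np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(widths[:-1])])
    return starts


def consensus_pwm(consensus: str, match_p: float = 0.97) -> np.ndarray:
    """Near-degenerate 4xL probability matrix (rows A,C,G,T) concentrated on
    a consensus string."""
    alphabet = "ACGT"
    L = len(consensus)
    pwm = np.full((4, L), (1.0 - match_p) / 3.0)
    for j, b in enumerate(consensus):
        pwm[alphabet.index(b), j] = match_p
    return pwm


def _cpgs_from_sequence(seq: np.ndarray) -> np.ndarray:
    """Positions of the + strand C of each CpG dinucleotide."""
    is_c = seq[:-1] == 1  # C
    is_g = seq[1:] == 2  # G
    return np.flatnonzero(is_c & is_g)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


# ------------------------------------------------------------ generate_genome

def generate_genome(design: SimDesign) -> tuple[GenomeLayout, dict[str, str]]:
    """Build the toy genome: uniform-ACGT sequence with genes, implanted
    motif instances, enhancers, and the CpG map derived from the final
    sequence.  Returns (layout, {chrom: sequence})."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    L = design.chrom_length
    lo, hi = design.gene_span_range
    if L < 10 * hi:
        raise ValueError("chromosome must be >= 10x the largest gene span")

    seq = rng.integers(0, 4, size=L, dtype=np.int8)  # 0=A 1=C 2=G 3=T

    # genes
    spans = rng.integers(lo, hi + 1, size=design.n_genes)
    starts = _pack_intervals(rng, 0, L, spans)
    strands = rng.choice(["+", "-"], size=design.n_genes)
    ig_labels: list[str | None] = [None] * design.n_genes
    ig_total = sum(design.ig_genes.values())
    if ig_total > design.n_genes:
        raise ValueError("more Ig genes requested than genes")
    ig_idx = rng.choice(design.n_genes, size=ig_total, replace=False)
    k = 0
    for cls, n in design.ig_genes.items():
        for _ in range(n):
            ig_labels[ig_idx[k]] = cls
            k += 1
    genes = []
    n_ex_lo, n_ex_hi = design.exons_per_gene
    for i in range(design.n_genes):
        s, e = int(starts[i]), int(starts[i] + spans[i])
        n_ex = int(rng.integers(n_ex_lo, n_ex_hi + 1))
        cuts = np.sort(rng.choice(np.arange(s + 1, e), size=2 * n_ex - 2, replace=False))
        bounds = np.concatenate([[s], cuts, [e]])
        exons = tuple((int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(n_ex))
        if strands[i] == "+":
            tss, tts = s, e - 1
        else:
            tss, tts = e - 1, s
        genes.append(Gene(f"gene{i:04d}", design.chrom, str(strands[i]), tss, tts,
                          exons, ig_labels[i]))

    # motif instances (implanted verbatim; reverse-complemented on -)
    truth_rows = []
    occupied = np.zeros(L, dtype=bool)
    for mid, consensus in design.motifs.items():
        ml = len(consensus)
        cons_arr = np.array([("ACGT").index(b) for b in consensus], dtype=np.int8)
        rc_arr = np.array([("ACGT").index(b) for b in revcomp(consensus)], dtype=np.int8)
        placed = 0
        attempts = 0
        while placed < design.n_motif_instances:
            attempts += 1
            if attempts > 50 * design.n_motif_instances:
                raise ValueError("infeasible packing: cannot place motif instances")
            pos = int(rng.integers(0, L - ml))
            if occupied[pos : pos + ml].any():
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            seq[pos : pos + ml] = cons_arr if strand == "+" else rc_arr
            occupied[pos : pos + ml] = True
            truth_rows.append((mid, design.chrom, pos, strand))
            placed += 1
    motif_truth = pd.DataFrame(truth_rows, columns=["motif_id", "chrom", "start", "strand"])

    # enhancers
    enh_starts = np.sort(
        rng.integers(0, L - design.enhancer_width, size=design.n_enhancers)
    )
    enhancers = pd.DataFrame(
        {
            "chrom": design.chrom,
            "start": enh_starts,
            "end": enh_starts + design.enhancer_width,
            "name": [f"enh{i:03d}" for i in range(design.n_enhancers)],
        }
    )

    layout = GenomeLayout(
        chrom_sizes={design.chrom: L},
        genes=genes,
        cpg_positions={design.chrom: _cpgs_from_sequence(seq)},
        enhancers=enhancers,
        motif_truth=motif_truth,
    )
    layout.validate()
    return layout, {design.chrom: _decode(seq.astype(np.uint8))}


# -------------------------------------------------------- expression baselines

def gene_baselines(layout: GenomeLayout, design: SimDesign) -> pd.DataFrame:
    """Deterministic per-gene relative expression and differential truth,
    shared between the expression and (promoter-methylation) simulators.

    Returns a DataFrame indexed by gene_id with the baseline relative
    expression (non-Ig genes, unnormalized), is_down/is_up spike flags and
    the Dnmt3-dependence flag for down genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    gt = layout.gene_table().set_index("gene_id")
    n = len(gt)
    base = rng.lognormal(mean=0.0, sigma=design.expr_log_sd, size=n)
    non_ig = gt["ig_class"].isna().to_numpy()
    candidates = np.flatnonzero(non_ig)
    rng.shuffle(candidates)
    n_down = int(round(design.frac_down * n))
    n_up = int(round(design.frac_up * n))
    if n_down + n_up > len(candidates):
        raise ValueError("too many differential genes for the layout")
    down = candidates[:n_down]
    up = candidates[n_down : n_down + n_up]
    is_down = np.zeros(n, dtype=bool)
    is_up = np.zeros(n, dtype=bool)
    is_down[down] = True
    is_up[up] = True
    dnmt3_dep = np.zeros(n, dtype=bool)
    n_dep = int(round(design.dnmt3_dependent_frac * n_down))
    dnmt3_dep[down[:n_dep]] = True
    return pd.DataFrame(
        {"baseline": base, "is_down": is_down, "is_up": is_up, "dnmt3_dependent": dnmt3_dep},
        index=gt.index,
    )


def _group_relative_expression(layout: GenomeLayout, design: SimDesign,
                               baselines: pd.DataFrame) -> pd.DataFrame:
    """Per-group relative expression (columns = groups, rows = genes,
    columns sum to 1), applying repression, repression failure and the Ig
    transcript budget."""
    gt = layout.gene_table().set_index("gene_id")
    ig_class = gt["ig_class"]
    out = {}
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    # V-gene usage fixed across groups
    v_genes = ig_class[ig_class == "IgV"].index
    v_usage = rng.dirichlet(np.ones(len(v_genes)) * 2.0) if len(v_genes) else np.array([])
    for group in design.groups:
        _gt_name, ct = design.split_group(group)
        rel = baselines["baseline"].copy()
        if design.is_differentiated(group):
            down = baselines["is_down"].copy()
            if design.is_affected(group):
                down &= ~baselines["dnmt3_dependent"]  # Dnmt3-dependent repression fails
            rel[down] /= design.fold_change
            rel[baselines["is_up"]] *= design.fold_change
        rel[ig_class.notna()] = 0.0
        ig_frac = design.ig_fraction.get(ct, 0.0)
        rel = rel / rel.sum() * (1.0 - ig_frac)
        if ig_frac > 0:
            sw = design.switched_fraction.get(ct, 0.0)
            const_share, v_share = 0.75, 0.25
            unsw = {"IgM": 0.8, "IgD": 0.2}
            swc = {"IgG": 0.7, "IgA": 0.3}
            for cls, cls_frac in list(unsw.items()) + list(swc.items()):
                members = ig_class[ig_class == cls].index
                if len(members) == 0:
                    continue
                cls_total = ig_frac * const_share * (
                    (1.0 - sw) * unsw.get(cls, 0) if cls in unsw else sw * swc[cls]
                )
                rel[members] = cls_total / len(members)
            if len(v_genes):
                rel[v_genes] = ig_frac * v_share * v_usage
        out[group] = rel / rel.sum()
    return pd.DataFrame(out)


# -------------------------------------------------------- simulate_methylation

def simulate_methylation(
    layout: GenomeLayout, design: SimDesign
) -> tuple[MethCountTable, pd.DataFrame]:
    """Beta-binomial CpG counts per sample with ground truth.

    Site baselines are Beta-distributed; differentiated cell types lose
    ``meth_delta`` at the hypo set (both genotypes) and gain ``meth_delta``
    at the hyper set only in non-last genotypes (de novo methylation fails
    in the perturbed genotype).  Coverage is negative-binomial.
    """
    design.validate()
    if len(design.groups) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 3]))
    chrom = design.chrom
    all_cpg = layout.cpg_positions[chrom]
    n = min(design.n_cpg_sites, len(all_cpg))
    pos = np.sort(rng.choice(all_cpg, size=n, replace=False))

    a, b = design.meth_baseline
    pi0 = rng.beta(a, b, size=n)

    n_hypo = int(round(design.frac_hypo * n))
    n_hyper = int(round(design.frac_hyper * n))
    order = rng.permutation(n)

    hypo_pool = order
    if design.hypo_near_motif is not None:
        mt = layout.motif_truth
        inst = mt.loc[mt["motif_id"] == design.hypo_near_motif, "start"].to_numpy()
        ml = len(design.motifs[design.hypo_near_motif])
        centers = inst + ml // 2
        near = np.zeros(n, dtype=bool)
        for c in centers:
            j = np.searchsorted(pos, [c - design.hypo_near_window - ml,
                                      c + design.hypo_near_window + ml])
            near[j[0]: j[1]] = True
        hypo_pool = order[near[order]]
    elif design.hypo_in_enhancer_frac > 0 and layout.enhancers is not None:
        enh = layout.enhancers
        in_enh = np.zeros(n, dtype=bool)
        for s, e in zip(enh["start"], enh["end"]):
            j = np.searchsorted(pos, [s, e])
            in_enh[j[0]: j[1]] = True
        pool_enh = order[in_enh[order]]
        n_from_enh = min(int(round(design.hypo_in_enhancer_frac * n_hypo)), len(pool_enh))
        rest = order[~np.isin(order, pool_enh[:n_from_enh])]
        hypo_pool = np.concatenate([pool_enh[:n_from_enh], rest])

    hypo_idx = hypo_pool[:n_hypo]
    remaining = order[~np.isin(order, hypo_idx)]
    if design.couple_hyper_to_repressed and n_hyper > 0:
        baselines = gene_baselines(layout, design)
        gt = layout.gene_table().set_index("gene_id")
        dep = gt.loc[baselines.index[baselines["dnmt3_dependent"]]]
        in_dep = np.zeros(n, dtype=bool)
        for s_, e_ in zip(dep["start"], dep["end"]):
            j = np.searchsorted(pos, [s_ - 1000, e_])  # span + 1 kb upstream-ish
            in_dep[j[0]: j[1]] = True
        pool_dep = remaining[in_dep[remaining]]
        rest = remaining[~in_dep[remaining]]
        remaining = np.concatenate([pool_dep, rest])
    hyper_idx = remaining[:n_hyper]
    is_hypo = np.zeros(n, dtype=bool)
    is_hyper = np.zeros(n, dtype=bool)
    is_hypo[hypo_idx] = True
    is_hyper[hyper_idx] = True
    # effects need headroom to be visible
    pi0[is_hypo] = np.clip(pi0[is_hypo], design.meth_delta + 0.05, 0.95)
    pi0[is_hyper] = np.clip(pi0[is_hyper], 0.05, 0.95 - design.meth_delta)

    if design.promoter_hypo_top_stratum:
        baselines = gene_baselines(layout, design)
        gt = layout.gene_table().set_index("gene_id")
        # expression level on the FPKM scale (length-normalized), matching
        # how downstream stratification ranks genes
        expr = baselines["baseline"] / gt["length"]
        expr[gt["ig_class"].notna()] = np.nan
        top = expr[expr >= expr.quantile(0.75)].index
        for gid in top:
            g = gt.loc[gid]
            j = np.searchsorted(pos, [g["tss"] - design.promoter_window,
                                      g["tss"] + design.promoter_window + 1])
            # V-shaped dip deepest at the TSS, shouldering back to baseline
            d = np.abs(pos[j[0]: j[1]] - g["tss"]) / design.promoter_window
            pi0[j[0]: j[1]] = 0.05 + (pi0[j[0]: j[1]] - 0.05) * d

    # per-group true proportions
    true_pi = {}
    for group in design.groups:
        p = pi0.copy()
        if design.is_differentiated(group):
            p[is_hypo] = np.clip(p[is_hypo] - design.meth_delta, 0.01, 0.99)
            if not design.is_affected(group):  # de novo gain needs Dnmt3
                p[is_hyper] = np.clip(p[is_hyper] + design.meth_delta, 0.01, 0.99)
        true_pi[group] = p

    samples = design.samples
    groups_of = design.sample_groups
    cov = np.empty((n, len(samples)), dtype=int)
    met = np.empty((n, len(samples)), dtype=int)
    p_nb = design.coverage_size / (design.coverage_size + design.coverage_mean)
    phi = design.meth_dispersion
    conc = 1.0 / phi - 1.0
    for j, s in enumerate(samples):
        p = np.clip(true_pi[groups_of[s]], 1e-6, 1 - 1e-6)
        c = rng.negative_binomial(design.coverage_size, p_nb, size=n)
        theta = rng.beta(p * conc, (1.0 - p) * conc)
        cov[:, j] = c
        met[:, j] = rng.binomial(c, theta)

    sites = pd.DataFrame({"chrom": chrom, "pos": pos})
    table = MethCountTable(sites, samples, cov, met, groups_of)
    truth = pd.DataFrame({"chrom": chrom, "pos": pos, "baseline": pi0,
                          "is_hypo": is_hypo, "is_hyper": is_hyper})
    for g, p in true_pi.items():
        truth[f"pi_{g}"] = p
    return table, truth


# -------------------------------------------------------- simulate_expression

def simulate_expression(
    layout: GenomeLayout, design: SimDesign
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial gene counts per sample with ground truth.

    Each sample's counts are NB with mean = library_size x group relative
    expression and constant dispersion; Ig genes receive the cell type's
    transcript share split into unswitched (IgM/IgD), switched (IgG/IgA)
    and variable (IgV) segments.
    """
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 4]))
    baselines = gene_baselines(layout, design)
    rel = _group_relative_expression(layout, design, baselines)
    samples = design.samples
    groups_of = design.sample_groups
    gt0 = layout.gene_table().set_index("gene_id")
    is_ig = gt0["ig_class"].reindex(rel.index).notna().to_numpy()
    size = np.where(is_ig, 1.0 / design.ig_dispersion, 1.0 / design.expr_dispersion)
    lib_sigma = np.sqrt(np.log(1 + design.library_size_cv**2))
    cols = {}
    for s in samples:
        lib = float(rng.lognormal(np.log(design.library_size_mean) - lib_sigma**2 / 2,
                                  lib_sigma))
        mu = rel[groups_of[s]].to_numpy() * lib
        p_nb = size / (size + np.maximum(mu, 1e-12))
        cols[s] = rng.negative_binomial(size, p_nb)
    counts = pd.DataFrame(cols, index=rel.index)
    library_size = counts.sum(axis=0).astype(float)  # total mapped = column sum
    gt = layout.gene_table().set_index("gene_id")
    lengths = gt["length"].astype(float)
    cm = CountMatrix(counts, library_size, lengths)
    truth = baselines.join(rel.add_prefix("rel_"))
    truth["ig_class"] = gt["ig_class"]
    return cm, truth


# --------------------------------------------------------------- simulate_atac

def simulate_atac(
    layout: GenomeLayout, design: SimDesign
) -> tuple[CutSiteSet, pd.DataFrame, pd.DataFrame]:
    """ATAC cut sites (5' read-start bases) plus the peak set and truth.

    A ``frip`` fraction of each sample's reads falls inside peaks
    (multinomial over peaks with gamma-noise weights; differentially
    accessible peaks scaled by ``da_fold`` in affected groups); the rest is
    uniform background outside peaks.  Within peaks carrying a bound motif
    instance, cut positions within +/- ``footprint_halfwidth`` of the motif
    center are accepted with probability ``footprint_depletion``
    (transcription-factor footprint).

    Returns (cutsites, peaks, peak_truth).
    """
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 5]))
    chrom = design.chrom
    L = design.chrom_length
    w = design.peak_width

    # peaks centered on bound motif instances, remainder packed into gaps
    bound_centers: list[int] = []
    if layout.motif_truth is not None and len(design.bound_motifs):
        mt = layout.motif_truth
        for mid in design.bound_motifs:
            ml = len(design.motifs[mid])
            inst = mt.loc[mt["motif_id"] == mid, "start"].to_numpy()
            bound_centers.extend((inst + ml // 2).tolist())
    bound_centers = sorted(bound_centers)
    peak_starts: list[int] = []
    peak_motif_center: list[int | None] = []
    last_end = -1
    for c in bound_centers:
        s = max(0, min(c - w // 2, L - w))
        if s <= last_end or len(peak_starts) >= design.n_peaks:
            continue
        peak_starts.append(s)
        peak_motif_center.append(c)
        last_end = s + w
    n_fill = design.n_peaks - len(peak_starts)
    if n_fill > 0:
        existing = [(s, s + w) for s in peak_starts]
        gaps = []
        prev = 0
        for s, e in existing + [(L, L)]:
            if s - prev > 3 * w:
                gaps.append((prev, s))
            prev = e
        gap_len = np.array([e - s for s, e in gaps], dtype=float)
        alloc = rng.multinomial(n_fill, gap_len / gap_len.sum())
        for (gs, ge), k in zip(gaps, alloc):
            cap = (ge - gs) // (2 * w)
            k = min(k, cap)
            if k == 0:
                continue
            starts = _pack_intervals(rng, gs, ge, np.full(k, w))
            peak_starts.extend(int(x) for x in starts)
            peak_motif_center.extend([None] * k)
    order = np.argsort(peak_starts)
    peak_starts = [peak_starts[i] for i in order]
    peak_motif_center = [peak_motif_center[i] for i in order]
    n_peaks = len(peak_starts)
    peaks = pd.DataFrame(
        {
            "chrom": chrom,
            "start": peak_starts,
            "end": [s + w for s in peak_starts],
            "name": [f"peak{i:05d}" for i in range(n_peaks)],
        }
    )

    # per-peak base weights and differential accessibility truth
    base_w = rng.lognormal(0.0, 0.5, size=n_peaks)
    is_da = np.zeros(n_peaks, dtype=bool)
    da_idx = rng.choice(n_peaks, size=int(round(design.frac_da * n_peaks)), replace=False)
    is_da[da_idx] = True

    p_start, p_end = peaks["start"].to_numpy(), peaks["end"].to_numpy()
    has_fp = np.array([c is not None for c in peak_motif_center])
    fp_center = np.array([c if c is not None else -1 for c in peak_motif_center])

    # non-peak background segments for uniform placement
    seg_starts = np.concatenate([[0], p_end])
    seg_ends = np.concatenate([p_start, [L]])
    keep = seg_ends > seg_starts
    seg_starts, seg_ends = seg_starts[keep], seg_ends[keep]
    seg_len = (seg_ends - seg_starts).astype(float)
    seg_p = seg_len / seg_len.sum()

    rows = []
    totals = {}
    groups_of = design.sample_groups
    shape = 1.0 / max(design.atac_dispersion, 1e-9)
    hw = design.footprint_halfwidth
    for s in design.samples:
        group = groups_of[s]
        wvec = base_w.copy()
        # accessibility gains in the perturbed differentiated groups; in a
        # single-genotype design the gain tracks differentiation itself
        gains = (design.is_affected(group) if len(design.genotypes) > 1
                 else design.is_differentiated(group))
        if gains:
            wvec[is_da] *= design.da_fold
        wvec = wvec * rng.gamma(shape, 1.0 / shape, size=n_peaks)
        R = design.reads_per_sample
        n_in = rng.binomial(R, design.frip_overrides.get(s, design.frip))
        per_peak = rng.multinomial(n_in, wvec / wvec.sum())
        # in-peak positions, footprint depletion by rejection
        pos_chunks = []
        for k in np.flatnonzero(per_peak):
            m = per_peak[k]
            p = rng.integers(p_start[k], p_end[k], size=m)
            if has_fp[k] and design.footprint_depletion < 1.0:
                # rejection sampling: a draw inside the footprint window is
                # kept with probability = depletion, else redrawn; each read
                # settles once (outside, or inside-and-accepted)
                c = fp_center[k]
                active = np.ones(m, dtype=bool)
                for _ in range(200):
                    idx = np.flatnonzero(active)
                    if idx.size == 0:
                        break
                    inside = np.abs(p[idx] - c) <= hw
                    keep = ~inside | (rng.random(idx.size) < design.footprint_depletion)
                    active[idx[keep]] = False
                    redraw = idx[~keep]
                    p[redraw] = rng.integers(p_start[k], p_end[k], size=redraw.size)
            pos_chunks.append(p)
        n_bg = R - n_in
        seg_idx = rng.choice(len(seg_len), size=n_bg, p=seg_p)
        bg = seg_starts[seg_idx] + (rng.random(n_bg) * seg_len[seg_idx]).astype(int)
        pos = np.concatenate(pos_chunks + [bg]) if pos_chunks else bg
        strand = rng.choice(["+", "-"], size=len(pos))
        order_idx = np.argsort(pos, kind="stable")
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos[order_idx],
                                  "strand": strand[order_idx], "sample": s}))
        totals[s] = int(R)
    table = pd.concat(rows, ignore_index=True)
    cutsites = CutSiteSet(table, totals)
    truth = pd.DataFrame(
        {
            "name": peaks["name"],
            "base_weight": base_w,
            "is_da": is_da,
            "has_footprint": has_fp,
            "footprint_center": fp_center,
        }
    )
    return cutsites, peaks, truth
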