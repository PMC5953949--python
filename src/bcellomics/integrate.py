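"""Cross-omic integration statistics.

Closest-gene annotation of CpGs, the hypergeometric DML x DEG overlap
test, meta-gene methylation profiles stratified by expression,
accessibility at differentially methylated cytosines, enhancer-overlap
odds ratios, Spearman correlation of paired changes, and PCA summaries
with percent variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CutSiteSet, GenomeLayout
from .motif import fisher_exact, _haldane_or

__all__ = [
    "annotate_closest_gene",
    "dml_deg_overlap",
    "OverlapResult",
    "metagene_methylation",
    "accessibility_at_sites",
    "enhancer_overlap",
    "correlate_changes",
    "pca_summary",
]


# ------------------------------------------------------- closest-gene lookup

def annotate_closest_gene(
    sites: pd.DataFrame, layout: GenomeLayout, anchor: str = "span"
) -> pd.DataFrame:
    """Annotate each site (``chrom, pos``) with its closest gene.

    With ``anchor="span"`` the distance is 0 inside the gene span
    [start, end) and otherwise the distance to the nearer span boundary;
    with ``anchor="tss"`` it is the distance to the TSS.  Ties go to the
    lexicographically smaller gene_id.  The reported distance is signed in
    gene orientation: negative upstream of the gene, positive downstream.
    """
    if not layout.genes:
        raise ValueError("layout has no genes")
    gt = layout.gene_table()
    sites_flat = sites[["chrom", "pos"]].reset_index(drop=True)
    out_gene = np.empty(len(sites_flat), dtype=object)
    out_dist = np.zeros(len(sites_flat), dtype=int)
    for chrom, sub in sites_flat.groupby("chrom", sort=False):
        genes = gt[gt["chrom"] == chrom]
        if genes.empty:
            raise ValueError(f"no genes on {chrom}")
        pos = sub["pos"].to_numpy()
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        gid = genes["gene_id"].to_numpy()
        strand = genes["strand"].to_numpy()
        tss = genes["tss"].to_numpy()
        if anchor == "span":
            # unsigned distance of every site to every gene, vectorized per gene
            d = np.maximum.reduce([gs[None, :] - pos[:, None],
                                   pos[:, None] - (ge[None, :] - 1),
                                   np.zeros((len(pos), len(gs)), dtype=int)])
        elif anchor == "tss":
            d = np.abs(pos[:, None] - tss[None, :])
        else:
            raise ValueError("anchor must be 'span' or 'tss'")
        # ties -> smaller gene_id: gene table is ordered by gene_id already,
        # but sort explicitly to be safe
        order = np.argsort(gid, kind="stable")
        d = d[:, order]
        best = d.argmin(axis=1)  # first minimum = smallest gene_id after sort
        sel = order[best]
        dist = d[np.arange(len(pos)), best]
        # sign in gene orientation: upstream negative, downstream positive
        signed = np.zeros(len(pos), dtype=int)
        for i, (p, j) in enumerate(zip(pos, sel)):
            if dist[i] == 0:
                continue
            before = p < gs[j]  # left of the span in genome coordinates
            if anchor == "tss":
                before = p < tss[j]
            upstream = before if strand[j] == "+" else not before
            signed[i] = -dist[i] if upstream else dist[i]
        out_gene[sub.index] = gid[sel]
        out_dist[sub.index] = signed
    res = sites.copy()
    res["gene_id"] = out_gene
    res["distance"] = out_dist
    return res


# -------------------------------------------------------------- overlap test

@dataclass
class OverlapResult:
    universe: int
    n_dml_genes: int
    n_deg: int
    observed: int
    expected: float
    fold: float
    p: float

    def to_dict(self) -> dict:
        return {
            "universe": self.universe,
            "n_dml_genes": self.n_dml_genes,
            "n_deg": self.n_deg,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "p": self.p,
        }


def dml_deg_overlap(dml_genes, deg_genes, universe_genes) -> OverlapResult:
    """Is the overlap of DML-proximal genes and DEGs larger than expected?

    With universe size G, D DML-proximal genes and E DEGs, the expected
    overlap is D*E/G and the p-value the hypergeometric upper tail
    P[X >= observed], X ~ Hypergeom(G, D, E).
    """
    uni = set(universe_genes)
    if not uni:
        raise ValueError("empty gene universe")
    dml = set(dml_genes) & uni
    deg = set(deg_genes) & uni
    if set(dml_genes) - uni or set(deg_genes) - uni:
        raise ValueError("dml_genes and deg_genes must be subsets of the universe")
    G, D, E = len(uni), len(dml), len(deg)
    O = len(dml & deg)
    expected = D * E / G
    fold = O / expected if expected > 0 else np.nan
    p = float(stats.hypergeom.sf(O - 1, G, D, E))
    return OverlapResult(G, D, E, O, expected, fold, p)


# ------------------------------------------------------- meta-gene profiles

def _tricube_smooth(y: np.ndarray, span: float, degree: int = 2) -> np.ndarray:
    """Local polynomial smoothing on an evenly spaced grid with tricube
    weights over a span-fraction window (loess-like)."""
    n = len(y)
    k = max(int(np.ceil(span * n)), degree + 1)
    half = max(k // 2, 1)
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        xi = x[lo:hi] - i
        yi = y[lo:hi]
        ok = ~np.isnan(yi)
        if ok.sum() == 0:
            out[i] = np.nan
            continue
        dmax = np.abs(xi[ok]).max() or 1.0
        wgt = (1 - (np.abs(xi[ok]) / (dmax + 1e-9)) ** 3) ** 3
        wgt = np.maximum(wgt, 1e-9)
        if ok.sum() <= degree:  # sparse window: weighted local mean
            out[i] = np.average(yi[ok], weights=wgt)
            continue
        coef = np.polyfit(xi[ok], yi[ok], deg=degree, w=np.sqrt(wgt))
        out[i] = np.polyval(coef, 0.0)
    # grid points whose whole window was empty: linear interpolation
    bad = np.isnan(out)
    if bad.any() and not bad.all():
        out[bad] = np.interp(x[bad], x[~bad], out[~bad])
    return out


def metagene_methylation(
    meth_sites: pd.DataFrame,
    layout: GenomeLayout,
    fpkm: pd.DataFrame,
    n_strata: int = 4,
    flank: int = 5000,
    body_bins: int = 100,
    flank_bins: int = 50,
    span: float = 0.1,
    value_col: str = "meth",
) -> pd.DataFrame:
    """Average methylation along a TSS/TTS-anchored meta-gene, stratified
    by expression quantile.

    ``meth_sites`` needs ``chrom, pos`` and a methylation column
    (``value_col``, fraction in [0, 1]).  Genes are stratified into
    ``n_strata`` quantile groups of their per-sample-mean FPKM (stratum
    ``n_strata`` = most expressed).  Each CpG is mapped to the grid of its
    closest gene — absolute position within the upstream flank, fractional
    position within the gene body, absolute position within the downstream
    flank — respecting strand.  Bin means are smoothed with a tricube
    local quadratic of the given span (fraction of grid points).

    Returns a tidy frame ``stratum, grid, segment, methylation`` where
    ``grid`` runs over flank_bins + body_bins + flank_bins points.
    """
    mean_fpkm = fpkm.mean(axis=1)
    strata = pd.qcut(mean_fpkm.rank(method="first"), n_strata, labels=False) + 1
    gene_stratum = dict(zip(mean_fpkm.index, strata))
    ann = annotate_closest_gene(meth_sites[["chrom", "pos"]], layout)
    gt = layout.gene_table().set_index("gene_id")
    n_grid = 2 * flank_bins + body_bins
    sums = np.zeros((n_strata, n_grid))
    cnts = np.zeros((n_strata, n_grid))
    vals = meth_sites[value_col].to_numpy(dtype=float)
    for i, (gid, pos) in enumerate(zip(ann["gene_id"], ann["pos"])):
        if gid not in gene_stratum:
            continue
        g = gt.loc[gid]
        start, end, strand = g["start"], g["end"], g["strand"]
        body = end - start
        # position relative to the strand-oriented gene
        if strand == "+":
            rel = pos - start
        else:
            rel = (end - 1) - pos
        if 0 <= rel < body:
            grid = flank_bins + min(int(rel / body * body_bins), body_bins - 1)
        elif -flank <= rel < 0:
            grid = flank_bins + int(np.floor(rel / flank * flank_bins))
            grid = max(grid, 0)
        elif body <= rel < body + flank:
            grid = flank_bins + body_bins + min(
                int((rel - body) / flank * flank_bins), flank_bins - 1)
        else:
            continue
        s = int(gene_stratum[gid]) - 1
        sums[s, grid] += vals[i]
        cnts[s, grid] += 1
    if (cnts.sum(axis=1) == 0).any():
        empty = int(np.flatnonzero(cnts.sum(axis=1) == 0)[0]) + 1
        raise ValueError(f"expression stratum {empty} has no covered genes")
    rows = []
    seg = (["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins)
    for s in range(n_strata):
        with np.errstate(invalid="ignore"):
            prof = np.where(cnts[s] > 0, sums[s] / np.maximum(cnts[s], 1), np.nan)
        smooth = _tricube_smooth(prof, span)
        for gpt in range(n_grid):
            rows.append((s + 1, gpt, seg[gpt], smooth[gpt]))
    return pd.DataFrame(rows, columns=["stratum", "grid", "segment", "methylation"])


# ------------------------------------------- accessibility at specific bases

def accessibility_at_sites(
    cutsites: CutSiteSet,
    sites: pd.DataFrame,
    sample_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Normalized ATAC read-start count exactly at each site's base.

    Counts reads whose 5' start equals the position, per sample, scaled
    per million total reads.  Adds per-group mean columns when
    ``sample_groups`` is given.
    """
    out = sites[["chrom", "pos"]].reset_index(drop=True)
    for s in cutsites.samples:
        col = np.zeros(len(sites), dtype=float)
        for chrom, sub in out.groupby("chrom", sort=False):
            pos = np.sort(cutsites.positions(s, chrom))
            lo = np.searchsorted(pos, sub["pos"].to_numpy(), side="left")
            hi = np.searchsorted(pos, sub["pos"].to_numpy(), side="right")
            col[sub.index] = hi - lo
        out[s] = col * 1e6 / cutsites.totals[s]
    if sample_groups:
        for g in sorted(set(sample_groups.values())):
            members = [s for s in cutsites.samples if sample_groups.get(s) == g]
            if members:
                out[f"mean_{g}"] = out[members].mean(axis=1)
    return out


# ------------------------------------------------------------ enhancer overlap

def enhancer_overlap(
    dml_sites: pd.DataFrame,
    universe_sites: pd.DataFrame,
    enhancers: pd.DataFrame,
) -> dict:
    """Odds ratio / Fisher p of DML falling inside enhancer intervals
    (half-open) versus the non-DML universe."""
    if enhancers is None or enhancers.empty:
        raise ValueError("empty enhancer set")
    uni = universe_sites[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    dml_keys = set(map(tuple, dml_sites[["chrom", "pos"]].to_numpy()))
    is_dml = np.array([(c, p) in dml_keys for c, p in uni.to_numpy()])
    inside = np.zeros(len(uni), dtype=bool)
    for chrom, sub in enhancers.groupby("chrom"):
        csel = (uni["chrom"] == chrom).to_numpy()
        pos = uni.loc[csel, "pos"].to_numpy()
        starts = np.sort(sub["start"].to_numpy())
        order = np.argsort(sub["start"].to_numpy())
        ends = sub["end"].to_numpy()[order]
        max_end = np.maximum.accumulate(ends)
        idx = np.searchsorted(starts, pos, side="right")
        inside[csel] = (idx > 0) & (pos < max_end[np.clip(idx - 1, 0, None)])
    a = int((is_dml & inside).sum())
    b = int((is_dml & ~inside).sum())
    c = int((~is_dml & inside).sum())
    d = int((~is_dml & ~inside).sum())
    orat, p = fisher_exact(a, b, c, d)
    return {"table": [[a, b], [c, d]], "odds_ratio": orat,
            "odds_ratio_haldane": _haldane_or(a, b, c, d), "p": p}


# ------------------------------------------------------------------ Spearman

def correlate_changes(delta_me, delta_feature) -> tuple[float, float]:
    """Spearman correlation of paired changes (average-rank ties,
    large-sample t approximation for the p-value)."""
    x = np.asarray(delta_me, dtype=float)
    y = np.asarray(delta_feature, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ----------------------------------------------------------------------- PCA

def pca_summary(matrix: pd.DataFrame) -> dict:
    """PCA of a features x samples matrix via SVD of the feature-centered
    data.  Returns sample scores and percent variance explained per
    component (fractions sum to 1)."""
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        raise ValueError("constant matrix has no principal components")
    # samples as observations: SVD of the samples x features matrix
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    var = S**2
    frac = var / var.sum()
    scores = U * S  # per-sample component scores
    k = min(X.shape[1], len(S))
    return {
        "scores": pd.DataFrame(
            scores[:, :k], index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        "variance_fraction": frac[:k],
        "percent_variance": 100.0 * frac[:k],
        "singular_values": S[:k],
    }
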