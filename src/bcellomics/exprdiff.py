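"""Gene-expression analysis: FPKM, expression filtering, negative-binomial
differential expression, K-means expression-program clustering, and
immunoglobulin repertoire summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_fdr, nb_wald_test
from .core import CountMatrix, GenomeLayout

__all__ = [
    "compute_fpkm",
    "filter_expressed",
    "test_deg",
    "call_deg",
    "kmeans_programs",
    "ig_repertoire",
]


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """FPKM = count * 1e9 / (exonic length in bp * library size)."""
    if cm.lengths is None:
        raise ValueError("feature lengths required for FPKM")
    lengths = cm.lengths.reindex(cm.counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    lib = cm.library_size.reindex(cm.counts.columns)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    return cm.counts * 1e9 / np.outer(lengths.to_numpy(), lib.to_numpy())


def filter_expressed(fpkm: pd.DataFrame, min_fpkm: float = 1.0,
                     min_samples: int = 2) -> pd.Index:
    """Genes expressed at more than ``min_fpkm`` (strict) in at least
    ``min_samples`` samples."""
    keep = (fpkm > min_fpkm).sum(axis=1) >= min_samples
    return fpkm.index[keep]


def test_deg(
    cm: CountMatrix,
    design: dict[str, str],
    groups: tuple[str, str],
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test between two groups with library-size offsets
    (total-count normalization).

    Returns ``gene, log2fc, mean_expr, dispersion, p, fdr`` with all-zero
    genes excluded; log2FC is group2 relative to group1 from shrunken
    pooled means.
    """
    counts = cm.counts if genes is None else cm.counts.loc[genes]
    samples = counts.columns
    ia = np.flatnonzero(np.array([design[s] == groups[0] for s in samples]))
    ib = np.flatnonzero(np.array([design[s] == groups[1] for s in samples]))
    res = nb_wald_test(
        counts.to_numpy(dtype=float),
        cm.library_size.reindex(samples).to_numpy(dtype=float),
        ia, ib,
    )
    res.insert(0, "gene", counts.index.to_numpy())
    res = res.dropna(subset=["p"]).reset_index(drop=True)
    res["fdr"] = bh_fdr(res["p"].to_numpy())
    return res


def call_deg(records: pd.DataFrame, alpha: float = 0.05, fc: float = 2.0) -> pd.DataFrame:
    """Flag DEGs: BH FDR <= ``alpha`` and fold change >= ``fc``
    (|log2FC| >= log2(fc))."""
    out = records.copy()
    out["is_deg"] = (out["fdr"] <= alpha) & (out["log2fc"].abs() >= np.log2(fc))
    return out


# ------------------------------------------------------------------ K-means

def kmeans_programs(
    matrix: pd.DataFrame,
    k: int,
    max_iter: int = 1000,
    n_start: int = 100,
    seed: int = 0,
    zscore: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster features (rows) into k expression/accessibility programs.

    Lloyd's algorithm, best of ``n_start`` random initializations by
    within-cluster sum of squares; rows are z-scored first (heat-map
    convention).  The per-iteration objective is asserted non-increasing.
    Returns (assignments, cluster means on the z-scored scale).
    """
    X = matrix.to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    if zscore:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    rng = np.random.default_rng(seed)
    best_obj, best_labels, best_centers = np.inf, None, None
    n = X.shape[0]
    for _ in range(n_start):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        prev_obj = np.inf
        labels = np.zeros(n, dtype=int)
        for _it in range(max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = d2.argmin(axis=1)
            obj = d2[np.arange(n), labels].sum()
            assert obj <= prev_obj + 1e-9, "k-means objective increased"
            if prev_obj - obj < 1e-12:
                break
            prev_obj = obj
            for j in range(k):
                members = labels == j
                if members.any():
                    centers[j] = X[members].mean(axis=0)
                else:  # re-seed empty cluster at the worst-fit point
                    centers[j] = X[d2[np.arange(n), labels].argmax()]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj = d2[np.arange(n), d2.argmin(axis=1)].sum()
        if obj < best_obj:
            best_obj, best_labels, best_centers = obj, labels.copy(), centers.copy()
    assign = pd.Series(best_labels, index=matrix.index, name="cluster")
    means = pd.DataFrame(best_centers, columns=matrix.columns)
    means.index.name = "cluster"
    means.attrs["objective"] = float(best_obj)
    return assign, means


# --------------------------------------------------------------- Ig repertoire

_SWITCHED = {"IgG", "IgA"}
_UNSWITCHED = {"IgM", "IgD"}
_CONSTANT = _SWITCHED | _UNSWITCHED


def ig_repertoire(cm: CountMatrix, layout: GenomeLayout,
                  sample_groups: dict[str, str] | None = None) -> dict:
    """Immunoglobulin transcript summary per sample (and per group).

    ``pct_ig`` is total Ig-gene counts over all gene counts; isotype
    fractions are over constant-class (IgM/IgD/IgG/IgA) counts only, with
    the class-switched fraction = (IgG + IgA) share; V-gene usage is over
    IgV-class counts.
    """
    gt = layout.gene_table().set_index("gene_id")
    ig_class = gt["ig_class"].reindex(cm.counts.index)
    if ig_class.notna().sum() == 0:
        raise ValueError("no Ig genes annotated in the layout")
    out: dict = {"samples": {}}
    for s in cm.samples:
        col = cm.counts[s]
        total = float(col.sum())
        ig_total = float(col[ig_class.notna()].sum())
        const = col[ig_class.isin(_CONSTANT)]
        const_total = float(const.sum())
        iso = {
            cls: (float(col[ig_class == cls].sum()) / const_total if const_total else 0.0)
            for cls in sorted(_CONSTANT)
        }
        switched = sum(iso[c] for c in _SWITCHED)
        v_counts = col[ig_class == "IgV"]
        v_total = float(v_counts.sum())
        v_usage = {g: float(c) / v_total for g, c in v_counts.items()} if v_total else {}
        out["samples"][s] = {
            "pct_ig": 100.0 * ig_total / total if total else 0.0,
            "isotype_fractions": iso,
            "switched_fraction": switched,
            "v_usage": v_usage,
        }
    if sample_groups:
        groups: dict[str, list[str]] = {}
        for s, g in sample_groups.items():
            if s in out["samples"]:
                groups.setdefault(g, []).append(s)
        out["groups"] = {
            g: {
                "pct_ig": float(np.mean([out["samples"][s]["pct_ig"] for s in ss])),
                "switched_fraction": float(
                    np.mean([out["samples"][s]["switched_fraction"] for s in ss])
                ),
            }
            for g, ss in groups.items()
        }
    return out
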