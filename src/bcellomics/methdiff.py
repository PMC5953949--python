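"""Differential CpG methylation from bisulfite counts.

Per-CpG beta-binomial model with moment dispersion estimates shrunk toward
the genome-wide median, a Wald test on arcsine-square-root-transformed
pooled proportions (variance-stabilized, so the null variance does not
depend on the unknown proportion), BH FDR, and locus calling at an FDR and
absolute-methylation-difference threshold.  Effect sizes are reported on
the raw proportion scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .core import MethCountTable

__all__ = ["filter_coverage", "test_dml", "call_dml"]

log = logging.getLogger(__name__)


def filter_coverage(
    table: MethCountTable, min_cov: int = 10, scope: str = "per_sample"
) -> MethCountTable:
    """Keep CpGs meeting the minimum-coverage rule.

    ``scope="per_sample"``: every sample must have coverage >= ``min_cov``
    (the set used for heat maps / PCA / average methylation).
    ``scope="per_group"``: the pooled coverage of every group must be
    >= ``min_cov`` (the set used for differential testing).
    """
    if scope == "per_sample":
        keep = (table.coverage >= min_cov).all(axis=1)
    elif scope == "per_group":
        keep = np.ones(table.n_sites, dtype=bool)
        for _g, idx in table.groups().items():
            keep &= table.coverage[:, idx].sum(axis=1) >= min_cov
    else:
        raise ValueError(f"scope must be 'per_sample' or 'per_group', got {scope!r}")
    if not keep.any():
        log.warning("coverage filter removed every site")
    return table.subset_sites(keep)


def _beta_binomial_phi_mom(cov: np.ndarray, met: np.ndarray,
                           groups: list[np.ndarray]) -> np.ndarray:
    """Per-site method-of-moments dispersion under group-specific means.

    For beta-binomial counts ``m ~ BB(c, pi, phi)``,
    ``Var(m) = c pi (1-pi) (1 + (c-1) phi)``; phi is solved from the
    pooled squared residuals of per-sample counts around the fitted
    (coverage-weighted) group mean.  Because the mean is estimated from
    the same samples, residual ``j`` carries coefficient
    ``w_j = (1 - c_j/S)^2 + (Q - c_j^2)/S^2`` (S, Q the group's coverage
    sum and sum of squares) on its variance; using these exact weights
    removes the degrees-of-freedom bias that would otherwise drive the
    moment estimate to zero at small replicate numbers.
    """
    num = np.zeros(cov.shape[0])
    den = np.zeros(cov.shape[0])
    for idx in groups:
        c = cov[:, idx].astype(float)
        m = met[:, idx].astype(float)
        S = c.sum(axis=1)
        Q = (c**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(S > 0, m.sum(axis=1) / np.maximum(S, 1), 0.0)
        v = pi * (1 - pi)
        resid2 = ((m - c * pi[:, None]) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = (1 - c / np.maximum(S[:, None], 1)) ** 2 + (
                Q[:, None] - c**2
            ) / np.maximum(S[:, None] ** 2, 1)
        # E[sum resid2] = sum_j w_j c_j v (1 + (c_j - 1) phi)
        num += resid2 - (w * c).sum(axis=1) * v
        den += (w * c * (c - 1.0)).sum(axis=1) * v
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(phi, 0.0, 1.0)


def test_dml(
    table: MethCountTable,
    groups: tuple[str, str],
    shrink: bool = True,
) -> pd.DataFrame:
    """Per-site two-group beta-binomial Wald test.

    Group means are pooled (coverage-weighted) proportions.  The test
    statistic is the difference of ``arcsin(sqrt(mu))`` between groups; by
    the delta method its variance is ``sum_i c_i (1 + (c_i - 1) phi) /
    (4 (sum_i c_i)^2)`` per group, independent of ``mu``.  With ``shrink``,
    per-site dispersions are pulled toward the genome-wide median with
    weight ``1/n_reps`` (less per-site trust with fewer replicates).

    Returns a DataFrame with ``chrom, pos, mu1, mu2, delta_me, phi, p, fdr``
    sorted by position; sites with zero pooled coverage in either group are
    excluded (counted in a log line).
    """
    gmap = table.groups()
    for g in groups:
        if g not in gmap:
            raise KeyError(f"group {g!r} not in design")
    i1 = np.asarray(gmap[groups[0]])
    i2 = np.asarray(gmap[groups[1]])

    cov, met = table.coverage, table.methylated
    c1, c2 = cov[:, i1].sum(axis=1), cov[:, i2].sum(axis=1)
    ok = (c1 > 0) & (c2 > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("test_dml: excluded %d sites with zero group coverage", n_dropped)

    m1 = met[:, i1].sum(axis=1)
    m2 = met[:, i2].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = np.where(c1 > 0, m1 / np.maximum(c1, 1), np.nan)
        mu2 = np.where(c2 > 0, m2 / np.maximum(c2, 1), np.nan)

    phi = _beta_binomial_phi_mom(cov, met, [i1, i2])
    if shrink:
        n_reps = min(len(i1), len(i2))
        wt = min(1.0, 2.0 / n_reps)
        # genome-wide mean: the per-site moment estimate is clipped at 0,
        # which skews its median low; the mean is close to unbiased
        phi_center = float(phi[ok].mean()) if ok.any() else 0.0
        phi = (1.0 - wt) * phi + wt * phi_center

    def _var_arcsine(cv: np.ndarray, idx: np.ndarray) -> np.ndarray:
        c = cov[:, idx].astype(float)
        S = c.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (c * (1.0 + (c - 1.0) * phi[:, None])).sum(axis=1) / (4.0 * S**2)

    t1 = np.arcsin(np.sqrt(np.clip(mu1, 0, 1)))
    t2 = np.arcsin(np.sqrt(np.clip(mu2, 0, 1)))
    var = _var_arcsine(cov, i1) + _var_arcsine(cov, i2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (t2 - t1) / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    res = table.sites.copy()
    res["mu1"], res["mu2"] = mu1, mu2
    res["delta_me"] = mu2 - mu1
    res["phi"] = phi
    res["p"] = p
    res = res.loc[ok].reset_index(drop=True)
    res["fdr"] = bh_fdr(res["p"].to_numpy())
    return res


def call_dml(records: pd.DataFrame, alpha: float = 0.05, delta: float = 0.20) -> pd.DataFrame:
    """Flag differentially methylated loci: FDR <= alpha and
    |delta_me| >= delta.  Adds ``is_dml`` and a ``direction`` column
    (hypo for delta_me < 0, hyper for > 0)."""
    out = records.copy()
    out["is_dml"] = (out["fdr"] <= alpha) & (out["delta_me"].abs() >= delta)
    out["direction"] = np.where(out["delta_me"] < 0, "hypo",
                                np.where(out["delta_me"] > 0, "hyper", "none"))
    n_hypo = int((out["is_dml"] & (out["direction"] == "hypo")).sum())
    n_hyper = int((out["is_dml"] & (out["direction"] == "hyper")).sum())
    out.attrs["summary"] = {"n_dml": n_hypo + n_hyper, "n_hypo": n_hypo, "n_hyper": n_hyper}
    return out
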