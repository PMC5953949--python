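"""Shared statistical machinery: BH FDR and the negative-binomial Wald test
used for both differential expression (genes) and differential accessibility
(ATAC peaks)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "nb_wald_test"]


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _dispersion_trend(mean_expr: np.ndarray, disp: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-dispersion trend: bin means over quantile bins of log mean
    expression, piecewise-linear between bin centers.  Bin means (not
    medians) because the per-feature moment estimate is clipped at zero,
    which skews its median low."""
    logm = np.log(mean_expr + 1e-8)
    order = np.argsort(logm)
    n = len(logm)
    n_bins = max(1, min(n_bins, n // 10)) if n >= 10 else 1
    edges = np.array_split(order, n_bins)
    centers = np.array([logm[idx].mean() for idx in edges])
    means = np.array([disp[idx].mean() for idx in edges])
    if n_bins == 1:
        return np.full(n, means[0])
    return np.interp(logm, centers, means)


def _moment_dispersion(y: np.ndarray, s: np.ndarray,
                       group_idx: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-feature NB dispersion by method of moments, pooled over groups.

    Counts ``y_ij ~ NB(s_j q_g, alpha)`` have ``Var = mu + alpha mu^2``.
    Residuals around the fitted (offset-weighted) group mean carry exact
    coefficients ``w_j = (1 - s_j/S)^2 + (Q - s_j^2)/S^2`` on their
    variances (S, Q the group's offset sum and sum of squares), which
    removes the degrees-of-freedom bias of the naive estimator.  Returns
    (alpha_hat clipped to [0, 10], per-group abundance estimates).
    """
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    qs = []
    for idx in group_idx:
        yy = y[:, idx]
        ss = s[idx]
        S = ss.sum()
        Q = (ss**2).sum()
        q = yy.sum(axis=1) / S
        mu = q[:, None] * ss[None, :]
        w = (1.0 - ss / S) ** 2 + (Q - ss**2) / S**2
        num += ((yy - mu) ** 2).sum(axis=1) - (w[None, :] * mu).sum(axis=1)
        den += (w[None, :] * mu**2).sum(axis=1)
        qs.append(q)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.clip(alpha, 0.0, 10.0), qs


def nb_wald_test(
    counts: np.ndarray,
    offsets: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-feature two-group Wald test under a negative-binomial model.

    Counts ``y_ij ~ NB(mean = s_j * q_g, dispersion = alpha_i)`` with
    sample offsets ``s_j`` (library size or reads-in-peaks).  Group
    abundances are pooled-count estimates ``q_g = sum(y)/sum(s)``; the
    tagwise dispersion is a bias-corrected moment estimate shrunk 50/50
    toward the mean trend over expression.  The Wald statistic on
    ``log q_B - log q_A`` is referred to a t distribution with
    ``3 (n_A + n_B - 2)`` degrees of freedom: the trend moderation cuts
    the dispersion-estimator variance by about a factor four, so the
    effective degrees of freedom sit well above the residual
    ``n_A + n_B - 2`` but below the normal limit (the factor validated on
    null simulations).

    Returns a DataFrame with ``log2fc`` (shrunken, via ``prior_count``
    added to pooled counts), ``mean_expr`` (counts per mean offset),
    ``dispersion``, ``p``; all-zero features get NaN p.
    """
    y = np.asarray(counts, dtype=float)
    s = np.asarray(offsets, dtype=float)
    ia = np.asarray(group_a)
    ib = np.asarray(group_b)
    if min(len(ia), len(ib)) < 2:
        raise ValueError("need >= 2 samples per group")

    disp_raw, (qa, qb) = _moment_dispersion(y, s, [ia, ib])
    both = np.r_[ia, ib]
    mean_expr = y[:, both].sum(axis=1) / s[both].sum() * s.mean()
    nonzero = mean_expr > 0
    disp = disp_raw.copy()
    if nonzero.sum() >= 2:
        trend = _dispersion_trend(mean_expr[nonzero], disp_raw[nonzero])
        disp[nonzero] = 0.5 * disp_raw[nonzero] + 0.5 * trend

    # shrunken fold change: prior count added on the pooled scale
    qa_sh = (y[:, ia].sum(axis=1) + prior_count) / s[ia].sum()
    qb_sh = (y[:, ib].sum(axis=1) + prior_count) / s[ib].sum()
    log2fc = np.log2(qb_sh) - np.log2(qa_sh)

    def _var_log_q(q: np.ndarray, idx: np.ndarray) -> np.ndarray:
        S = s[idx].sum()
        mu = q[:, None] * s[idx][None, :]
        var_q = (mu + disp[:, None] * mu**2).sum(axis=1) / S**2
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(q > 0, var_q / q**2, np.inf)

    va = _var_log_q(qa, ia)
    vb = _var_log_q(qb, ib)
    # groups with zero counts: evaluate at the shrunken abundance so the
    # statistic stays finite
    va = np.where(np.isfinite(va), va, _var_log_q(qa_sh, ia))
    vb = np.where(np.isfinite(vb), vb, _var_log_q(qb_sh, ib))
    se = np.sqrt(va + vb)
    beta = np.log(qb_sh) - np.log(qa_sh)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    n_tot = len(ia) + len(ib)
    # Satterthwaite-style reference: only the dispersion term of
    # Var = mu + alpha mu^2 carries estimation noise, so the effective
    # degrees of freedom grow as its share of the variance shrinks
    # (Poisson-dominated features are essentially normal).  The base
    # 3 (n_tot - 2) reflects the ~4-fold variance reduction of the 50/50
    # trend moderation; validated on null simulations.
    mu_bar = mean_expr
    share = disp * mu_bar / (1.0 + disp * mu_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = np.where(share > 0.05,
                      3.0 * max(n_tot - 2, 1) / share**2, np.inf)
    df = np.clip(df, 3.0, 1e6)
    p = 2.0 * stats.t.sf(np.abs(z), df)
    all_zero = y[:, both].sum(axis=1) == 0
    p = np.where(all_zero, np.nan, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    return pd.DataFrame(
        {"log2fc": log2fc, "mean_expr": mean_expr, "dispersion": disp, "p": p}
    )
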