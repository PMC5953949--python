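"""PWM motif scanning and Fisher-exact enrichment.

Motifs are 4xL probability matrices scored as log2-odds against a
background (uniform by default) with a small pseudocount; scanning covers
both strands and reports windows at or above a per-motif threshold
(default 80% of the maximum attainable score).  Enrichment of motifs near
differentially methylated loci and within region clusters uses Fisher's
exact test with BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr

__all__ = [
    "MotifModel",
    "read_jaspar",
    "write_jaspar",
    "scan_motifs",
    "fisher_exact",
    "enrich_near_dml",
    "enrich_in_regions",
]

log = logging.getLogger(__name__)

_ALPHABET = "ACGT"
_PSEUDOCOUNT = 1e-3


@dataclass
class MotifModel:
    """A position weight matrix with its scan threshold.

    ``pwm`` has rows A, C, G, T and columns summing to 1; scores are
    ``sum_j log2((pwm[b_j, j] + eps) / bg[b_j])``.  ``threshold_frac`` sets
    the hit threshold as a fraction of the maximum attainable score.
    """

    motif_id: str
    pwm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape[0] != 4 or self.pwm.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2((self.pwm + _PSEUDOCOUNT) / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def threshold(self) -> float:
        return self.threshold_frac * self.max_score

    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.pwm.argmax(axis=0))


# ----------------------------------------------------------- JASPAR format

def write_jaspar(path: str | Path, motifs: list[MotifModel], scale: int = 1000) -> None:
    """Write motifs as JASPAR-style count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.motif_id}\n")
            counts = np.round(m.pwm * scale).astype(int)
            for i, base in enumerate(_ALPHABET):
                row = " ".join(f"{c:6d}" for c in counts[i])
                fh.write(f"{base}  [ {row} ]\n")


def read_jaspar(path: str | Path, threshold_frac: float = 0.8) -> list[MotifModel]:
    """Read JASPAR-format matrices (via Bio.motifs) into MotifModels,
    normalizing counts to probabilities."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in _ALPHABET], dtype=float)
        pwm = counts / counts.sum(axis=0, keepdims=True)
        out.append(MotifModel(rec.name or rec.matrix_id, pwm,
                              threshold_frac=threshold_frac))
    return out


# ----------------------------------------------------------------- scanning

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_ALPHABET):
        code[ord(b)] = i
    return code[arr]


def _scan_strand(codes: np.ndarray, lodds: np.ndarray) -> np.ndarray:
    """Score every window start on the encoded + strand; windows with
    non-ACGT bases get -inf."""
    L = lodds.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    safe = codes.copy()
    bad = codes < 0
    safe[bad] = 0
    for j in range(L):
        scores += lodds[safe[j : j + n], j]
        valid &= ~bad[j : j + n]
    scores[~valid] = -np.inf
    return scores


def scan_motifs(sequences: dict[str, str], motifs: list[MotifModel]) -> pd.DataFrame:
    """Scan both strands of every chromosome for every motif.

    Returns hits with columns ``motif_id, chrom, start, end, strand,
    score`` (0-based half-open, end - start = motif length).  The reported
    ``start`` is always the leftmost genomic base of the window; ``-``
    strand hits are matches of the reverse complement.
    """
    rows = []
    for chrom, seq in sequences.items():
        codes = _encode(seq)
        for m in motifs:
            lodds = m.log_odds
            thr = m.threshold
            fwd = _scan_strand(codes, lodds)
            # - strand: score the reverse-complement PWM on the + sequence
            rc_lodds = lodds[::-1, ::-1]
            rev = _scan_strand(codes, rc_lodds)
            for strand, scores in (("+", fwd), ("-", rev)):
                hit = np.flatnonzero(scores >= thr)
                for i in hit:
                    rows.append((m.motif_id, chrom, int(i), int(i) + m.length,
                                 strand, float(scores[i])))
    df = pd.DataFrame(rows, columns=["motif_id", "chrom", "start", "end",
                                     "strand", "score"])
    return df.sort_values(["motif_id", "chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------- Fisher test

def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds ratio = a*d / (b*c), two-sided p by the
    probability-mass-at-most-observed rule); the OR may be 0 or inf.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        orat = (a * d) / (b * c)
    elif a * d > 0:
        orat = np.inf
    else:
        orat = np.nan  # 0/0: a margin is empty
    return float(orat), float(res.pvalue)


def _haldane_or(a: int, b: int, c: int, d: int) -> float:
    """Haldane-Anscombe corrected odds ratio (finite with zero cells)."""
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


# --------------------------------------------------------------- enrichment

def _proximal_mask(site_pos: np.ndarray, hit_starts: np.ndarray,
                   hit_ends: np.ndarray, window: int) -> np.ndarray:
    """True for sites with some hit within ``window`` bp (inclusive,
    distance from the site to the nearest base of the hit)."""
    if len(hit_starts) == 0:
        return np.zeros(len(site_pos), dtype=bool)
    order = np.argsort(hit_starts)
    hs, he = hit_starts[order], hit_ends[order]
    # site is proximal iff an interval [start - window, end - 1 + window] covers it
    lo = hs - window
    hi = he + window  # half-open
    # merge and test membership
    idx = np.searchsorted(lo, site_pos, side="right")
    out = np.zeros(len(site_pos), dtype=bool)
    # a site may be covered by an earlier interval with a large end; scan back
    max_hi = np.maximum.accumulate(hi)
    out = (idx > 0) & (site_pos < max_hi[np.clip(idx - 1, 0, None)])
    return out


def enrich_near_dml(
    hits: pd.DataFrame,
    dml_sites: pd.DataFrame,
    universe_sites: pd.DataFrame,
    window: int = 50,
) -> pd.DataFrame:
    """Per-motif Fisher enrichment of hits within ``window`` bp of DML
    versus the non-DML CpG universe.

    ``dml_sites``/``universe_sites`` need ``chrom, pos``; the universe must
    contain the DML.  Returns ``motif_id, n_dml_proximal, n_dml,
    n_bg_proximal, n_bg, odds_ratio, odds_ratio_haldane, p, fdr`` sorted
    by FDR.
    """
    if dml_sites.empty:
        raise ValueError("empty DML set")
    uni = universe_sites[["chrom", "pos"]].drop_duplicates()
    dml_keys = set(map(tuple, dml_sites[["chrom", "pos"]].to_numpy()))
    is_dml = np.array([(c, p) in dml_keys for c, p in uni.to_numpy()])
    rows = []
    for motif_id, sub in hits.groupby("motif_id"):
        prox = np.zeros(len(uni), dtype=bool)
        for chrom, chits in sub.groupby("chrom"):
            csel = (uni["chrom"] == chrom).to_numpy()
            prox[csel] = _proximal_mask(
                uni.loc[csel, "pos"].to_numpy(),
                chits["start"].to_numpy(), chits["end"].to_numpy(), window,
            )
        a = int((is_dml & prox).sum())
        b = int((is_dml & ~prox).sum())
        c = int((~is_dml & prox).sum())
        d = int((~is_dml & ~prox).sum())
        orat, p = fisher_exact(a, b, c, d)
        rows.append((motif_id, a, a + b, c, c + d, orat, _haldane_or(a, b, c, d), p))
    out = pd.DataFrame(rows, columns=["motif_id", "n_dml_proximal", "n_dml",
                                      "n_bg_proximal", "n_bg", "odds_ratio",
                                      "odds_ratio_haldane", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["fdr", "p"]).reset_index(drop=True)


def enrich_in_regions(
    hits: pd.DataFrame,
    cluster_regions: dict[int, pd.DataFrame],
    all_regions: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(motif, cluster) Fisher overrepresentation of regions containing
    >= 1 hit, against all other regions.  Regions are half-open intervals
    with ``chrom, start, end, name``."""
    def _contains_hit(regions: pd.DataFrame, sub: pd.DataFrame) -> np.ndarray:
        has = np.zeros(len(regions), dtype=bool)
        for chrom, chits in sub.groupby("chrom"):
            csel = (regions["chrom"] == chrom).to_numpy()
            if not csel.any():
                continue
            # a hit (s, e) is inside the region iff its start lies in [start, end - L + 1)
            hs = np.sort(chits["start"].to_numpy())
            rs = regions.loc[csel, "start"].to_numpy()
            re_ = regions.loc[csel, "end"].to_numpy()
            lo = np.searchsorted(hs, rs)
            hi = np.searchsorted(hs, re_)
            has[csel] = hi > lo
        return has

    rows = []
    for motif_id, sub in hits.groupby("motif_id"):
        overall = _contains_hit(all_regions, sub)
        names_all = all_regions["name"].to_numpy()
        has_by_name = dict(zip(names_all, overall))
        for cluster, regions in cluster_regions.items():
            if regions.empty:
                log.warning("cluster %s is empty, skipped", cluster)
                continue
            in_cluster = set(regions["name"])
            mask_in = np.array([n in in_cluster for n in names_all])
            a = int((mask_in & overall).sum())
            b = int((mask_in & ~overall).sum())
            c = int((~mask_in & overall).sum())
            d = int((~mask_in & ~overall).sum())
            orat, p = fisher_exact(a, b, c, d)
            rows.append((motif_id, cluster, a, b, c, d, orat, p))
    out = pd.DataFrame(rows, columns=["motif_id", "cluster", "a", "b", "c", "d",
                                      "odds_ratio", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["fdr", "p"]).reset_index(drop=True)
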