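"""ATAC-seq analysis on cut sites (read 5' start bases): peak counting,
reads-in-peaks normalization (RPM), FRiP quality control, differential
accessibility, and motif-centered footprinting."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_fdr, nb_wald_test
from .core import CountMatrix, CutSiteSet

__all__ = [
    "reads_in_peaks",
    "rpm_normalize",
    "qc_frip",
    "peak_count_matrix",
    "test_dar",
    "call_dar",
    "footprint",
    "FootprintProfile",
]

log = logging.getLogger(__name__)


def _count_starts_in_intervals(pos: np.ndarray, starts: np.ndarray,
                               ends: np.ndarray) -> np.ndarray:
    """Reads whose start base lies in [start, end) per interval (sorted,
    possibly overlapping intervals; a read in two intervals counts in both)."""
    pos = np.sort(pos)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    return hi - lo


def reads_in_peaks(cutsites: CutSiteSet, peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-sample per-peak read-start counts plus totals and FRiP.

    Returns a DataFrame indexed by peak name with one column per sample;
    ``attrs["frip"]`` and ``attrs["total_in_peaks"]`` carry the per-sample
    summaries.  Overlapping peaks are counted once per containing peak and
    flagged in the log.
    """
    if len(peaks) and (peaks["end"] <= peaks["start"]).any():
        raise ValueError("degenerate peak interval")
    pk = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    if len(pk) > 1:
        same = pk["chrom"].to_numpy()[1:] == pk["chrom"].to_numpy()[:-1]
        if np.any(same & (pk["start"].to_numpy()[1:] < pk["end"].to_numpy()[:-1])):
            log.warning("overlapping peaks: reads count once per containing peak")
    names = pk["name"] if "name" in pk else pd.Index([f"peak{i}" for i in range(len(pk))])
    counts = {}
    frip = {}
    total_in = {}
    for s in cutsites.samples:
        col = np.zeros(len(pk), dtype=int)
        for chrom, sub in pk.groupby("chrom", sort=False):
            pos = cutsites.positions(s, chrom)
            col[sub.index] = _count_starts_in_intervals(
                pos, sub["start"].to_numpy(), sub["end"].to_numpy()
            )
        counts[s] = col
        # a read in overlapping peaks must count once toward the total
        total = 0
        for chrom, sub in pk.groupby("chrom", sort=False):
            pos = np.sort(cutsites.positions(s, chrom))
            inside = np.zeros(len(pos), dtype=bool)
            lo = np.searchsorted(pos, sub["start"].to_numpy())
            hi = np.searchsorted(pos, sub["end"].to_numpy())
            for a, b in zip(lo, hi):
                inside[a:b] = True
            total += int(inside.sum())
        total_in[s] = total
        frip[s] = total / cutsites.totals[s] if cutsites.totals[s] else 0.0
    out = pd.DataFrame(counts, index=names.to_numpy())
    out.index.name = "name"
    out.attrs["total_in_peaks"] = total_in
    out.attrs["frip"] = frip
    return out


def rpm_normalize(counts, total_in_peaks):
    """Reads-per-million on the reads-in-peaks scale:
    RPM = reads * 1e6 / total reads in peaks.

    ``counts`` may be a scalar, array, or peaks x samples DataFrame (then
    ``total_in_peaks`` is per-sample, broadcast along columns)."""
    totals = np.asarray(total_in_peaks, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("total reads in peaks must be > 0")
    if isinstance(counts, pd.DataFrame):
        return counts * 1e6 / totals
    return np.asarray(counts, dtype=float) * 1e6 / totals


def qc_frip(frip: dict[str, float], lower: float = 0.05, upper: float = 0.25) -> pd.DataFrame:
    """Pass/fail the 5-25% reads-in-peaks window (inclusive bounds);
    failing samples are to be removed from downstream analysis."""
    rows = []
    for s, f in frip.items():
        ok = lower <= f <= upper
        rows.append({"sample": s, "frip": f, "pass": ok})
        if not ok:
            log.warning("sample %s fails FRiP QC (%.3f outside [%.2f, %.2f])",
                        s, f, lower, upper)
    return pd.DataFrame(rows)


def peak_count_matrix(peak_counts: pd.DataFrame) -> CountMatrix:
    """Wrap per-peak counts as a CountMatrix with reads-in-peaks as the
    normalization totals (the RPM denominator)."""
    totals = pd.Series(peak_counts.attrs["total_in_peaks"], dtype=float)
    totals = totals.reindex(peak_counts.columns)
    return CountMatrix(peak_counts.copy(), totals)


def test_dar(
    cm: CountMatrix,
    design: dict[str, str],
    groups: tuple[str, str],
) -> pd.DataFrame:
    """Differential accessibility: the NB Wald test with reads-in-peaks
    offsets (consistent with RPM normalization)."""
    samples = cm.counts.columns
    ia = np.flatnonzero(np.array([design.get(s) == groups[0] for s in samples]))
    ib = np.flatnonzero(np.array([design.get(s) == groups[1] for s in samples]))
    res = nb_wald_test(
        cm.counts.to_numpy(dtype=float),
        cm.library_size.reindex(samples).to_numpy(dtype=float),
        ia, ib,
    )
    res.insert(0, "name", cm.counts.index.to_numpy())
    res = res.dropna(subset=["p"]).reset_index(drop=True)
    res["fdr"] = bh_fdr(res["p"].to_numpy())
    return res


def call_dar(records: pd.DataFrame, alpha: float = 0.01, fc: float = 2.0) -> pd.DataFrame:
    """Flag differentially accessible regions: FDR <= 0.01 and a signal fold
    change >= 2 by default."""
    out = records.copy()
    out["is_dar"] = (out["fdr"] <= alpha) & (out["log2fc"].abs() >= np.log2(fc))
    return out


# ---------------------------------------------------------------- footprint

@dataclass
class FootprintProfile:
    """Aggregate read-start pileup around motif instances, motif-oriented."""

    motif_id: str
    offsets: np.ndarray  # -w .. +w
    counts: np.ndarray  # read-start incidences per offset
    rate: np.ndarray  # counts per million total reads
    n_instances: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "count": self.counts, "rate": self.rate}
        )

    def minimum_offset(self, smooth_bp: int = 21) -> int:
        """Offset of the profile minimum after a moving-average smooth
        wider than the depleted well, so a flat-bottomed footprint
        resolves to its center rather than a noise minimum."""
        kernel = np.ones(smooth_bp) / smooth_bp
        sm = np.convolve(self.rate, kernel, mode="same")
        # edges are biased low by zero padding; exclude half a kernel
        h = smooth_bp // 2
        inner = slice(h, len(sm) - h)
        return int(self.offsets[inner][np.argmin(sm[inner])])

    def center_flank_ratio(self, center_hw: int = 5,
                           flank: tuple[int, int] = (50, 100)) -> float:
        """Mean rate at |offset| <= center_hw over mean rate in the flank
        band — the footprint depth statistic."""
        o = np.abs(self.offsets)
        c = self.rate[o <= center_hw].mean()
        f = self.rate[(o >= flank[0]) & (o <= flank[1])].mean()
        return float(c / f) if f > 0 else np.nan


def footprint(
    cutsites: CutSiteSet,
    motif_hits: pd.DataFrame,
    w: int = 100,
    samples: list[str] | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> FootprintProfile:
    """Cut-site footprint around motif instances.

    ``motif_hits`` needs columns ``motif_id, chrom, start, strand`` (and
    optionally ``end``; the motif center is ``start + floor(len/2)``,
    taking the length from end-start when present, else from hits of equal
    length).  Only the base at which each read began is counted.  For
    ``+`` instances the offset is ``read_start - center``; for ``-``
    instances it is ``center - read_start`` so the profile is oriented
    along the motif.  Counts aggregate over all instances and samples;
    the rate is per million total reads.
    """
    if motif_hits.empty:
        raise ValueError("no motif instances supplied")
    motif_id = str(motif_hits["motif_id"].iloc[0])
    if "end" in motif_hits:
        length = (motif_hits["end"] - motif_hits["start"]).to_numpy()
    else:
        raise ValueError("motif_hits must carry an 'end' column to locate centers")
    centers = motif_hits["start"].to_numpy() + length // 2
    strands = motif_hits["strand"].to_numpy()
    chroms = motif_hits["chrom"].to_numpy()
    use_samples = samples if samples is not None else cutsites.samples
    offsets = np.arange(-w, w + 1)
    counts = np.zeros(2 * w + 1, dtype=int)
    n_truncated = 0
    if chrom_sizes:
        for c, ch in zip(centers, chroms):
            if c - w < 0 or c + w >= chrom_sizes.get(ch, np.inf):
                n_truncated += 1
        if n_truncated:
            log.warning("%d motif windows truncated at chromosome ends", n_truncated)
    for s in use_samples:
        sub = cutsites.table[cutsites.table["sample"] == s]
        for chrom in np.unique(chroms):
            pos = np.sort(sub.loc[sub["chrom"] == chrom, "pos"].to_numpy())
            csel = chroms == chrom
            for c, st in zip(centers[csel], strands[csel]):
                lo = np.searchsorted(pos, c - w)
                hi = np.searchsorted(pos, c + w + 1)
                if hi > lo:
                    off = pos[lo:hi] - c
                    if st == "-":
                        off = -off
                    np.add.at(counts, off + w, 1)
    total_reads = sum(cutsites.totals[s] for s in use_samples)
    rate = counts * 1e6 / total_reads if total_reads else counts.astype(float)
    return FootprintProfile(motif_id, offsets, counts, rate, len(motif_hits))
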