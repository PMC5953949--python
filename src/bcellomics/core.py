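"""Core domain containers shared across the tri-omic modules.

Coordinates are 0-based, half-open throughout the in-memory model; file
readers/writers convert at the boundary (bismark coverage files are 1-based
inclusive, GTF is 1-based inclusive, BED is 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "GenomeLayout",
    "MethCountTable",
    "CountMatrix",
    "CutSiteSet",
]


@dataclass(frozen=True)
class Gene:
    """A gene model anchored by TSS/TTS in genome orientation.

    ``tss``/``tts`` are the transcription start/termination positions
    (0-based); for a ``-`` strand gene ``tss > tts``.  ``exons`` are
    half-open intervals within the gene span.  ``ig_class`` marks
    immunoglobulin segments (``IgM``/``IgD``/``IgG``/``IgA`` constant
    classes or ``IgV`` variable segments); ``None`` for ordinary genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...]
    ig_class: str | None = None

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts) + 1  # half-open span

    @property
    def exonic_length(self) -> int:
        """Length of the union of exons in bp."""
        ivs = sorted(self.exons)
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total


@dataclass
class GenomeLayout:
    """Genomic context: chromosome sizes, gene models, CpG map, enhancers,
    and the ground-truth locations of implanted motif instances."""

    chrom_sizes: dict[str, int]
    genes: list[Gene]
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    enhancers: pd.DataFrame | None = None  # columns chrom,start,end,name
    motif_truth: pd.DataFrame | None = None  # columns motif_id,chrom,start,strand

    def validate(self) -> None:
        for chrom, pos in self.cpg_positions.items():
            if len(pos) and (np.any(np.diff(pos) <= 0) or pos[-1] >= self.chrom_sizes[chrom]):
                raise ValueError(f"CpG positions on {chrom} not strictly increasing in-bounds")
        for g in self.genes:
            size = self.chrom_sizes[g.chrom]
            if not (0 <= g.start < g.end <= size):
                raise ValueError(f"gene {g.gene_id} out of bounds")
            for s, e in g.exons:
                if not (g.start <= s < e <= g.end):
                    raise ValueError(f"exon of {g.gene_id} outside gene span")

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "tts": [g.tts for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "length": [g.exonic_length for g in self.genes],
                "ig_class": [g.ig_class for g in self.genes],
            }
        )


@dataclass
class MethCountTable:
    """Per-CpG, per-sample bisulfite counts with the sample->group design.

    ``sites`` has columns ``chrom``, ``pos`` (0-based C of the CpG) and is
    sorted/unique; ``coverage`` and ``methylated`` are (n_sites, n_samples)
    integer arrays aligned to ``samples``.
    """

    sites: pd.DataFrame
    samples: list[str]
    coverage: np.ndarray
    methylated: np.ndarray
    design: dict[str, str]  # sample -> group

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage)
        self.methylated = np.asarray(self.methylated)
        if np.any(self.methylated > self.coverage) or np.any(self.methylated < 0):
            raise ValueError("methylated counts must satisfy 0 <= m <= coverage")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def groups(self) -> dict[str, list[int]]:
        """Group name -> column indices."""
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault(self.design[s], []).append(j)
        return out

    def subset_sites(self, mask: np.ndarray) -> "MethCountTable":
        return MethCountTable(
            self.sites.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.coverage[mask],
            self.methylated[mask],
            dict(self.design),
        )

    def subset_samples(self, samples: list[str]) -> "MethCountTable":
        idx = [self.samples.index(s) for s in samples]
        return MethCountTable(
            self.sites.copy(),
            samples,
            self.coverage[:, idx],
            self.methylated[:, idx],
            {s: self.design[s] for s in samples},
        )


@dataclass
class CountMatrix:
    """Non-negative integer features x samples matrix (genes or ATAC peaks).

    ``library_size`` is the normalization total per sample (total mapped
    reads for RNA, reads-in-peaks for ATAC); it need not equal the column
    sum.  ``lengths`` (exonic bp) is present when features are genes.
    """

    counts: pd.DataFrame  # index = feature ids, columns = samples
    library_size: pd.Series
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lengths is not None and (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive length for feature {bad!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class CutSiteSet:
    """Per-sample ATAC read 5' start positions with strand.

    ``table`` has columns ``chrom``, ``pos`` (0-based 5' base), ``strand``,
    ``sample``.  ``totals`` is the total read count per sample.
    """

    table: pd.DataFrame
    totals: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return list(self.totals)

    def positions(self, sample: str, chrom: str | None = None) -> np.ndarray:
        t = self.table[self.table["sample"] == sample]
        if chrom is not None:
            t = t[t["chrom"] == chrom]
        return t["pos"].to_numpy()
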