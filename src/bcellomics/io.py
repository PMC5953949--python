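"""Readers and writers for the package's on-disk formats.

Conventions at the file boundary:

* FASTA — genome sequence (via ``pyfaidx`` on read).
* GTF — gene models, 1-based inclusive; ``gene`` and ``exon`` features with
  ``gene_id`` and optional ``ig_class`` attributes.
* BED6 — 0-based half-open intervals (peaks, enhancers, motif truth, DML).
* Bismark coverage — ``chrom  start1  end1  pct_meth  count_meth
  count_unmeth`` with 1-based inclusive single-base intervals.
* Cut-site TSV — ``chrom  pos0  strand  sample`` (0-based 5' base).
* Count matrices — TSV, features in rows, samples in columns.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountMatrix, CutSiteSet, Gene, GenomeLayout, MethCountTable

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ------------------------------------------------------------------ GTF

def write_gtf(path: str | Path, layout: GenomeLayout) -> None:
    with open(path, "w") as fh:
        for g in layout.genes:
            attrs = f'gene_id "{g.gene_id}";'
            if g.ig_class:
                attrs += f' ig_class "{g.ig_class}";'
            fh.write(
                f"{g.chrom}\tbcellomics\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tbcellomics\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[Gene]:
    """Parse the subset of GTF this package writes (gene + exon features)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feat, start1, end1, _score, strand, _frame, attrs = line.rstrip(
                "\n"
            ).split("\t")
            a = dict(_ATTR_RE.findall(attrs))
            gid = a["gene_id"]
            rec = genes.setdefault(
                gid,
                {"chrom": chrom, "strand": strand, "span": None, "exons": [],
                 "ig_class": a.get("ig_class")},
            )
            s0, e0 = int(start1) - 1, int(end1)
            if feat == "gene":
                rec["span"] = (s0, e0)
            elif feat == "exon":
                rec["exons"].append((s0, e0))
    out = []
    for gid, rec in genes.items():
        span = rec["span"]
        if span is None:
            es = rec["exons"]
            span = (min(s for s, _ in es), max(e for _, e in es))
        start, end = span
        if rec["strand"] == "+":
            tss, tts = start, end - 1
        else:
            tss, tts = end - 1, start
        out.append(
            Gene(gid, rec["chrom"], rec["strand"], tss, tts,
                 tuple(sorted(rec["exons"])), rec["ig_class"])
        )
    return out


# ------------------------------------------------------------------ BED

def write_bed6(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLS)]
    df.columns = BED6_COLS[: df.shape[1]]
    return df


# -------------------------------------------------- bismark coverage files

def write_bismark_cov(path: str | Path, table: MethCountTable, sample: str) -> None:
    j = table.samples.index(sample)
    cov = table.coverage[:, j]
    met = table.methylated[:, j]
    keep = cov > 0
    with np.errstate(invalid="ignore"):
        pct = np.where(cov > 0, 100.0 * met / np.maximum(cov, 1), 0.0)
    df = pd.DataFrame(
        {
            "chrom": table.sites["chrom"][keep],
            "start1": table.sites["pos"][keep] + 1,
            "end1": table.sites["pos"][keep] + 1,
            "pct": np.round(pct[keep], 6),
            "met": met[keep],
            "unmet": (cov - met)[keep],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bismark_cov(paths: dict[str, str | Path], design: dict[str, str]) -> MethCountTable:
    """Assemble a MethCountTable from per-sample bismark ``.cov`` files.

    Sites missing from a sample get coverage 0.  ``design`` maps sample
    name -> group.
    """
    samples = list(paths)
    frames = {}
    for s in samples:
        df = pd.read_csv(
            paths[s], sep="\t", header=None,
            names=["chrom", "start1", "end1", "pct", "met", "unmet"],
        )
        df["pos"] = df["start1"] - 1
        frames[s] = df.set_index(["chrom", "pos"])
    all_sites = sorted(set().union(*(f.index for f in frames.values())))
    idx = pd.MultiIndex.from_tuples(all_sites, names=["chrom", "pos"])
    n = len(idx)
    cov = np.zeros((n, len(samples)), dtype=int)
    met = np.zeros((n, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        f = frames[s].reindex(idx)
        c = (f["met"].fillna(0) + f["unmet"].fillna(0)).to_numpy(dtype=int)
        cov[:, j] = c
        met[:, j] = f["met"].fillna(0).to_numpy(dtype=int)
    sites = idx.to_frame(index=False)
    return MethCountTable(sites, samples, cov, met, dict(design))


# ------------------------------------------------------------- matrices

def write_count_matrix(path: str | Path, cm: CountMatrix) -> None:
    df = cm.counts.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t")
    side = Path(path).with_suffix(".meta.tsv")
    meta = pd.DataFrame({"library_size": cm.library_size})
    meta.index.name = "sample"
    meta.to_csv(side, sep="\t")
    if cm.lengths is not None:
        lp = Path(path).with_suffix(".lengths.tsv")
        ls = pd.DataFrame({"length": cm.lengths})
        ls.index.name = "feature"
        ls.to_csv(lp, sep="\t")


def read_count_matrix(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(Path(path).with_suffix(".meta.tsv"), sep="\t", index_col=0)
    lengths = None
    lp = Path(path).with_suffix(".lengths.tsv")
    if lp.exists():
        lengths = pd.read_csv(lp, sep="\t", index_col=0)["length"]
    return CountMatrix(df, meta["library_size"], lengths)


# ------------------------------------------------------------- cut sites

def write_cutsites(path: str | Path, cs: CutSiteSet) -> None:
    cs.table.to_csv(path, sep="\t", index=False)
    with open(Path(path).with_suffix(".totals.json"), "w") as fh:
        json.dump(cs.totals, fh, indent=1, sort_keys=True)


def read_cutsites(path: str | Path) -> CutSiteSet:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "strand": str, "sample": str})
    with open(Path(path).with_suffix(".totals.json")) as fh:
        totals = {k: int(v) for k, v in json.load(fh).items()}
    return CutSiteSet(table, totals)


# ----------------------------------------------------------------- JSON

def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
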