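"""Shared fixtures: small simulated designs reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bcellomics.core import Gene, GenomeLayout
from bcellomics.simulate import SimDesign, generate_genome


@pytest.fixture(scope="session")
def two_group_design() -> SimDesign:
    """A one-genotype, two-cell-type design at desk scale."""
    return SimDesign(
        seed=101,
        genotypes=("WT",),
        celltypes=("A", "B"),
        n_reps=3,
        chrom_length=500_000,
        n_genes=60,
        n_cpg_sites=3_000,
        n_peaks=300,
        reads_per_sample=60_000,
        n_motif_instances=100,
        hypo_in_enhancer_frac=0.0,
    )


@pytest.fixture(scope="session")
def two_group_genome(two_group_design):
    return generate_genome(two_group_design)


@pytest.fixture()
def tiny_layout() -> GenomeLayout:
    """Hand-built two-gene layout for exact-coordinate assertions."""
    genes = [
        Gene("gA", "chr1", "+", 1000, 1999, ((1000, 1400), (1600, 2000))),
        Gene("gB", "chr1", "-", 5999, 5000, ((5000, 6000),)),
    ]
    return GenomeLayout(
        chrom_sizes={"chr1": 10_000},
        genes=genes,
        cpg_positions={"chr1": np.array([10, 1500, 3500, 5500, 9000])},
    )


def make_random_layout(rng: np.random.Generator, n_genes: int = 8,
                       chrom_len: int = 50_000) -> GenomeLayout:
    """Random non-overlapping gene layout (no sequence) for brute-force
    comparisons."""
    starts = np.sort(rng.choice(chrom_len // 100 - 10, size=n_genes, replace=False)) * 100
    genes = []
    for i, s in enumerate(starts):
        span = int(rng.integers(50, 900))
        strand = "+" if rng.random() < 0.5 else "-"
        e = s + span
        tss, tts = (s, e - 1) if strand == "+" else (e - 1, s)
        genes.append(Gene(f"g{i:02d}", "chr1", strand, tss, tts, ((s, e),)))
    return GenomeLayout(chrom_sizes={"chr1": chrom_len}, genes=genes,
                        cpg_positions={"chr1": np.array([], dtype=int)})
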