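"""Expression-analysis contracts: FPKM arithmetic and invariances, the
expression filter's strict boundary, NB test symmetry, K-means behavior
(including a cross-check against scikit-learn), and Ig repertoire sums."""

import numpy as np
import pandas as pd
import pytest

from bcellomics.core import CountMatrix
from bcellomics.exprdiff import (
    call_deg,
    compute_fpkm,
    filter_expressed,
    ig_repertoire,
    kmeans_programs,
)
from bcellomics.exprdiff import test_deg as run_deg_test
from bcellomics.simulate import SimDesign, generate_genome, simulate_expression


def make_cm(counts, libs, lengths=None):
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(len(counts))],
                      columns=[f"s{j}" for j in range(len(counts[0]))])
    lib = pd.Series(libs, index=df.columns, dtype=float)
    lg = None
    if lengths is not None:
        lg = pd.Series(lengths, index=df.index, dtype=float)
    return CountMatrix(df, lib, lg)


class TestFpkm:
    def test_direct_arithmetic(self):
        cm = make_cm([[1000], [0]], [1e6], [1000, 500])
        f = compute_fpkm(cm)
        assert f.iloc[0, 0] == pytest.approx(1000.0)
        assert f.iloc[1, 0] == 0.0

    def test_invariant_to_doubling_count_and_library(self):
        a = make_cm([[100]], [1e6], [2000])
        b = make_cm([[200]], [2e6], [2000])
        assert compute_fpkm(a).iloc[0, 0] == pytest.approx(compute_fpkm(b).iloc[0, 0])

    def test_zero_length_rejected_by_name(self):
        with pytest.raises(ValueError, match="g1"):
            make_cm([[1], [1]], [1e6], [100, 0])


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "fpkm,kept",
        [((1.5, 1.2, 0.0), True),
         ((1.5, 0.8, 0.9), False),
         ((1.0, 1.0, 1.0), False)],  # strict > 1
    )
    def test_rule(self, fpkm, kept):
        df = pd.DataFrame([fpkm], index=["g"], columns=["a", "b", "c"])
        assert ("g" in filter_expressed(df)) is kept


class TestDeg:
    def test_duplicated_columns_no_calls(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, size=100)
        counts = np.column_stack([col] * 4)
        cm = make_cm(counts, [col.sum()] * 4)
        design = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        rec = call_deg(run_deg_test(cm, design, ("a", "b")))
        assert np.allclose(rec["log2fc"], 0)
        assert not rec["is_deg"].any()

    def test_group_swap_negates_log2fc(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(10, 0.1, size=(80, 6))
        cm = make_cm(counts, counts.sum(axis=0))
        design = {f"s{j}": ("a" if j < 3 else "b") for j in range(6)}
        r1 = run_deg_test(cm, design, ("a", "b"))
        r2 = run_deg_test(cm, design, ("b", "a"))
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], atol=1e-10)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)

    def test_all_zero_gene_excluded(self):
        counts = np.vstack([np.zeros(4, dtype=int), np.full(4, 20)])
        cm = make_cm(counts, [100] * 4)
        design = {f"s{j}": ("a" if j < 2 else "b") for j in range(4)}
        rec = run_deg_test(cm, design, ("a", "b"))
        assert list(rec["gene"]) == ["g1"]

    def test_calls_invariant_to_global_library_rescaling(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(10, 0.05, size=(60, 6))
        design = {f"s{j}": ("a" if j < 3 else "b") for j in range(6)}
        cm1 = make_cm(counts, counts.sum(axis=0))
        cm2 = make_cm(counts, counts.sum(axis=0) * 7.0)
        r1 = run_deg_test(cm1, design, ("a", "b"))
        r2 = run_deg_test(cm2, design, ("a", "b"))
        np.testing.assert_allclose(r1["log2fc"], r2["log2fc"], atol=1e-10)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-10)


class TestKmeans:
    def test_k1_centroid_is_column_mean(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 5)))
        _, means = kmeans_programs(m, k=1, n_start=3, seed=0)
        x = m.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        np.testing.assert_allclose(means.iloc[0], z.mean(axis=0), atol=1e-10)

    def test_two_blobs_exact_recovery(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.05, size=(30, 4)) + np.array([1, 1, -1, -1])
        b = rng.normal(0, 0.05, size=(30, 4)) + np.array([-1, -1, 1, 1])
        m = pd.DataFrame(np.vstack([a, b]))
        assign, _ = kmeans_programs(m, k=2, n_start=10, seed=0)
        first, second = assign.iloc[:30], assign.iloc[30:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        a1, _ = kmeans_programs(m, k=3, n_start=5, seed=42)
        a2, _ = kmeans_programs(m, k=3, n_start=5, seed=42)
        pd.testing.assert_series_equal(a1, a2)

    def test_objective_matches_sklearn(self):
        """Best-of-n-start Lloyd reaches the same optimum as sklearn."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(80, 5)))
        _, means = kmeans_programs(m, k=3, n_start=20, seed=0)
        x = m.to_numpy()
        sd = x.std(axis=1, keepdims=True)
        z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        km = sklearn_cluster.KMeans(n_clusters=3, n_init=20, random_state=0,
                                    algorithm="lloyd").fit(z)
        assert means.attrs["objective"] == pytest.approx(km.inertia_, rel=0.02)

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_programs(pd.DataFrame(np.eye(3)), k=5, seed=0)


class TestIgRepertoire:
    def _layout_cm(self, counts_by_class):
        design = SimDesign(seed=21, genotypes=("WT",), celltypes=("A",), n_reps=1,
                           chrom_length=500_000, n_genes=30, n_cpg_sites=200,
                           n_peaks=100)
        layout, _ = generate_genome(design)
        gt = layout.gene_table()
        counts = pd.Series(0, index=gt["gene_id"], dtype=int)
        for cls, value in counts_by_class.items():
            members = gt.loc[gt["ig_class"] == cls, "gene_id"]
            if cls is None:
                members = gt.loc[gt["ig_class"].isna(), "gene_id"]
            counts[members] = value // max(len(members), 1)
        cm = CountMatrix(counts.to_frame("s1"), pd.Series({"s1": 1e6}))
        return layout, cm

    def test_pct_ig_arithmetic(self):
        layout, cm = self._layout_cm({None: 960, "IgM": 40})
        total = cm.counts["s1"].sum()
        ig = ig_repertoire(cm, layout)
        gt = layout.gene_table()
        ig_total = cm.counts.loc[
            gt.set_index("gene_id")["ig_class"].notna().reindex(cm.counts.index).to_numpy(),
            "s1"].sum()
        assert ig["samples"]["s1"]["pct_ig"] == pytest.approx(100 * ig_total / total)

    def test_unswitched_only_gives_zero_switched_fraction(self):
        layout, cm = self._layout_cm({None: 900, "IgM": 80, "IgD": 20})
        ig = ig_repertoire(cm, layout)
        assert ig["samples"]["s1"]["switched_fraction"] == 0.0

    def test_simulated_gcb_switched_fraction_recovered(self):
        """79% class-switched transcripts in the GCB-like state."""
        design = SimDesign(seed=22, genotypes=("WT",), celltypes=("nB", "GCB"),
                           n_reps=3, chrom_length=500_000, n_genes=60,
                           n_cpg_sites=200, n_peaks=100)
        layout, _ = generate_genome(design)
        cm, _ = simulate_expression(layout, design)
        rep = ig_repertoire(cm, layout, design.sample_groups)
        assert rep["groups"]["WT_GCB"]["switched_fraction"] == pytest.approx(0.79, abs=0.02)

    def test_no_ig_genes_is_an_error(self):
        counts = pd.DataFrame({"s1": [5, 5]}, index=["x", "y"])
        cm = CountMatrix(counts, pd.Series({"s1": 10.0}))
        design = SimDesign(seed=23, genotypes=("WT",), celltypes=("A",), n_reps=1,
                           chrom_length=500_000, n_genes=10, ig_genes={},
                           n_cpg_sites=100, n_peaks=50)
        layout, _ = generate_genome(design)
        with pytest.raises(ValueError, match="Ig"):
            ig_repertoire(cm, layout)
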