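"""Integration-statistics contracts: closest-gene annotation against a
brute-force oracle, hypergeometric overlap closed forms, meta-gene mapping
and smoothing, exact-base accessibility, enhancer overlap conventions,
Spearman ties, and PCA variance accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcellomics.core import CutSiteSet
from bcellomics.integrate import (
    accessibility_at_sites,
    annotate_closest_gene,
    correlate_changes,
    dml_deg_overlap,
    enhancer_overlap,
    metagene_methylation,
    pca_summary,
    _tricube_smooth,
)
from conftest import make_random_layout


def brute_closest(layout, pos):
    """O(n*m) oracle: nearest gene-span boundary, ties to smaller id."""
    best = None
    for g in sorted(layout.genes, key=lambda g: g.gene_id):
        s, e = g.start, g.end
        d = 0 if s <= pos < e else (s - pos if pos < s else pos - (e - 1))
        if best is None or d < best[1]:
            best = (g.gene_id, d)
    return best


class TestClosestGene:
    def test_site_inside_gene_distance_zero(self, tiny_layout):
        res = annotate_closest_gene(pd.DataFrame({"chrom": ["chr1"], "pos": [1500]}),
                                    tiny_layout)
        assert res["gene_id"].iloc[0] == "gA"
        assert res["distance"].iloc[0] == 0

    def test_midpoint_tie_goes_to_smaller_gene_id(self, tiny_layout):
        # gA span [1000,2000), gB span [5000,6000): midpoint of the gap
        # between boundaries 1999 and 5000 is 3499.5; 3500 is 1501 from gA's
        # last base and 1500 from gB -> gB.  At 3499 both are 1500 away.
        res = annotate_closest_gene(pd.DataFrame({"chrom": ["chr1"] * 2,
                                                  "pos": [3499, 3500]}), tiny_layout)
        assert list(res["gene_id"]) == ["gA", "gB"]

    def test_sign_follows_gene_orientation(self, tiny_layout):
        # gA is '+': a site left of it is upstream (negative)
        # gB is '-': a site right of its span is upstream (negative)
        res = annotate_closest_gene(pd.DataFrame({"chrom": ["chr1"] * 2,
                                                  "pos": [500, 6500]}), tiny_layout)
        assert res["gene_id"].tolist() == ["gA", "gB"]
        assert res["distance"].iloc[0] < 0
        assert res["distance"].iloc[1] < 0

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(40)
        for _ in range(25):
            layout = make_random_layout(rng)
            pos = rng.integers(0, 50_000, size=40)
            res = annotate_closest_gene(pd.DataFrame({"chrom": "chr1", "pos": pos}),
                                        layout)
            for p, gid, d in zip(pos, res["gene_id"], res["distance"]):
                bg, bd = brute_closest(layout, p)
                assert gid == bg, (p, gid, bg)
                assert abs(d) == bd


class TestOverlap:
    def test_expected_fold_and_tail(self):
        res = dml_deg_overlap([f"g{i}" for i in range(100)],
                              [f"g{i}" for i in range(90, 190)],
                              [f"g{i}" for i in range(1000)])
        assert res.expected == pytest.approx(10.0)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(
            float(stats.hypergeom.sf(9, 1000, 100, 100)), rel=1e-12)
        assert 0.5 < res.p < 0.6

    def test_full_containment_closed_form(self):
        # O = E with E <= D: p = C(D,E)/C(G,E)
        from math import comb
        G, D, E = 40, 12, 5
        res = dml_deg_overlap([f"g{i}" for i in range(D)],
                              [f"g{i}" for i in range(E)],
                              [f"g{i}" for i in range(G)])
        assert res.observed == E
        assert res.p == pytest.approx(comb(D, E) / comb(G, E), rel=1e-9)

    def test_universe_sized_dml_set_gives_p_one(self):
        res = dml_deg_overlap([f"g{i}" for i in range(30)],
                              [f"g{i}" for i in range(7)],
                              [f"g{i}" for i in range(30)])
        assert res.p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            dml_deg_overlap([], [], [])

    def test_permutation_null_is_uniform_and_mean_matches(self):
        """Random DML gene draws: p uniform, mean overlap = D*E/G."""
        rng = np.random.default_rng(41)
        genes = [f"g{i}" for i in range(400)]
        deg = set(rng.choice(genes, size=80, replace=False))
        ps, obs = [], []
        for _ in range(500)[:500]:
            dml = rng.choice(genes, size=60, replace=False)
            r = dml_deg_overlap(dml, deg, genes)
            ps.append(r.p)
            obs.append(r.observed)
        assert np.mean(obs) == pytest.approx(60 * 80 / 400, abs=0.35)
        # discrete conservative p; check no excess of small values
        assert np.mean(np.array(ps) <= 0.05) <= 0.07


class TestMetagene:
    def _flat_input(self, layout, value=0.8):
        pos = np.arange(0, layout.chrom_sizes["chr1"], 37)
        return pd.DataFrame({"chrom": "chr1", "pos": pos, "meth": value})

    def _fpkm(self, layout, rng):
        genes = [g.gene_id for g in layout.genes]
        return pd.DataFrame(rng.lognormal(0, 1, size=(len(genes), 4)), index=genes)

    def test_flat_methylation_gives_flat_profile(self):
        rng = np.random.default_rng(42)
        layout = make_random_layout(rng, n_genes=20, chrom_len=100_000)
        prof = metagene_methylation(self._flat_input(layout), layout,
                                    self._fpkm(layout, rng), flank=2000)
        assert np.allclose(prof["methylation"], 0.8, atol=0.01)

    def test_smoothing_preserves_flat_signal_exactly(self):
        y = np.full(200, 0.37)
        np.testing.assert_allclose(_tricube_smooth(y, 0.1), y, atol=1e-12)

    def test_strand_flip_with_mirrored_data_identical(self):
        """Flipping every gene's strand and mirroring the genome leaves the
        profile unchanged."""
        rng = np.random.default_rng(43)
        layout = make_random_layout(rng, n_genes=15, chrom_len=80_000)
        L = layout.chrom_sizes["chr1"]
        meth = self._flat_input(layout)
        meth["meth"] = rng.uniform(0, 1, size=len(meth))
        fpkm = self._fpkm(layout, rng)
        prof = metagene_methylation(meth, layout, fpkm, flank=2000)
        # mirrored layout: coordinates x -> L-1-x, strands flipped
        from bcellomics.core import Gene, GenomeLayout
        genes_m = []
        for g in layout.genes:
            s, e = L - g.end, L - g.start
            strand = "-" if g.strand == "+" else "+"
            tss, tts = (s, e - 1) if strand == "+" else (e - 1, s)
            genes_m.append(Gene(g.gene_id, "chr1", strand, tss, tts, ((s, e),)))
        layout_m = GenomeLayout(chrom_sizes={"chr1": L}, genes=genes_m,
                                cpg_positions={"chr1": np.array([], dtype=int)})
        meth_m = meth.copy()
        meth_m["pos"] = L - 1 - meth["pos"]
        prof_m = metagene_methylation(meth_m, layout_m, fpkm, flank=2000)
        np.testing.assert_allclose(prof["methylation"], prof_m["methylation"],
                                   atol=1e-9)

    def test_empty_stratum_rejected(self):
        rng = np.random.default_rng(44)
        layout = make_random_layout(rng, n_genes=8, chrom_len=50_000)
        meth = pd.DataFrame({"chrom": ["chr1"], "pos": [0], "meth": [0.5]})
        with pytest.raises(ValueError, match="stratum"):
            metagene_methylation(meth, layout, self._fpkm(layout, rng), flank=100)


class TestAccessibility:
    def make_cuts(self, positions, total=10**6):
        t = pd.DataFrame({"chrom": "chr1", "pos": positions, "strand": "+",
                          "sample": "s1"})
        return CutSiteSet(t, {"s1": total})

    def test_exact_base_rule(self):
        cuts = self.make_cuts([100, 101, 99])
        res = accessibility_at_sites(cuts, pd.DataFrame({"chrom": ["chr1"],
                                                         "pos": [100]}))
        assert res["s1"].iloc[0] == pytest.approx(1.0)  # only the exact base

    def test_per_million_scaling(self):
        cuts = self.make_cuts([100, 100, 100])
        res = accessibility_at_sites(cuts, pd.DataFrame({"chrom": ["chr1"],
                                                         "pos": [100]}))
        assert res["s1"].iloc[0] == pytest.approx(3.0)

    def test_group_difference_detected_at_gained_sites(self):
        """Accessibility gained only in one group at chosen sites shows a
        group ratio >= 2."""
        rng = np.random.default_rng(45)
        sites = np.arange(1000, 21_000, 1000)
        rows = []
        totals = {}
        for s, gained in [("a1", False), ("a2", False), ("b1", True), ("b2", True)]:
            bg = rng.integers(0, 50_000, size=5_000)
            extra = np.repeat(sites, 5) if gained else np.repeat(sites, 1)
            pos = np.concatenate([bg, extra])
            rows.append(pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                                      "sample": s}))
            totals[s] = len(pos)
        cuts = CutSiteSet(pd.concat(rows, ignore_index=True), totals)
        res = accessibility_at_sites(cuts, pd.DataFrame({"chrom": "chr1",
                                                         "pos": sites}),
                                     {"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
        ratio = res["mean_b"].mean() / res["mean_a"].mean()
        assert ratio >= 2.0


class TestEnhancerOverlap:
    def test_boundary_half_open(self):
        enh = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200],
                            "name": ["e"]})
        uni = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [100, 199, 200]})
        dml = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [100, 200]})
        res = enhancer_overlap(dml, uni, enh)
        # 100 inside, 200 outside; non-DML 199 inside
        assert res["table"] == [[1, 1], [1, 0]]

    def test_dml_confined_to_enhancers_strongly_enriched(self):
        rng = np.random.default_rng(46)
        enh = pd.DataFrame({"chrom": "chr1", "start": np.arange(20) * 5_000,
                            "end": np.arange(20) * 5_000 + 1_000,
                            "name": [f"e{i}" for i in range(20)]})
        inside = np.concatenate([rng.integers(s, s + 1000, size=5)
                                 for s in enh["start"]])
        outside = np.array([p for p in rng.integers(0, 100_000, size=2_000)
                            if not ((p % 5_000) < 1_000)])
        uni = pd.DataFrame({"chrom": "chr1",
                            "pos": np.concatenate([inside, outside])})
        dml = pd.DataFrame({"chrom": "chr1", "pos": inside[:60]})
        res = enhancer_overlap(dml, uni, enh)
        assert res["odds_ratio"] == np.inf or res["odds_ratio"] > 10
        assert res["p"] < 1e-6

    def test_empty_enhancers_rejected(self):
        with pytest.raises(ValueError):
            enhancer_overlap(pd.DataFrame({"chrom": [], "pos": []}),
                             pd.DataFrame({"chrom": [], "pos": []}),
                             pd.DataFrame(columns=["chrom", "start", "end", "name"]))


class TestSpearman:
    def test_perfectly_decreasing_is_minus_one(self):
        rho, _ = correlate_changes([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 2.0, 6.0])
        rho, _ = correlate_changes(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_changes([1, 1, 1, 1], [1, 2, 3, 4])

    def test_independent_pairs_usually_uncorrelated(self):
        rng = np.random.default_rng(47)
        hits = 0
        for _ in range(40):
            rho, _ = correlate_changes(rng.normal(size=200), rng.normal(size=200))
            hits += abs(rho) < 0.2
        assert hits >= 38  # >= 95% of runs


class TestPca:
    def test_duplicated_sample_groups_pc1_dominates(self):
        rng = np.random.default_rng(48)
        a = rng.normal(0, 1, size=50)
        m = pd.DataFrame({"a1": a, "a2": a, "b1": a + 5, "b2": a + 5})
        res = pca_summary(m)
        assert res["variance_fraction"][0] == pytest.approx(1.0, abs=1e-9)
        s = res["scores"]
        assert np.sign(s.loc["a1", "PC1"]) != np.sign(s.loc["b1", "PC1"])

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(49)
        m = pd.DataFrame(rng.normal(size=(30, 6)))
        res = pca_summary(m)
        # fractions over all components sum to 1
        assert res["variance_fraction"].sum() == pytest.approx(1.0, abs=1e-8)

    def test_rank_two_matrix_has_two_nonzero_singular_values(self):
        rng = np.random.default_rng(50)
        u = rng.normal(size=(40, 2))
        v = rng.normal(size=(2, 6))
        m = pd.DataFrame(u @ v)
        res = pca_summary(m)
        sv = res["singular_values"]
        assert (sv[2:] < 1e-8 * sv[0]).all()

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_summary(pd.DataFrame(np.ones((5, 3))))
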