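"""Motif-module contracts: scan correctness against a string-matching
oracle, strand symmetry, Fisher's exact test against hypergeometric
enumeration, and the proximity/region enrichment constructions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bcellomics.motif import (
    MotifModel,
    enrich_in_regions,
    enrich_near_dml,
    fisher_exact,
    read_jaspar,
    scan_motifs,
    write_jaspar,
)
from bcellomics.simulate import consensus_pwm, revcomp


def fisher_oracle(a, b, c, d):
    """Two-sided exact p by direct enumeration of tables with fixed
    margins, summing hypergeometric probabilities <= the observed one."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0  # single degenerate table
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestFisher:
    def test_balanced_table(self):
        orat, p = fisher_exact(5, 5, 5, 5)
        assert orat == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation(self):
        orat, p = fisher_exact(10, 0, 0, 10)
        from math import comb
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert orat == np.inf

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        _, p = fisher_exact(a, b, c, d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20))
    def test_transpose_invariance(self, a, b, c, d):
        assert fisher_exact(a, b, c, d)[1] == pytest.approx(
            fisher_exact(a, c, b, d)[1], abs=1e-12)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 2, 3, 4)


class TestScan:
    def brute_hits(self, seq, consensus):
        """String-matching oracle: all occurrences of the consensus or its
        reverse complement."""
        out = set()
        rc = revcomp(consensus)
        for i in range(len(seq) - len(consensus) + 1):
            win = seq[i : i + len(consensus)]
            if win == consensus:
                out.add((i, "+"))
            if win == rc:
                out.add((i, "-"))
        return out

    def test_consensus_window_scores_maximum(self):
        m = MotifModel("m", consensus_pwm("TGACTCA"))
        hits = scan_motifs({"c": "AATGACTCAAA"}, [m])
        assert len(hits) == 1
        assert hits["score"].iloc[0] == pytest.approx(m.max_score)

    def test_hits_match_string_oracle_on_random_sequence(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        consensus = "TGACTCA"
        m = MotifModel("m", consensus_pwm(consensus, match_p=0.997),
                       threshold_frac=0.95)
        hits = scan_motifs({"c": seq}, [m])
        got = set(zip(hits["start"], hits["strand"]))
        assert got == self.brute_hits(seq, consensus)

    def test_reverse_complement_genome_flips_strands(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        m = MotifModel("m", consensus_pwm("ATGCAAAT", match_p=0.997),
                       threshold_frac=0.95)
        fwd = scan_motifs({"c": seq}, [m])
        rev = scan_motifs({"c": revcomp(seq)}, [m])
        L = len(seq)
        mirrored = set(
            (L - row["end"], {"+": "-", "-": "+"}[row["strand"]])
            for _, row in fwd.iterrows()
        )
        assert set(zip(rev["start"], rev["strand"])) == mirrored

    def test_n_bases_skip_windows(self):
        m = MotifModel("m", consensus_pwm("TGACTCA"))
        hits = scan_motifs({"c": "AATGACNCAAATGACTCA"}, [m])
        assert list(hits["start"]) == [11]

    def test_concatenating_unrelated_chromosome_keeps_hits(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        other = "".join(rng.choice(list("ACGT"), size=2_000))
        m = MotifModel("m", consensus_pwm("TGACTCA", match_p=0.997),
                       threshold_frac=0.95)
        one = scan_motifs({"a": seq}, [m])
        two = scan_motifs({"a": seq, "b": other}, [m])
        pd.testing.assert_frame_equal(one, two[two["chrom"] == "a"].reset_index(drop=True))

    def test_jaspar_roundtrip(self, tmp_path):
        models = [MotifModel("AP1", consensus_pwm("TGACTCA")),
                  MotifModel("OCT2", consensus_pwm("ATGCAAAT"))]
        path = tmp_path / "m.jaspar"
        write_jaspar(path, models)
        back = read_jaspar(path)
        assert [m.motif_id for m in back] == ["AP1", "OCT2"]
        np.testing.assert_allclose(back[0].pwm, models[0].pwm, atol=1e-3)


def _sites(positions):
    return pd.DataFrame({"chrom": "chr1", "pos": positions})


class TestEnrichNearDml:
    def test_implanted_motif_maximally_enriched(self):
        rng = np.random.default_rng(20)
        universe = np.sort(rng.choice(100_000, size=2_000, replace=False))
        dml = universe[:40]
        hits = pd.DataFrame({
            "motif_id": "m", "chrom": "chr1",
            "start": dml + 10, "end": dml + 18, "strand": "+",
        })
        res = enrich_near_dml(hits, _sites(dml), _sites(universe), window=50)
        row = res.iloc[0]
        assert row["n_dml_proximal"] == 40
        assert row["odds_ratio"] == np.inf or row["odds_ratio"] > 100
        assert row["p"] < 1e-6
        # hypergeometric oracle for the resulting 2x2 table
        a, b = int(row["n_dml_proximal"]), int(row["n_dml"] - row["n_dml_proximal"])
        c, d = int(row["n_bg_proximal"]), int(row["n_bg"] - row["n_bg_proximal"])
        assert row["p"] == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-6)

    def test_boundary_distance_50_is_proximal(self):
        universe = np.array([1000, 5000])
        dml = np.array([1000])
        # hit occupying [1050, 1058): nearest base at distance 50 -> proximal
        hits = pd.DataFrame({"motif_id": ["m"], "chrom": ["chr1"],
                             "start": [1050], "end": [1058], "strand": ["+"]})
        res = enrich_near_dml(hits, _sites(dml), _sites(universe), window=50)
        assert res["n_dml_proximal"].iloc[0] == 1
        hits51 = hits.assign(start=1051, end=1059)
        res51 = enrich_near_dml(hits51, _sites(dml), _sites(universe), window=50)
        assert res51["n_dml_proximal"].iloc[0] == 0

    def test_empty_dml_rejected(self):
        hits = pd.DataFrame({"motif_id": ["m"], "chrom": ["chr1"],
                             "start": [0], "end": [8], "strand": ["+"]})
        with pytest.raises(ValueError):
            enrich_near_dml(hits, _sites([]), _sites([1, 2]), window=50)


class TestEnrichInRegions:
    def regions(self, n, width=100):
        starts = np.arange(n) * 1_000
        return pd.DataFrame({"chrom": "chr1", "start": starts,
                             "end": starts + width,
                             "name": [f"r{i}" for i in range(n)]})

    def test_motif_confined_to_one_cluster_tops(self):
        all_regions = self.regions(60)
        clusters = {
            5: all_regions.iloc[:20].copy(),
            1: all_regions.iloc[20:40].copy(),
            2: all_regions.iloc[40:].copy(),
        }
        hits = pd.DataFrame({
            "motif_id": "m", "chrom": "chr1",
            "start": clusters[5]["start"] + 50,
            "end": clusters[5]["start"] + 58, "strand": "+",
        })
        res = enrich_in_regions(hits, clusters, all_regions)
        best = res.iloc[0]
        assert best["cluster"] == 5
        assert best["p"] == pytest.approx(
            fisher_oracle(20, 0, 0, 40), abs=1e-12)

    def test_balanced_table_is_null(self):
        all_regions = self.regions(20)
        clusters = {0: all_regions.iloc[:10].copy(), 1: all_regions.iloc[10:].copy()}
        starts = pd.concat([all_regions.iloc[:5]["start"],
                            all_regions.iloc[10:15]["start"]])
        hits = pd.DataFrame({"motif_id": "m", "chrom": "chr1",
                             "start": starts + 10, "end": starts + 18,
                             "strand": "+"})
        res = enrich_in_regions(hits, clusters, all_regions)
        assert np.allclose(res["odds_ratio"], 1.0)
        assert np.allclose(res["p"], 1.0)

    def test_uniform_hits_type_i_control(self):
        """Hits scattered independently of clusters produce no FDR <= 0.05
        enrichment across 1000 regions."""
        rng = np.random.default_rng(30)
        all_regions = self.regions(1000)
        labels = rng.integers(0, 4, size=1000)
        clusters = {int(k): all_regions[labels == k].copy() for k in range(4)}
        chosen = all_regions[rng.random(1000) < 0.3]
        hits = pd.DataFrame({"motif_id": "m", "chrom": "chr1",
                             "start": chosen["start"] + 10,
                             "end": chosen["start"] + 18, "strand": "+"})
        res = enrich_in_regions(hits, clusters, all_regions)
        assert not (res["fdr"] <= 0.05).any()
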