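import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from circaepi.io_formats import GeneModel, IntervalSet
from circaepi.motif_enrich import (
    PWM,
    fisher_enrichment,
    genes_with_motif,
    motif_promoter_windows,
    pwm_scan,
    read_meme_pwms,
    uniquely_enriched,
)


def consensus_pwm(seq="ACGTA", eps=1e-9):
    rows = []
    for base in seq:
        row = np.full(4, eps / 3)
        row["ACGT".index(base)] = 1.0 - eps
        rows.append(row)
    return PWM("consensus", np.array(rows))


class TestMotifWindows:
    def test_plus_strand(self):
        (w,) = motif_promoter_windows([GeneModel("g", "chr1", "+", 5_000)])
        assert (w.start, w.end) == (4_100, 5_100)

    def test_minus_strand_reflected(self):
        (w,) = motif_promoter_windows([GeneModel("g", "chr1", "-", 5_000)])
        assert (w.start, w.end) == (4_900, 5_900)

    def test_clipping(self):
        with pytest.warns(UserWarning, match="clipped"):
            (w,) = motif_promoter_windows([GeneModel("g", "chr1", "+", 100)])
        assert (w.start, w.end) == (0, 200)


class TestGenesWithMotif:
    def test_site_hits_only_its_window(self):
        models = [GeneModel("g1", "chr1", "+", 5_000), GeneModel("g2", "chr1", "+", 9_000)]
        windows = motif_promoter_windows(models)
        sites = IntervalSet.from_records([("chr1", 4_500, 4_510, "m1", 0.0, "+")])
        assert genes_with_motif(sites, windows) == {"m1": {"g1"}}

    def test_site_spanning_two_windows_hits_both(self):
        models = [GeneModel("g1", "chr1", "+", 5_000), GeneModel("g2", "chr1", "+", 6_000)]
        windows = motif_promoter_windows(models)  # [4100,5100) and [5100,6100)
        sites = IntervalSet.from_records([("chr1", 5_095, 5_105, "m1", 0.0, "+")])
        assert genes_with_motif(sites, windows)["m1"] == {"g1", "g2"}

    def test_site_without_motif_id_rejected(self):
        models = [GeneModel("g1", "chr1", "+", 5_000)]
        sites = IntervalSet.from_records([("chr1", 4_500, 4_510)])
        with pytest.raises(ValueError, match="no motif id"):
            genes_with_motif(sites, motif_promoter_windows(models))

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        models = [GeneModel(f"g{i}", "chr1", "+-"[i % 2], 2_000 + 2_000 * i) for i in range(40)]
        windows = motif_promoter_windows(models)
        recs = []
        for i in range(300):
            s = int(rng.integers(0, 85_000))
            recs.append(("chr1", s, s + 10, f"m{i % 5}", 0.0, "+"))
        sites = IntervalSet.from_records(recs)
        fast = genes_with_motif(sites, windows)
        slow: dict = {f"m{i}": set() for i in range(5)}
        for chrom, s, e, name, *_ in recs:
            for w in windows:
                if chrom == w.chrom and s < w.end and e > w.start:
                    slow[name].add(w.gene_id)
        assert fast == slow


def exact_two_sided_p(k, n1, K, N):
    lo, hi = max(0, n1 + K - N), min(n1, K)
    denom = math.comb(N, K)
    pmf = {
        kk: Fraction(math.comb(n1, kk) * math.comb(N - n1, K - kk), denom)
        for kk in range(lo, hi + 1)
    }
    return float(sum(p for p in pmf.values() if p <= pmf[k]))


class TestFisherEnrichment:
    def test_worked_example_matches_tail_enumeration(self):
        """List of 10 in universe of 100; motif hits 8/10 in the list and
        10/90 outside: the two-sided Fisher p equals the exhaustive tail sum."""
        universe = [f"g{i}" for i in range(100)]
        lst = universe[:10]
        hits = set(universe[:8]) | set(universe[10:20])
        out = fisher_enrichment(lst, universe, {"m": hits})
        row = out.iloc[0]
        assert (row["x1"], row["x2"], row["z1"], row["z2"]) == (8, 2, 18, 82)
        assert row["p"] == pytest.approx(exact_two_sided_p(8, 10, 18, 100), abs=1e-12)

    def test_counts_satisfy_marginal_identities(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        lst = list(rng.choice(universe, 40, replace=False))
        sets = {
            f"m{j}": set(rng.choice(universe, rng.integers(1, 150), replace=False))
            for j in range(20)
        }
        out = fisher_enrichment(lst, universe, sets)
        assert ((out["x1"] + out["x2"]) == 40).all()
        assert ((out["z1"] + out["z2"]) == 200).all()
        assert (out["x1"] <= out["z1"]).all() and (out["x2"] <= out["z2"]).all()

    def test_motif_everywhere_is_degenerate(self):
        universe = [f"g{i}" for i in range(50)]
        out = fisher_enrichment(universe[:10], universe, {"m": universe})
        assert out.iloc[0]["p"] == 1.0

    def test_bh_order_matches_p_order(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(300)]
        lst = list(rng.choice(universe, 50, replace=False))
        sets = {
            f"m{j}": set(rng.choice(universe, 60, replace=False)) for j in range(30)
        }
        out = fisher_enrichment(lst, universe, sets)
        by_p = out.sort_values(["p", "motif_id"])["motif_id"]
        by_fdr = out.sort_values(["fdr", "p", "motif_id"])["motif_id"]
        assert list(by_p) == list(by_fdr)

    def test_list_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment(["x"], ["a", "b"], {"m": ["a"]})

    def test_uniquely_enriched(self):
        a = pd.DataFrame({"motif_id": ["m1", "m2"], "fdr": [0.01, 0.2]})
        b = pd.DataFrame({"motif_id": ["m1", "m2"], "fdr": [0.3, 0.01]})
        out = uniquely_enriched(a, b)
        assert out == {"only_a": ["m1"], "only_b": ["m2"]}


class TestPwmScan:
    def test_exact_match_passes_lr_500(self):
        """A width-5 consensus on a uniform background scores ~4^5 = 1024."""
        pwm = consensus_pwm("ACGTA")
        sites = pwm_scan([("s", "TTACGTATT")], pwm)
        fwd = sites.df[sites.df["strand"] == "+"]
        assert len(fwd) == 1
        assert fwd.iloc[0]["start"] == 2 and fwd.iloc[0]["end"] == 7
        assert np.exp(fwd.iloc[0]["score"]) == pytest.approx(1024, rel=1e-4)

    def test_single_mismatch_kills_site(self):
        pwm = consensus_pwm("ACGTA")
        sites = pwm_scan([("s", "TTACGGATT")], pwm)
        assert (sites.df["strand"] == "+").sum() == 0

    def test_reverse_complement_found_on_minus_strand(self):
        pwm = consensus_pwm("ACGTA")
        # revcomp(ACGTA) = TACGT placed at positions 3..8
        sites = pwm_scan([("s", "GGGTACGTGG")], pwm)
        minus = sites.df[sites.df["strand"] == "-"]
        assert len(minus) == 1
        assert (minus.iloc[0]["start"], minus.iloc[0]["end"]) == (3, 8)

    def test_scan_mirror_symmetry(self):
        from Bio.Seq import Seq

        pwm = consensus_pwm("ACGTA")
        seq = "TTACGTATTGGACGTACC"
        fwd_sites = pwm_scan([("s", seq)], pwm).df
        rc_sites = pwm_scan([("s", str(Seq(seq).reverse_complement()))], pwm).df
        n = len(seq)
        mirrored = sorted((n - e, n - s) for s, e in zip(rc_sites["start"], rc_sites["end"]))
        assert mirrored == sorted(zip(fwd_sites["start"], fwd_sites["end"]))

    def test_n_bases_force_no_site(self):
        pwm = consensus_pwm("ACGTA")
        assert len(pwm_scan([("s", "TTACGNATT")], pwm)) == 0

    def test_sequence_shorter_than_motif(self):
        assert len(pwm_scan([("s", "ACG")], consensus_pwm("ACGTA"))) == 0


class TestMemeFormat:
    def test_read_minimal_meme(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF M1\nletter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0\n"
            " 0.90 0.05 0.03 0.02\n 0.05 0.85 0.05 0.05\n 0.10 0.10 0.10 0.70\n"
        )
        p = tmp_path / "m.meme"
        p.write_text(text)
        (pwm,) = read_meme_pwms(p)
        assert pwm.motif_id == "M1"
        assert pwm.width == 3
        np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert pwm.matrix[0, 0] == pytest.approx(0.90, abs=1e-6)
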