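import numpy as np
import pytest
from hypothesis import given, strategies as st

from lck.io_core import GenomicInterval, Peak, ValidationError
from lck.motifs import (
    PWM,
    best_hit_near_center,
    build_pwm,
    default_min_score,
    motif_presence,
    read_meme,
    revcomp,
    scan,
    write_meme,
)

dna = st.text(alphabet="ACGT", min_size=12, max_size=60)


def _peak(chrom="chrS", start=0, end=200, name="p1", summit=100):
    return Peak(GenomicInterval(chrom, start, end), name, summit_offset=summit - start)


class TestBuildPwm:
    def test_unanimous_column_probability_one(self):
        pwm = build_pwm(["CACGTG", "CACGTG"], pseudocount=0.0)
        assert pwm.probs[1, 0] == 1.0  # C in column 0

    def test_pseudocount_formula(self):
        pwm = build_pwm(["AA", "CC"], pseudocount=0.5)
        assert pwm.probs[0, 0] == pytest.approx((1 + 0.5) / (2 + 2))

    def test_positive_pseudocount_gives_positive_probs(self):
        pwm = build_pwm(["ACGT", "TGCA", "AAAA"], pseudocount=0.5)
        assert np.all(pwm.probs > 0)

    def test_non_acgt_character_named(self):
        with pytest.raises(ValidationError, match="position 2"):
            build_pwm(["ACNT", "ACGT"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            build_pwm(["ACG", "ACGT"])


class TestScan:
    def test_background_pwm_scores_zero_everywhere(self):
        pwm = PWM(np.full((4, 4), 0.25))
        assert scan(pwm, "ACGTACGTACGT", min_score=0.1) == []
        hits = scan(pwm, "ACGTACGT", min_score=-0.001)
        assert all(h.score == 0.0 for h in hits)

    def test_consensus_score_matches_hand_sum(self, strict_pwm):
        # hand sum: 6 columns, each log2(p_max / 0.25)
        p_max = (20 + 0.1) / (20 + 0.4)
        expected = 6 * np.log2(p_max / 0.25)
        assert strict_pwm.consensus_score() == pytest.approx(expected)
        hits = scan(strict_pwm, "TT" + "CACGTG" + "TT", min_score=0.0)
        assert hits[0].score == pytest.approx(expected)
        assert hits[0].start == 2

    def test_palindrome_collapses_to_plus_strand(self, strict_pwm):
        hits = scan(strict_pwm, "AACACGTGAA", min_score=default_min_score(strict_pwm))
        assert len(hits) == 1 and hits[0].strand == "+"

    def test_minus_strand_hit_found(self):
        pwm = build_pwm(["TGACTCAT"] * 20, pseudocount=0.1)
        seq = "GG" + revcomp("TGACTCAT") + "GG"
        hits = scan(pwm, seq, min_score=default_min_score(pwm))
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].start == 2

    @given(dna)
    def test_strand_symmetry(self, seq):
        pwm = build_pwm(["ACGTGA", "ACGTGA", "ACCTGA"], pseudocount=0.5)
        fwd = sorted(round(h.score, 9) for h in scan(pwm, seq, min_score=-100))
        rev = sorted(round(h.score, 9) for h in scan(pwm, revcomp(seq), min_score=-100))
        assert fwd == rev

    def test_nested_thresholds_give_nested_hit_sets(self, rng):
        pwm = build_pwm(["ACGTGA", "ACGTGA", "ACCTGA"], pseudocount=0.5)
        seq = "".join(rng.choice(list("ACGT"), 300))
        keys = lambda hits: {(h.start, h.strand) for h in hits}
        lo = keys(scan(pwm, seq, min_score=-2))
        mid = keys(scan(pwm, seq, min_score=0))
        hi = keys(scan(pwm, seq, min_score=2))
        assert hi <= mid <= lo


class TestBestHitNearCenter:
    def test_planted_consensus_at_summit(self, strict_pwm):
        seq = "A" * 97 + "CACGTG" + "A" * 97
        peak = _peak(end=len(seq), summit=100)
        hit = best_hit_near_center(strict_pwm, peak, {"chrS": seq})
        assert hit is not None
        assert hit.offset == 0  # midpoint at the summit
        assert hit.score == pytest.approx(strict_pwm.consensus_score())

    def test_site_outside_window_is_none(self, strict_pwm):
        seq = "A" * 157 + "CACGTG" + "A" * 97  # midpoint 60 bp past summit
        peak = _peak(end=len(seq), summit=100)
        assert best_hit_near_center(strict_pwm, peak, {"chrS": seq}, window=50) is None

    def test_equal_score_tie_prefers_smaller_offset(self, strict_pwm):
        # sites at offsets -30 and +10 from the summit
        seq = list("A" * 200)
        seq[100 - 30 - 3 : 100 - 30 + 3] = "CACGTG"
        seq[100 + 10 - 3 : 100 + 10 + 3] = "CACGTG"
        hit = best_hit_near_center(strict_pwm, _peak(summit=100), {"chrS": "".join(seq)})
        assert hit.offset == 10

    def test_invariant_to_peak_padding_beyond_window(self, strict_pwm):
        seq = "G" * 300 + "CACGTG" + "G" * 300
        narrow = Peak(GenomicInterval("chrS", 250, 356), "p", summit_offset=53)
        wide = Peak(GenomicInterval("chrS", 0, 606), "p", summit_offset=303)
        h1 = best_hit_near_center(strict_pwm, narrow, {"chrS": seq})
        h2 = best_hit_near_center(strict_pwm, wide, {"chrS": seq})
        assert (h1.offset, h1.score) == (h2.offset, h2.score)


class TestMotifPresence:
    def test_planted_consensus_fraction_one(self, strict_pwm):
        seq = ("T" * 97 + "CACGTG" + "T" * 97) * 3
        peaks = [_peak(start=200 * i, end=200 * (i + 1), name=f"p{i}",
                       summit=200 * i + 100) for i in range(3)]
        res = motif_presence({"planted": peaks}, strict_pwm, {"chrS": seq})
        assert res.loc[0, "fraction_with_motif"] == 1.0

    def test_background_fraction_matches_string_search_oracle(self, strict_pwm, rng):
        """Dual route: PWM best-hit presence at consensus threshold must agree
        with a direct string search for CACGTG (palindromic) under the same
        midpoint-within-window geometry."""
        n, plen, window = 300, 200, 50
        seq = "".join(rng.choice(list("ACGT"), n * plen))
        peaks = [_peak(start=plen * i, end=plen * (i + 1), name=f"p{i}",
                       summit=plen * i + plen // 2) for i in range(n)]
        res = motif_presence({"bg": peaks}, strict_pwm, {"chrS": seq}, window=window,
                             min_score=strict_pwm.consensus_score() - 1e-9)
        expected = 0
        for p in peaks:
            found = False
            for s in range(p.summit - window - 3, p.summit + window):
                if seq[s : s + 6] == "CACGTG" and abs(s + 3 - p.summit) <= window:
                    found = True
            expected += found
        assert res.loc[0, "n_with_motif"] == expected

    def test_degenerate_sites_score_below_perfect_sites(self, strict_pwm, rng):
        def make(peaks_sites, offset):
            seqs = []
            for site in peaks_sites:
                s = list(rng.choice(list("ACGT"), 200))
                s[100 - 3 : 100 + 3] = site
                seqs.append("".join(s))
            return "".join(seqs)

        perfect = ["CACGTG"] * 40
        mismatched = ["AACGTG", "CACGTA", "CTCGTG", "CACTTG"] * 10
        seq = make(perfect, 0) + make(mismatched, 0)
        peaks_b = [_peak(start=200 * i, end=200 * (i + 1), name=f"b{i}",
                         summit=200 * i + 100) for i in range(40)]
        peaks_a = [_peak(start=8000 + 200 * i, end=8000 + 200 * (i + 1), name=f"a{i}",
                         summit=8000 + 200 * i + 100) for i in range(40)]
        res = motif_presence({"perfect": peaks_b, "degenerate": peaks_a},
                             strict_pwm, {"chrS": seq},
                             min_score=0.3 * strict_pwm.consensus_score())
        r = res.set_index("subset")
        assert r.loc["degenerate", "mean_best_score"] < r.loc["perfect", "mean_best_score"]
        assert r.loc["degenerate", "fraction_with_motif"] <= r.loc["perfect", "fraction_with_motif"]

    def test_overlapping_subsets_rejected(self, strict_pwm):
        p = _peak()
        with pytest.raises(ValidationError):
            motif_presence({"a": [p], "b": [p]}, strict_pwm, {"chrS": "A" * 200})

    def test_empty_subset_reports_na(self, strict_pwm):
        res = motif_presence({"empty": []}, strict_pwm, {"chrS": "A" * 200})
        assert np.isnan(res.loc[0, "fraction_with_motif"])


class TestMemeIO:
    def test_round_trip(self, tmp_path, strict_pwm):
        other = build_pwm(["TGACTCAT"] * 20, pseudocount=0.1, name="BOXB")
        path = tmp_path / "m.meme"
        write_meme([strict_pwm, other], path)
        back = read_meme(path)
        assert [p.name for p in back] == ["GBOX", "BOXB"]
        np.testing.assert_allclose(back[0].probs, strict_pwm.probs, atol=1e-6)
        np.testing.assert_allclose(back[1].probs, other.probs, atol=1e-6)
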