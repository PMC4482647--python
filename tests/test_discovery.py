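"""Word enrichment statistics, PFM extension and redundancy collapsing."""

import math

import numpy as np
import pytest

from dhnscan import (
    bh_qvalues,
    collapse_redundant,
    enrich_words,
    extend_to_pfm,
    make_promoter_sets,
    promoters_containing,
    reverse_complement,
)
from dhnscan.discovery import MotifModel, binomial_upper_tail, canonical_word


def seqs_of(records):
    return [str(r.seq) for r in records]


class TestPromotersContaining:
    def test_planted_in_all(self):
        fg, _, _ = make_promoter_sets(10, 0, "CCGACGTA", 1.0, 0.0, seed=1)
        assert promoters_containing("CCGACGTA", seqs_of(fg)) == 10

    def test_reverse_complement_counted(self):
        assert promoters_containing("CCGAC", ["AAAGTCGGAAA"]) == 1
        assert promoters_containing("CCGAC", ["AAAGTCGGAAA"], both_strands=False) == 0

    def test_promoter_counts_once(self):
        assert promoters_containing("CCGAC", ["CCGACTTCCGACTTGTCGG"]) == 1

    def test_matches_brute_force_on_synthetic_truth(self):
        fg, _, truth = make_promoter_sets(60, 0, "GATAAGC", 0.5, 0.0, seed=2)
        seqs = seqs_of(fg)
        word, rc = "GATAAGC", reverse_complement("GATAAGC")
        brute = sum(1 for s in seqs if word in s or rc in s)
        assert promoters_containing(word, seqs) == brute
        assert brute >= len(truth.planted_motifs)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            promoters_containing("CCGAC", [])


class TestEnrichmentStatistics:
    def test_binomial_tail_matches_summation_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(2, 60))
            obs = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.6))
            oracle = sum(
                math.comb(n, k) * p0**k * (1 - p0) ** (n - k)
                for k in range(obs, n + 1)
            )
            assert binomial_upper_tail(obs, n, p0) == pytest.approx(oracle, abs=1e-12)

    def test_tail_probability_monotone_in_observation(self):
        for obs in range(0, 50):
            assert binomial_upper_tail(obs + 1, 50, 0.2) <= binomial_upper_tail(
                obs, 50, 0.2
            )

    def test_bh_matches_brute_force_oracle(self):
        def bh_oracle(ps):
            m = len(ps)
            order = sorted(range(m), key=lambda i: ps[i])
            q = [0.0] * m
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * m / rank)
                q[i] = running
            return q

        rng = np.random.default_rng(5)
        for size in (1, 2, 10, 500, 1000):
            ps = rng.uniform(size=size) ** 2
            assert bh_qvalues(ps) == pytest.approx(bh_oracle(list(ps)), abs=1e-12)

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        ps = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(ps, method="fdr_bh")
        assert bh_qvalues(ps) == pytest.approx(q_ref, abs=1e-12)


class TestEnrichWords:
    def test_planted_word_dominates(self):
        fg, bg, _ = make_promoter_sets(100, 1000, "ACCGACA", 0.9, 0.1, seed=7)
        motifs = enrich_words(seqs_of(fg), seqs_of(bg))
        assert motifs, "planted 7-mer must be discovered"
        top = motifs[0]
        assert canonical_word("ACCGACA") in (top.seed_word, reverse_complement(top.seed_word))
        assert top.q_value <= 1e-10

    def test_null_foreground_rarely_discovers(self):
        """Foreground drawn from the same null as the background passes the
        q-gate in at most 1 of 20 seeded replicates."""
        false_runs = 0
        for rep in range(20):
            fg, bg, _ = make_promoter_sets(
                50, 300, "ACCGACA", 0.0, 0.0, length=500, seed=500 + rep
            )
            if enrich_words(seqs_of(fg), seqs_of(bg), k_min=6, k_max=8):
                false_runs += 1
        assert false_runs <= 1

    def test_strand_symmetry(self):
        """Reverse-complementing every promoter leaves the discovered word
        set invariant up to reverse complement."""
        fg, bg, _ = make_promoter_sets(60, 400, "GGATCCA", 0.9, 0.05, seed=8)
        fgs, bgs = seqs_of(fg), seqs_of(bg)
        direct = {m.seed_word for m in enrich_words(fgs, bgs, 6, 8)}
        flipped = {
            m.seed_word
            for m in enrich_words(
                [reverse_complement(s) for s in fgs],
                [reverse_complement(s) for s in bgs],
                6,
                8,
            )
        }
        assert direct == {canonical_word(w) for w in flipped}

    def test_small_foreground_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            enrich_words(["ACGTACGT"], ["ACGTACGT"] * 5)


class TestExtendToPfm:
    def test_identical_occurrences_give_point_masses(self):
        promoters = ["TTGATAAGCAA"] * 5
        motif = extend_to_pfm("GATAAGC", promoters, flank=2)
        assert motif.n_with == 5
        assert motif.consensus_iupac == "TTGATAAGCAA"
        assert np.allclose(motif.pfm.frequencies.max(axis=1), 1.0)

    def test_minus_strand_plants_match_plus_strand_pfm(self):
        plus = ["TTGATAAGCAA"] * 5
        minus = [reverse_complement(s) for s in plus]
        pfm_plus = extend_to_pfm("GATAAGC", plus).pfm
        pfm_minus = extend_to_pfm("GATAAGC", minus).pfm
        assert np.allclose(pfm_plus.counts, pfm_minus.counts)

    def test_random_flanks_keep_core_sharp(self):
        fg, _, _ = make_promoter_sets(200, 0, "GATAAGC", 1.0, 0.0, seed=9)
        motif = extend_to_pfm("GATAAGC", seqs_of(fg), flank=2)
        freq = motif.pfm.frequencies
        assert np.all(freq[2:9].max(axis=1) > 0.95)  # core columns
        assert np.all(freq[[0, 1, 9, 10]].max(axis=1) < 0.5)  # flank columns

    def test_edge_occurrences_padded_not_counted(self):
        # the occurrence sits at the promoter start: the left flank columns
        # have no observations and are dropped
        motif = extend_to_pfm("GATAAGC", ["GATAAGCTT"], flank=2)
        assert motif.consensus_iupac == "GATAAGCTT"

    def test_absent_word_rejected(self):
        with pytest.raises(ValueError, match="no occurrence"):
            extend_to_pfm("GATAAGC", ["TTTTTTTTTT"])


class TestCollapseRedundant:
    def mk(self, word, q):
        return MotifModel(word, 5, 10, 1, 100, q, q)

    def test_substring_collapses(self):
        kept = collapse_redundant([self.mk("CCGAC", 1e-8), self.mk("CCGACG", 1e-4)])
        assert [m.seed_word for m in kept] == ["CCGAC"]

    def test_disjoint_words_both_kept(self):
        kept = collapse_redundant([self.mk("AAAAAA", 1e-8), self.mk("CCCGGG", 1e-4)])
        assert len(kept) == 2

    def test_reverse_complement_overlap_collapses(self):
        kept = collapse_redundant([self.mk("ACGTG", 1e-8), self.mk("CACGT", 1e-4)])
        assert [m.seed_word for m in kept] == ["ACGTG"]

    def test_shifted_overlap_collapses(self):
        kept = collapse_redundant([self.mk("ACGTGCA", 1e-8), self.mk("CGTGCAT", 1e-4)])
        assert [m.seed_word for m in kept] == ["ACGTGCA"]
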