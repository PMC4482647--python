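"""PFM scanning, S-run detection and the iterative seed-expansion search."""

import math

import numpy as np
import pytest

from dhnscan.pfm import AA_ALPHABET
from dhnscan.segments import (
    K_SEGMENT_CONSENSUS,
    UNIFORM_AA_BACKGROUND,
    build_pfm,
    find_s_segments,
    iterative_expand,
    log_odds_score,
    scan_sequence,
)


class TestLogOdds:
    def test_single_symbol_uniform_background(self):
        pfm = build_pfm(["K"], 0.0)
        score = log_odds_score(pfm, "K", {aa: 0.05 for aa in AA_ALPHABET})
        assert score == pytest.approx(math.log2(20), abs=1e-12)

    def test_argmax_word_is_maximum(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            seeds = ["".join(rng.choice(list(AA_ALPHABET), 6)) for _ in range(4)]
            pfm = build_pfm(seeds, 0.5)
            best = pfm.argmax_word()
            best_score = log_odds_score(pfm, best)
            assert best_score == pytest.approx(pfm.max_score(UNIFORM_AA_BACKGROUND))
            for _ in range(20):
                word = "".join(rng.choice(list(AA_ALPHABET), 6))
                assert log_odds_score(pfm, word) <= best_score + 1e-9

    def test_symmetric_columns_score_equally(self):
        pfm = build_pfm(["AC", "CA"], 0.0)
        assert log_odds_score(pfm, "AC") == pytest.approx(log_odds_score(pfm, "CA"))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            log_odds_score(build_pfm(["KK"], 0.0), "K")

    def test_zero_background_rejected(self):
        bad = {aa: 0.0 for aa in AA_ALPHABET}
        bad["K"] = 1.0
        with pytest.raises(ValueError, match="positive"):
            log_odds_score(build_pfm(["K"], 0.0), "K", bad)


class TestScanSequence:
    def test_embedded_consensus_found_at_offset(self):
        pfm = build_pfm([K_SEGMENT_CONSENSUS], 0.5, kind_tag="K")
        protein = "M" * 10 + K_SEGMENT_CONSENSUS + "M" * 10
        hits = scan_sequence(pfm, protein, 0.8)
        assert any(h.start == 10 and h.relative_score == pytest.approx(1.0) for h in hits)

    def test_unrelated_sequence_has_no_hits(self):
        pfm = build_pfm([K_SEGMENT_CONSENSUS], 0.5)
        assert scan_sequence(pfm, "WWWWCWWWWCWWWWCWWWWC", 0.8) == []

    def test_short_protein_returns_empty(self):
        pfm = build_pfm([K_SEGMENT_CONSENSUS], 0.5)
        assert scan_sequence(pfm, "MKV", 0.5) == []

    def test_matches_brute_force_oracle(self):
        """Exhaustive per-window scoring on short sequences."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            seeds = ["".join(rng.choice(list(AA_ALPHABET), 5)) for _ in range(3)]
            pfm = build_pfm(seeds, 0.5)
            protein = "".join(rng.choice(list(AA_ALPHABET), 50))
            lo_max = pfm.max_score(UNIFORM_AA_BACKGROUND)
            lo_min = pfm.min_score(UNIFORM_AA_BACKGROUND)
            threshold = 0.6
            expected = []
            for i in range(len(protein) - 4):
                s = log_odds_score(pfm, protein[i : i + 5])
                rel = (s - lo_min) / (lo_max - lo_min)
                if rel >= threshold - 1e-12:
                    expected.append((i, pytest.approx(s)))
            hits = scan_sequence(pfm, protein, threshold)
            assert [(h.start, h.score) for h in hits] == [
                (i, s) for i, s in expected
            ]

    def test_spacer_shifts_hits(self):
        pfm = build_pfm([K_SEGMENT_CONSENSUS], 0.5)
        protein = "M" * 5 + K_SEGMENT_CONSENSUS + "M" * 5
        spacer = "W" * 13
        original = scan_sequence(pfm, protein, 0.7)
        shifted = scan_sequence(pfm, spacer + protein, 0.7)
        shifted_starts = {h.start for h in shifted}
        for h in original:
            assert h.start + len(spacer) in shifted_starts


class TestFindSSegments:
    @pytest.mark.parametrize(
        "protein, expected",
        [
            ("KKSSSSDD", [(2, 6)]),
            ("SSS", [(0, 3)]),
            ("SSKSS", []),
            ("SSSKSSSS", [(0, 3), (4, 8)]),
        ],
    )
    def test_maximal_runs(self, protein, expected):
        hits = find_s_segments(protein, 3)
        assert [(h.start, h.end) for h in hits] == expected
        assert all(h.kind == "S" and h.score == h.length for h in hits)

    def test_min_run_validation(self):
        with pytest.raises(ValueError, match="min_run"):
            find_s_segments("SSS", 0)


class TestIterativeExpand:
    def test_consensus_only_proteome_converges_immediately(self):
        proteome = {f"p{i}": "M" * 5 + K_SEGMENT_CONSENSUS + "M" * 5 for i in range(3)}
        _, hits, rounds = iterative_expand([K_SEGMENT_CONSENSUS], proteome)
        assert rounds == [0]
        assert len(hits) == 3

    def test_hit_set_grows_monotonically(self, standard_proteome):
        proteome, _ = standard_proteome
        pfm0 = build_pfm([K_SEGMENT_CONSENSUS], 0.5)
        round1 = set()
        for sid, seq in proteome.items():
            for h in scan_sequence(pfm0, seq, 0.7, sequence_id=sid):
                round1.add((sid, h.start))
        _, final, _ = iterative_expand([K_SEGMENT_CONSENSUS], proteome)
        final_keys = {(h.sequence_id, h.start) for h in final}
        assert round1 <= final_keys

    def test_deterministic(self, standard_proteome):
        proteome, _ = standard_proteome
        pfm_a, _, rounds_a = iterative_expand([K_SEGMENT_CONSENSUS], proteome)
        pfm_b, _, rounds_b = iterative_expand([K_SEGMENT_CONSENSUS], proteome)
        assert rounds_a == rounds_b
        assert np.array_equal(pfm_a.counts, pfm_b.counts)

    def test_planted_k_segment_recall(self, standard_proteome):
        """At substitution rate 0.1 and threshold 0.7, at least 95% of
        planted K-segments are recovered."""
        proteome, truth = standard_proteome
        _, hits, _ = iterative_expand([K_SEGMENT_CONSENSUS], proteome, 0.7)
        found = {(h.sequence_id, h.start) for h in hits}
        total = recovered = 0
        for planted in truth.planted_dehydrins:
            for kind, (start, _) in zip(planted.kinds, planted.intervals):
                if kind == "K":
                    total += 1
                    recovered += (planted.sequence_id, start) in found
        assert recovered / total >= 0.95

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty proteome"):
            iterative_expand([K_SEGMENT_CONSENSUS], {})
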