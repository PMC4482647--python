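"""Synthetic-data generators: determinism, planted truth, composition."""

import numpy as np
import pytest
from scipy import stats

from dhnscan import (
    classify_kinds,
    gravy,
    make_genome_with_genes,
    make_promoter_sets,
    make_proteome,
)
from dhnscan.segments import K_SEGMENT_CONSENSUS
from dhnscan.simulate import SegmentSpec, records_to_fasta


class TestMakeProteome:
    def test_zero_mutation_plants_exact_consensus(self):
        records, truth = make_proteome(0, {"K_n": 1}, 0.0, seed=1)
        seq = str(records[0].seq)
        planted = truth.planted_dehydrins[0]
        for kind, (start, end) in zip(planted.kinds, planted.intervals):
            if kind == "K":
                assert seq[start:end] == K_SEGMENT_CONSENSUS

    def test_class_order_is_canonical(self):
        _, truth = make_proteome(0, {"Y_nSK_n": 5}, 0.1, seed=2)
        for planted in truth.planted_dehydrins:
            kinds = "".join(planted.kinds)
            assert kinds == "".join(sorted(kinds, key="YSK".index))

    def test_record_counts_and_byte_determinism(self):
        mix = {"K_n": 10, "KS": 10, "SK_n": 10, "Y_nK_n": 10, "Y_nSK_n": 10}
        a_records, a_truth = make_proteome(200, mix, 0.1, seed=7)
        b_records, b_truth = make_proteome(200, mix, 0.1, seed=7)
        assert len(a_records) == 250
        assert len(a_truth.planted_dehydrins) == 50
        assert records_to_fasta(a_records) == records_to_fasta(b_records)
        assert a_truth.to_json() == b_truth.to_json()

    def test_truth_consistent_with_class_grammar(self):
        mix = {"K_n": 3, "KS": 3, "SK_n": 3, "Y_nK_n": 3, "Y_nSK_n": 3}
        _, truth = make_proteome(0, mix, 0.0, seed=3)
        for planted in truth.planted_dehydrins:
            assert classify_kinds("".join(planted.kinds)) == planted.class_label

    def test_composition_contrast_direction(self):
        records, truth = make_proteome(40, {"SK_n": 40}, 0.1, seed=5)
        planted_ids = {d.sequence_id for d in truth.planted_dehydrins}
        dhn = [gravy(str(r.seq)) for r in records if r.id in planted_ids]
        bg = [gravy(str(r.seq)) for r in records if r.id not in planted_ids]
        assert len(dhn) >= 30 and len(bg) >= 30
        assert np.mean(dhn) < np.mean(bg)

    @pytest.mark.parametrize(
        "kwargs, err",
        [
            (dict(n_background=0, class_mix={"Z_n": 1}), "unknown class"),
            (dict(n_background=0, class_mix={"K_n": 1}, substitution_rate=0.5), "substitution_rate"),
            (dict(n_background=0, class_mix={}), "at least one"),
            (dict(n_background=-1, class_mix={"K_n": 1}), ">= 0"),
        ],
    )
    def test_input_validation(self, kwargs, err):
        with pytest.raises(ValueError, match=err):
            make_proteome(seed=0, **kwargs)


class TestSegmentSpec:
    def test_valid(self):
        SegmentSpec("K", K_SEGMENT_CONSENSUS, 0.1)
        SegmentSpec("S", "SSSSS", 0.0)

    @pytest.mark.parametrize(
        "args", [("K", "", 0.0), ("K", "AB1", 0.0), ("K", "KKK", 0.5), ("S", "SS", 0.0)]
    )
    def test_invalid(self, args):
        with pytest.raises(ValueError):
            SegmentSpec(*args)


class TestMakeGenome:
    def test_no_near_edge_genes_have_full_upstream(self):
        _, _, truth = make_genome_with_genes(20, near_edge_fraction=0.0, seed=1)
        assert all(g.upstream_available >= 1000 for g in truth.planted_genes)

    def test_all_near_edge_genes_truncated(self):
        _, _, truth = make_genome_with_genes(8, near_edge_fraction=1.0, seed=2)
        assert all(g.upstream_available < 1000 for g in truth.planted_genes)

    def test_minus_strand_upstream_arithmetic(self):
        records, _, truth = make_genome_with_genes(30, near_edge_fraction=0.5, seed=3)
        lengths = {r.id: len(r.seq) for r in records}
        for g in truth.planted_genes:
            if g.strand == "-":
                assert g.upstream_available == lengths[g.contig_id] - 1 - g.tss
            else:
                assert g.upstream_available == g.tss

    def test_both_strands_used(self):
        _, _, truth = make_genome_with_genes(30, seed=4)
        strands = {g.strand for g in truth.planted_genes}
        assert strands == {"+", "-"}

    def test_gff_is_one_based_inclusive(self):
        records, gff, truth = make_genome_with_genes(5, seed=5)
        genome = {r.id: str(r.seq) for r in records}
        for line in gff.splitlines():
            if line.startswith("#"):
                continue
            contig, _, ftype, start, end = line.split("\t")[:5]
            assert 1 <= int(start) <= int(end) <= len(genome[contig])

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            make_genome_with_genes(0)


class TestMakePromoterSets:
    def test_certain_planting(self):
        fg, _, truth = make_promoter_sets(10, 0, "CCGAC", 1.0, 0.0, seed=1)
        assert len(truth.planted_motifs) == 10
        planted_ids = {m.promoter_id for m in truth.planted_motifs}
        assert planted_ids == {r.id for r in fg}

    def test_planted_words_present_at_truth_coordinates(self):
        from dhnscan import reverse_complement

        fg, _, truth = make_promoter_sets(50, 0, "GATAAG", 0.9, 0.0, seed=2)
        seqs = {r.id: str(r.seq) for r in fg}
        for m in truth.planted_motifs:
            window = seqs[m.promoter_id][m.start : m.start + len(m.word)]
            expected = m.word if m.strand == "+" else reverse_complement(m.word)
            assert window == expected

    def test_background_plant_count_within_binomial_range(self):
        _, bg, truth = make_promoter_sets(0, 1000, "CCGAC", 0.1, 0.1, seed=3)
        n_planted = len(truth.planted_motifs)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 1000, 0.1)
        assert lo <= n_planted <= hi

    def test_reproducible(self):
        a = make_promoter_sets(100, 0, "CCGAC", 0.9, 0.0, seed=4)
        b = make_promoter_sets(100, 0, "CCGAC", 0.9, 0.0, seed=4)
        assert records_to_fasta(a[0]) == records_to_fasta(b[0])
        assert len(a[2].planted_motifs) == len(b[2].planted_motifs)

    @pytest.mark.parametrize(
        "kwargs, err",
        [
            (dict(word="CCGAX"), "A/C/G/T"),
            (dict(word="A" * 2000), "longer"),
            (dict(word="CCGAC", p_fg=0.1, p_bg=0.5), "p_bg <= p_fg"),
        ],
    )
    def test_input_validation(self, kwargs, err):
        defaults = dict(n_fg=5, n_bg=5, word="CCGAC", p_fg=0.9, p_bg=0.1, seed=0)
        defaults.update(kwargs)
        with pytest.raises(ValueError, match=err):
            make_promoter_sets(**defaults)
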