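"""Circular-genome feature arithmetic and composition statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoforge.annostats import (
    FeatureError,
    FeatureRecord,
    FeatureTable,
    circular_gap,
    composition,
    feature_length,
    gc_percent_from_counts,
    intergenic_spacer,
    load_km023192_features,
    read_feature_tsv,
    read_gff3,
    spacer_table,
    terminal_codons,
    write_feature_tsv,
    write_gff3,
)
from mitoforge.seqcore import revcomp

from conftest import random_dna


def F(name, start, end, strand="H", ftype="other"):
    return FeatureRecord(name=name, start=start, end=end, strand=strand, ftype=ftype)


class TestFeatureLength:
    @pytest.mark.parametrize(
        "start,end,length",
        [(12_326, 14_137, 1_812), (538, 609, 72), (5, 5, 1)],
    )
    def test_inclusive_length(self, start, end, length):
        assert feature_length(F("x", start, end)) == length

    def test_invalid_coordinates(self):
        with pytest.raises(FeatureError):
            F("x", 10, 5)
        with pytest.raises(FeatureError):
            F("x", 0, 5)


class TestSpacers:
    def test_overlap_is_negative(self):
        # ATP8 / ATP6: a 46 bp same-strand overlap
        assert intergenic_spacer(F("ATP8", 8_355, 8_561), F("ATP6", 8_516, 9_196)) == -46

    def test_gap_is_positive(self):
        # the light-strand replication origin between tRNA-Asn and tRNA-Cys
        assert intergenic_spacer(F("N", 5_610, 5_682, "L"), F("C", 5_715, 5_783, "L")) == 32

    def test_abutting_is_zero(self):
        assert intergenic_spacer(F("a", 1, 10), F("b", 11, 20)) == 0

    def test_order_enforced(self):
        with pytest.raises(FeatureError):
            intergenic_spacer(F("b", 11, 20), F("a", 1, 10))

    @given(st.data())
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_with_lengths(self, data):
        """spacer(a,b) + len(a) + len(b) == b.end - a.start + 1."""
        a_start = data.draw(st.integers(1, 500))
        a_end = data.draw(st.integers(a_start, 600))
        b_start = data.draw(st.integers(a_start, 700))
        b_end = data.draw(st.integers(b_start, 800))
        a, b = F("a", a_start, a_end), F("b", b_start, b_end)
        assert (
            intergenic_spacer(a, b) + feature_length(a) + feature_length(b)
            == b.end - a.start + 1
        )


class TestCircularGap:
    def test_control_region_wrap(self):
        # tRNA-Pro ends 16,012; tRNA-Phe starts 538 on a 16,563 bp circle
        assert circular_gap(F("Pro", 15_945, 16_012, "L"), F("Phe", 538, 609), 16_563) == 1_088

    def test_abutting_across_origin(self):
        assert circular_gap(F("a", 90, 100), F("b", 1, 10), 100) == 0

    def test_hand_counted_wrap(self):
        L = 1000
        assert circular_gap(F("a", 1, L - 5), F("b", 6, 10), L) == 10

    def test_coordinates_beyond_genome(self):
        with pytest.raises(FeatureError):
            circular_gap(F("a", 1, 200), F("b", 1, 10), 100)


class TestSpacerTable:
    def test_published_coordinates_reproduce_spacer_column(self):
        """Spacers computed from the published coordinates match the printed
        values, including the overlaps and the control-region wrap."""
        table = load_km023192_features()
        spacers = dict(spacer_table(table))
        expected = {
            "tRNA-Ile": -3, "COX1": -28, "ND4L": -7, "COX2": 73,
            "ATP8": -46, "ATP6": -1, "tRNA-Asn": 32, "tRNA-Trp": 7,
            "tRNA-Leu(L2)": 2, "tRNA-Tyr": 4, "tRNA-Glu": 4,
            "ND1": 0, "ND5": 0, "tRNA-Pro": 1_088,
        }
        for name, value in expected.items():
            assert spacers[name] == value, name

    def test_single_feature_only_wrap(self):
        t = FeatureTable(genome_length=100, records=[F("solo", 10, 20)])
        assert spacer_table(t) == [("solo", 89)]

    def test_brute_force_occupancy_oracle(self, rng):
        """Random non-nested tables: spacer == unoccupied bases strictly
        between consecutive features, counted position by position."""
        for _ in range(20):
            genome_length = 500
            starts = sorted(rng.choice(np.arange(1, 480), size=5, replace=False).tolist())
            records = []
            for i, s in enumerate(starts):
                e = int(min(genome_length, s + int(rng.integers(1, 30))))
                records.append(F(f"f{i}", int(s), e))
            table = FeatureTable(genome_length=genome_length, records=records, circular=False)
            recs = table.records
            for (name, spacer), a, b in zip(spacer_table(table), recs, recs[1:]):
                if spacer >= 0:
                    between = [p for p in range(1, genome_length + 1) if a.end < p < b.start]
                    assert spacer == len(between)
                else:
                    overlap = [p for p in range(1, genome_length + 1)
                               if b.start <= p <= a.end]
                    assert -spacer == len(overlap)


class TestComposition:
    def test_published_control_region_gc(self):
        assert gc_percent_from_counts(a=316, c=340, g=142, t=290) == 44.30

    def test_homopolymer(self):
        stats = composition("AAAA")
        assert stats.gc_percent == 0.0 and stats.cpg_count == 0

    def test_cpg_hand_enumeration(self):
        assert composition("CGCGCG").cpg_count == 3

    def test_counts_sum_and_percent(self, rng):
        s = random_dna(rng, 1088)
        stats = composition(s)
        assert sum(stats.counts.values()) == 1088
        assert abs(sum(stats.percents[b] for b in "ACGTN") - 100) < 0.05

    def test_gc_revcomp_invariant(self, rng):
        s = random_dna(rng, 777)
        assert composition(s).gc_percent == composition(revcomp(s)).gc_percent

    def test_permutation_invariant_counts(self, rng):
        s = random_dna(rng, 300)
        shuffled = "".join(np.random.default_rng(0).permutation(list(s)))
        assert composition(s).counts == composition(shuffled).counts


class TestTerminalCodons:
    def test_complete_stop(self):
        genome = "ATGTAA"
        f = F("g", 1, 6, "H", "PCG")
        assert terminal_codons(genome, f) == ("ATG", "TAA")

    def test_l_strand_revcomp(self):
        genome = "TTACAT"  # revcomp -> ATGTAA
        f = F("g", 1, 6, "L", "PCG")
        assert terminal_codons(genome, f) == ("ATG", "TAA")

    def test_incomplete_stop_length_mod_3_is_1(self):
        # length 7 = 3k+1: trailing single base rendered with the dash mark
        genome = "ATGAAAT"
        f = F("g", 1, 7, "H", "PCG")
        assert terminal_codons(genome, f) == ("ATG", "T—")

    def test_incomplete_stop_two_bases(self):
        genome = "ATGAAATA"
        f = F("g", 1, 8, "H", "PCG")
        assert terminal_codons(genome, f) == ("ATG", "TA—")

    def test_non_pcg_rejected(self):
        with pytest.raises(FeatureError):
            terminal_codons("ATGTAA", F("t", 1, 6, "H", "tRNA"))

    def test_too_short(self):
        with pytest.raises(FeatureError):
            terminal_codons("ATGTAA", F("g", 1, 2, "H", "PCG"))


class TestTableIO:
    def test_bundled_table_shape(self):
        table = load_km023192_features()
        assert table.genome_length == 16_563
        assert len(table.records) == 37  # 13 PCGs + 2 rRNAs + 22 tRNAs
        assert sum(1 for r in table if r.ftype == "PCG") == 13
        assert sum(1 for r in table if r.ftype == "tRNA") == 22
        assert sum(1 for r in table if r.strand == "L") == 9  # 8 tRNAs + ND6

    def test_tsv_round_trip(self, tmp_path):
        table = load_km023192_features()
        p = tmp_path / "features.tsv"
        write_feature_tsv(table, p)
        back = read_feature_tsv(p, genome_length=table.genome_length)
        assert [(r.name, r.start, r.end, r.strand, r.ftype) for r in back.records] == [
            (r.name, r.start, r.end, r.strand, r.ftype) for r in table.records
        ]

    def test_gff3_round_trip(self, tmp_path):
        table = load_km023192_features()
        p = tmp_path / "features.gff3"
        write_gff3(table, p)
        back = read_gff3(p, genome_length=table.genome_length)
        assert [(r.name, r.start, r.end, r.strand) for r in back.records] == [
            (r.name, r.start, r.end, r.strand) for r in table.records
        ]

    def test_duplicate_names_rejected(self):
        with pytest.raises(FeatureError):
            FeatureTable(genome_length=100, records=[F("a", 1, 5), F("a", 6, 9)])
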