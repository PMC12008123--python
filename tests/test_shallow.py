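"""Trinucleotide composition, PseEIIP, fusion, and the entropy diagnostic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supenh.sequences import SegmentTriple, SequenceRecord, segment_sequence
from supenh.shallow import (
    EIIP_MONO,
    EIIPTable,
    TRINUCLEOTIDES,
    entropy_table,
    fuse_shallow,
    pseeiip,
    segment_trifreq,
    threemer_composition,
    trinucleotide_entropy,
)
from supenh.synthetic import SyntheticConfig, generate_dataset


def _triple(up, mid, down):
    return SegmentTriple(up, mid, down, parent_id="t")


class TestComposition:
    def test_homopolymer_segment(self):
        freqs = segment_trifreq("AAAA")
        assert freqs[TRINUCLEOTIDES.index("AAA")] == 1.0
        assert freqs.sum() == 1.0 and (freqs > 0).sum() == 1

    def test_two_window_segment(self):
        freqs = segment_trifreq("ACGT")
        assert freqs[TRINUCLEOTIDES.index("ACG")] == 0.5
        assert freqs[TRINUCLEOTIDES.index("CGT")] == 0.5

    def test_tri_segment_layout(self):
        vec = threemer_composition(_triple("AAA", "CCC", "GGG"))
        assert len(vec) == 192
        nonzero = np.flatnonzero(vec.values)
        assert list(nonzero) == [
            TRINUCLEOTIDES.index("AAA"),
            64 + TRINUCLEOTIDES.index("CCC"),
            128 + TRINUCLEOTIDES.index("GGG"),
        ]
        assert np.all(vec.values[nonzero] == 1.0)

    def test_all_n_segment_gives_zero_block(self):
        vec = threemer_composition(_triple("NNNN", "ACGT", "ACGT"))
        assert not vec.values[:64].any()
        assert vec.values[64:128].sum() == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=60))
    def test_simplex_property(self, seg):
        assert segment_trifreq(seg).sum() == pytest.approx(1.0, abs=1e-12)


class TestPseEIIP:
    def test_printed_mononucleotide_constants(self):
        assert EIIP_MONO == {"A": 0.1260, "T": 0.1335, "G": 0.0806, "C": 0.1340}

    def test_homopolymer_value_under_sum_convention(self):
        vec = pseeiip(_triple("AAAA", "AAAA", "AAAA"))
        idx = TRINUCLEOTIDES.index("AAA")
        assert vec.values[idx] == pytest.approx(3 * 0.1260)  # 0.3780

    def test_mean_convention_is_one_third(self):
        t = _triple("ACGTACG", "GGTTCCA", "ACACACA")
        s = pseeiip(t, EIIPTable(convention="sum")).values
        m = pseeiip(t, EIIPTable(convention="mean")).values
        assert np.allclose(m, s / 3.0, atol=1e-15)

    @settings(max_examples=25, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=9, max_size=90))
    def test_definitional_identity_with_composition(self, seq):
        triple = segment_sequence(SequenceRecord("x", seq))
        comp = threemer_composition(triple).values
        table = EIIPTable()
        expected = comp * np.tile(table.tri, 3)
        assert np.array_equal(pseeiip(triple, table).values, expected)


class TestFusion:
    def test_fused_length_and_unique_prefixed_names(self):
        t = _triple("ACGTA", "CGTAC", "GTACG")
        fused = fuse_shallow(threemer_composition(t), pseeiip(t))
        assert len(fused) == 384
        assert len(set(fused.names)) == 384
        assert fused.names[0].startswith("comp_") and fused.names[192].startswith("eiip_")

    def test_zero_composition_passes_through(self):
        t = _triple("NNNN", "NNNN", "NNNN")
        fused = fuse_shallow(threemer_composition(t), pseeiip(t))
        assert not fused.values.any()

    def test_mismatched_parents_rejected(self):
        a = threemer_composition(_triple("ACGTA", "CGTAC", "GTACG"))
        b = pseeiip(SegmentTriple("ACGTA", "CGTAC", "GTACG", parent_id="other"))
        with pytest.raises(ValueError, match="different records"):
            fuse_shallow(a, b)


class TestEntropy:
    def test_degenerate_distribution_is_zero(self):
        assert trinucleotide_entropy("AAAA") == 0.0

    def test_two_equiprobable_outcomes_is_one_bit(self):
        assert trinucleotide_entropy("ACGT") == pytest.approx(1.0)

    def test_uniform_over_64_is_six_bits(self):
        # a de Bruijn-like concatenation of all 64 trinucleotides, each once
        seq = "".join(TRINUCLEOTIDES)
        freqs = np.full(64, 1 / 64.0)
        assert -(freqs * np.log2(freqs)).sum() == pytest.approx(6.0)
        assert 0.0 <= trinucleotide_entropy(seq) <= 6.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trinucleotide_entropy("AC")

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=100))
    def test_bounds(self, seq):
        assert 0.0 <= trinucleotide_entropy(seq) <= 6.0

    def test_tidy_table_regions_and_signal_location(self):
        ds = generate_dataset(
            SyntheticConfig(n_pos=60, n_neg=60, length_range=(300, 600), seed=21)
        )
        table = entropy_table(ds)
        assert set(table.region) == {"up", "mid", "down", "whole"}
        assert len(table) == 4 * len(ds)
        mid = table[table.region == "mid"]
        gap = (
            mid[mid.label == 0].entropy.mean() - mid[mid.label == 1].entropy.mean()
        )
        assert gap > 0.3  # planted midstream signal lowers positive-class entropy
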