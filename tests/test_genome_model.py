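"""Transcript geometry: distances, bins, isoform context, sequence windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronbench.genome import (
    DEFAULT_BINS,
    DistanceBins,
    ExonicPositionError,
    GenomeSequence,
    IntergenicPositionError,
    TranscriptModel,
    assign_bin,
    decompose_isoform_context,
    load_reference,
    load_transcripts,
    reverse_complement,
    sense_window,
    splice_distance,
)


# ---------------------------------------------------------------------------
# GenomeSequence / FASTA
# ---------------------------------------------------------------------------

class TestGenomeSequence:
    def test_fasta_identity_readback(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chrT\nACGT\n")
        g = load_reference(str(path))
        assert g.fetch("chrT", 1, 4) == "ACGT"
        assert g.fetch("chrT", 2, 3) == "CG"

    def test_out_of_range_is_error(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chrT\nACGT\n")
        g = load_reference(str(path))
        with pytest.raises(IndexError):
            g.fetch("chrT", 4, 5)
        with pytest.raises(IndexError):
            g.fetch("chrT", 0, 2)
        with pytest.raises(KeyError):
            g.fetch("chrX", 1, 1)

    def test_lowercase_and_ambiguity_normalized(self):
        g = GenomeSequence({"c": "acgRt"})
        assert g.fetch("c", 1, 5) == "ACGNT"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            GenomeSequence({"c": ""})


# ---------------------------------------------------------------------------
# Transcript models and GTF loading
# ---------------------------------------------------------------------------

GTF = """\
chrT\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; transcript_biotype "protein_coding";
chrT\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; transcript_biotype "protein_coding";
chrT\tsrc\texon\t501\t600\t.\t-\t.\tgene_id "G2"; transcript_id "T2"; transcript_biotype "protein_coding";
chrT\tsrc\texon\t701\t800\t.\t-\t.\tgene_id "G2"; transcript_id "T2"; transcript_biotype "protein_coding";
chrT\tsrc\texon\t901\t950\t.\t+\t.\tgene_id "G3"; transcript_id "T3"; transcript_biotype "protein_coding";
"""


@pytest.fixture(scope="module")
def transcripts(tmp_path_factory):
    path = tmp_path_factory.mktemp("gtf") / "t.gtf"
    path.write_text(GTF)
    return {t.transcript_id: t for t in load_transcripts(str(path))}


class TestTranscripts:

    def test_intron_is_gap_between_exons(self, transcripts):
        assert transcripts["T1"].introns == ((201, 300),)

    def test_minus_strand_same_genomic_intron_different_donor(self, transcripts):
        t2 = transcripts["T2"]
        assert t2.introns == ((601, 700),)
        # on the minus strand the donor is the higher-coordinate intron end
        assert splice_distance(700, t2).nearest_site_kind == "donor"
        assert splice_distance(601, t2).nearest_site_kind == "acceptor"

    def test_single_exon_transcript_is_intronless(self, transcripts):
        assert transcripts["T3"].is_intronless
        assert transcripts["T3"].introns == ()

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("x", "g", "c", "+", ((1, 10), (5, 20)))

    def test_zero_exons_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("x", "g", "c", "+", ())


# ---------------------------------------------------------------------------
# splice_distance
# ---------------------------------------------------------------------------

PLUS = TranscriptModel("tp", "g", "c", "+", ((101, 200), (301, 400)))
MINUS = TranscriptModel("tm", "g", "c", "-", ((101, 200), (301, 400)))


class TestSpliceDistance:
    @pytest.mark.parametrize(
        "pos,kind,offset",
        [
            (201, "donor", 1),
            (202, "donor", 2),
            (300, "acceptor", 1),
            (257, "acceptor", 44),  # 57 from the donor, 44 from the acceptor
        ],
    )
    def test_plus_strand_offsets(self, pos, kind, offset):
        ctx = splice_distance(pos, PLUS)
        assert (ctx.nearest_site_kind, ctx.intronic_offset) == (kind, offset)

    def test_minus_strand_mirrors_roles(self):
        ctx = splice_distance(300, MINUS)
        assert ctx.nearest_site_kind == "donor"
        assert ctx.intronic_offset == 1
        ctx = splice_distance(257, MINUS)
        assert ctx.nearest_site_kind == "donor"
        assert ctx.intronic_offset == 44

    def test_exonic_and_intergenic_errors_distinguished(self):
        with pytest.raises(ExonicPositionError):
            splice_distance(150, PLUS)
        with pytest.raises(IntergenicPositionError):
            splice_distance(500, PLUS)

    def test_brute_force_min_distance_oracle(self):
        s, e = PLUS.introns[0]
        for pos in range(s, e + 1):
            expected = min(pos - s + 1, e - pos + 1)
            assert splice_distance(pos, PLUS).intronic_offset == expected

    @given(st.integers(min_value=201, max_value=300))
    @settings(max_examples=100, deadline=None)
    def test_strand_symmetry(self, pos):
        """Reflecting the transcript leaves the mirrored position's offset unchanged."""
        lo, hi = 1, 500
        mirrored = hi - pos + lo
        flipped = TranscriptModel(
            "tf", "g", "c", "-",
            tuple(sorted((hi - e + lo, hi - s + lo) for s, e in PLUS.exons)),
        )
        a, b = splice_distance(pos, PLUS), splice_distance(mirrored, flipped)
        assert a.intronic_offset == b.intronic_offset
        assert a.nearest_site_kind == b.nearest_site_kind


# ---------------------------------------------------------------------------
# Distance bins
# ---------------------------------------------------------------------------

class TestBins:
    @pytest.mark.parametrize(
        "offset,label",
        [
            (1, "1-2"), (2, "1-2"), (3, "3-10"), (10, "3-10"),
            (11, "11-40"), (40, "11-40"), (41, "41-200"), (200, "41-200"),
            (201, "201-500"), (500, "201-500"), (501, "501-1000"),
            (1000, "501-1000"), (1001, "1000+"), (1500, "1000+"),
        ],
    )
    def test_boundaries_inclusive(self, offset, label):
        assert assign_bin(offset) == label

    def test_offset_below_one_rejected(self):
        with pytest.raises(ValueError):
            assign_bin(0)

    def test_sweep_covers_every_label_exactly_once_each(self):
        """Every position of a long synthetic intron hits exactly one bin."""
        tx = TranscriptModel("t", "g", "c", "+", ((1, 100), (2700, 2800)))
        seen = set()
        for pos in range(101, 2700):
            seen.add(assign_bin(splice_distance(pos, tx).intronic_offset))
        assert seen == set(DEFAULT_BINS.labels)

    def test_non_contiguous_bins_rejected(self):
        with pytest.raises(ValueError):
            DistanceBins((("a", 1, 2), ("b", 4, 10), ("c", 11, None)))


# ---------------------------------------------------------------------------
# Isoform context
# ---------------------------------------------------------------------------

REF_TX = TranscriptModel("R", "g", "c", "+", ((101, 200), (1501, 1600)))
EXONIC_ISO = TranscriptModel("B", "g", "c", "+", ((101, 200), (701, 820), (1501, 1600)))
CLOSER_ISO = TranscriptModel("C", "g", "c", "+", ((101, 200), (641, 700), (1501, 1600)))
SAME_ISO = TranscriptModel("D", "g", "c", "+", ((101, 200), (1501, 1600)))


class TestIsoformContext:
    def test_exonic_in_other_isoform(self):
        assert decompose_isoform_context(750, [REF_TX, EXONIC_ISO], "R") == "exonic"

    def test_smaller_offset_in_other_isoform(self):
        # offset 610 in R, but only 10 bp past isoform C's extra exon
        assert decompose_isoform_context(710, [REF_TX, CLOSER_ISO], "R") == "smaller_offset"

    def test_same_offset_everywhere(self):
        assert decompose_isoform_context(710, [REF_TX, SAME_ISO], "R") == "same_offset"

    def test_single_transcript_gene(self):
        assert decompose_isoform_context(710, [REF_TX], "R") == "no_other_transcript"

    def test_exonic_takes_precedence_over_smaller_offset(self):
        cat = decompose_isoform_context(750, [REF_TX, EXONIC_ISO, CLOSER_ISO], "R")
        assert cat == "exonic"

    def test_order_invariance(self):
        txs = [REF_TX, EXONIC_ISO, CLOSER_ISO, SAME_ISO]
        expected = decompose_isoform_context(750, txs, "R")
        assert decompose_isoform_context(750, txs[::-1], "R") == expected

    def test_missing_reference_is_error(self):
        with pytest.raises(KeyError):
            decompose_isoform_context(750, [EXONIC_ISO], "R")


# ---------------------------------------------------------------------------
# sense_window
# ---------------------------------------------------------------------------

class TestSenseWindow:
    def test_plus_strand_identity(self):
        g = GenomeSequence({"c": "ACGTA"})
        assert sense_window(g, "c", "+", 3, 2) == "ACGTA"

    def test_minus_strand_reverse_complement(self):
        g = GenomeSequence({"c": "ACGTA"})
        assert sense_window(g, "c", "-", 3, 2) == "TACGT"
        assert sense_window(g, "c", "-", 3, 2) == reverse_complement("ACGTA")

    def test_window_off_contig_is_error(self):
        g = GenomeSequence({"c": "ACGTA"})
        with pytest.raises(IndexError):
            sense_window(g, "c", "+", 2, 2)
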