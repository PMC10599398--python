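"""Branchpoint motif scanning and six-way mechanism classification."""

import numpy as np
import pytest

from intronbench.genome import GenomeSequence, TranscriptModel, reverse_complement
from intronbench.regions import (
    ACCEPTOR_CREATION_RULE,
    DEFAULT_BP_MOTIFS,
    DONOR_CREATION_RULE,
    BranchpointMotifSet,
    CrypticSpliceEvent,
    JunctionIndex,
    MotifHit,
    SpliceMotifRule,
    bp_motif_change,
    check_junction_evidence,
    classify_negative,
    classify_positive,
    detect_created_splice_motif,
    is_branchpoint_associated,
    match_bp_motifs,
)

# independent brute-force oracle: every (motif, offset) placement tested with
# its own degenerate-code table
_ORACLE_SETS = {"Y": "CT", "N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T"}


def oracle_hits(window, motifs=DEFAULT_BP_MOTIFS):
    hits = set()
    for motif in motifs:
        for start in range(len(window) - len(motif) + 1):
            if all(window[start + i] in _ORACLE_SETS[p] for i, p in enumerate(motif)):
                hits.add((motif, start, start + motif.index("A")))
    return hits


class TestBranchpointScan:
    def test_ctgac_matches_all_motifs(self):
        hits = set(match_bp_motifs("CTGAC"))
        assert ("YTNAY", 0, 3) in hits
        assert ("YTNA", 0, 3) in hits
        assert ("TNA", 1, 3) in hits
        assert ("YNA", 1, 3) in hits

    def test_no_adenine_no_hits(self):
        assert match_bp_motifs("GGGGG") == []

    def test_sequence_n_never_matches(self):
        assert match_bp_motifs("CTNAC") == []  # N at the pattern-N slot still fails

    def test_overlapping_hits_reported(self):
        hits = set(match_bp_motifs("TAATA"))
        assert hits == oracle_hits("TAATA")

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            match_bp_motifs("")

    def test_agrees_with_brute_force_on_random_windows(self, rng):
        bases = np.array(list("ACGTN"))
        for _ in range(300):
            w = "".join(bases[rng.integers(0, 5, size=20)])
            assert set(match_bp_motifs(w)) == oracle_hits(w), w

    def test_motif_relaxation_monotonicity(self, rng):
        """A YTNAY hit implies YTNA, TNA and YNA hits at compatible offsets."""
        bases = np.array(list("ACGT"))
        for _ in range(200):
            w = "".join(bases[rng.integers(0, 4, size=30)])
            hits = set(match_bp_motifs(w))
            for motif, start, a in hits:
                if motif == "YTNAY":
                    assert ("YTNA", start, a) in hits
                    assert ("TNA", start + 1, a) in hits
                    assert ("YNA", start + 1, a) in hits

    def test_motif_must_contain_single_adenine(self):
        with pytest.raises(ValueError):
            BranchpointMotifSet(("YTNAYA",))


class TestMotifChange:
    def test_disruption_of_ytnay(self):
        created, disrupted = bp_motif_change("CTGAC", "CTGGC", 3)
        assert created == set()
        assert MotifHit("YTNAY", 0, 3) in disrupted

    def test_no_change(self):
        assert bp_motif_change("CTGAC", "CTGAC", 2) == (set(), set())

    def test_creation_symmetric_with_disruption(self):
        created, _ = bp_motif_change("CTGGC", "CTGAC", 3)
        _, disrupted = bp_motif_change("CTGAC", "CTGGC", 3)
        assert created == disrupted
        assert MotifHit("YTNAY", 0, 3) in created

    def test_hits_not_overlapping_variant_ignored(self):
        # variant at offset 0; the TAATA hits at offsets >= 1 are untouched
        created, disrupted = bp_motif_change("GTAAT", "CTAAT", 0)
        for h in created | disrupted:
            assert h.start <= 0 < h.start + len(h.motif)

    def test_unequal_windows_rejected(self):
        with pytest.raises(ValueError):
            bp_motif_change("CTGAC", "CTGA", 1)


class TestBranchpointAssociation:
    W = "AAACTGACAAA"  # YTNAY CTGAC at offsets 3-7, adenine at 6

    def test_disrupting_adenine_inside_window(self):
        ev = is_branchpoint_associated(self.W, "AAACTGGCAAA", 6, upstream_offset=25)
        assert ev.is_associated
        assert any(h.motif == "YTNAY" for h in ev.disrupted)

    @pytest.mark.parametrize("offset,expected", [(17, False), (18, True), (44, True), (45, False)])
    def test_window_boundaries_inclusive(self, offset, expected):
        ev = is_branchpoint_associated(self.W, "AAACTGGCAAA", 6, upstream_offset=offset)
        assert ev.is_associated is expected

    def test_no_motif_change_not_associated(self):
        # A->G at offset 0 touches no motif placement
        ev = is_branchpoint_associated(self.W, "GAACTGACAAA", 0, upstream_offset=30)
        assert not ev.is_associated
        assert not ev.created and not ev.disrupted

    def test_variant_one_bp_upstream_of_adenine_excluded(self):
        # the A->G at offset 5 disrupts a TNA, but the reference also carries
        # a motif whose branchpoint adenine sits at offset 6, so the variant
        # is exactly 1 bp upstream of a candidate adenine and is excluded
        ref, alt = "AAATTAAAAAA", "AAATTGAAAAA"
        ev = is_branchpoint_associated(ref, alt, 5, upstream_offset=30)
        assert ev.disrupted  # the motif change alone would have qualified
        assert not ev.is_associated
        assert ev.excluded_adenine_minus_one

    def test_downstream_position_rejected(self):
        with pytest.raises(ValueError):
            is_branchpoint_associated(self.W, self.W, 6, upstream_offset=0)


def _event(kind, strand="+", exon=(1001, 1080)):
    site = exon[0] - 2 if kind == "acceptor" else exon[1] + 1
    if strand == "-":
        site = exon[1] + 1 if kind == "acceptor" else exon[0] - 2
    return CrypticSpliceEvent(kind, "c", strand, site, exon)


NEUTRAL = "A" * 17  # windows without any branchpoint motif


class TestClassifyPositive:
    @pytest.mark.parametrize(
        "pos,category",
        [
            (1001, "new_splice_acceptor"),  # first cryptic-exon base
            (1000, "new_splice_acceptor"),  # the G of the AG
            (999, "new_splice_acceptor"),   # the A of the AG
            (991, "acceptor_upstream"),     # 10 bp upstream
            (1040, "exonic_like"),
        ],
    )
    def test_acceptor_side_geometry(self, pos, category):
        assert classify_positive(pos, NEUTRAL, NEUTRAL, 8, _event("acceptor")) == category

    def test_branchpoint_beats_flank_when_motif_changes(self):
        # 25 bp upstream of the cryptic acceptor, disrupting a planted YTNAY
        ref = "AAAAACTGACAAAAAAA"  # adenine at center offset 8
        alt = ref[:8] + "G" + ref[9:]
        assert classify_positive(976, ref, alt, 8, _event("acceptor")) == "branchpoint_associated"

    @pytest.mark.parametrize(
        "pos,category",
        [
            (1080, "new_splice_donor"),  # last cryptic-exon base
            (1081, "new_splice_donor"),  # the G of the GT
            (1082, "new_splice_donor"),  # the T of the GT
            (1087, "donor_downstream"),  # 7 bp downstream
            (1083, "donor_downstream"),  # first position past the dinucleotide
            (1050, "exonic_like"),
        ],
    )
    def test_donor_side_geometry(self, pos, category):
        assert classify_positive(pos, NEUTRAL, NEUTRAL, 8, _event("donor")) == category

    def test_minus_strand_mirrors(self):
        ev = _event("donor", strand="-")
        assert classify_positive(1000, NEUTRAL, NEUTRAL, 8, ev) == "new_splice_donor"
        assert classify_positive(995, NEUTRAL, NEUTRAL, 8, ev) == "donor_downstream"

    def test_unlocatable_variant_is_error(self):
        # upstream of the cryptic exon of a donor event: no defined region
        with pytest.raises(ValueError):
            classify_positive(900, NEUTRAL, NEUTRAL, 8, _event("donor"))


TX = TranscriptModel("t", "g", "c", "+", ((101, 200), (1201, 1300)))


class TestClassifyNegative:
    @pytest.mark.parametrize(
        "pos,category",
        [
            (1171, "branchpoint_associated"),  # 30 bp upstream of the acceptor
            (1183, "branchpoint_associated"),  # offset 18 boundary
            (1184, "acceptor_upstream"),       # offset 17, outside the BP window
            (1140, "acceptor_upstream"),       # offset 61
            (260, "donor_downstream"),         # 60 bp downstream of the donor
        ],
    )
    def test_annotated_site_geometry(self, pos, category):
        assert classify_negative(pos, TX) == category

    def test_exonic_control(self):
        assert classify_negative(150, TX, is_exonic_control=True) == "exonic_like"


class TestCreatedSpliceMotif:
    def test_acceptor_motif_created_at_core(self):
        # CATGT -> CAGGT, variant at the 3rd base = the G of the core AG
        ref = "AAACATGTAAA"
        alt = "AAACAGGTAAA"
        hit = detect_created_splice_motif(ref, alt, 5, ACCEPTOR_CREATION_RULE)
        assert hit.created and hit.placement_start == 3 and hit.core_index == 2

    def test_donor_motif_created_at_core(self):
        ref = "AAGCTAAGAAAA"
        alt = "AAGGTAAGAAAA"
        hit = detect_created_splice_motif(ref, alt, 3, DONOR_CREATION_RULE)
        assert hit.created and hit.core_index == 1

    def test_preexisting_motif_not_creation(self):
        ref = "ACAGGTAAAAA"  # CAGGT already present
        alt = "ACAGGTAATAA"  # SNV elsewhere
        assert not detect_created_splice_motif(ref, alt, 8, ACCEPTOR_CREATION_RULE).created

    def test_variant_outside_core_not_creation(self):
        ref = "AAATAGGTAAA"  # T->C at position 3 completes CAGGT but at a non-core slot
        alt = "AAACAGGTAAA"
        assert not detect_created_splice_motif(ref, alt, 3, ACCEPTOR_CREATION_RULE).created

    def test_strand_symmetry(self):
        """A plus-strand creation and its minus-strand genomic mirror agree."""
        from intronbench.reports import variant_sense_windows

        plus_seq = "AAACATGTAAA"  # T->G at 1-based pos 6 creates CAGGT
        g_plus = GenomeSequence({"c": plus_seq})
        g_minus = GenomeSequence({"c": reverse_complement(plus_seq)})
        mirrored_pos = len(plus_seq) - 6 + 1
        a = detect_created_splice_motif(
            *variant_sense_windows(g_plus, "c", "+", 6, "T", "G", flank=5),
            ACCEPTOR_CREATION_RULE,
        )
        b = detect_created_splice_motif(
            *variant_sense_windows(g_minus, "c", "-", mirrored_pos, "A", "C", flank=5),
            ACCEPTOR_CREATION_RULE,
        )
        assert a.created and b.created and a.core_index == b.core_index

    def test_core_offsets_validated(self):
        with pytest.raises(ValueError):
            SpliceMotifRule("acceptor", "CAGGT", (0, 1))


class TestJunctionEvidence:
    def test_position_inside_interval(self):
        idx = JunctionIndex([("chr1", 100, 200)])
        assert check_junction_evidence("chr1", 150, idx)

    def test_empty_index(self):
        assert not check_junction_evidence("chr1", 150, JunctionIndex())

    def test_half_open_end_boundary(self):
        idx = JunctionIndex([("chr1", 100, 200)])
        assert check_junction_evidence("chr1", 199, idx)
        assert not check_junction_evidence("chr1", 200, idx)  # end is exclusive

    def test_malformed_bed_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(ValueError):
            JunctionIndex.from_bed(str(p))

    def test_bed_round_trip(self, tmp_path):
        p = tmp_path / "jx.bed"
        p.write_text("# comment\nchr1\t10\t20\nchr2\t5\t6\n")
        idx = JunctionIndex.from_bed(str(p))
        assert check_junction_evidence("chr1", 15, idx)
        assert check_junction_evidence("chr2", 5, idx)
        assert not check_junction_evidence("chr2", 6, idx)
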