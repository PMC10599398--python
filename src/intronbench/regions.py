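"""Splicing-mechanism region classification.

Variants that alter splicing are assigned to one of six regions defined by
their position relative to the (cryptic or annotated) splice sites they
act on:

* ``branchpoint_associated`` — 18-44 bp upstream of an acceptor, creating or
  disrupting one of the degenerate adenine-branchpoint consensus motifs
  (YTNAY, YTNA, TNA, YNA), excluding variants sitting 1 bp upstream of the
  branchpoint adenine;
* ``acceptor_upstream`` — 2-18 bp upstream of the cryptic acceptor
  (polypyrimidine-tract territory);
* ``new_splice_acceptor`` — at the acceptor AG positions or the first
  nucleotide of the cryptic exon;
* ``exonic_like`` — inside the cryptic exon (pseudoexon or retained
  intron segment);
* ``new_splice_donor`` — at the donor GT positions or the last nucleotide of
  the cryptic exon;
* ``donor_downstream`` — more than 2 bp downstream of the cryptic donor.

All motif scanning happens on the transcribed (sense) strand; windows for
minus-strand genes are reverse-complemented before matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from intervaltree import IntervalTree

from .genome import GenomeSequence, SpliceSiteContext, TranscriptModel, sense_window, splice_distance

REGION_CATEGORIES = (
    "branchpoint_associated",
    "acceptor_upstream",
    "new_splice_acceptor",
    "exonic_like",
    "new_splice_donor",
    "donor_downstream",
)

# Degenerate base codes used by the branchpoint consensus motifs.
_CODE = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "Y": frozenset("CT"),
    "N": frozenset("ACGT"),  # a sequence N matches nothing, see _base_matches
}

DEFAULT_BP_MOTIFS = ("YTNAY", "YTNA", "TNA", "YNA")


@dataclass(frozen=True)
class BranchpointMotifSet:
    """Ordered degenerate branchpoint motifs, strictest first.

    Every motif carries exactly one mandatory A: the branchpoint adenine.
    """

    motifs: tuple[str, ...] = DEFAULT_BP_MOTIFS

    def __post_init__(self):
        for m in self.motifs:
            if m.count("A") != 1:
                raise ValueError(f"motif {m!r} must contain exactly one literal A")

    def adenine_index(self, motif: str) -> int:
        return motif.index("A")


DEFAULT_BP_SET = BranchpointMotifSet()


class MotifHit(NamedTuple):
    """One placement of one motif; offsets are 0-based within the window."""

    motif: str
    start: int
    adenine: int


def _base_matches(pattern_char: str, seq_char: str) -> bool:
    # A sequence N never matches, not even a pattern N.
    return seq_char in _CODE[pattern_char]


def _motif_matches_at(motif: str, window: str, start: int) -> bool:
    if start < 0 or start + len(motif) > len(window):
        return False
    return all(_base_matches(p, window[start + i]) for i, p in enumerate(motif))


def match_bp_motifs(
    window: str, motif_set: BranchpointMotifSet = DEFAULT_BP_SET
) -> list[MotifHit]:
    """All placements of all branchpoint motifs in ``window`` (overlaps included)."""
    if not window:
        raise ValueError("empty window")
    window = window.upper()
    hits = []
    for motif in motif_set.motifs:
        a_idx = motif_set.adenine_index(motif)
        for start in range(len(window) - len(motif) + 1):
            if _motif_matches_at(motif, window, start):
                hits.append(MotifHit(motif, start, start + a_idx))
    return hits


def bp_motif_change(
    ref_window: str,
    alt_window: str,
    variant_offset: int,
    motif_set: BranchpointMotifSet = DEFAULT_BP_SET,
) -> tuple[set[MotifHit], set[MotifHit]]:
    """Motif placements created / disrupted by an SNV at ``variant_offset``.

    Only placements overlapping the variant offset are considered; a hit is
    *created* when present in alt but not at the same placement in ref, and
    *disrupted* in the converse case.
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("SNV windows must have equal length")

    def overlapping(hits):
        return {
            h for h in hits if h.start <= variant_offset < h.start + len(h.motif)
        }

    ref_hits = overlapping(match_bp_motifs(ref_window, motif_set))
    alt_hits = overlapping(match_bp_motifs(alt_window, motif_set))
    return alt_hits - ref_hits, ref_hits - alt_hits


@dataclass(frozen=True)
class BranchpointEvidence:
    is_associated: bool
    upstream_offset: int
    created: frozenset[MotifHit]
    disrupted: frozenset[MotifHit]
    excluded_adenine_minus_one: bool = False


# Inclusive window (in exon-adjacent intronic offsets) for the branchpoint
# region upstream of an acceptor.
BP_WINDOW = (18, 44)


def is_branchpoint_associated(
    ref_window: str,
    alt_window: str,
    variant_offset: int,
    upstream_offset: int,
    window_bounds: tuple[int, int] = BP_WINDOW,
    motif_set: BranchpointMotifSet = DEFAULT_BP_SET,
) -> BranchpointEvidence:
    """Branchpoint-association test for a variant upstream of an acceptor.

    True iff the variant (a) lies within the branchpoint window upstream of
    the acceptor, (b) creates or disrupts at least one consensus motif, and
    (c) is not located exactly 1 bp upstream (5') of a candidate branchpoint
    adenine — the adenine of any reference-window motif hit overlapping the
    variant.  (In all four consensus motifs the base 5' of the adenine is
    the N slot, so a substitution there never changes the motif itself; the
    exclusion therefore keys on the reference motif's adenine.)

    ``upstream_offset`` counts the exon-adjacent intronic base as 1; windows
    are on the transcribed strand and centered on the variant.
    """
    if upstream_offset < 1:
        raise ValueError("variant must be upstream of the acceptor")
    lo, hi = window_bounds
    if not (lo <= upstream_offset <= hi):
        return BranchpointEvidence(False, upstream_offset, frozenset(), frozenset())
    created, disrupted = bp_motif_change(
        ref_window, alt_window, variant_offset, motif_set
    )
    if not created and not disrupted:
        return BranchpointEvidence(False, upstream_offset, frozenset(), frozenset())
    ref_hits = {
        h
        for h in match_bp_motifs(ref_window, motif_set)
        if h.start <= variant_offset < h.start + len(h.motif)
    }
    if any(variant_offset == h.adenine - 1 for h in ref_hits):
        return BranchpointEvidence(
            False, upstream_offset, frozenset(created), frozenset(disrupted),
            excluded_adenine_minus_one=True,
        )
    return BranchpointEvidence(
        True, upstream_offset, frozenset(created), frozenset(disrupted)
    )


# ---------------------------------------------------------------------------
# Cryptic splice events and positive-set classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrypticSpliceEvent:
    """An experimentally observed cryptic acceptor/donor with its cryptic exon."""

    kind: str  # acceptor | donor
    contig: str
    strand: str
    cryptic_site_position: int  # first base of the core dinucleotide, genomic
    cryptic_exon: tuple[int, int]  # 1-based inclusive genomic interval
    outcome_group: str = "pseudoexon_activation"

    def __post_init__(self):
        s, e = self.cryptic_exon
        if s > e:
            raise ValueError("empty cryptic exon interval")
        if self.kind not in ("acceptor", "donor"):
            raise ValueError(f"bad event kind {self.kind!r}")


def _acceptor_upstream_offset(pos: int, event: CrypticSpliceEvent) -> int:
    """Intronic offset upstream of the cryptic-exon acceptor boundary (1 = adjacent)."""
    s, e = event.cryptic_exon
    if event.strand == "+":
        return s - pos
    return pos - e


def _donor_downstream_offset(pos: int, event: CrypticSpliceEvent) -> int:
    s, e = event.cryptic_exon
    if event.strand == "+":
        return pos - e
    return s - pos


def _in_exon(pos: int, event: CrypticSpliceEvent) -> bool:
    s, e = event.cryptic_exon
    return s <= pos <= e


def _first_exon_base(event: CrypticSpliceEvent) -> int:
    s, e = event.cryptic_exon
    return s if event.strand == "+" else e


def _last_exon_base(event: CrypticSpliceEvent) -> int:
    s, e = event.cryptic_exon
    return e if event.strand == "+" else s


def classify_positive(
    pos: int,
    ref_window: str,
    alt_window: str,
    window_offset: int,
    event: CrypticSpliceEvent,
    bp_window: tuple[int, int] = BP_WINDOW,
    acceptor_upstream_window: tuple[int, int] = (2, 18),
) -> str:
    """Region category of a splicing-altering variant given its cryptic event.

    ``ref_window``/``alt_window`` are sense-strand windows centered on the
    variant (center index ``window_offset``), used only for the branchpoint
    motif-change test.  Precedence on overlap: splice-site categories >
    branchpoint > flanking windows > exonic_like.
    """
    if event.kind == "acceptor":
        u = _acceptor_upstream_offset(pos, event)
        if u in (1, 2) or pos == _first_exon_base(event):
            return "new_splice_acceptor"
        if u >= 1:
            ev = is_branchpoint_associated(
                ref_window, alt_window, window_offset, u, bp_window
            )
            if ev.is_associated:
                return "branchpoint_associated"
            lo, hi = acceptor_upstream_window
            if lo <= u <= hi:
                return "acceptor_upstream"
            if lo <= u:  # beyond the window but still upstream: PPT side
                return "acceptor_upstream"
        if _in_exon(pos, event):
            return "exonic_like"
        raise ValueError(
            f"variant at {pos} not locatable relative to acceptor event at "
            f"{event.cryptic_site_position}"
        )
    else:  # donor
        d = _donor_downstream_offset(pos, event)
        if d in (1, 2) or pos == _last_exon_base(event):
            return "new_splice_donor"
        if d > 2:
            return "donor_downstream"
        if _in_exon(pos, event):
            return "exonic_like"
        raise ValueError(
            f"variant at {pos} not locatable relative to donor event at "
            f"{event.cryptic_site_position}"
        )


def classify_negative(
    pos: int,
    transcript: TranscriptModel,
    is_exonic_control: bool = False,
    bp_window: tuple[int, int] = BP_WINDOW,
) -> str:
    """Region category of a splicing-neutral variant (annotated-site geometry).

    Negatives in the branchpoint window upstream of an annotated acceptor are
    branchpoint_associated (no motif requirement); the rest split into
    acceptor_upstream / donor_downstream by the side of the nearest annotated
    splice site.  Exonic control variants map to exonic_like.
    """
    if is_exonic_control:
        return "exonic_like"
    ctx = splice_distance(pos, transcript)
    lo, hi = bp_window
    if ctx.side == "upstream_of_acceptor":
        if lo <= ctx.intronic_offset <= hi:
            return "branchpoint_associated"
        return "acceptor_upstream"
    return "donor_downstream"


# ---------------------------------------------------------------------------
# Splice-motif creation (negative-set construction)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpliceMotifRule:
    """A literal splice-site consensus with the obligatory core dinucleotide."""

    kind: str  # acceptor | donor
    motif: str
    core_offsets: tuple[int, int]  # 0-based indices of the core dinucleotide

    def __post_init__(self):
        i, j = self.core_offsets
        core = self.motif[i] + self.motif[j]
        expected = "AG" if self.kind == "acceptor" else "GT"
        if core != expected:
            raise ValueError(
                f"{self.kind} motif {self.motif!r} lacks {expected} at {self.core_offsets}"
            )


#: The most common acceptor 5-mer, AG at (1-based) positions 2-3.
ACCEPTOR_CREATION_RULE = SpliceMotifRule("acceptor", "CAGGT", (1, 2))
#: The most common donor 6-mer, GT at (1-based) positions 2-3.
DONOR_CREATION_RULE = SpliceMotifRule("donor", "GGTAAG", (1, 2))


class MotifCreation(NamedTuple):
    created: bool
    placement_start: int | None  # 0-based start of the motif within the window
    core_index: int | None  # which core offset the variant occupies


def detect_created_splice_motif(
    ref_window: str,
    alt_window: str,
    variant_offset: int,
    rule: SpliceMotifRule,
) -> MotifCreation:
    """Does an SNV create ``rule.motif`` with the variant at the core dinucleotide?

    Windows are sense-strand, centered on the variant.  True iff some
    placement overlapping the variant (i) matches alt exactly, (ii) does not
    match ref at the same placement, and (iii) puts the variant at one of the
    core dinucleotide offsets.
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("SNV windows must have equal length")
    m = rule.motif
    for start in range(
        max(0, variant_offset - len(m) + 1),
        min(variant_offset, len(alt_window) - len(m)) + 1,
    ):
        within = variant_offset - start
        if within not in rule.core_offsets:
            continue
        if alt_window[start : start + len(m)] != m:
            continue
        if ref_window[start : start + len(m)] == m:
            continue
        return MotifCreation(True, start, within)
    return MotifCreation(False, None, None)


# ---------------------------------------------------------------------------
# Junction evidence (local BED lookup)
# ---------------------------------------------------------------------------

class JunctionIndex:
    """Observed splice-junction boundary intervals from a BED file.

    BED semantics: 0-based half-open.  Queries are made with 0-based
    positions (convert 1-based variant coordinates with ``pos - 1``); a
    position equal to an interval's ``end`` is outside it.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            self.add(contig, start, end)

    def add(self, contig: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"malformed interval {contig}:{start}-{end}")
        self._trees.setdefault(contig, IntervalTree()).addi(start, end)

    @classmethod
    def from_bed(cls, path: str) -> "JunctionIndex":
        idx = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed BED line")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
                idx.add(fields[0], start, end)
        return idx


def check_junction_evidence(contig: str, pos0: int, junctions: JunctionIndex) -> bool:
    """True iff the 0-based position coincides with a listed junction interval."""
    tree = junctions._trees.get(contig)
    return bool(tree is not None and tree.overlaps_point(pos0))
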