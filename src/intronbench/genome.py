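"""Transcript-structure model and splice-site distance geometry.

Coordinates are 1-based inclusive throughout (VCF/GTF convention).  An
intronic position's *offset* counts the first intronic base adjacent to an
exon as 1, so offsets 1-2 are the canonical splice-site dinucleotide (GT at
the donor, AG at the acceptor).  All donor/acceptor assignments are
strand-aware: on the minus strand the donor sits at the higher-coordinate
end of the intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from pyfaidx import Fasta

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC ambiguity codes normalized to N on load.
_AMBIGUOUS = set("RYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory reference genome with strict 1-based inclusive lookup."""

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
            seq = seq.upper()
            if any(c in _AMBIGUOUS for c in set(seq)):
                log.warning("contig %s: ambiguity codes normalized to N", name)
                seq = "".join("N" if c in _AMBIGUOUS else c for c in seq)
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r}: invalid characters {sorted(bad)}")
            self.contigs[name] = seq

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence at ``contig:start-end`` (1-based inclusive)."""
        try:
            seq = self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"range {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


def load_reference(path: str) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Duplicate contig names and empty sequences are errors; lower-case and
    IUPAC-ambiguous bases are normalized (to upper case and N).
    """
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True,
               duplicate_action="stop", rebuild=False, build_index=True)
    contigs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return GenomeSequence(contigs)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of exons on one contig/strand."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: zero exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for (s, e) in exons:
            if s > e:
                raise ValueError(f"transcript {self.transcript_id}: exon {s}>{e}")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order, 1-based inclusive."""
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def is_intronless(self) -> bool:
        return len(self.exons) == 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def is_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def intron_index_at(self, pos: int) -> int | None:
        for i, (s, e) in enumerate(self.introns):
            if s <= pos <= e:
                return i
        return None


@dataclass(frozen=True)
class SpliceSiteContext:
    """Position of an intronic variant relative to its nearest splice site."""

    transcript_id: str
    nearest_site_kind: str  # donor | acceptor
    intronic_offset: int  # 1 = first intronic base adjacent to the exon
    intron_index: int
    side: str  # downstream_of_donor | upstream_of_acceptor


class ExonicPositionError(ValueError):
    """Position overlaps an exon of the transcript."""


class IntergenicPositionError(ValueError):
    """Position falls outside the transcript body."""


def splice_distance(pos: int, transcript: TranscriptModel) -> SpliceSiteContext:
    """Distance (in intronic offsets) from ``pos`` to the closest splice site.

    ``pos`` must be strictly intronic.  Ties between the two boundaries of an
    intron resolve to the donor side for determinism.
    """
    if not transcript.contains(pos):
        raise IntergenicPositionError(
            f"position {pos} outside transcript {transcript.transcript_id} "
            f"({transcript.start}-{transcript.end})"
        )
    if transcript.is_exonic(pos):
        raise ExonicPositionError(
            f"position {pos} is exonic in transcript {transcript.transcript_id}"
        )
    idx = transcript.intron_index_at(pos)
    assert idx is not None
    s, e = transcript.introns[idx]
    dist_low = pos - s + 1  # offset from the lower-coordinate intron end
    dist_high = e - pos + 1
    if transcript.strand == "+":
        donor_off, acceptor_off = dist_low, dist_high
    else:
        donor_off, acceptor_off = dist_high, dist_low
    if donor_off <= acceptor_off:
        kind, offset, side = "donor", donor_off, "downstream_of_donor"
    else:
        kind, offset, side = "acceptor", acceptor_off, "upstream_of_acceptor"
    return SpliceSiteContext(
        transcript_id=transcript.transcript_id,
        nearest_site_kind=kind,
        intronic_offset=offset,
        intron_index=idx,
        side=side,
    )


# ---------------------------------------------------------------------------
# Distance bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceBins:
    """Contiguous, non-overlapping offset bins covering 1..infinity.

    The default edges follow the intronic-bin scheme with the splice-site
    dinucleotide as its own "1-2" bin and an open-ended "1000+" tail.
    """

    bins: tuple[tuple[str, int, int | None], ...] = (
        ("1-2", 1, 2),
        ("3-10", 3, 10),
        ("11-40", 11, 40),
        ("41-200", 41, 200),
        ("201-500", 201, 500),
        ("501-1000", 501, 1000),
        ("1000+", 1001, None),
    )

    def __post_init__(self):
        expected_lo = 1
        for label, lo, hi in self.bins[:-1]:
            if lo != expected_lo or hi is None or hi < lo:
                raise ValueError(f"bins not contiguous at {label!r}")
            expected_lo = hi + 1
        last_label, last_lo, last_hi = self.bins[-1]
        if last_lo != expected_lo or last_hi is not None:
            raise ValueError("final bin must be open-ended and contiguous")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.bins)


DEFAULT_BINS = DistanceBins()


def assign_bin(offset: int, bins: DistanceBins = DEFAULT_BINS) -> str:
    """Map an intronic offset (>=1) to its bin label (inclusive edges)."""
    if offset < 1:
        raise ValueError(f"intronic offset must be >= 1, got {offset}")
    for label, lo, hi in bins.bins:
        if offset >= lo and (hi is None or offset <= hi):
            return label
    raise AssertionError("unreachable: bins cover 1..inf")


# ---------------------------------------------------------------------------
# Multi-isoform context
# ---------------------------------------------------------------------------

def decompose_isoform_context(
    pos: int,
    transcripts: Iterable[TranscriptModel],
    reference_transcript_id: str,
) -> str:
    """Categorize a deep-intronic position against a gene's other isoforms.

    Returns one of ``exonic``, ``smaller_offset``, ``same_offset``,
    ``no_other_transcript`` (precedence in that order).  The reference
    transcript must be in ``transcripts`` and intronic at ``pos``.
    Output is invariant to the order transcripts are supplied in.
    """
    txs = {t.transcript_id: t for t in transcripts}
    if reference_transcript_id not in txs:
        raise KeyError(f"reference transcript {reference_transcript_id!r} not supplied")
    ref = txs[reference_transcript_id]
    ref_offset = splice_distance(pos, ref).intronic_offset

    others = [
        t
        for tid, t in sorted(txs.items())
        if tid != reference_transcript_id and t.contains(pos)
    ]
    if not others:
        return "no_other_transcript"
    if any(t.is_exonic(pos) for t in others):
        return "exonic"
    offsets = [splice_distance(pos, t).intronic_offset for t in others]
    if any(o < ref_offset for o in offsets):
        return "smaller_offset"
    return "same_offset"


# ---------------------------------------------------------------------------
# Sequence windows
# ---------------------------------------------------------------------------

def sense_window(
    genome: GenomeSequence, contig: str, strand: str, center: int, flank: int
) -> str:
    """Sequence of length ``2*flank+1`` centered on ``center``, transcribed strand.

    Reverse-complemented for minus-strand genes so the window reads 5'->3'
    along the pre-mRNA; the center base always corresponds to ``center``.
    """
    seq = genome.fetch(contig, center - flank, center + flank)
    return reverse_complement(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# GTF/GFF3 loading
# ---------------------------------------------------------------------------

def _first_attr(feature, *keys: str, default: str | None = None) -> str | None:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return default


def load_transcripts(path: str) -> list[TranscriptModel]:
    """Parse transcripts with their exons from a GTF or GFF3 file.

    Attribute keys honored: ``transcript_id``, ``gene_id``, and
    ``transcript_biotype``/``gene_biotype`` (falling back to
    ``protein_coding`` if absent).  Exon coordinates are preserved exactly.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = _first_attr(exon, "transcript_id")
        if tid is None:
            raise ValueError(f"exon without transcript_id at {exon.seqid}:{exon.start}")
        rec = grouped.setdefault(
            tid,
            {
                "gene_id": _first_attr(exon, "gene_id", default=tid),
                "contig": exon.seqid,
                "strand": exon.strand,
                "biotype": _first_attr(
                    exon, "transcript_biotype", "gene_biotype",
                    default="protein_coding",
                ),
                "exons": [],
            },
        )
        rec["exons"].append((exon.start, exon.end))

    models = []
    for tid, rec in grouped.items():
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            contig=rec["contig"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"],
        )
        if model.is_intronless:
            log.warning("transcript %s is intronless", tid)
        models.append(model)
    if not models:
        raise ValueError(f"no transcripts with exons found in {path}")
    return models
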