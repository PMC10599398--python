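"""Deterministic synthetic testbed: toy genomes, gene models, planted variants.

Everything downstream of this module (distance binning, region
classification, metric engines, calibration, audits) is exercised on
fixtures generated here instead of downloaded datasets.  The generator
plants, by construction:

* multi-isoform genes with GT/AG intron boundaries, including an isoform
  whose extra internal exon makes a deep-intronic position of the reference
  isoform exonic in another transcript;
* cryptic splice events (pseudoexon-style cryptic exons with AG/GT cores)
  carrying positive variants of all six mechanism region categories, on
  both strands (the minus-strand gene is an exact mirror of the sense-axis
  layout, so strand handling is tested by construction);
* negative variants placed relative to annotated splice sites, including
  deep intronic SNVs that create the CAGGT acceptor / GGTAAG donor
  consensus at the core dinucleotide;
* per-tool scores drawn from class-conditional Beta distributions tuned to
  a target auROC, with missingness growing with intronic offset (emulating
  tools that do not score deep introns).

All outputs are reproducible from the spec seed and write as plain-text
FASTA / GTF / VCF / TSV / BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import beta as beta_fn

from .genome import (
    GenomeSequence,
    TranscriptModel,
    assign_bin,
    reverse_complement,
    splice_distance,
)
from .regions import (
    ACCEPTOR_CREATION_RULE,
    DONOR_CREATION_RULE,
    CrypticSpliceEvent,
    detect_created_splice_motif,
)

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# Score models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToolScoreModel:
    """Class-conditional Beta score model for one simulated predictor.

    Positive-class scores ~ Beta(s, 1) and negative-class ~ Beta(1, s) with
    the shape ``s`` solved numerically so that P(pos > neg) equals
    ``target_auroc`` (closed form: auROC(s) = 1 - s*B(s, s+1)).  Missingness
    is a monotone non-decreasing function of intronic offset:
    ``p_miss = clip(intercept + slope * log10(offset)/3, 0, 0.98)``.
    """

    name: str
    target_auroc: float = 0.9
    missing_intercept: float = 0.0
    missing_slope: float = 0.0
    reference_threshold: float = 0.5

    def shape(self) -> float:
        t = self.target_auroc
        if not 0.5 <= t < 1.0:
            raise ValueError(f"target auROC must be in [0.5, 1), got {t}")
        if t == 0.5:
            return 1.0
        return brentq(lambda s: (1.0 - s * beta_fn(s, s + 1.0)) - t, 1.0, 500.0)

    def missing_probability(self, offset: np.ndarray) -> np.ndarray:
        off = np.maximum(np.asarray(offset, dtype=float), 1.0)
        p = self.missing_intercept + self.missing_slope * np.log10(off) / 3.0
        return np.clip(p, 0.0, 0.98)


def analytic_auroc(shape: float) -> float:
    """P(Beta(s,1) > Beta(1,s)) in closed form."""
    return 1.0 - shape * beta_fn(shape, shape + 1.0)


def simulate_scores(
    labels: np.ndarray,
    offsets: np.ndarray,
    tools: list[ToolScoreModel],
    seed: int,
) -> pd.DataFrame:
    """One score column per tool; NaN marks a missing prediction."""
    labels = np.asarray(labels, dtype=bool)
    offsets = np.asarray(offsets, dtype=float)
    rng = np.random.default_rng(seed)
    out = {}
    for tool in tools:
        s = tool.shape()
        scores = np.where(
            labels,
            rng.beta(s, 1.0, size=len(labels)),
            rng.beta(1.0, s, size=len(labels)),
        )
        p_miss = tool.missing_probability(np.nan_to_num(offsets, nan=1.0))
        missing = rng.random(len(labels)) < p_miss
        scores[missing] = np.nan
        out[tool.name] = scores
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Fixture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic benchmark bundle."""

    seed: int = 0
    #: cryptic-event slots per gene; each slot carries one positive variant
    #: of each of the six categories (two genes -> 2*n_slots per category).
    n_slots: int = 30
    #: negatives planted per category per gene.
    n_negatives_per_gene: int = 30
    gc: float = 0.5
    exon_length: int = 200
    cryptic_exon_length: int = 80
    tools: tuple[ToolScoreModel, ...] = (
        ToolScoreModel("deepsplice", 0.95, 0.02, 0.05, 0.5),
        ToolScoreModel("midsplice", 0.75, 0.05, 0.45, 0.5),
        ToolScoreModel("shallowsplice", 0.55, 0.10, 0.80, 0.5),
    )


def simulate_contig(length: int, seed: int, gc: float = 0.5) -> str:
    """Random ACGT sequence with the given expected GC fraction."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# Gene layout on the sense axis
# ---------------------------------------------------------------------------

class _SenseLayout:
    """A gene built on a 1-based sense axis; mirrored later for minus strand.

    Stamped sequence regions are tracked so colliding plantings raise
    instead of silently overwriting each other.
    """

    def __init__(self, spec: FixtureSpec, seed: int):
        self.spec = spec
        el = spec.exon_length
        self.intron1_len = 7000
        self.intron2_len = spec.n_slots * 300 + 1200
        self.intron3_len = 500
        pad = 1000
        pos = pad + 1
        self.exons = []
        for intron_len in (self.intron1_len, self.intron2_len, self.intron3_len):
            self.exons.append((pos, pos + el - 1))
            pos = pos + el + intron_len
        self.exons.append((pos, pos + el - 1))
        self.length = pos + el - 1 + pad
        self.seq = list(simulate_contig(self.length, seed, spec.gc))
        self._stamped: list[tuple[int, int]] = []
        self._used_positions: set[int] = set()
        # annotated GT/AG intron boundaries
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            self.stamp(e1 + 1, "GT")
            self.stamp(s2 - 2, "AG")
        # the alternative isoform's extra exon inside intron 1
        i1s = self.exons[0][1] + 1
        self.alt_exon = (i1s + 2800, i1s + 2899)
        self.stamp(self.alt_exon[0] - 2, "AG")
        self.stamp(self.alt_exon[1] + 1, "GT")

    def stamp(self, start: int, motif: str) -> None:
        """Write ``motif`` at 1-based sense position ``start``."""
        end = start + len(motif) - 1
        for (s, e) in self._stamped:
            if start <= e and s <= end:
                raise ValueError(f"stamp collision at {start}-{end} vs {s}-{e}")
        self._stamped.append((start, end))
        self.seq[start - 1 : end] = list(motif)

    def base(self, pos: int) -> str:
        return self.seq[pos - 1]

    def claim(self, pos: int) -> int:
        if pos in self._used_positions:
            raise ValueError(f"variant position {pos} already used")
        self._used_positions.add(pos)
        return pos

    @property
    def intron2(self) -> tuple[int, int]:
        return (self.exons[1][1] + 1, self.exons[2][0] - 1)


_ALT_CYCLE = "ACGT"


def _snv_alt(ref: str, offset: int = 1) -> str:
    return _ALT_CYCLE[(_ALT_CYCLE.index(ref) + offset) % 4]


@dataclass
class _Planted:
    pos: int  # sense axis
    ref: str
    alt: str
    label: str
    category: str
    mechanism: str
    outcome_group: str
    event: dict | None  # sense-axis event geometry, or None for negatives


def _plant_slot(layout: _SenseLayout, slot_index: int, spec: FixtureSpec) -> list[_Planted]:
    """One cryptic-exon event slot with one positive variant per category."""
    b = layout.intron2[0] + 600 + slot_index * 300
    ce_len = spec.cryptic_exon_length
    ce = (b + 60, b + 60 + ce_len - 1)
    layout.stamp(ce[0] - 2, "AG")
    layout.stamp(ce[1] + 1, "GT")
    # alternate donor-event outcome so the audit has intron-retention truth
    donor_outcome = (
        "partial_intron_retention" if slot_index % 2 else "pseudoexon_activation"
    )
    acceptor_event = {
        "kind": "acceptor",
        "site": ce[0] - 2,
        "exon": ce,
        "outcome": "pseudoexon_activation",
    }
    donor_event = {"kind": "donor", "site": ce[1] + 1, "exon": ce, "outcome": donor_outcome}

    out = []
    # branchpoint: plant a YTNAY (CTGAC) with its adenine 20-40 bp upstream
    u_bp = 20 + (slot_index * 7) % 21
    pos = ce[0] - u_bp
    layout.stamp(pos - 3, "CTGAC")
    out.append(
        _Planted(layout.claim(pos), "A", "G", "positive", "branchpoint_associated",
                 "branchpoint", "pseudoexon_activation", acceptor_event)
    )
    # acceptor upstream (polypyrimidine-tract territory, offsets 4-17)
    u_au = 4 + (slot_index * 5) % 14
    pos = layout.claim(ce[0] - u_au)
    ref = layout.base(pos)
    out.append(
        _Planted(pos, ref, _snv_alt(ref), "positive", "acceptor_upstream",
                 "activates_cryptic_acceptor", "pseudoexon_activation", acceptor_event)
    )
    # new splice acceptor: at the AG (offset 1 = the G)
    pos = layout.claim(ce[0] - 1)
    out.append(
        _Planted(pos, "G", "C", "positive", "new_splice_acceptor",
                 "creates_new_splice_site", "pseudoexon_activation", acceptor_event)
    )
    # exonic-like: inside the cryptic exon
    pos = layout.claim(ce[0] + 10 + (slot_index * 3) % (ce_len - 20))
    ref = layout.base(pos)
    out.append(
        _Planted(pos, ref, _snv_alt(ref), "positive", "exonic_like",
                 "exonic_regulatory_within_pseudoexon", "pseudoexon_activation",
                 acceptor_event)
    )
    # new splice donor: at the GT (offset 1 = the G)
    pos = layout.claim(ce[1] + 1)
    out.append(
        _Planted(pos, "G", "C", "positive", "new_splice_donor",
                 "creates_new_splice_site", donor_outcome, donor_event)
    )
    # donor downstream: >2 bp past the cryptic donor
    d = 3 + (slot_index * 11) % 28
    pos = layout.claim(ce[1] + d)
    ref = layout.base(pos)
    out.append(
        _Planted(pos, ref, _snv_alt(ref), "positive", "donor_downstream",
                 "activates_cryptic_donor", donor_outcome, donor_event)
    )
    # deep-intronic motif-creation negatives parked at the slot tail
    layout.stamp(b + 200, "CATGT")
    out.append(
        _Planted(layout.claim(b + 202), "T", "G", "negative", "new_splice_acceptor",
                 "creates_new_splice_site", "pseudoexon_activation", None)
    )
    layout.stamp(b + 220, "GCTAAG")
    out.append(
        _Planted(layout.claim(b + 221), "C", "G", "negative", "new_splice_donor",
                 "creates_new_splice_site", "pseudoexon_activation", None)
    )
    return out


def _plant_negatives(layout: _SenseLayout, spec: FixtureSpec) -> list[_Planted]:
    """Splicing-neutral variants placed relative to annotated splice sites."""
    out = []
    introns = [
        (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(layout.exons, layout.exons[1:])
    ]
    n = spec.n_negatives_per_gene

    def _safe_alt(pos: int, ref: str) -> str:
        # pick an alt allele that does not, by chance, create the CAGGT /
        # GGTAAG splice-site consensus at its core (which would legitimately
        # reclassify the variant as a motif-creation record)
        flank = 8
        lo, hi = pos - flank, pos + flank
        ref_win = "".join(layout.seq[lo - 1 : hi])
        for k in (1, 2, 3):
            alt = _snv_alt(ref, k)
            alt_win = ref_win[:flank] + alt + ref_win[flank + 1 :]
            creates = any(
                detect_created_splice_motif(ref_win, alt_win, flank, rule).created
                for rule in (ACCEPTOR_CREATION_RULE, DONOR_CREATION_RULE)
            )
            if not creates:
                return alt
        raise ValueError(f"no safe alt allele at position {pos}")

    def add(pos, category):
        pos = layout.claim(pos)
        ref = layout.base(pos)
        out.append(
            _Planted(pos, ref, _safe_alt(pos, ref), "negative", category,
                     "branchpoint", "pseudoexon_activation", None)
        )

    # branchpoint window upstream of annotated acceptors (offsets 18-44)
    windows = [(e - u + 1) for (s, e) in (introns[0], introns[2]) for u in range(18, 45)]
    for pos in windows[:n]:
        add(pos, "branchpoint_associated")
    # acceptor-upstream: offsets 3-17 and 45-120 (outside the BP window)
    au_offsets = list(range(3, 18)) + list(range(45, 121))
    au_positions = [introns[0][1] - u + 1 for u in au_offsets] + [
        introns[2][1] - u + 1 for u in au_offsets[:10]
    ]
    for pos in au_positions[:n]:
        add(pos, "acceptor_upstream")
    # donor-downstream: offsets 3-150 past annotated donors
    dd_positions = [introns[0][0] + d - 1 for d in range(3, 153)]
    for pos in dd_positions[:n]:
        add(pos, "donor_downstream")
    # exonic controls inside annotated internal exons
    ex2, ex3 = layout.exons[1], layout.exons[2]
    el_positions = [ex2[0] + 10 + i for i in range(spec.exon_length - 30)] + [
        ex3[0] + 10 + i for i in range(spec.exon_length - 30)
    ]
    for pos in el_positions[:n]:
        add(pos, "exonic_like")
    return out


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    spec: FixtureSpec
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    variants: pd.DataFrame  # ground truth + per-tool scores
    events: dict[str, CrypticSpliceEvent]  # variant_id -> event
    junctions: list[tuple[str, int, int]]  # BED-style half-open intervals

    def reference_transcript(self, gene_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.gene_id == gene_id and t.transcript_id.endswith("T1"):
                return t
        raise KeyError(gene_id)


def _mirror(pos: int, length: int) -> int:
    return length - pos + 1


def build_gene(
    spec: FixtureSpec, contig: str, gene_id: str, strand: str, seed: int
) -> tuple[str, list[TranscriptModel], list[dict], list[tuple[str, int, int]]]:
    """Build one gene's contig sequence, transcripts, and planted variants."""
    layout = _SenseLayout(spec, seed)
    planted = []
    for i in range(spec.n_slots):
        planted.extend(_plant_slot(layout, i, spec))
    planted.extend(_plant_negatives(layout, spec))

    sense_seq = "".join(layout.seq)
    L = layout.length
    if strand == "+":
        seq = sense_seq
        g = lambda p: p
        interval = lambda s, e: (s, e)
    else:
        seq = reverse_complement(sense_seq)
        g = lambda p: _mirror(p, L)
        interval = lambda s, e: (_mirror(e, L), _mirror(s, L))

    exons = [interval(s, e) for s, e in layout.exons]
    t1 = TranscriptModel(f"{gene_id}-T1", gene_id, contig, strand, tuple(exons))
    alt_exons = sorted(exons + [interval(*layout.alt_exon)])
    t2 = TranscriptModel(f"{gene_id}-T2", gene_id, contig, strand, tuple(alt_exons))

    records = []
    for idx, p in enumerate(planted):
        ref = p.ref if strand == "+" else _COMP[p.ref]
        alt = p.alt if strand == "+" else _COMP[p.alt]
        event = None
        if p.event is not None:
            es, ee = interval(*p.event["exon"])
            event = {
                "kind": p.event["kind"],
                "site": g(p.event["site"]),
                "exon_start": es,
                "exon_end": ee,
                "outcome": p.event["outcome"],
            }
        records.append(
            {
                "variant_id": f"{gene_id}_{idx:04d}",
                "contig": contig,
                "pos": g(p.pos),
                "ref": ref,
                "alt": alt,
                "strand": strand,
                "gene_id": gene_id,
                "transcript_id": t1.transcript_id,
                "label": p.label,
                "category": p.category,
                "mechanism": p.mechanism,
                "outcome_group": p.outcome_group,
                "event": event,
            }
        )
    junctions = []
    for (s1, e1), (s2, _) in zip(
        sorted(exons), sorted(exons)[1:]
    ):  # annotated junction boundaries, BED half-open
        junctions.append((contig, e1, e1 + 2))
        junctions.append((contig, s2 - 3, s2 - 1))
    return seq, [t1, t2], records, junctions


def build_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Assemble the full two-gene (plus/minus strand) benchmark bundle."""
    seq_p, txs_p, rec_p, jx_p = build_gene(spec, "chrP", "GP", "+", spec.seed + 11)
    seq_m, txs_m, rec_m, jx_m = build_gene(spec, "chrM", "GM", "-", spec.seed + 23)
    # a small single-transcript gene for isoform-context edge cases
    single_seq = simulate_contig(3000, spec.seed + 37, spec.gc)
    single_seq = single_seq[:1000] + "GT" + single_seq[1002:1998] + "AG" + single_seq[2000:]
    t_single = TranscriptModel(
        "GS-T1", "GS", "chrS", "+", ((801, 1000), (2001, 2200))
    )

    genome = GenomeSequence({"chrP": seq_p, "chrM": seq_m, "chrS": single_seq})
    transcripts = txs_p + txs_m + [t_single]
    records = rec_p + rec_m

    frame = pd.DataFrame([{k: v for k, v in r.items() if k != "event"} for r in records])
    events = {}
    ev_cols = {"event_kind": [], "event_site": [], "event_exon_start": [], "event_exon_end": []}
    for r in records:
        ev = r["event"]
        if ev is None:
            for key in ev_cols:
                ev_cols[key].append(None)
        else:
            events[r["variant_id"]] = CrypticSpliceEvent(
                kind=ev["kind"],
                contig=r["contig"],
                strand=r["strand"],
                cryptic_site_position=ev["site"],
                cryptic_exon=(ev["exon_start"], ev["exon_end"]),
                outcome_group=ev["outcome"],
            )
            ev_cols["event_kind"].append(ev["kind"])
            ev_cols["event_site"].append(ev["site"])
            ev_cols["event_exon_start"].append(ev["exon_start"])
            ev_cols["event_exon_end"].append(ev["exon_end"])
    for key, vals in ev_cols.items():
        frame[key] = vals

    # intronic offsets/bins against the reference transcript
    tx_by_id = {t.transcript_id: t for t in transcripts}
    offsets, bins = [], []
    for _, row in frame.iterrows():
        tx = tx_by_id[row["transcript_id"]]
        if row["category"] == "exonic_like" and row["label"] == "negative":
            offsets.append(np.nan)
            bins.append("exonic")
            continue
        ctx = splice_distance(int(row["pos"]), tx)
        offsets.append(ctx.intronic_offset)
        bins.append(assign_bin(ctx.intronic_offset))
    frame["intronic_offset"] = offsets
    frame["bin"] = bins

    scores = simulate_scores(
        (frame["label"] == "positive").to_numpy(),
        frame["intronic_offset"].to_numpy(),
        list(spec.tools),
        seed=spec.seed + 101,
    )
    frame = pd.concat([frame.reset_index(drop=True), scores], axis=1)
    return FixtureBundle(
        spec=spec,
        genome=genome,
        transcripts=transcripts,
        variants=frame,
        events=events,
        junctions=jx_p + jx_m,
    )


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------

def write_fasta(genome: GenomeSequence, path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.contigs):
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(transcripts: list[TranscriptModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for t in sorted(transcripts, key=lambda t: (t.contig, t.start, t.transcript_id)):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            fh.write(
                f"{t.contig}\tintronbench\ttranscript\t{t.start}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\tintronbench\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_vcf(bundle: FixtureBundle, path: Path) -> None:
    tools = [t.name for t in bundle.spec.tools]
    frame = bundle.variants.sort_values(["contig", "pos"]).reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in sorted(bundle.genome.contigs):
            fh.write(f"##contig=<ID={name},length={len(bundle.genome.contigs[name])}>\n")
        fh.write('##INFO=<ID=LABEL,Number=1,Type=String,Description="Class label">\n')
        for tool in tools:
            fh.write(
                f'##INFO=<ID={tool},Number=1,Type=Float,Description="Simulated {tool} score">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in frame.iterrows():
            info = [f"LABEL={row['label']}"]
            for tool in tools:
                if pd.notna(row[tool]):
                    info.append(f"{tool}={row[tool]:.6f}")
            fh.write(
                f"{row['contig']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t{';'.join(info)}\n"
            )


def write_truth(bundle: FixtureBundle, path: Path) -> None:
    cols = [
        "variant_id", "contig", "pos", "ref", "alt", "strand", "gene_id",
        "transcript_id", "label", "category", "mechanism", "outcome_group",
        "event_kind", "event_site", "event_exon_start", "event_exon_end",
        "intronic_offset", "bin",
    ] + [t.name for t in bundle.spec.tools]
    bundle.variants[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_junctions(bundle: FixtureBundle, path: Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in sorted(bundle.junctions):
            fh.write(f"{contig}\t{start}\t{end}\n")


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the complete bundle directory; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "vcf": outdir / "variants.vcf",
        "truth": outdir / "truth.tsv",
        "junctions": outdir / "junctions.bed",
    }
    write_fasta(bundle.genome, paths["fasta"])
    write_gtf(bundle.transcripts, paths["gtf"])
    write_vcf(bundle, paths["vcf"])
    write_truth(bundle, paths["truth"])
    write_junctions(bundle, paths["junctions"])
    return paths
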