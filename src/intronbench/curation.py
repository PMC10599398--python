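"""Curation rules that turn annotated clinical variant records into benchmark sets.

The pipeline mirrors standard clinical-archive curation for an intronic
benchmark: keep only confidently asserted pathogenic/benign records, keep
only variants intronic in a protein-coding transcript with no exonic
annotation in any other gene (rescuing records whose picked consequence is
outside the gene body but that carry an intronic molecular-consequence
ontology term), cap the benign class to keep the class imbalance workable,
and assign each variant to a major mechanistic group (pseudoexon activation
vs partial intron retention).

Every filter reports its drop counts so dataset audits can reconstruct the
funnel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import SpliceSiteContext

log = logging.getLogger(__name__)

POSITIVE_TERMS = {"pathogenic", "likely_pathogenic"}
NEGATIVE_TERMS = {"benign", "likely_benign"}

#: ClinVar review-status strings -> confidence stars.
REVIEW_STATUS_STARS = {
    "practice_guideline": 4,
    "reviewed_by_expert_panel": 3,
    "criteria_provided,_multiple_submitters,_no_conflicts": 2,
    "criteria_provided,_conflicting_interpretations": 1,
    "criteria_provided,_single_submitter": 1,
    "no_assertion_criteria_provided": 0,
    "no_assertion_provided": 0,
    "no_interpretation_for_the_single_variant": 0,
}

#: Picked consequences outside the gene body that may be rescued by MC terms.
OUTSIDE_GENE_CONSEQUENCES = {
    "TF_binding_site_variant",
    "downstream_gene_variant",
    "upstream_gene_variant",
    "regulatory_region_variant",
}

INTRONIC_MC_TERMS = {"intron_variant", "SO:0001627"}


@dataclass(frozen=True)
class TranscriptAnnotation:
    gene_id: str
    transcript_id: str
    biotype: str
    is_intronic: bool
    is_exonic: bool
    consequence_terms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ClinicalRecord:
    contig: str
    pos: int
    ref: str
    alt: str
    clinical_significance: str
    review_stars: int
    annotations: tuple[TranscriptAnnotation, ...] = ()
    mc_terms: frozenset[str] = frozenset()
    picked_consequence: str = ""

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref/alt must be non-empty")
        if not (0 <= self.review_stars <= 4):
            raise ValueError(f"review stars {self.review_stars} outside 0-4")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class LabeledVariant:
    contig: str
    pos: int
    ref: str
    alt: str
    label: str  # positive | negative
    review_stars: int = 0
    major_group: str = "unassigned"
    source: str = ""

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


def stars_from_review_status(status: str) -> int:
    """Map a ClinVar CLNREVSTAT string to its confidence-star count."""
    key = status.strip().lower().replace(" ", "_")
    if key not in REVIEW_STATUS_STARS:
        raise KeyError(f"unknown review status {status!r}")
    return REVIEW_STATUS_STARS[key]


def _significance_terms(value: str) -> set[str]:
    # ClinVar dialects join multi-valued significance on "/" or ","
    parts = value.replace("/", ",").split(",")
    return {p.strip().lower() for p in parts if p.strip()}


def filter_significance(
    records: Iterable[ClinicalRecord],
) -> tuple[list[tuple[ClinicalRecord, str]], dict[str, int]]:
    """Label records pathogenic->positive, benign->negative; drop the rest.

    Multi-valued significance fields are split on "/" and ","; any kept term
    suffices (matched case-insensitively).  Returns (record, label) pairs
    plus drop accounting.
    """
    kept, dropped = [], {"dropped_other_significance": 0, "dropped_conflicting": 0}
    for rec in records:
        terms = _significance_terms(rec.clinical_significance)
        pos = bool(terms & POSITIVE_TERMS)
        neg = bool(terms & NEGATIVE_TERMS)
        if pos and neg:
            dropped["dropped_conflicting"] += 1
        elif pos:
            kept.append((rec, "positive"))
        elif neg:
            kept.append((rec, "negative"))
        else:
            dropped["dropped_other_significance"] += 1
    return kept, dropped


def filter_stars(
    records: Iterable[ClinicalRecord], min_stars: int = 1
) -> tuple[list[ClinicalRecord], dict[str, int]]:
    """Keep records with at least ``min_stars`` confidence stars."""
    kept, n_dropped = [], 0
    for rec in records:
        if rec.review_stars >= min_stars:
            kept.append(rec)
        else:
            n_dropped += 1
    return kept, {"dropped_low_stars": n_dropped}


def select_intronic(
    records: Iterable[ClinicalRecord],
) -> tuple[list[ClinicalRecord], dict[str, int]]:
    """Keep variants intronic in a protein-coding transcript.

    A record passes when it has >= 1 intronic protein-coding annotation and
    no exonic annotation in any *other* gene.  Records whose picked
    consequence is outside the gene body are rescued when their MC ontology
    terms include an intronic term.  Records with no annotations at all are
    dropped with a warning.
    """
    kept = []
    dropped = {
        "dropped_no_annotation": 0,
        "dropped_not_intronic": 0,
        "dropped_exonic_other_gene": 0,
    }
    for rec in records:
        if not rec.annotations:
            if rec.picked_consequence in OUTSIDE_GENE_CONSEQUENCES and (
                rec.mc_terms & INTRONIC_MC_TERMS
            ):
                kept.append(rec)
                continue
            log.warning("record %s has no annotations; dropped", rec.key)
            dropped["dropped_no_annotation"] += 1
            continue
        intronic_pc = [
            a
            for a in rec.annotations
            if a.is_intronic and a.biotype == "protein_coding"
        ]
        if not intronic_pc:
            if rec.picked_consequence in OUTSIDE_GENE_CONSEQUENCES and (
                rec.mc_terms & INTRONIC_MC_TERMS
            ):
                kept.append(rec)
            else:
                dropped["dropped_not_intronic"] += 1
            continue
        intronic_genes = {a.gene_id for a in intronic_pc}
        exonic_other = any(
            a.is_exonic and a.gene_id not in intronic_genes for a in rec.annotations
        )
        if exonic_other:
            dropped["dropped_exonic_other_gene"] += 1
            continue
        kept.append(rec)
    return kept, dropped


def cap_class(
    variants: Sequence[LabeledVariant],
    label: str = "negative",
    cap: int = 50_000,
    seed: int = 0,
    high_confidence_stars: int = 2,
) -> list[LabeledVariant]:
    """Cap one class at ``cap`` records, preferring high-confidence entries.

    All capped-class records with >= ``high_confidence_stars`` stars are
    kept; the remainder of the budget is filled with a seeded uniform random
    sample of the lower-star records.  The other class passes through
    untouched and input order is preserved in the output.
    """
    in_class = [v for v in variants if v.label == label]
    if len(in_class) <= cap:
        return list(variants)
    high = [v for v in in_class if v.review_stars >= high_confidence_stars]
    low = [v for v in in_class if v.review_stars < high_confidence_stars]
    if len(high) >= cap:
        log.warning(
            "cap %d below the %d high-confidence records; keeping all of them",
            cap, len(high),
        )
        chosen = set(id(v) for v in high)
    else:
        rng = np.random.default_rng(seed)
        n_fill = cap - len(high)
        idx = rng.choice(len(low), size=n_fill, replace=False)
        chosen = set(id(v) for v in high) | {id(low[i]) for i in idx}
    return [v for v in variants if v.label != label or id(v) in chosen]


def assign_major_group(
    variant: LabeledVariant,
    outcome_annotation: Sequence[str] | None = None,
    splice_context: SpliceSiteContext | None = None,
    acceptor_threshold: int = 100,
    donor_threshold: int = 20,
) -> str:
    """Major mechanistic group of a variant.

    Positives follow their experimental outcome annotation; a variant whose
    outcomes include pseudoexon activation goes to that group even when
    partial intron retention co-occurs.  Negatives have no observed outcome,
    so they are split by geometry: within ``acceptor_threshold`` bp of an
    annotated acceptor or ``donor_threshold`` bp of an annotated donor they
    mimic partial-intron-retention positives, deeper ones mimic
    pseudoexon-activation positives.
    """
    if variant.label == "positive":
        if not outcome_annotation:
            return "unassigned"
        outcomes = {o.strip().lower().replace(" ", "_") for o in outcome_annotation}
        if any("pseudoexon" in o for o in outcomes):
            return "pseudoexon_activation"
        if any("intron_retention" in o for o in outcomes):
            return "partial_intron_retention"
        return "unassigned"
    if splice_context is None:
        raise ValueError("negative variants require a splice-site context")
    threshold = (
        acceptor_threshold
        if splice_context.nearest_site_kind == "acceptor"
        else donor_threshold
    )
    if splice_context.intronic_offset <= threshold:
        return "partial_intron_retention"
    return "pseudoexon_activation"
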