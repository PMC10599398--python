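"""Quantitative auditing of tools' mechanistic interpretations.

Some splicing predictors explain *why* they call a variant deleterious
(branchpoint disruption, creation of a splice site, ...).  Given ground
truth about the actual molecular mechanism, each explanation receives one
of four verdicts: ``correct``, ``incorrect``, ``not_informative`` (the tool
said something non-mechanistic) or ``no_interpretation`` (the tool said
nothing usable).  Summaries report the fraction of each verdict per tool.

Three explanation dialects are audited:

* SPiP emits pipe-delimited records whose third field is a short
  interpretation tag ("Alter BP", "Alter by create new Exon", ...);
* SQUIRLS explanations arrive pre-structured (its HTML report is inspected
  upstream and transcribed to a small enum);
* SpliceVault returns a ranked list of up to 10 misplicing events, judged
  by whether the experimentally observed cryptic event appears within the
  top-k (default 4) ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

MECHANISMS = (
    "creates_new_splice_site",
    "activates_cryptic_acceptor",
    "activates_cryptic_donor",
    "branchpoint",
    "polypyrimidine_tract",
    "exonic_regulatory_within_pseudoexon",
)

OUTCOME_GROUPS = ("pseudoexon_activation", "partial_intron_retention", "exon_skipping")

VERDICTS = ("correct", "incorrect", "not_informative", "no_interpretation")

SQUIRLS_INTERPRETATIONS = (
    "new_cryptic_acceptor",
    "new_cryptic_donor",
    "activate_cryptic_acceptor",
    "activate_cryptic_donor",
    "not_informative",
    "no_interpretation",
)


@dataclass(frozen=True)
class MechanismAnnotation:
    """Ground truth for one variant: mechanism, splicing outcome, region."""

    variant_key: str
    mechanism: str
    outcome_group: str
    region_category: str

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.outcome_group not in OUTCOME_GROUPS:
            raise ValueError(f"unknown outcome group {self.outcome_group!r}")


@dataclass(frozen=True)
class AuditVerdict:
    value: str
    rationale: str = ""

    def __post_init__(self):
        if self.value not in VERDICTS:
            raise ValueError(f"unknown verdict {self.value!r}")


# ---------------------------------------------------------------------------
# SPiP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpipRecord:
    interpretation_tag: str
    confidence_interval: str = ""
    score: float = float("nan")


def parse_spip(raw: str) -> SpipRecord:
    """Extract (tag, CI, score) from a pipe-delimited SPiP prediction string.

    The interpretation tag, confidence interval, and score are the third,
    fourth, and fifth pipe-separated fields.
    """
    fields = raw.split("|")
    if len(fields) < 5:
        raise ValueError(f"unparseable SPiP record ({len(fields)} fields): {raw!r}")
    try:
        score = float(fields[4])
    except ValueError as exc:
        raise ValueError(f"unparseable SPiP score field: {fields[4]!r}") from exc
    return SpipRecord(fields[2].strip(), fields[3].strip(), score)


_SPIP_NEW_SITE_MECHANISMS = {
    "creates_new_splice_site",
    "activates_cryptic_acceptor",
    "activates_cryptic_donor",
}


def audit_spip(record: SpipRecord, truth: MechanismAnnotation) -> AuditVerdict:
    """Verdict for one SPiP interpretation tag against ground truth."""
    tag = record.interpretation_tag
    if tag == "NTR":
        return AuditVerdict("no_interpretation", "NTR tag: no mechanistic call")
    if tag == "Alter by complex event":
        return AuditVerdict("not_informative", "complex event: no specific mechanism")
    if tag == "Alter BP":
        ok = truth.mechanism == "branchpoint"
    elif tag == "Alter by create new Exon":
        ok = truth.outcome_group == "pseudoexon_activation"
    elif tag == "Alter by create New splice site":
        # correct regardless of pseudoexon vs intron-retention outcome
        ok = truth.mechanism in _SPIP_NEW_SITE_MECHANISMS
    elif tag == "Alter ESR":
        ok = truth.mechanism == "exonic_regulatory_within_pseudoexon"
    elif tag == "Alter by MES (Poly TC)":
        ok = truth.mechanism == "polypyrimidine_tract"
    else:
        import logging

        logging.getLogger(__name__).warning("unknown SPiP tag %r", tag)
        return AuditVerdict("not_informative", f"unknown tag {tag!r}")
    return AuditVerdict(
        "correct" if ok else "incorrect",
        f"tag {tag!r} vs mechanism {truth.mechanism}/{truth.outcome_group}",
    )


# ---------------------------------------------------------------------------
# SQUIRLS
# ---------------------------------------------------------------------------

def audit_squirls(interpretation: str, truth: MechanismAnnotation) -> AuditVerdict:
    """Verdict for a structured SQUIRLS interpretation against ground truth.

    A "new cryptic" call is correct only for a variant that itself creates a
    splice site on the matching side; an "activate cryptic acceptor" call
    must additionally not be branchpoint-associated truth.
    """
    if interpretation not in SQUIRLS_INTERPRETATIONS:
        raise ValueError(f"unknown SQUIRLS interpretation {interpretation!r}")
    if interpretation in ("not_informative", "no_interpretation"):
        return AuditVerdict(interpretation, "pass-through")
    if interpretation == "new_cryptic_acceptor":
        ok = (
            truth.mechanism == "creates_new_splice_site"
            and truth.region_category == "new_splice_acceptor"
        )
    elif interpretation == "new_cryptic_donor":
        ok = (
            truth.mechanism == "creates_new_splice_site"
            and truth.region_category == "new_splice_donor"
        )
    elif interpretation == "activate_cryptic_acceptor":
        ok = (
            truth.mechanism == "activates_cryptic_acceptor"
            and truth.mechanism != "branchpoint"
            and truth.region_category != "branchpoint_associated"
        )
    else:  # activate_cryptic_donor
        ok = truth.mechanism == "activates_cryptic_donor"
    return AuditVerdict(
        "correct" if ok else "incorrect",
        f"{interpretation} vs {truth.mechanism}/{truth.region_category}",
    )


# ---------------------------------------------------------------------------
# SpliceVault
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpliceVaultEvent:
    rank: int
    kind: str  # acceptor | donor
    contig: str
    position: int


@dataclass(frozen=True)
class SpliceVaultEvents:
    events: tuple[SpliceVaultEvent, ...]

    def __post_init__(self):
        ranks = [e.rank for e in self.events]
        if len(set(ranks)) != len(ranks):
            raise ValueError("duplicate ranks in SpliceVault event list")
        if any(r < 1 or r > 10 for r in ranks):
            raise ValueError("SpliceVault ranks must lie in 1..10")


class PseudoexonExclusionError(ValueError):
    """SpliceVault cannot assess pseudoexon-activation outcomes."""


def audit_splicevault(
    events: SpliceVaultEvents,
    truth: MechanismAnnotation,
    observed_kind: str,
    observed_contig: str,
    observed_position: int,
    top_k: int = 4,
    tolerance: int = 0,
) -> AuditVerdict:
    """Verdict for a SpliceVault ranked event list against the observed event.

    A matching event (same kind and contig, position within ``tolerance``)
    at rank <= ``top_k`` is correct; at a lower rank (top_k+1..10) incorrect;
    absent from the list entirely -> no_interpretation.  Pseudoexon-
    activating variants must be excluded upstream.
    """
    if truth.outcome_group == "pseudoexon_activation":
        raise PseudoexonExclusionError(
            "pseudoexon-activating variants are outside SpliceVault's scope"
        )
    best_rank = None
    for ev in events.events:
        if (
            ev.kind == observed_kind
            and ev.contig == observed_contig
            and abs(ev.position - observed_position) <= tolerance
        ):
            if best_rank is None or ev.rank < best_rank:
                best_rank = ev.rank
    if best_rank is None:
        return AuditVerdict("no_interpretation", "observed event not in top 10")
    if best_rank <= top_k:
        return AuditVerdict("correct", f"observed event at rank {best_rank}")
    return AuditVerdict("incorrect", f"observed event only at rank {best_rank}")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_audit(verdicts_per_tool: dict[str, Sequence[AuditVerdict]]):
    """Per-tool verdict counts and fractions (fractions sum to 1 per tool)."""
    import pandas as pd

    rows = []
    for tool, verdicts in verdicts_per_tool.items():
        if not verdicts:
            raise ValueError(f"tool {tool!r}: no verdicts to summarize")
        n = len(verdicts)
        for v in VERDICTS:
            count = sum(1 for x in verdicts if x.value == v)
            rows.append(
                {"tool": tool, "verdict": v, "count": count, "fraction": count / n}
            )
    return pd.DataFrame(rows)
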