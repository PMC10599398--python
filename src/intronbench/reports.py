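"""Run orchestration: tying genome, metrics, calibration and audits together.

Functions here are the engine behind the CLI commands; each takes in-memory
objects (DataFrames, transcript lists) and returns tidy DataFrames.  File
writing goes through :func:`write_table`, which prepends a reproducibility
header (version, seed, config hash) so identical runs produce byte-identical
primary outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audit import (
    AuditVerdict,
    MechanismAnnotation,
    SpipRecord,
    SpliceVaultEvent,
    SpliceVaultEvents,
    audit_spip,
    audit_splicevault,
    audit_squirls,
    parse_spip,
    summarize_audit,
)
from .calibration import DEFAULT_BETAS, bootstrap_calibrate
from .genome import (
    DEFAULT_BINS,
    DistanceBins,
    GenomeSequence,
    TranscriptModel,
    assign_bin,
    sense_window,
    splice_distance,
)
from .metrics import (
    ToolConfig,
    evaluate_tool,
    full_intron_tools,
    per_bin_evaluate,
    rank_variants,
    roc_and_pr,
)
from .regions import (
    ACCEPTOR_CREATION_RULE,
    DONOR_CREATION_RULE,
    CrypticSpliceEvent,
    classify_negative,
    classify_positive,
    detect_created_splice_motif,
)

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# Config and IO plumbing
# ---------------------------------------------------------------------------

def load_tool_registry(path: str | Path) -> list[ToolConfig]:
    """Tool registry YAML: a list of {name, score_key, direction, reference_threshold}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    tools = []
    for entry in raw["tools"] if isinstance(raw, dict) else raw:
        tools.append(
            ToolConfig(
                name=entry["name"],
                score_key=entry.get("score_key", entry["name"]),
                direction=entry.get("direction", "higher_deleterious"),
                reference_threshold=float(entry.get("reference_threshold", 0.5)),
            )
        )
    return tools


def config_hash(params: dict) -> str:
    canon = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_table(
    frame: pd.DataFrame, path: str | Path, seed: int | None, params: dict
) -> Path:
    """Write a TSV with a reproducibility header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# intronbench {__version__}; seed={seed}; config={config_hash(params)}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def write_manifest(outdir: str | Path, command: str, seed: int | None, params: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(params),
        "parameters": {k: str(v) for k, v in sorted(params.items())},
    }
    path = outdir / f"{command}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_scores_vcf(path: str | Path, tools: Sequence[ToolConfig]) -> pd.DataFrame:
    """Variant table from a VCF with per-tool scores in INFO fields."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        row = {
            "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
            "contig": rec.CHROM,
            "pos": rec.POS,
            "ref": rec.REF,
            "alt": rec.ALT[0] if rec.ALT else ".",
        }
        label = rec.INFO.get("LABEL")
        if label is not None:
            row["label"] = label
        for tool in tools:
            val = rec.INFO.get(tool.score_key)
            row[tool.score_key] = float(val) if val is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _binary_labels(frame: pd.DataFrame, label_col: str = "label") -> np.ndarray:
    lab = frame[label_col]
    if lab.dtype == object:
        return (lab == "positive").to_numpy()
    return lab.astype(bool).to_numpy()


# ---------------------------------------------------------------------------
# benchmark / bins
# ---------------------------------------------------------------------------

def run_benchmark(
    frame: pd.DataFrame,
    tools: Sequence[ToolConfig],
    balanced: bool = True,
    thresholds: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tool metrics at (reference or supplied) thresholds, plus curves.

    Tools are ranked by coverage-weighted normalized MCC on balanced data
    and by coverage-weighted F1 on unbalanced data.
    """
    labels = _binary_labels(frame)
    thresholds = thresholds or {}
    rows, curve_frames = [], []
    for tool in tools:
        scores = frame[tool.score_key].to_numpy(dtype=float)
        t = thresholds.get(tool.name, tool.reference_threshold)
        ms = evaluate_tool(scores, labels, tool, t)
        rows.append({"tool": tool.name, "threshold": t, "n": len(frame), **ms.as_dict()})
        roc, pr, _, _ = roc_and_pr(scores, labels, tool.direction)
        for curve in (roc, pr):
            if curve is not None:
                curve_frames.append(curve.to_frame().assign(tool=tool.name))
    metrics = pd.DataFrame(rows)
    rank_metric = "weighted_normalized_mcc" if balanced else "weighted_f1"
    metrics = metrics.sort_values(
        [rank_metric, "tool"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    metrics.insert(1, "rank", np.arange(1, len(metrics) + 1))
    metrics.insert(2, "ranked_by", rank_metric)
    curves = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["threshold", "x", "y", "kind", "tool"])
    )
    return metrics, curves


def run_bins(
    frame: pd.DataFrame,
    tools: Sequence[ToolConfig],
    bins: DistanceBins = DEFAULT_BINS,
    min_scored_fraction: float = 0.9,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-(tool, bin) metrics and the subset of tools scoring whole introns."""
    sub = frame[frame["bin"].isin(bins.labels)].copy()
    sub["__label"] = _binary_labels(sub)
    table = per_bin_evaluate(sub, tools, bins.labels, label_col="__label")
    full = full_intron_tools(sub, tools, min_scored_fraction)
    return table, full


def run_interrogate(
    frame: pd.DataFrame,
    tools: Sequence[ToolConfig],
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    return rank_variants(frame, tools, thresholds)


# ---------------------------------------------------------------------------
# calibrate
# ---------------------------------------------------------------------------

def run_calibrate(
    frame: pd.DataFrame,
    tools: Sequence[ToolConfig],
    betas: Sequence[float] = DEFAULT_BETAS,
    n_boot: int = 1000,
    seed: int = 0,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Recalibrated threshold per (tool, beta) with bootstrap summaries."""
    labels = _binary_labels(frame)
    rows = []
    for tool in tools:
        scores = tool.transform(frame[tool.score_key].to_numpy(dtype=float))
        result = bootstrap_calibrate(
            scores, labels, betas=tuple(betas), n_boot=n_boot, seed=seed, n_grid=n_grid
        )
        boot = {b.beta: b for b in result.bootstrap}
        for point in result.point:
            b = boot[point.beta]
            rows.append(
                {
                    "tool": tool.name,
                    "beta": point.beta,
                    "best_threshold": point.best_threshold,
                    "best_fbeta": point.best_fbeta,
                    "bootstrap_mean_threshold": b.mean_threshold,
                    "ci_low": b.ci_low,
                    "ci_high": b.ci_high,
                    "n_boot": b.n_boot,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regions: classify a ground-truth variant table
# ---------------------------------------------------------------------------

def variant_sense_windows(
    genome: GenomeSequence,
    contig: str,
    strand: str,
    pos: int,
    ref: str,
    alt: str,
    flank: int = 8,
) -> tuple[str, str, int]:
    """(ref_window, alt_window, center_index) on the transcribed strand."""
    ref_win = sense_window(genome, contig, strand, pos, flank)
    ref_base = ref if strand == "+" else _COMP[ref]
    alt_base = alt if strand == "+" else _COMP[alt]
    if ref_win[flank] != ref_base:
        raise ValueError(
            f"reference mismatch at {contig}:{pos}: genome has {ref_win[flank]}, "
            f"variant says {ref_base}"
        )
    alt_win = ref_win[:flank] + alt_base + ref_win[flank + 1 :]
    return ref_win, alt_win, flank


def classify_truth_frame(
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    frame: pd.DataFrame,
    flank: int = 8,
) -> pd.DataFrame:
    """Derive a region category for every variant in a ground-truth table.

    Positives are classified against their cryptic splice event; negatives
    first through the splice-motif-creation detectors, then by annotated-
    site geometry (exonic positions become exonic-like controls).  Returns
    the frame with ``derived_category`` (and the motif-creation evidence).
    """
    tx_by_id = {t.transcript_id: t for t in transcripts}
    derived, evidence = [], []
    for _, row in frame.iterrows():
        strand = row["strand"]
        tx = tx_by_id[row["transcript_id"]]
        ref_win, alt_win, center = variant_sense_windows(
            genome, row["contig"], strand, int(row["pos"]), row["ref"], row["alt"], flank
        )
        if row["label"] == "positive":
            event = CrypticSpliceEvent(
                kind=row["event_kind"],
                contig=row["contig"],
                strand=strand,
                cryptic_site_position=int(row["event_site"]),
                cryptic_exon=(int(row["event_exon_start"]), int(row["event_exon_end"])),
                outcome_group=row["outcome_group"],
            )
            derived.append(
                classify_positive(int(row["pos"]), ref_win, alt_win, center, event)
            )
            evidence.append("")
            continue
        # negatives: motif creation first, then annotated-site geometry
        acc = detect_created_splice_motif(ref_win, alt_win, center, ACCEPTOR_CREATION_RULE)
        don = detect_created_splice_motif(ref_win, alt_win, center, DONOR_CREATION_RULE)
        if acc.created:
            derived.append("new_splice_acceptor")
            evidence.append(f"creates {ACCEPTOR_CREATION_RULE.motif}")
        elif don.created:
            derived.append("new_splice_donor")
            evidence.append(f"creates {DONOR_CREATION_RULE.motif}")
        else:
            exonic = tx.is_exonic(int(row["pos"]))
            derived.append(
                classify_negative(int(row["pos"]), tx, is_exonic_control=exonic)
            )
            evidence.append("exonic control" if exonic else "")
    out = frame.copy()
    out["derived_category"] = derived
    out["evidence"] = evidence
    return out


# ---------------------------------------------------------------------------
# audit orchestration
# ---------------------------------------------------------------------------

def run_audit(
    truth: pd.DataFrame,
    interpretations: pd.DataFrame,
    splicevault_events: pd.DataFrame | None = None,
    top_k: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Audit per-variant interpretations against mechanism ground truth.

    ``interpretations`` columns: variant_id, tool (spip|squirls),
    interpretation (raw SPiP pipe string, or the structured SQUIRLS value).
    ``splicevault_events`` columns: variant_id, rank, kind, contig, position.
    """
    truth_by_id = {}
    for _, row in truth.iterrows():
        truth_by_id[row["variant_id"]] = MechanismAnnotation(
            variant_key=row["variant_id"],
            mechanism=row["mechanism"],
            outcome_group=row["outcome_group"],
            region_category=row["category"],
        )
    verdict_rows = []
    per_tool: dict[str, list[AuditVerdict]] = {}
    for _, row in interpretations.iterrows():
        vid, tool = row["variant_id"], row["tool"]
        if vid not in truth_by_id:
            log.warning("no ground truth for %s; skipped", vid)
            continue
        t = truth_by_id[vid]
        if tool == "spip":
            raw = row["interpretation"]
            record = parse_spip(raw) if "|" in raw else SpipRecord(raw)
            verdict = audit_spip(record, t)
        elif tool == "squirls":
            verdict = audit_squirls(row["interpretation"], t)
        else:
            raise ValueError(f"unknown interpretation tool {tool!r}")
        per_tool.setdefault(tool, []).append(verdict)
        verdict_rows.append(
            {"variant_id": vid, "tool": tool, "verdict": verdict.value,
             "rationale": verdict.rationale}
        )
    if splicevault_events is not None and len(splicevault_events):
        for vid, group in splicevault_events.groupby("variant_id"):
            if vid not in truth_by_id:
                log.warning("no ground truth for %s; skipped", vid)
                continue
            t = truth_by_id[vid]
            row0 = truth[truth["variant_id"] == vid].iloc[0]
            events = SpliceVaultEvents(
                tuple(
                    SpliceVaultEvent(int(r["rank"]), r["kind"], r["contig"], int(r["position"]))
                    for _, r in group.iterrows()
                )
            )
            verdict = audit_splicevault(
                events, t,
                observed_kind=row0["event_kind"],
                observed_contig=row0["contig"],
                observed_position=int(row0["event_site"]),
                top_k=top_k,
            )
            per_tool.setdefault("splicevault", []).append(verdict)
            verdict_rows.append(
                {"variant_id": vid, "tool": "splicevault", "verdict": verdict.value,
                 "rationale": verdict.rationale}
            )
    verdicts = pd.DataFrame(verdict_rows)
    summary = summarize_audit(per_tool) if per_tool else pd.DataFrame()
    return verdicts, summary
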