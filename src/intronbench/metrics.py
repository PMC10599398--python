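"""Confusion-matrix metrics with prediction-coverage weighting.

Tools that do not score deep in the introns leave variants without
predictions.  Excluding those variants from the confusion matrix would
silently flatter low-coverage tools, so every scalar metric here comes in a
coverage-weighted companion:

    coverage            = scored / total
    weighted F1         = coverage * F1
    normalized MCC      = (MCC + 1) / 2            (range [0, 1])
    weighted norm. MCC  = coverage * normalized MCC

Predictions are positive on strict ``score > threshold`` (thresholds are
published as ">x" cutoffs); tools whose score is symmetric around zero use
``direction="absolute_value"`` and are compared as ``|score| > threshold``.
Missing scores (NaN) never enter confusion counts or curves but always
count toward the coverage denominator.  Any 0/0 metric ratio is defined as
0 so rankings remain total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ToolConfig:
    """Registry entry for one predictor: where its score lives and how to read it."""

    name: str
    score_key: str
    direction: str = "higher_deleterious"  # or "absolute_value"
    reference_threshold: float = 0.5

    def __post_init__(self):
        if self.direction not in ("higher_deleterious", "absolute_value"):
            raise ValueError(f"bad direction {self.direction!r}")

    def transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return np.abs(scores) if self.direction == "absolute_value" else scores


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    n_missing: int = 0

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn + self.n_missing

    @property
    def n_scored(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float
    coverage: float
    weighted_f1: float
    mcc: float
    normalized_mcc: float
    weighted_normalized_mcc: float
    auroc: float | None = None
    auprc: float | None = None

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "coverage": self.coverage,
            "weighted_f1": self.weighted_f1,
            "mcc": self.mcc,
            "normalized_mcc": self.normalized_mcc,
            "weighted_normalized_mcc": self.weighted_normalized_mcc,
            "auroc": self.auroc,
            "auprc": self.auprc,
        }


def _ratio(num: float, den: float) -> float:
    """num/den with the 0/0 -> 0 convention."""
    return num / den if den else 0.0


def apply_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    tool: ToolConfig,
    threshold: float | None = None,
) -> ConfusionCounts:
    """Confusion counts at a decision threshold (strict ``>``); NaN = missing."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    t = tool.reference_threshold if threshold is None else threshold
    transformed = tool.transform(scores)
    scored = ~np.isnan(transformed)
    if not scored.any():
        log.warning("tool %s: no scored variants", tool.name)
    pred = np.zeros_like(labels)
    pred[scored] = transformed[scored] > t
    tp = int(np.sum(scored & labels & pred))
    fp = int(np.sum(scored & ~labels & pred))
    fn = int(np.sum(scored & labels & ~pred))
    tn = int(np.sum(scored & ~labels & ~pred))
    return ConfusionCounts(tp, fp, fn, tn, n_missing=int(np.sum(~scored)))


def metric_set(counts: ConfusionCounts) -> MetricSet:
    """Scalar metrics from confusion counts (curve areas not included)."""
    if counts.n_total == 0:
        raise ValueError("empty dataset: n_total == 0")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = _ratio(2 * precision * recall, precision + recall)
    coverage = counts.n_scored / counts.n_total
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, denom)
    normalized_mcc = (mcc + 1.0) / 2.0
    return MetricSet(
        precision=precision,
        recall=recall,
        f1=f1,
        coverage=coverage,
        weighted_f1=coverage * f1,
        mcc=mcc,
        normalized_mcc=normalized_mcc,
        weighted_normalized_mcc=coverage * normalized_mcc,
    )


def evaluate_tool(
    scores: Sequence[float],
    labels: Sequence[int],
    tool: ToolConfig,
    threshold: float | None = None,
) -> MetricSet:
    """Scalar metrics plus curve areas for one tool on one dataset."""
    counts = apply_threshold(scores, labels, tool, threshold)
    base = metric_set(counts)
    _, _, auroc, auprc = roc_and_pr(scores, labels, tool.direction)
    return MetricSet(**{**base.as_dict(), "auroc": auroc, "auprc": auprc})


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurvePoints:
    """(threshold, x, y) triples; ROC uses (FPR, TPR), PR uses (recall, precision)."""

    kind: str
    thresholds: tuple[float, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "x": self.x, "y": self.y}
        ).assign(kind=self.kind)


def roc_and_pr(
    scores: Sequence[float], labels: Sequence[int], direction: str = "higher_deleterious"
) -> tuple[CurvePoints | None, CurvePoints | None, float | None, float | None]:
    """ROC and PR curves with trapezoidal auROC and step-wise average precision.

    Missing scores are excluded; tied scores are grouped into a single
    threshold.  With a single class present the auROC is undefined (None);
    average precision additionally needs at least one positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if direction == "absolute_value":
        scores = np.abs(scores)
    mask = ~np.isnan(scores)
    s, y = scores[mask], labels[mask]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    roc = pr = auroc = auprc = None
    if n_pos and n_neg:
        fpr, tpr, thr = roc_curve(y, s)
        roc = CurvePoints("roc", tuple(thr), tuple(fpr), tuple(tpr))
        auroc = float(roc_auc_score(y, s))
    elif len(s):
        log.warning("single-class input: auROC undefined")
    if n_pos:
        prec, rec, thr = precision_recall_curve(y, s)
        pr = CurvePoints(
            "pr", tuple(thr) + (math.inf,), tuple(rec), tuple(prec)
        )
        auprc = float(average_precision_score(y, s))
    return roc, pr, auroc, auprc


# ---------------------------------------------------------------------------
# Per-bin evaluation
# ---------------------------------------------------------------------------

def per_bin_evaluate(
    frame: pd.DataFrame,
    tools: Sequence[ToolConfig],
    bin_labels: Sequence[str],
    label_col: str = "label",
    bin_col: str = "bin",
) -> pd.DataFrame:
    """Metrics per (tool, bin) plus a per-tool unweighted mean across bins.

    ``frame`` holds one row per variant with a binary label column, a bin
    column, and one score column per tool (NaN = unscored).  Empty bins are
    excluded from the mean with a warning.  Rows with ``bin == "mean"``
    summarize each tool.
    """
    rows = []
    for tool in tools:
        per_bin = {}
        for b in bin_labels:
            sub = frame[frame[bin_col] == b]
            if sub.empty:
                log.warning("bin %s: no variants; excluded from mean", b)
                continue
            ms = evaluate_tool(sub[tool.score_key], sub[label_col], tool)
            per_bin[b] = ms
            rows.append({"tool": tool.name, "bin": b, "n": len(sub), **ms.as_dict()})
        if per_bin:
            mean_row = {"tool": tool.name, "bin": "mean", "n": int(sum(
                (frame[bin_col] == b).sum() for b in per_bin))}
            for key in (
                "precision", "recall", "f1", "coverage", "weighted_f1",
                "mcc", "normalized_mcc", "weighted_normalized_mcc",
            ):
                mean_row[key] = float(
                    np.mean([getattr(ms, key) for ms in per_bin.values()])
                )
            mean_row["auroc"] = mean_row["auprc"] = None
            rows.append(mean_row)
    return pd.DataFrame(rows)


def full_intron_tools(
    frame: pd.DataFrame, tools: Sequence[ToolConfig], min_fraction: float = 0.9
) -> list[str]:
    """Tools that score strictly more than ``min_fraction`` of all variants."""
    kept = []
    for tool in tools:
        scored = frame[tool.score_key].notna().mean()
        if scored > min_fraction:
            kept.append(tool.name)
    return kept


# ---------------------------------------------------------------------------
# Variant ranking ("interrogate" mode)
# ---------------------------------------------------------------------------

def rank_variants(
    frame: pd.DataFrame,
    tools: Sequence[ToolConfig],
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Order candidate variants by cross-tool support.

    Sort key: fraction of scoring tools calling the variant positive (at
    each tool's threshold), then the mean min-max-normalized score across
    scoring tools; exact ties fall back to genomic coordinate so the order
    is deterministic.  Requires ``contig`` and ``pos`` columns.
    """
    if not tools:
        raise ValueError("at least one tool required")
    thresholds = thresholds or {}
    support = np.zeros(len(frame))
    n_scoring = np.zeros(len(frame))
    norm_sum = np.zeros(len(frame))
    for tool in tools:
        t = thresholds.get(tool.name, tool.reference_threshold)
        s = tool.transform(frame[tool.score_key].to_numpy())
        scored = ~np.isnan(s)
        called = scored & (s > t)
        smin = np.nanmin(s) if scored.any() else 0.0
        smax = np.nanmax(s) if scored.any() else 1.0
        span = smax - smin
        norm = (s - smin) / span if span else np.where(scored, 0.5, np.nan)
        support += called
        n_scoring += scored
        norm_sum += np.where(scored, norm, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_scoring > 0, support / n_scoring, 0.0)
        mean_norm = np.where(n_scoring > 0, norm_sum / n_scoring, 0.0)
    out = frame.copy()
    out["n_supporting_tools"] = support.astype(int)
    out["n_scoring_tools"] = n_scoring.astype(int)
    out["support_fraction"] = frac
    out["mean_normalized_score"] = mean_norm
    out = out.sort_values(
        by=["support_fraction", "mean_normalized_score", "contig", "pos"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out
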