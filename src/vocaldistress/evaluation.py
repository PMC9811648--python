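"""Segment-level aggregation and confusion reporting.

Frame probabilities are averaged within each annotated segment; the
segment is called high distress when the mean probability reaches the
frame-level operating threshold.  Confusion summaries report, per true
class and per level (frame or segment), the counts and the percentage
correctly classified — rounded half-up to 2 decimals at frame level and 1
decimal at segment level, so any printed percentage is exactly
recomputable from the printed counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "SegmentResult",
    "ConfusionSummary",
    "percent",
    "aggregate_segments",
    "confusion_summary",
    "misclassification_report",
]


def percent(correct: int, total: int, decimals: int) -> float:
    """100*correct/total rounded half-up to the requested precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(correct) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class SegmentResult:
    segment_id: str
    mean_prob: float
    predicted: str  # "low" | "high"
    truth: str
    n_frames: int
    misclassified: bool


@dataclass
class ConfusionSummary:
    level: str  # "frame" | "segment"
    per_class: dict  # class -> {total, correct, incorrect, pct_correct, pct_incorrect}

    @property
    def n_total(self) -> int:
        return sum(v["total"] for v in self.per_class.values())


def aggregate_segments(
    frame_probs: np.ndarray, segment_ids, truths, tau: float
) -> list[SegmentResult]:
    """Mean frame probability per segment; predicted high iff mean >= tau.

    truths maps rows to the segment's true label ("low"/"high"); segments
    without scored frames never appear (they are excluded upstream).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    df = pd.DataFrame(
        {"segment_id": segment_ids, "prob": np.asarray(frame_probs, float), "truth": truths}
    )
    df = df[np.isfinite(df["prob"])]
    out: list[SegmentResult] = []
    for seg, grp in df.groupby("segment_id", sort=True):
        mean_p = float(grp["prob"].mean())
        truth = grp["truth"].iloc[0]
        pred = "high" if mean_p >= tau else "low"
        out.append(
            SegmentResult(
                segment_id=str(seg), mean_prob=mean_p, predicted=pred,
                truth=truth, n_frames=len(grp), misclassified=pred != truth,
            )
        )
    return out


def confusion_summary(predicted, truth, level: str) -> ConfusionSummary:
    """Per-true-class counts and percentage correct at the stated precision."""
    pred = np.asarray(predicted)
    tru = np.asarray(truth)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != tru.shape:
        raise ValueError("predicted and truth must have equal length")
    decimals = {"frame": 2, "segment": 1}[level]
    per_class = {}
    for cls in sorted(np.unique(tru)):
        mask = tru == cls
        total = int(mask.sum())
        correct = int(np.sum(pred[mask] == cls))
        per_class[str(cls)] = {
            "total": total,
            "correct": correct,
            "incorrect": total - correct,
            "pct_correct": percent(correct, total, decimals),
            "pct_incorrect": percent(total - correct, total, decimals),
        }
    return ConfusionSummary(level=level, per_class=per_class)


def misclassification_report(
    segment_results: list[SegmentResult], annotations=None
) -> pd.DataFrame:
    """Misclassified segments with error direction and any annotation note."""
    notes = {}
    if annotations is not None:
        notes = {a.segment_id: a.note for a in annotations}
    rows = [
        {
            "segment_id": r.segment_id,
            "truth": r.truth,
            "predicted": r.predicted,
            "direction": f"{r.truth}_called_{r.predicted}",
            "mean_prob": r.mean_prob,
            "n_frames": r.n_frames,
            "note": notes.get(r.segment_id, ""),
        }
        for r in segment_results
        if r.misclassified
    ]
    return pd.DataFrame(
        rows, columns=["segment_id", "truth", "predicted", "direction", "mean_prob", "n_frames", "note"]
    )


def results_paragraph(frame_cm: ConfusionSummary, segment_cm: ConfusionSummary) -> str:
    """One-paragraph text summary in the style of a results section."""
    f, s = frame_cm.per_class, segment_cm.per_class
    parts = []
    for cls in f:
        fc, sc = f[cls], s.get(cls, None)
        seg_txt = (
            f" nested within {sc['correct']} of {sc['total']} ({sc['pct_correct']}%) segments"
            if sc
            else ""
        )
        parts.append(
            f"{fc['correct']} of {fc['total']} ({fc['pct_correct']}%) speech frames"
            f"{seg_txt} were correctly classified as exhibiting {cls} psychological distress"
        )
    return "; ".join(parts) + "."
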