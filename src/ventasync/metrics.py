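"""Evaluation metrics and monitoring summaries for asynchrony detection.

One-vs-rest confusion counts per asynchrony type feed sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy (TP+TN)/total; incidence
reports give per-window label fractions, cumulative per-breath fractions and
the asynchrony index (asynchronous breaths over total breaths).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .rules import ASYNCHRONY_TYPES, LABELS

__all__ = [
    "ConfusionCounts",
    "IncidenceReport",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "incidence_report",
    "percent",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tallies for a single target label (or binary asynchrony)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class IncidenceReport:
    """Windowed and cumulative label fractions over a monitoring period."""

    window_size: int
    windows: list            # [{start, end, partial, fractions: {label: f}}]
    cumulative: dict         # label -> per-breath running fraction (ndarray)
    asynchrony_index: float


def _validate_labels(labels) -> list[str]:
    labels = list(labels)
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
    return labels


def confusion(pred, truth, target: str = "any") -> ConfusionCounts:
    """One-vs-rest confusion counts for ``target``.

    ``target="any"`` collapses all seven asynchrony types into a single
    asynchrony-vs-none comparison.
    """
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth) or not pred:
        raise ValueError("pred and truth must be equal-length, non-empty")
    if target == "any":
        is_pos_pred = [p != "none" for p in pred]
        is_pos_true = [t != "none" for t in truth]
    elif target in LABELS:
        is_pos_pred = [p == target for p in pred]
        is_pos_true = [t == target for t in truth]
    else:
        raise ValueError(f"unknown target {target!r}")
    tp = sum(p and t for p, t in zip(is_pos_pred, is_pos_true))
    fn = sum((not p) and t for p, t in zip(is_pos_pred, is_pos_true))
    fp = sum(p and (not t) for p, t in zip(is_pos_pred, is_pos_true))
    tn = len(pred) - tp - fn - fp
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def sensitivity(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None (not available) when no positives exist."""
    denom = c.tp + c.fn
    return None if denom == 0 else c.tp / denom


def specificity(c: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when no negatives exist."""
    denom = c.tn + c.fp
    return None if denom == 0 else c.tn / denom


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.tp + c.tn) / c.total


def percent(fraction: float | None, decimals: int = 1) -> str:
    """Render a fraction as a percentage, half-up at ``decimals``; N/A if None."""
    if fraction is None:
        return "N/A"
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


def incidence_report(labels, window_size: int = 100) -> IncidenceReport:
    """Windowed label fractions, cumulative fractions and asynchrony index.

    The final partial window (if any) is included and flagged.  Within each
    window the fractions over all labels (types plus none) sum to one.
    """
    labels = _validate_labels(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = len(labels)
    windows = []
    for start in range(0, n, window_size):
        end = min(start + window_size, n)
        chunk = labels[start:end]
        fractions = {lab: chunk.count(lab) / len(chunk) for lab in LABELS}
        windows.append({
            "start": start,
            "end": end,
            "partial": (end - start) < window_size,
            "fractions": fractions,
        })
    arr = np.array(labels)
    denom = np.arange(1, n + 1, dtype=float)
    cumulative = {
        lab: np.cumsum(arr == lab) / denom for lab in LABELS
    }
    asynchrony_index = float(np.mean(arr != "none"))
    return IncidenceReport(
        window_size=window_size,
        windows=windows,
        cumulative=cumulative,
        asynchrony_index=asynchrony_index,
    )


def per_type_table(pred, truth) -> dict:
    """Per-type and overall metrics in one structure (machine fractions).

    Keys: each asynchrony type, ``none`` (non-asynchrony one-vs-rest) and
    ``any`` (binary asynchrony-vs-none); values carry the counts and the
    three metrics.
    """
    out = {}
    for target in ASYNCHRONY_TYPES + ("none", "any"):
        c = confusion(pred, truth, target)
        out[target] = {
            "tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp,
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "accuracy": accuracy(c),
        }
    return out
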