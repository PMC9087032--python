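"""Segmentation and verdict-classification evaluation statistics.

Covers the Dice similarity coefficient (DSC) per structure, summaries over
structures, and 2x2 qualified/unqualified confusion statistics (accuracy,
sensitivity, specificity, qualified rate) with the half-up one-decimal
percent formatting conventional in radiology reports.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass

import numpy as np

from .schema import LabelMask

__all__ = [
    "DiceResult",
    "DscSummary",
    "ConfusionTable",
    "dice",
    "dice_binary",
    "summarize_dsc",
    "confusion",
    "classification_stats",
    "qualified_rate",
    "round_percent",
]


@dataclass(frozen=True)
class DiceResult:
    structure: str
    dsc: float
    both_empty: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError("DSC must lie in [0, 1]")


@dataclass(frozen=True)
class DscSummary:
    mean: float
    sd: float | None  # None when fewer than 2 values
    min: float
    max: float


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 verdict counts; the positive class is "qualified".

    tp: both say qualified; fp: predicted qualified, truly unqualified;
    fn: predicted unqualified, truly qualified; tn: both unqualified.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def dice_binary(pred: np.ndarray, truth: np.ndarray) -> float:
    """DSC between two boolean pixel sets: 2|P∩T| / (|P|+|T|).

    Defined as 1.0 when both sets are empty (both agree the structure is
    absent).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & truth).sum()) / denom


def dice(pred: LabelMask, truth: LabelMask, structure: str) -> DiceResult:
    """Per-structure DSC between a predicted and a reference mask."""
    if pred.shape != truth.shape:
        raise ValueError(f"mask dimensions differ: {pred.shape} vs {truth.shape}")
    p = pred.structure_pixels(structure)
    t = truth.structure_pixels(structure)
    empty = not (p.any() or t.any())
    return DiceResult(structure=structure, dsc=dice_binary(p, t),
                      both_empty=empty)


def summarize_dsc(results: list[DiceResult] | list[float]) -> DscSummary:
    """Unweighted mean, sample sd (n-1) and extremes over structure DSCs."""
    values = [r.dsc if isinstance(r, DiceResult) else float(r) for r in results]
    if not values:
        raise ValueError("need at least one DSC value")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return DscSummary(mean=float(arr.mean()), sd=sd,
                      min=float(arr.min()), max=float(arr.max()))


def confusion(pred_verdicts, truth_verdicts) -> ConfusionTable:
    """Tally paired qualified/unqualified verdicts into a 2x2 table."""
    pred = [bool(v) for v in pred_verdicts]
    truth = [bool(v) for v in truth_verdicts]
    if len(pred) != len(truth):
        raise ValueError(
            f"verdict lists differ in length: {len(pred)} vs {len(truth)}")
    tp = sum(p and t for p, t in zip(pred, truth))
    fp = sum(p and not t for p, t in zip(pred, truth))
    fn = sum(t and not p for p, t in zip(pred, truth))
    tn = sum(not p and not t for p, t in zip(pred, truth))
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def classification_stats(
    t: ConfusionTable,
) -> tuple[float | None, float | None, float | None]:
    """(accuracy, sensitivity, specificity) as fractions; None when the
    denominator is zero."""
    accuracy = (t.tp + t.tn) / t.total if t.total > 0 else None
    sensitivity = t.tp / (t.tp + t.fn) if (t.tp + t.fn) > 0 else None
    specificity = t.tn / (t.tn + t.fp) if (t.tn + t.fp) > 0 else None
    return accuracy, sensitivity, specificity


def qualified_rate(verdicts) -> float:
    """Percentage of qualified verdicts (0-100, unrounded)."""
    verdicts = [bool(v) for v in verdicts]
    if not verdicts:
        raise ValueError("need at least one verdict")
    return 100.0 * sum(verdicts) / len(verdicts)


def round_percent(fraction_or_pct: float, *, is_fraction: bool = True,
                  decimals: int = 1) -> float:
    """Half-up rounding of a rate to report precision (e.g. 0.14634 -> 14.6)."""
    pct = fraction_or_pct * 100.0 if is_fraction else fraction_or_pct
    if not math.isfinite(pct):
        raise ValueError("rate must be finite")
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(pct)).quantize(
        q, rounding=decimal.ROUND_HALF_UP))
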