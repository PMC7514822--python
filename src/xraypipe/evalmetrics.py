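"""Confusion-matrix bookkeeping and derived classification metrics."""

from __future__ import annotations

from dataclasses import dataclass

from xraypipe.errors import ValidationError
from xraypipe.fracture import FractureReport

__all__ = ["ConfusionCounts", "MetricSet", "compute_metrics", "match_detection", "tally"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Nine derived rates; ``None`` marks an undefined (0/0) metric."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None
    fpr: float | None
    fdr: float | None
    fnr: float | None
    accuracy: float | None
    f1: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """All nine rates from raw counts.

    Note the false discovery rate is FP/(FP+TP), the complement of precision.
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics on empty counts")
    return MetricSet(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.fp + c.tn),
        precision=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        fpr=_ratio(c.fp, c.fp + c.tn),
        fdr=_ratio(c.fp, c.fp + c.tp),
        fnr=_ratio(c.fn, c.fn + c.tp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def match_detection(
    report: FractureReport,
    truth=None,
    line_to_bone=None,
) -> str:
    """Score one image: returns "TP", "FN", "TN" or "FP".

    A true positive requires the image to be flagged AND at least one circle
    to contain the true fracture row on a line of the fractured bone; a
    flagged image whose circles all miss still counts as a false negative.
    ``line_to_bone`` maps bone-line index to bone index (default: lines 0,1
    belong to bone 0 and lines 2,3 to bone 1).
    """
    if truth is None:
        return "FP" if report.fractured else "TN"
    if not report.fractured:
        return "FN"
    mapping = line_to_bone or (lambda i: i // 2)
    if isinstance(mapping, (list, tuple, dict)):
        table = mapping
        mapping = lambda i: table[i]  # noqa: E731
    for det in report.detections:
        if mapping(det.bone_line) != truth.bone_index:
            continue
        if abs(det.row - truth.row) <= det.radius:
            return "TP"
    return "FN"


def tally(outcomes) -> ConfusionCounts:
    """Aggregate per-image outcome labels into counts."""
    counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for o in outcomes:
        if o not in counts:
            raise ValidationError(f"unknown outcome label {o!r}")
        counts[o] += 1
    return ConfusionCounts(
        tp=counts["TP"], tn=counts["TN"], fp=counts["FP"], fn=counts["FN"]
    )
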