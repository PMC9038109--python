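"""Scoring of segmentation and classification against ground truth.

Detection: a manually annotated cell center counts as detected when it falls
on a pixel of a retained segment; when several centers share one segment,
one is detected and the rest are missed (an under-split cluster). Retained
segments containing no center are spurious "additional regions".

Classification rates are reported under two denominators: relative to the
correctly segmented cells and relative to all annotated cells, so the cost
of segmentation losses is visible in the final rates.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats

from .errors import ValidationError
from .segmentation import SegmentLabelMap


@dataclasses.dataclass
class DetectionMatch:
    """Per-center segment assignment and per-segment center counts."""

    center_segment: list[int | None]  # retained segment id per center, None if missed
    segment_center_count: dict[int, int]
    n_detected: int  # centers credited as detections (<=1 per segment)
    n_total: int
    spurious_segments: list[int]

    @property
    def n_missed(self) -> int:
        return self.n_total - self.n_detected


def match_detections(
    centers: Sequence[tuple[int, int]],
    segments: SegmentLabelMap,
) -> DetectionMatch:
    """Match ground-truth centers (x, y) to retained segments."""
    labels = segments.labels
    h, w = labels.shape
    center_segment: list[int | None] = []
    seg_counts: dict[int, int] = {i: 0 for i in segments.segment_ids()}
    for x, y in centers:
        if not (0 <= x < w and 0 <= y < h):
            raise ValidationError(f"center ({x}, {y}) outside image {w}x{h}")
        seg = int(labels[y, x])
        if seg > 0:
            center_segment.append(seg)
            seg_counts[seg] += 1
        else:
            center_segment.append(None)
    # one detection credit per segment; extra centers in a segment are missed
    n_detected = sum(1 for c in seg_counts.values() if c > 0)
    spurious = sorted(i for i, c in seg_counts.items() if c == 0)
    return DetectionMatch(
        center_segment=center_segment,
        segment_center_count=seg_counts,
        n_detected=n_detected,
        n_total=len(center_segment),
        spurious_segments=spurious,
    )


def detection_rate(match: DetectionMatch) -> float:
    """Detected centers / all ground-truth centers."""
    if match.n_total == 0:
        raise ValidationError("detection rate undefined: no ground-truth centers")
    return match.n_detected / match.n_total


def aggregate_detection_rates(matches: Sequence[DetectionMatch]) -> dict[str, float]:
    """Pooled (sum/sum) and macro (mean of per-image rates) aggregations."""
    if not matches:
        raise ValidationError("no detection matches supplied")
    detected = sum(m.n_detected for m in matches)
    total = sum(m.n_total for m in matches)
    if total == 0:
        raise ValidationError("detection rate undefined: no ground-truth centers")
    per_image = [detection_rate(m) for m in matches if m.n_total > 0]
    return {"pooled": detected / total, "macro": float(np.mean(per_image))}


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with osteoclast as the positive class."""

    tp_oc: int  # osteoclast predicted osteoclast
    fn_oc: int  # osteoclast predicted non-osteoclast
    fp_oc: int  # non-osteoclast predicted osteoclast
    tn_oc: int  # non-osteoclast predicted non-osteoclast

    def __post_init__(self) -> None:
        if min(self.tp_oc, self.fn_oc, self.fp_oc, self.tn_oc) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp_oc + self.fn_oc + self.fp_oc + self.tn_oc

    @property
    def n_oc(self) -> int:
        return self.tp_oc + self.fn_oc

    @property
    def n_non_oc(self) -> int:
        return self.fp_oc + self.tn_oc

    @classmethod
    def from_predictions(cls, true_labels: Sequence[int],
                         pred_labels: Sequence[int]) -> "ConfusionCounts":
        t = np.asarray(true_labels)
        p = np.asarray(pred_labels)
        if t.shape != p.shape:
            raise ValidationError("label vectors differ in length")
        return cls(
            tp_oc=int(((t == 1) & (p == 1)).sum()),
            fn_oc=int(((t == 1) & (p == 0)).sum()),
            fp_oc=int(((t == 0) & (p == 1)).sum()),
            tn_oc=int(((t == 0) & (p == 0)).sum()),
        )


def _rate(num: int, den: int) -> float | None:
    """None encodes an undefined rate (zero denominator), never silently 0."""
    return num / den if den else None


@dataclasses.dataclass
class EvaluationReport:
    """Classification rates, optionally under the two-denominator accounting."""

    counts: ConfusionCounts
    accuracy: float | None
    precision_oc: float | None
    precision_non_oc: float | None
    recall_oc: float | None
    recall_non_oc: float | None
    # versus-all-cells rates, present when segmentation losses are supplied
    vs_all: dict[str, float | None] | None = None
    segmentation_recall: dict[str, float | None] | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def classification_report(
    counts: ConfusionCounts,
    all_totals: Mapping[str, int] | None = None,
) -> EvaluationReport:
    """Rates from confusion counts; two denominators when ``all_totals`` given.

    ``counts`` are tallied over the segmented cells. ``all_totals``
    ({"osteoclast": ..., "non_osteoclast": ...}) are the full annotated cell
    counts including segmentation losses; when given, every recall/accuracy is
    also emitted relative to all cells.
    """
    report = EvaluationReport(
        counts=counts,
        accuracy=_rate(counts.tp_oc + counts.tn_oc, counts.total),
        precision_oc=_rate(counts.tp_oc, counts.tp_oc + counts.fp_oc),
        precision_non_oc=_rate(counts.tn_oc, counts.tn_oc + counts.fn_oc),
        recall_oc=_rate(counts.tp_oc, counts.n_oc),
        recall_non_oc=_rate(counts.tn_oc, counts.n_non_oc),
    )
    if all_totals is not None:
        n_oc_all = int(all_totals["osteoclast"])
        n_non_all = int(all_totals["non_osteoclast"])
        if n_oc_all < counts.n_oc or n_non_all < counts.n_non_oc:
            raise ValidationError("all-cell totals smaller than segmented totals")
        report.vs_all = {
            "accuracy": _rate(counts.tp_oc + counts.tn_oc, n_oc_all + n_non_all),
            "recall_oc": _rate(counts.tp_oc, n_oc_all),
            "recall_non_oc": _rate(counts.tn_oc, n_non_all),
        }
        report.segmentation_recall = {
            "oc": _rate(counts.n_oc, n_oc_all),
            "non_oc": _rate(counts.n_non_oc, n_non_all),
            "overall": _rate(counts.total, n_oc_all + n_non_all),
        }
    return report


def count_correlation(
    manual: Sequence[float], automated: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and Spearman rho between per-image manual and automated counts."""
    manual = np.asarray(manual, dtype=np.float64)
    automated = np.asarray(automated, dtype=np.float64)
    if manual.shape != automated.shape:
        raise ValidationError("count vectors differ in length")
    if manual.size < 3:
        raise ValidationError("need at least 3 paired counts")
    if manual.std() == 0 or automated.std() == 0:
        raise ValidationError("correlation undefined: zero variance in counts")
    pearson = sp_stats.pearsonr(manual, automated).statistic
    spearman = sp_stats.spearmanr(manual, automated).statistic
    return float(pearson), float(spearman)
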