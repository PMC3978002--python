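"""Assessment metrics for detections against annotated events.

The detector is scored event-wise rather than window-wise: an annotated
misstep counts as detected (a "hit") if at least one flagged window overlaps
it, even when the event spans several windows. Specificity is computed over
the gait windows that overlap no annotated event. On unannotated free-living
data there is no ground truth, so detections are only "suspected missteps"
(sMS) and are normalized per 100 gait windows to compare subjects with very
different amounts of walking. A pooled 2x2 event/trial odds ratio compares
fallers (two or more falls in the prior six months) with non-fallers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AnnotationEvent",
    "EvaluationReport",
    "SubjectTrialCounts",
    "hit_ratio",
    "hit_ratio_spans",
    "specificity",
    "specificity_spans",
    "normalized_sms",
    "faller_odds_ratio",
    "evaluate",
    "evaluate_spans",
]


@dataclass(frozen=True)
class AnnotationEvent:
    """Ground-truth misstep: start time and duration in seconds."""

    start_time: float
    duration: float
    label: str = "misstep"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")

    @property
    def stop_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class EvaluationReport:
    n_events: int
    n_hits: int
    hit_ratio: float
    n_negative_windows: int
    n_false_positives: int
    specificity: float
    normalized_sms: float

    def rounded(self) -> dict:
        """Report dictionary with percentages at one decimal place."""
        return {
            "n_events": self.n_events,
            "n_hits": self.n_hits,
            "hit_ratio": round(self.hit_ratio, 1),
            "n_negative_windows": self.n_negative_windows,
            "n_false_positives": self.n_false_positives,
            "specificity": round(self.specificity, 1),
            "normalized_sms": round(self.normalized_sms, 2),
        }


@dataclass(frozen=True)
class SubjectTrialCounts:
    """Per-subject event/trial counts for the faller comparison."""

    subject_id: str
    is_faller: bool
    n_sms_windows: int
    n_gait_windows: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_sms_windows <= self.n_gait_windows):
            raise ValueError("need 0 <= n_sms_windows <= n_gait_windows")


def _spans_overlap(a_start: float, a_stop: float, b_start: float, b_stop: float) -> bool:
    # half-open intervals [start, stop)
    return a_start < b_stop and b_start < a_stop


def _detection_spans(detections: Iterable) -> list[tuple[float, float]]:
    spans = []
    for det in detections:
        w = det.window
        spans.append((w.start_s, w.stop_s))
    return spans


def hit_ratio_spans(
    detection_spans: Sequence[tuple[float, float]],
    events: Sequence[AnnotationEvent],
) -> float:
    """Hit ratio from plain (start_s, stop_s) detection spans."""
    if len(events) == 0:
        raise ValueError("hit ratio is undefined with no annotated events")
    hits = sum(
        any(_spans_overlap(s, e, ev.start_time, ev.stop_time) for s, e in detection_spans)
        for ev in events
    )
    return 100.0 * hits / len(events)


def hit_ratio(
    detections: Sequence,
    events: Sequence[AnnotationEvent],
    window_s: float = 5.0,
) -> float:
    """Percentage of annotated events overlapped by >= 1 detection window.

    ``window_s`` documents the window length but the spans of the detection
    windows themselves define the overlap; duplicate detections of the same
    window do not change the result.
    """
    return hit_ratio_spans(_detection_spans(detections), events)


def _negatives_and_fp(
    detection_spans: Sequence[tuple[float, float]],
    gait_spans: Sequence[tuple[float, float]],
    events: Sequence[AnnotationEvent],
) -> tuple[int, int]:
    det_keys = {(round(s, 9), round(e, 9)) for s, e in detection_spans}
    n_neg = 0
    n_fp = 0
    for s, e in gait_spans:
        if any(_spans_overlap(s, e, ev.start_time, ev.stop_time) for ev in events):
            continue
        n_neg += 1
        if (round(s, 9), round(e, 9)) in det_keys:
            n_fp += 1
    return n_neg, n_fp


def specificity_spans(
    detection_spans: Sequence[tuple[float, float]],
    gait_spans: Sequence[tuple[float, float]],
    events: Sequence[AnnotationEvent],
) -> float:
    """Specificity from plain (start_s, stop_s) spans."""
    n_neg, n_fp = _negatives_and_fp(detection_spans, gait_spans, events)
    if n_neg == 0:
        raise ValueError("specificity is undefined with no negative gait windows")
    return 100.0 * (n_neg - n_fp) / n_neg


def specificity(
    detections: Sequence,
    events: Sequence[AnnotationEvent],
    gait_windows: Sequence,
) -> float:
    """Percentage of event-free gait windows not flagged.

    Negative windows are gait windows that overlap no annotated event; a
    flagged window that partially overlaps an event is a hit, not a false
    positive.
    """
    gait_spans = [
        (r.window.start_s, r.window.stop_s)
        for r in gait_windows
        if getattr(r, "is_gait", True)
    ]
    return specificity_spans(_detection_spans(detections), gait_spans, events)


def normalized_sms(n_sms: int, n_gait_windows: int) -> float:
    """Suspected-misstep windows per 100 gait windows.

    Normalizes detection counts for unequal walking time across subjects.
    """
    if n_gait_windows < 1:
        raise ValueError("normalized sMS is undefined with zero gait windows")
    if n_sms < 0:
        raise ValueError("n_sms must be non-negative")
    return 100.0 * n_sms / n_gait_windows


def evaluate_spans(
    detection_spans: Sequence[tuple[float, float]],
    gait_spans: Sequence[tuple[float, float]],
    events: Sequence[AnnotationEvent],
) -> EvaluationReport:
    """Full report from plain (start_s, stop_s) spans."""
    if len(events) == 0:
        raise ValueError("evaluation requires at least one annotated event")
    hits = sum(
        any(_spans_overlap(s, e, ev.start_time, ev.stop_time) for s, e in detection_spans)
        for ev in events
    )
    n_neg, n_fp = _negatives_and_fp(detection_spans, gait_spans, events)
    if n_neg == 0:
        raise ValueError("specificity is undefined with no negative gait windows")
    n_unique = len({(round(s, 9), round(e, 9)) for s, e in detection_spans})
    n_gait = len(gait_spans)
    return EvaluationReport(
        n_events=len(events),
        n_hits=hits,
        hit_ratio=100.0 * hits / len(events),
        n_negative_windows=n_neg,
        n_false_positives=n_fp,
        specificity=100.0 * (n_neg - n_fp) / n_neg,
        normalized_sms=normalized_sms(n_unique, n_gait) if n_gait else 0.0,
    )


def evaluate(
    detections: Sequence,
    events: Sequence[AnnotationEvent],
    gait_windows: Sequence,
) -> EvaluationReport:
    """Full report: hit ratio, specificity and normalized sMS."""
    gait_spans = [
        (r.window.start_s, r.window.stop_s)
        for r in gait_windows
        if getattr(r, "is_gait", True)
    ]
    return evaluate_spans(_detection_spans(detections), gait_spans, events)


def faller_odds_ratio(
    subjects: Sequence[SubjectTrialCounts],
) -> tuple[float, tuple[float, float]]:
    """Pooled event/trial odds ratio of fallers vs non-fallers with 95% CI.

    Pools suspected-misstep windows (events) and gait windows (trials) by
    group into a 2x2 table; the odds ratio is (a/b)/(c/d) with a, b the
    faller sMS and non-sMS window counts and c, d the non-faller counts. The
    confidence interval is Woolf's log method (log OR +/- 1.96 SE); a zero
    cell triggers the Haldane-Anscombe 0.5 correction on all cells. Subject-
    level correlation of windows is not modeled: this is a pooled
    approximation, not a repeated-measures regression.
    """
    fallers = [s for s in subjects if s.is_faller]
    non_fallers = [s for s in subjects if not s.is_faller]
    if not fallers or not non_fallers:
        raise ValueError("both faller and non-faller groups must be non-empty")
    a = sum(s.n_sms_windows for s in fallers)
    b = sum(s.n_gait_windows - s.n_sms_windows for s in fallers)
    c = sum(s.n_sms_windows for s in non_fallers)
    d = sum(s.n_gait_windows - s.n_sms_windows for s in non_fallers)
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    if np.any(cells <= 0):
        raise ValueError("2x2 table has a non-positive cell after correction")
    or_ = (a_ / b_) / (c_ / d_)
    se = float(np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_))
    log_or = float(np.log(or_))
    lo = float(np.exp(log_or - 1.96 * se))
    hi = float(np.exp(log_or + 1.96 * se))
    return float(or_), (lo, hi)
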