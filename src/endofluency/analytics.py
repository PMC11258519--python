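"""Evaluation against ground truth, human-review simulation, and
per-10-minute surgical-fluency statistics.

Two granularities are reported side by side. Frame-level evaluation turns
the predicted and true event lists into boolean per-frame series and
computes the usual confusion rates (sensitivity, specificity, accuracy).
Event-level matching pairs predicted events with truth events by temporal
overlap; it feeds the human-computer collaboration model, in which a
reviewer inspects each detected event and discards the spurious ones —
false positives vanish, but interruptions the detector never flagged stay
missed.

Fluency is summarized as the number of interruptions and the seconds spent
interrupted per 10-minute (600 s) window, overall and per surgical phase
(nasal, sphenoidal, sellar).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import InterruptionEvent, PhaseAnnotation

WINDOW_S = 600.0  # the 10-minute normalization window


@dataclass(frozen=True)
class EvaluationResult:
    """Frame-level confusion counts with rates reported as percentages.

    Rates with an empty denominator (no positive or no negative frames in
    truth) are reported as 100%: there was nothing to miss.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity_pct(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else 100.0

    @property
    def specificity_pct(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else 100.0

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n_frames

    def to_dict(self) -> dict:
        return {
            **asdict(self),
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
        }


@dataclass(frozen=True)
class FluencySummary:
    """Interruption frequency and duration normalized to 600-second windows.

    ``burden_pct`` is the fraction of operative time spent interrupted,
    i.e. ``interruption_s_per_10min / 600 × 100`` — identically
    ``interruption_s_per_10min / 6``.
    """

    phase: str
    window_s: float
    phase_duration_s: float
    n_events: int
    events_per_10min: float
    interruption_s_per_10min: float
    burden_pct: float


def frame_labels_from_events(events: list[InterruptionEvent], n_frames: int) -> np.ndarray:
    """Boolean series: frame i is True iff it lies in some event span."""
    if n_frames <= 0:
        raise ValidationError(f"n_frames must be positive, got {n_frames}")
    labels = np.zeros(n_frames, dtype=bool)
    for ev in events:
        if ev.start_frame < 0 or ev.end_frame > n_frames:
            raise ValidationError(
                f"event [{ev.start_frame}, {ev.end_frame}) exceeds [0, {n_frames})"
            )
        labels[ev.start_frame : ev.end_frame] = True
    return labels


def evaluate_frames(
    predicted: list[InterruptionEvent],
    truth: list[InterruptionEvent],
    n_frames: int,
    fps: float,
) -> EvaluationResult:
    """Frame-level confusion of predicted events against ground truth."""
    pred = frame_labels_from_events(predicted, n_frames)
    true = frame_labels_from_events(truth, n_frames)
    return EvaluationResult(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
        tn=int(np.sum(~pred & ~true)),
    )


def _overlap_frames(a: InterruptionEvent, b: InterruptionEvent) -> int:
    return max(0, min(a.end_frame, b.end_frame) - max(a.start_frame, b.start_frame))


def match_events(
    predicted: list[InterruptionEvent],
    truth: list[InterruptionEvent],
    min_overlap_fraction: float = 0.5,
) -> tuple[list[tuple[InterruptionEvent, InterruptionEvent]], list[InterruptionEvent], list[InterruptionEvent]]:
    """Greedy temporal matching of predicted events to truth events.

    Walking predicted events in start order, each one matches the earliest
    still-unmatched truth event with which it overlaps by at least
    ``min_overlap_fraction`` of the truth event's duration. Returns
    (matched pairs, unmatched predicted = FP, unmatched truth = FN).
    """
    if not 0 < min_overlap_fraction <= 1:
        raise ValidationError("min_overlap_fraction must be in (0, 1]")
    unmatched_truth = sorted(truth, key=lambda e: e.start_frame)
    pairs = []
    false_positives = []
    for pred in sorted(predicted, key=lambda e: e.start_frame):
        hit = next(
            (
                t for t in unmatched_truth
                if _overlap_frames(pred, t) >= min_overlap_fraction * t.duration_frames
            ),
            None,
        )
        if hit is None:
            false_positives.append(pred)
        else:
            pairs.append((pred, hit))
            unmatched_truth.remove(hit)
    return pairs, false_positives, unmatched_truth


def simulate_collaboration(
    predicted: list[InterruptionEvent],
    truth: list[InterruptionEvent],
    n_frames: int,
    fps: float,
) -> EvaluationResult:
    """Frame-level evaluation after a human reviewer vets each detection.

    The reviewer inspects every predicted event and discards those that
    capture no real interruption at all (zero overlap with every truth
    event); any event touching a real interruption is kept, so no
    true-positive frame is ever lost. Interruptions the detector missed
    stay missed — review can only remove false positives.
    """
    kept = [
        p for p in predicted
        if any(_overlap_frames(p, t) > 0 for t in truth)
    ]
    return evaluate_frames(kept, truth, n_frames, fps)


def summarize_fluency(
    events: list[InterruptionEvent],
    phases: list[PhaseAnnotation] | None,
    video_duration_s: float,
    fps: float,
) -> list[FluencySummary]:
    """Per-phase (and overall) interruption frequency and duration per 10 min.

    An event is *counted* in the phase containing its midpoint (so an event
    straddling a boundary is counted once), but its *duration* is split by
    exact overlap with each phase (so seconds are conserved across a phase
    split).
    """
    if video_duration_s <= 0:
        raise ValidationError("video_duration_s must be positive")
    for ev in events:
        if ev.end_s > video_duration_s + 1e-9:
            raise ValidationError(
                f"event ending at {ev.end_s:.3f}s exceeds video duration "
                f"{video_duration_s:.3f}s"
            )
    intervals = [("overall", 0.0, video_duration_s)]
    for ph in phases or []:
        if ph.duration_s <= 0:
            raise ValidationError(f"phase {ph.phase} has zero duration")
        intervals.append((ph.phase, ph.start_s, ph.end_s))

    summaries = []
    for name, lo, hi in intervals:
        duration = hi - lo
        midpoints = [(ev.start_s + ev.end_s) / 2 for ev in events]
        n_events = sum(1 for m in midpoints if lo <= m < hi)
        overlap_s = sum(
            max(0.0, min(ev.end_s, hi) - max(ev.start_s, lo)) for ev in events
        )
        per10_events = n_events * WINDOW_S / duration
        per10_seconds = overlap_s * WINDOW_S / duration
        summaries.append(
            FluencySummary(
                phase=name,
                window_s=WINDOW_S,
                phase_duration_s=duration,
                n_events=n_events,
                events_per_10min=per10_events,
                interruption_s_per_10min=per10_seconds,
                burden_pct=per10_seconds / 6.0,
            )
        )
    return summaries


def fluency_to_dataframe(summaries: list[FluencySummary]) -> pd.DataFrame:
    """Tidy table ready for CSV export or external statistical software."""
    return pd.DataFrame(
        [asdict(s) for s in summaries],
        columns=[
            "phase",
            "window_s",
            "phase_duration_s",
            "n_events",
            "events_per_10min",
            "interruption_s_per_10min",
            "burden_pct",
        ],
    )


def evaluation_report(
    predicted: list[InterruptionEvent],
    truth: list[InterruptionEvent],
    n_frames: int,
    fps: float,
    min_overlap_fraction: float = 0.5,
    collaborate: bool = False,
) -> dict:
    """JSON-ready report combining both evaluation granularities."""
    frame_level = (
        simulate_collaboration(predicted, truth, n_frames, fps)
        if collaborate
        else evaluate_frames(predicted, truth, n_frames, fps)
    )
    pairs, fps_events, fns_events = match_events(predicted, truth, min_overlap_fraction)
    report = frame_level.to_dict()
    report["event_level"] = {
        "matched": len(pairs),
        "fp": len(fps_events),
        "fn": len(fns_events),
    }
    report["collaborative_review"] = collaborate
    return report
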