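"""Shared domain records.

These dataclasses are the currency the modules exchange: raw frames,
per-frame dominant-color profiles, detected interruption events, and
surgical-phase annotations. They live here (rather than in the module that
"owns" each concept) so that frame I/O, color classification, and event
detection can depend on them without importing each other.

Conventions
-----------
* Frames are 0-based. Event intervals are half-open ``[start_frame,
  end_frame)`` so that ``duration_frames = end_frame - start_frame`` with no
  off-by-one.
* Time is always seconds; ``time_s = frame_index / fps`` with the *original*
  (un-strided) frame index.
* Pixel channel order is (red, green, blue), 8-bit, at every API boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Surgical phases of the endonasal endoscopic approach, in operative order.
PHASES = ("nasal", "sphenoidal", "sellar")


@dataclass
class FrameRecord:
    """One decoded video frame.

    Attributes
    ----------
    frame_index : int
        0-based index in the *original* stream (striding preserves it).
    time_s : float
        ``frame_index / fps`` of the source.
    pixels : numpy.ndarray
        ``(H, W, 3)`` uint8 array in (red, green, blue) order.
    """

    frame_index: int
    time_s: float
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"frame {self.frame_index}: pixels must be (H, W, 3), "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError(f"frame {self.frame_index}: empty frame")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValidationError(
                    f"frame {self.frame_index}: channel values outside [0, 255]"
                )
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width)."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class FrameColorProfile:
    """Percentages of pixels whose dominant color is S, R, or B-G.

    The three percentages partition the frame: every pixel receives exactly
    one label, so ``s_pct + r_pct + bg_pct == 100`` to floating tolerance.
    """

    frame_index: int
    time_s: float
    s_pct: float
    r_pct: float
    bg_pct: float

    def __post_init__(self) -> None:
        total = self.s_pct + self.r_pct + self.bg_pct
        if not np.isclose(total, 100.0, atol=1e-6):
            raise ValidationError(
                f"frame {self.frame_index}: S/R/B-G percentages sum to "
                f"{total!r}, expected 100"
            )


@dataclass(frozen=True)
class InterruptionEvent:
    """A detected (or ground-truth) endoscope-out interval.

    ``[start_frame, end_frame)`` half-open; ``duration_s`` is
    ``(end_frame - start_frame) / fps``.
    """

    start_frame: int
    end_frame: int
    start_s: float
    end_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValidationError(
                f"event [{self.start_frame}, {self.end_frame}) has "
                "end_frame <= start_frame"
            )

    @classmethod
    def from_frames(cls, start_frame: int, end_frame: int, fps: float) -> "InterruptionEvent":
        """Build an event from frame bounds, deriving the second coordinates."""
        return cls(
            start_frame=int(start_frame),
            end_frame=int(end_frame),
            start_s=start_frame / fps,
            end_s=end_frame / fps,
            duration_s=(end_frame - start_frame) / fps,
        )

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame


def validate_event_list(events: list[InterruptionEvent]) -> None:
    """Check sortedness and pairwise disjointness of an event list."""
    for prev, cur in zip(events, events[1:]):
        if cur.start_frame < prev.end_frame:
            raise ValidationError(
                f"events [{prev.start_frame}, {prev.end_frame}) and "
                f"[{cur.start_frame}, {cur.end_frame}) overlap or are unsorted"
            )


@dataclass(frozen=True)
class PhaseAnnotation:
    """A labeled surgical-phase interval, in seconds.

    Phases are consumed as annotations (produced by a human or an external
    phase-recognition system); this package never infers them from video.
    """

    phase: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(
                f"unknown phase {self.phase!r}; expected one of {PHASES}"
            )
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"phase {self.phase}: start_s {self.start_s} must be < end_s {self.end_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s
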