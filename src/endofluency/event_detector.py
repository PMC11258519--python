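"""Interruption detection from frame color profiles.

A surgical interruption is an episode in which blood contaminates the
endoscopic view, the endoscope is removed from the nasal cavity, and the
lens is cleaned; while it lasts, the camera sees the blue-green surgical
drape instead of red mucosa. Detection therefore watches the frame-to-frame
changes of the SRB-G profile:

    flag a frame when  ΔB-G > T(Δbg)  AND  ΔR < −T(Δr)  AND  S < T(s)

i.e. a sufficient jump in the blue-green percentage, a simultaneous drop in
the red percentage, and few silver pixels (the S ceiling excludes frames
where a moving instrument or gauze — not a withdrawal — causes the color
swing). Because a withdrawal spans many consecutive frames, flagged frames
are grown into intervals by a two-state machine with hysteresis re-entry
(the event ends when the red percentage recovers, i.e. the endoscope is
back inside), nearby intervals are merged, and intervals shorter than the
minimum length T(f) are discarded.

Default thresholds are T(Δbg)=35, T(Δr)=22, T(s)=32 (percentage points) and
T(f)=30 frames. ``literal_rule=True`` switches the ΔR term to the signed
form ``ΔR < T(Δr)`` (no explicit decrease required) for sensitivity
analysis; the default encodes the required decrease.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from . import video_io
from .color_model import (
    ColorReference,
    calibrate_color_references,
    classify_dominant_colors,
    classify_dominant_colors_rule,
    profile_frame,
)
from .errors import CalibrationError, ConfigurationError, ValidationError
from .types import FrameColorProfile, FrameRecord, InterruptionEvent, validate_event_list

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = (
    "frame_index",
    "time_s",
    "s_pct",
    "r_pct",
    "bg_pct",
    "d_s",
    "d_r",
    "d_bg",
    "candidate",
)


@dataclass(frozen=True)
class ColorDeltas:
    """Signed change (percentage points) of each SRB-G channel versus the
    profile ``lookback`` frames earlier. Because the three percentages
    partition every frame, ``d_s + d_r + d_bg == 0`` to floating tolerance.
    """

    frame_index: int
    d_s: float
    d_r: float
    d_bg: float


@dataclass
class DetectionConfig:
    """Thresholds and segmentation parameters of the detector.

    Attributes
    ----------
    t_dbg, t_dr, t_s : float
        Percentage-point thresholds T(Δbg), T(Δr), T(s).
    min_event_frames : int
        Minimum event length T(f), in frames of the analyzed stream.
    lookback : int
        How many frames back the deltas compare against.
    merge_gap_frames : int
        Provisional events separated by a gap of at most this many frames
        are merged (lens-cleaning flicker should not split one event).
    reentry_r_pct : float
        The red percentage at which the endoscope is considered back inside
        (hysteresis re-entry ending an event).
    fps : float
        Frame rate used to convert frame spans to seconds.
    literal_rule : bool
        If True, use the signed comparison ΔR < T(Δr) instead of the
        decrease form ΔR < −T(Δr).
    """

    t_dbg: float = 35.0
    t_dr: float = 22.0
    t_s: float = 32.0
    min_event_frames: int = 30
    lookback: int = 1
    merge_gap_frames: int = 15
    reentry_r_pct: float = 50.0
    fps: float = 30.0
    literal_rule: bool = False

    def __post_init__(self) -> None:
        for name in ("t_dbg", "t_dr", "t_s", "reentry_r_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigurationError(f"{name} must be in [0, 100], got {v}")
        if self.min_event_frames < 1:
            raise ConfigurationError("min_event_frames must be >= 1")
        if self.lookback < 1:
            raise ConfigurationError("lookback must be >= 1")
        if self.merge_gap_frames < 0:
            raise ConfigurationError("merge_gap_frames must be >= 0")
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "DetectionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping of config keys")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def compute_color_deltas(
    profiles: Sequence[FrameColorProfile], lookback: int = 1
) -> list[ColorDeltas]:
    """Channel-wise difference of each profile against the one ``lookback``
    positions earlier; positions with no comparand get zero deltas."""
    if not profiles:
        raise ValidationError("profiles must be non-empty")
    if lookback < 1:
        raise ConfigurationError("lookback must be >= 1")
    deltas = []
    for i, prof in enumerate(profiles):
        if i < lookback:
            deltas.append(ColorDeltas(prof.frame_index, 0.0, 0.0, 0.0))
        else:
            prev = profiles[i - lookback]
            deltas.append(
                ColorDeltas(
                    prof.frame_index,
                    prof.s_pct - prev.s_pct,
                    prof.r_pct - prev.r_pct,
                    prof.bg_pct - prev.bg_pct,
                )
            )
    return deltas


def detect_candidate_frames(
    profiles: Sequence[FrameColorProfile],
    deltas: Sequence[ColorDeltas],
    config: DetectionConfig,
) -> np.ndarray:
    """Apply the threshold rule; returns one boolean flag per frame."""
    if len(profiles) != len(deltas):
        raise ValidationError("profiles and deltas are not aligned")
    d_bg = np.array([d.d_bg for d in deltas])
    d_r = np.array([d.d_r for d in deltas])
    s_pct = np.array([p.s_pct for p in profiles])
    r_bound = config.t_dr if config.literal_rule else -config.t_dr
    return (d_bg > config.t_dbg) & (d_r < r_bound) & (s_pct < config.t_s)


def segment_interruptions(
    profiles: Sequence[FrameColorProfile],
    candidates: np.ndarray,
    config: DetectionConfig,
) -> list[InterruptionEvent]:
    """Grow candidate flags into disjoint interruption events.

    Two-state machine over the frame series: the state switches to OUT at a
    flagged frame and back to IN at the first later frame whose red
    percentage has recovered to ``reentry_r_pct``. Each OUT run is a
    provisional event; runs separated by gaps of at most
    ``merge_gap_frames`` are merged, then runs shorter than
    ``min_event_frames`` are dropped. If the stream ends while OUT the event
    is closed at the final frame and logged as truncated.

    Positions are indices into the profile series; frame coordinates come
    from each profile's ``frame_index``.
    """
    candidates = np.asarray(candidates, dtype=bool)
    if len(profiles) != len(candidates):
        raise ValidationError("profiles and candidate flags are not aligned")
    runs: list[tuple[int, int]] = []  # half-open index runs
    out_since: int | None = None
    for i, prof in enumerate(profiles):
        if out_since is None:
            if candidates[i]:
                out_since = i
        elif prof.r_pct >= config.reentry_r_pct:
            runs.append((out_since, i))
            out_since = i if candidates[i] else None
    if out_since is not None:
        logger.warning(
            "stream ended while endoscope out; truncating event at frame %d",
            profiles[-1].frame_index,
        )
        runs.append((out_since, len(profiles)))

    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= config.merge_gap_frames:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    events = []
    n = len(profiles)
    for start, end in merged:
        start_frame = profiles[start].frame_index
        end_frame = (
            profiles[end].frame_index if end < n
            else profiles[-1].frame_index + 1
        )
        if end_frame - start_frame < config.min_event_frames:
            continue
        events.append(InterruptionEvent.from_frames(start_frame, end_frame, config.fps))
    validate_event_list(events)
    return events


@dataclass
class DetectionResult:
    """Events plus the per-frame audit table.

    ``profiles`` has columns frame_index, time_s, s_pct, r_pct, bg_pct,
    d_s, d_r, d_bg, candidate — enough to re-trace every decision the
    detector made.
    """

    events: list[InterruptionEvent]
    profiles: pd.DataFrame
    #: None when detection ran on the calibration-free rule classifier.
    reference: ColorReference | None


def _frame_factory(source, config: DetectionConfig, stride: int, downsample_width):
    """Return (callable yielding FrameRecords, n_frames or None)."""
    if hasattr(source, "iter_frames"):  # e.g. a SyntheticClip
        n = getattr(getattr(source, "schedule", None), "n_frames", None)
        return source.iter_frames, n
    if isinstance(source, (str, Path)):
        n = video_io.count_frames(source)
        return (
            lambda: video_io.iter_frames(
                source, fps_override=config.fps, stride=stride,
                downsample_width=downsample_width,
            ),
            n,
        )
    if isinstance(source, (list, tuple)):
        return (lambda: iter(source)), len(source)
    return None, None


def detect(
    source,
    reference: ColorReference | None = None,
    config: DetectionConfig | None = None,
    *,
    stride: int = 1,
    downsample_width: int | None = None,
    calibration_frames: int = 20,
    calibration_pixels: int = 5000,
    seed: int = 0,
) -> DetectionResult:
    """Run the full pipeline: frames → labels → profiles → deltas → events.

    Parameters
    ----------
    source
        A video path, an image-directory path, a sequence of
        :class:`FrameRecord`, or any object with an ``iter_frames()``
        method (e.g. a synthetic clip).
    reference
        A calibrated :class:`ColorReference`. If omitted, one is calibrated
        from ``calibration_frames`` frames evenly spaced through the source
        (``calibration_pixels`` pixels each, seeded by ``seed``); this
        requires a re-iterable source. If the calibration sample is
        degenerate (fewer than three distinct colors) detection falls back
        to the calibration-free rule classifier.
    config
        Detection thresholds; defaults to :class:`DetectionConfig()`.

    Returns
    -------
    DetectionResult
        Detected events, the per-frame audit table, and the reference used.
    """
    config = config or DetectionConfig()
    factory, n_frames = _frame_factory(source, config, stride, downsample_width)

    use_rule_fallback = False
    if reference is None:
        if factory is None:
            raise ConfigurationError(
                "source is a one-shot iterator; pass a ColorReference "
                "or a re-iterable source for auto-calibration"
            )
        try:
            reference = _auto_calibrate(
                source, factory, n_frames, config, stride, downsample_width,
                calibration_frames, calibration_pixels, seed,
            )
        except CalibrationError as exc:
            logger.warning("calibration degenerate (%s); using rule classifier", exc)
            use_rule_fallback = True

    frames: Iterable[FrameRecord] = factory() if factory is not None else source
    profiles = []
    for rec in frames:
        if use_rule_fallback:
            labels = classify_dominant_colors_rule(rec)
        else:
            labels = classify_dominant_colors(rec, reference)
        profiles.append(profile_frame(labels, rec.frame_index, rec.time_s))
    if not profiles:
        raise ValidationError("source yielded no frames")

    deltas = compute_color_deltas(profiles, config.lookback)
    candidates = detect_candidate_frames(profiles, deltas, config)
    events = segment_interruptions(profiles, candidates, config)

    table = pd.DataFrame(
        {
            "frame_index": [p.frame_index for p in profiles],
            "time_s": [p.time_s for p in profiles],
            "s_pct": [p.s_pct for p in profiles],
            "r_pct": [p.r_pct for p in profiles],
            "bg_pct": [p.bg_pct for p in profiles],
            "d_s": [d.d_s for d in deltas],
            "d_r": [d.d_r for d in deltas],
            "d_bg": [d.d_bg for d in deltas],
            "candidate": candidates,
        },
        columns=list(PROFILE_COLUMNS),
    )
    return DetectionResult(events=events, profiles=table, reference=reference)


def _auto_calibrate(
    source, factory, n_frames, config, stride, downsample_width,
    calibration_frames, calibration_pixels, seed,
) -> ColorReference:
    """Sample frames evenly through the source and calibrate on them."""
    if isinstance(source, (str, Path)) and n_frames:
        indices = np.unique(
            np.linspace(0, n_frames - 1, min(calibration_frames, n_frames)).round().astype(int)
        )
        sample = video_io.read_frames_at(
            source, indices, fps_override=config.fps, downsample_width=downsample_width
        )
    elif hasattr(source, "frame_at") and n_frames:
        indices = np.unique(
            np.linspace(0, n_frames - 1, min(calibration_frames, n_frames)).round().astype(int)
        )
        sample = [source.frame_at(int(i)) for i in indices]
    else:
        every = max(1, (n_frames or 0) // calibration_frames) if n_frames else 1
        sample = [rec for i, rec in enumerate(factory()) if i % every == 0]
        sample = sample[:calibration_frames] if calibration_frames else sample
    return calibrate_color_references(sample, sample_pixels=calibration_pixels, seed=seed)
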