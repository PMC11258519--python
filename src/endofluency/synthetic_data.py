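"""Seeded synthetic endoscopic scenes with scripted ground truth.

No operative video is distributed with this package, so every other module
is exercised against rendered clips that mimic the color structure of an
endonasal endoscopic scene: a red-pinkish mucosa field, a blue-greenish
surgical-drape field shown while the endoscope is withdrawn, silver
instrument/gauze occlusions, and bleeding episodes that darken the mucosa
toward blood red. A :class:`SceneSchedule` scripts *when* each element
appears; the ground-truth interruption events are derived from the
schedule's withdrawal intervals, never re-derived from rendered pixels, so
truth stays independent of the renderer.

Bleeding alone is deliberately NOT an interruption: a real interruption
requires blood contamination *and* endoscope removal *and* lens cleaning,
and only the scripted withdrawals model that.

Default palettes (RGB means): mucosa (200, 40, 60), drape (30, 120, 130),
instrument/gauze silver (180, 180, 180), blood (110, 15, 25). Per-pixel
Gaussian noise with standard deviation ``noise_sd`` is added and clipped to
[0, 255]. Rendering is reproducible frame-by-frame: each frame's noise is
drawn from a generator seeded by (seed, frame index), so a clip can be
re-iterated or randomly accessed with identical output.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v2 as iio
import numpy as np
import yaml

from . import video_io
from .errors import GenerationError, ValidationError
from .types import FrameRecord, InterruptionEvent

DEFAULT_PALETTE = {
    "mucosa": (200, 40, 60),
    "drape": (30, 120, 130),
    "instrument": (180, 180, 180),
    "blood": (110, 15, 25),
}


def palette_reference(palette: dict | None = None, seed: int = 0):
    """A :class:`~endofluency.color_model.ColorReference` whose centroids are
    the generator's palette means — the exact-knowledge reference for clips
    rendered from that palette (useful when a clip never shows all three
    classes, which starves k-means calibration)."""
    from .color_model import ColorReference

    pal = palette or DEFAULT_PALETTE
    centroids = np.array([pal["instrument"], pal["mucosa"], pal["drape"]], dtype=float)
    return ColorReference(centroids=centroids, seed=seed)


def _check_intervals(intervals, n_frames: int, what: str, disjoint: bool) -> None:
    for lo, hi in intervals:
        if not (0 <= lo < hi <= n_frames):
            raise ValidationError(f"{what} interval [{lo}, {hi}) outside [0, {n_frames})")
    if disjoint:
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise ValidationError(f"{what} intervals overlap or are unsorted")


@dataclass
class SceneSchedule:
    """Script of a synthetic clip.

    ``withdrawals`` are half-open frame intervals during which the endoscope
    is out (the ground-truth interruptions). ``occlusions`` are
    (interval, coverage) pairs painting a silver region over the stated
    fraction of the frame; ``bleeding`` are (interval, intensity) pairs
    blending the mucosa toward blood red. ``transition_frames`` frames of
    linear blending surround each withdrawal boundary (0 = abrupt cuts).
    """

    fps: float
    n_frames: int
    withdrawals: list[tuple[int, int]] = field(default_factory=list)
    occlusions: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    bleeding: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    transition_frames: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.fps <= 0:
            raise ValidationError("n_frames must be >= 1 and fps positive")
        if self.transition_frames < 0:
            raise ValidationError("transition_frames must be >= 0")
        self.withdrawals = sorted(tuple(w) for w in self.withdrawals)
        _check_intervals(self.withdrawals, self.n_frames, "withdrawal", disjoint=True)
        self.occlusions = [(tuple(iv), float(c)) for iv, c in self.occlusions]
        self.bleeding = [(tuple(iv), float(x)) for iv, x in self.bleeding]
        _check_intervals([iv for iv, _ in self.occlusions], self.n_frames, "occlusion", False)
        _check_intervals([iv for iv, _ in self.bleeding], self.n_frames, "bleeding", False)
        for _, cov in self.occlusions:
            if not 0 <= cov <= 1:
                raise ValidationError(f"occlusion coverage {cov} outside [0, 1]")
        for _, inten in self.bleeding:
            if not 0 <= inten <= 1:
                raise ValidationError(f"bleeding intensity {inten} outside [0, 1]")

    def truth_events(self) -> list[InterruptionEvent]:
        """Ground-truth interruptions: exactly the withdrawal intervals."""
        return [
            InterruptionEvent.from_frames(lo, hi, self.fps) for lo, hi in self.withdrawals
        ]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneSchedule":
        data = yaml.safe_load(Path(path).read_text())
        data["withdrawals"] = [tuple(w) for w in data.get("withdrawals", [])]
        data["occlusions"] = [(tuple(iv), c) for iv, c in data.get("occlusions", [])]
        data["bleeding"] = [(tuple(iv), x) for iv, x in data.get("bleeding", [])]
        return cls(**data)


def random_schedule(
    n_frames: int,
    fps: float = 30.0,
    n_withdrawals: int = 3,
    n_occlusions: int = 0,
    seed: int = 0,
    n_bleeding: int = 0,
    withdrawal_frames: tuple[int, int] = (30, 300),
    occlusion_frames: tuple[int, int] = (30, 150),
    occlusion_coverage: tuple[float, float] = (0.2, 0.6),
    bleeding_frames: tuple[int, int] = (30, 150),
    bleeding_intensity: tuple[float, float] = (0.3, 0.9),
    min_gap_frames: int = 60,
    transition_frames: int = 0,
) -> SceneSchedule:
    """Draw a reproducible random schedule.

    Withdrawal durations are uniform over ``withdrawal_frames``; events are
    placed disjointly with at least ``min_gap_frames`` between them and
    before the first (so every event has preceding mucosa frames to diff
    against). Occlusions and bleeding are placed inside the non-withdrawal
    spans, so distractors never coincide with a true interruption.

    Raises :class:`GenerationError` when the requested events cannot be
    packed into ``n_frames``.
    """
    rng = np.random.default_rng(seed)
    durations = (
        rng.integers(withdrawal_frames[0], withdrawal_frames[1] + 1, size=n_withdrawals)
        if n_withdrawals
        else np.array([], dtype=int)
    )
    slack = n_frames - int(durations.sum()) - min_gap_frames * (n_withdrawals + 1)
    if slack < 0:
        raise GenerationError(
            f"cannot pack {n_withdrawals} withdrawals totalling {durations.sum()} "
            f"frames plus gaps into {n_frames} frames"
        )
    extra = rng.multinomial(slack, np.ones(n_withdrawals + 1) / (n_withdrawals + 1)) \
        if n_withdrawals else np.array([slack])
    withdrawals = []
    cursor = 0
    for dur, pad in zip(durations, extra):
        start = cursor + min_gap_frames + int(pad)
        withdrawals.append((start, start + int(dur)))
        cursor = start + int(dur)

    free_spans = _complement(withdrawals, n_frames)
    occlusions = _place_distractors(
        rng, free_spans, n_occlusions, occlusion_frames, occlusion_coverage, "occlusion"
    )
    bleeding = _place_distractors(
        rng, free_spans, n_bleeding, bleeding_frames, bleeding_intensity, "bleeding"
    )
    return SceneSchedule(
        fps=fps,
        n_frames=n_frames,
        withdrawals=withdrawals,
        occlusions=occlusions,
        bleeding=bleeding,
        transition_frames=transition_frames,
    )


def _complement(intervals: list[tuple[int, int]], n_frames: int) -> list[tuple[int, int]]:
    spans = []
    cursor = 0
    for lo, hi in intervals:
        if lo > cursor:
            spans.append((cursor, lo))
        cursor = hi
    if cursor < n_frames:
        spans.append((cursor, n_frames))
    return spans


def _place_distractors(rng, free_spans, count, frame_range, value_range, what):
    placed = []
    if not count:
        return placed
    spans = [s for s in free_spans if s[1] - s[0] > frame_range[0]]
    if not spans:
        raise GenerationError(f"no room outside withdrawals to place {what}s")
    for _ in range(count):
        lo, hi = spans[rng.integers(len(spans))]
        dur = int(rng.integers(frame_range[0], min(frame_range[1], hi - lo) + 1))
        start = int(rng.integers(lo, hi - dur + 1))
        value = float(rng.uniform(*value_range))
        placed.append(((start, start + dur), value))
    return placed


@dataclass
class SyntheticClip:
    """A lazily rendered clip plus its schedule and ground truth.

    Frames are rendered on demand (``frame_at``/``iter_frames``), so long
    clips never sit in memory; re-iteration yields bit-identical frames.
    """

    schedule: SceneSchedule
    seed: int = 0
    width: int = 480
    height: int = 270
    noise_sd: float = 0.0
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValidationError("clip must be at least 16x16 pixels")
        pal = {k: np.array(v, dtype=float) for k, v in self.palette.items()}
        missing = set(DEFAULT_PALETTE) - set(pal)
        if missing:
            raise ValidationError(f"palette missing entries: {sorted(missing)}")
        self.palette = pal
        if self.noise_sd > 0:
            gap = min(
                np.linalg.norm(pal["mucosa"] - pal["drape"]),
                np.linalg.norm(pal["mucosa"] - pal["instrument"]),
                np.linalg.norm(pal["drape"] - pal["instrument"]),
            )
            if gap < 3 * self.noise_sd:
                warnings.warn(
                    f"palette means are only {gap:.1f} apart with noise_sd="
                    f"{self.noise_sd}; color classes may be inseparable",
                    stacklevel=2,
                )
        self._frame_cache: dict = {}

    @property
    def truth_events(self) -> list[InterruptionEvent]:
        return self.schedule.truth_events()

    # -- rendering ----------------------------------------------------------

    def _drape_weight(self, index: int) -> float:
        """Blend weight of the drape at this frame: 1 inside a withdrawal,
        linear ramps over transition_frames just outside each boundary."""
        t = self.schedule.transition_frames
        w = 0.0
        for lo, hi in self.schedule.withdrawals:
            if lo <= index < hi:
                return 1.0
            if t:
                if lo - t <= index < lo:
                    w = max(w, (index - (lo - t) + 1) / (t + 1))
                elif hi <= index < hi + t:
                    w = max(w, 1.0 - (index - hi + 1) / (t + 1))
        return w

    def frame_at(self, index: int) -> FrameRecord:
        """Render frame ``index`` deterministically.

        Noiseless frames with the same scene content share one cached pixel
        array (treat frames as read-only); noisy frames are drawn from a
        generator seeded by (clip seed, frame index), so random access and
        re-iteration are bit-identical.
        """
        sched = self.schedule
        if not 0 <= index < sched.n_frames:
            raise ValidationError(f"frame index {index} outside [0, {sched.n_frames})")
        base = self.palette["mucosa"]
        for (lo, hi), intensity in sched.bleeding:
            if lo <= index < hi:
                base = base + intensity * (self.palette["blood"] - base)
        w = self._drape_weight(index)
        color = base + w * (self.palette["drape"] - base)
        paints = tuple(
            round(cov * self.height * self.width)
            for (lo, hi), cov in sched.occlusions
            if w == 0.0 and lo <= index < hi  # instruments retract during withdrawals
        )

        cache_key = (tuple(color), paints) if self.noise_sd == 0 else None
        if cache_key is not None and cache_key in self._frame_cache:
            pixels = self._frame_cache[cache_key]
        else:
            frame = np.broadcast_to(color, (self.height, self.width, 3)).copy()
            flat = frame.reshape(-1, 3)
            for n_paint in paints:
                flat[:n_paint] = self.palette["instrument"]
            if self.noise_sd > 0:
                rng = np.random.default_rng([self.seed, index])
                frame = frame + rng.normal(0.0, self.noise_sd, size=frame.shape)
            pixels = np.clip(frame, 0, 255).round().astype(np.uint8)
            if cache_key is not None:
                self._frame_cache[cache_key] = pixels
        return FrameRecord(frame_index=index, time_s=index / sched.fps, pixels=pixels)

    def iter_frames(self) -> Iterator[FrameRecord]:
        for index in range(self.schedule.n_frames):
            yield self.frame_at(index)


def render_clip(
    schedule: SceneSchedule,
    palette: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    width: int = 480,
    height: int = 270,
) -> SyntheticClip:
    """Bind a schedule to a renderer; frames are produced lazily."""
    return SyntheticClip(
        schedule=schedule,
        seed=seed,
        width=width,
        height=height,
        noise_sd=noise_sd,
        palette=palette or dict(DEFAULT_PALETTE),
    )


def make_benchmark(
    out_dir: str | Path,
    seed: int = 0,
    n_frames: int = 1800,
    fps: float = 30.0,
    n_withdrawals: int = 3,
    n_occlusions: int = 2,
    n_bleeding: int = 1,
    noise_sd: float = 10.0,
    width: int = 480,
    height: int = 270,
    transition_frames: int = 0,
) -> Path:
    """Persist a benchmark clip: frame PNGs + truth JSON + schedule YAML.

    The frame directory is readable by :func:`endofluency.video_io.iter_frames`;
    ``manifest.json`` records the generator arguments and a truth checksum
    so the benchmark can be regenerated bit-for-bit.
    """
    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    config = {
        "seed": seed,
        "n_frames": n_frames,
        "fps": fps,
        "n_withdrawals": n_withdrawals,
        "n_occlusions": n_occlusions,
        "n_bleeding": n_bleeding,
        "noise_sd": noise_sd,
        "width": width,
        "height": height,
        "transition_frames": transition_frames,
    }
    schedule = random_schedule(
        n_frames=n_frames,
        fps=fps,
        n_withdrawals=n_withdrawals,
        n_occlusions=n_occlusions,
        n_bleeding=n_bleeding,
        seed=seed,
        transition_frames=transition_frames,
    )
    clip = render_clip(schedule, noise_sd=noise_sd, seed=seed, width=width, height=height)
    digits = len(str(n_frames - 1))
    for rec in clip.iter_frames():
        iio.imwrite(frames_dir / f"frame_{rec.frame_index:0{digits}d}.png", rec.pixels)
    video_io.write_events(clip.truth_events, out_dir / "truth.json")
    schedule.to_yaml(out_dir / "schedule.yaml")
    truth_checksum = hashlib.sha256((out_dir / "truth.json").read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps({"config": config, "truth_sha256": truth_checksum}, indent=2) + "\n"
    )
    return out_dir
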