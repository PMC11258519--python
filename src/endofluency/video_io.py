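"""Frame-stream and file I/O.

Reads ordered :class:`~endofluency.types.FrameRecord` streams from a video
file or a directory of image frames, and reads/writes the tool's event,
phase-annotation, and color-profile files.

Timestamps are always computed from the *original* frame index and the
source fps, so striding through a stream never distorts them.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v2 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError, InputError, ParseError, ValidationError
from .types import FrameRecord, InterruptionEvent, PhaseAnnotation

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

#: Optional per-directory manifest: one frame filename per line, overriding
#: the natural-sort ordering of an image directory.
FRAME_MANIFEST_NAME = "frames.txt"

EVENT_FIELDS = ("start_frame", "end_frame", "start_s", "end_s", "duration_s")


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically: frame2 < frame10."""
    return tuple(
        int(part) if part.isdigit() else part.lower()
        for part in re.split(r"(\d+)", name)
    )


def _list_frame_files(directory: Path) -> list[Path]:
    manifest = directory / FRAME_MANIFEST_NAME
    if manifest.exists():
        names = [ln.strip() for ln in manifest.read_text().splitlines() if ln.strip()]
        files = [directory / n for n in names]
        missing = [str(f) for f in files if not f.exists()]
        if missing:
            raise InputError(f"manifest {manifest} names missing frames: {missing}")
        return files
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise InputError(f"no image frames found in directory {directory}")
    return files


def _ensure_rgb(arr: np.ndarray, origin: str) -> np.ndarray:
    """Normalize a decoded image to (H, W, 3) uint8 RGB."""
    arr = np.asarray(arr)
    if arr.ndim == 2:  # grayscale
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"{origin}: cannot interpret shape {arr.shape} as RGB")
    return arr.astype(np.uint8, copy=False)


def _downsample(arr: np.ndarray, target_width: int) -> np.ndarray:
    h, w = arr.shape[:2]
    if target_width >= w:
        return arr
    target_height = max(1, round(h * target_width / w))
    img = Image.fromarray(arr).resize((target_width, target_height), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def count_frames(source: str | Path) -> int:
    """Number of frames in a video file or image directory."""
    path = Path(source)
    if not path.exists():
        raise InputError(f"source does not exist: {path}")
    if path.is_dir():
        return len(_list_frame_files(path))
    try:
        reader = iio.get_reader(path)
    except Exception as exc:  # decoder-specific exception types vary
        raise InputError(f"cannot decode video {path}: {exc}") from exc
    with reader:
        n = reader.count_frames()
    if n is None or (isinstance(n, float) and math.isinf(n)):
        raise InputError(f"cannot determine frame count of {path}")
    return int(n)


def probe_fps(source: str | Path, fps_override: float | None = None) -> float:
    """Frames-per-second of a source.

    Image directories carry no rate metadata, so ``fps_override`` is
    mandatory for them.
    """
    if fps_override is not None:
        if fps_override <= 0:
            raise ConfigurationError(f"fps_override must be positive, got {fps_override}")
        return float(fps_override)
    path = Path(source)
    if path.is_dir():
        raise ConfigurationError(
            f"{path} is an image directory with no fps metadata; pass fps_override"
        )
    try:
        reader = iio.get_reader(path)
    except Exception as exc:
        raise InputError(f"cannot decode video {path}: {exc}") from exc
    with reader:
        meta = reader.get_meta_data()
    fps = meta.get("fps")
    if not fps or fps <= 0:
        raise ConfigurationError(f"no fps metadata in {path}; pass fps_override")
    return float(fps)


def iter_frames(
    source: str | Path,
    fps_override: float | None = None,
    stride: int = 1,
    downsample_width: int | None = None,
) -> Iterator[FrameRecord]:
    """Yield every ``stride``-th frame of a video file or image directory.

    Parameters
    ----------
    source
        Path to a decodable video file, or a directory of image frames
        (ordered by natural filename sort, or by a ``frames.txt`` manifest).
    fps_override
        Frame rate to use instead of (or in absence of) container metadata.
        Required for image directories.
    stride
        Keep frames with original index 0, stride, 2*stride, ... For an
        N-frame source this yields exactly ``ceil(N / stride)`` records.
    downsample_width
        If set, resize frames to this width, preserving aspect ratio.

    Notes
    -----
    ``time_s`` is computed from the original frame index, so striding and
    downsampling never change timestamps.
    """
    if stride < 1:
        raise ConfigurationError(f"stride must be >= 1, got {stride}")
    if downsample_width is not None and downsample_width < 1:
        raise ConfigurationError(f"downsample_width must be positive, got {downsample_width}")
    path = Path(source)
    if not path.exists():
        raise InputError(f"source does not exist: {path}")
    fps = probe_fps(path, fps_override)

    if path.is_dir():
        files = _list_frame_files(path)
        for index in range(0, len(files), stride):
            arr = _ensure_rgb(iio.imread(files[index]), str(files[index]))
            if downsample_width is not None:
                arr = _downsample(arr, downsample_width)
            yield FrameRecord(frame_index=index, time_s=index / fps, pixels=arr)
        return

    try:
        reader = iio.get_reader(path)
    except Exception as exc:
        raise InputError(f"cannot decode video {path}: {exc}") from exc
    with reader:
        for index, arr in enumerate(reader):
            if index % stride:
                continue
            arr = _ensure_rgb(arr, f"{path}#{index}")
            if downsample_width is not None:
                arr = _downsample(arr, downsample_width)
            yield FrameRecord(frame_index=index, time_s=index / fps, pixels=arr)


def read_frames_at(
    source: str | Path,
    indices: Sequence[int],
    fps_override: float | None = None,
    downsample_width: int | None = None,
) -> list[FrameRecord]:
    """Read specific frames by original index (used for calibration sampling)."""
    path = Path(source)
    fps = probe_fps(path, fps_override)
    wanted = sorted(set(int(i) for i in indices))
    records: list[FrameRecord] = []
    if path.is_dir():
        files = _list_frame_files(path)
        for index in wanted:
            if index >= len(files):
                raise InputError(f"frame index {index} out of range for {path}")
            arr = _ensure_rgb(iio.imread(files[index]), str(files[index]))
            if downsample_width is not None:
                arr = _downsample(arr, downsample_width)
            records.append(FrameRecord(index, index / fps, arr))
        return records
    remaining = set(wanted)
    for rec in iter_frames(path, fps_override=fps, downsample_width=downsample_width):
        if rec.frame_index in remaining:
            records.append(rec)
            remaining.discard(rec.frame_index)
            if not remaining:
                break
    if remaining:
        raise InputError(f"frame indices {sorted(remaining)} out of range for {path}")
    return records


# ---------------------------------------------------------------------------
# Event files


def write_events(
    events: Iterable[InterruptionEvent],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write events as JSON (array of objects) or CSV.

    The format is taken from ``format`` if given, else from the file suffix.
    A write→read round trip reproduces the events exactly (frame indices
    exact, seconds to at least six decimals).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    rows = [asdict(e) for e in events]
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    elif fmt == "csv":
        # pandas' default float formatting is the shortest round-tripping
        # repr, so second coordinates survive a write→read cycle exactly
        pd.DataFrame(rows, columns=EVENT_FIELDS).to_csv(path, index=False)
    else:
        raise ConfigurationError(f"unsupported event format {fmt!r} (use json or csv)")


def read_events(path: str | Path, format: str | None = None) -> list[InterruptionEvent]:
    """Read an event file written by :func:`write_events` (or hand-edited)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"event file does not exist: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        try:
            rows = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        if not isinstance(rows, list):
            raise ParseError(f"{path}: expected a JSON array of events")
    elif fmt == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        missing = set(EVENT_FIELDS) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        rows = df.to_dict("records")
    else:
        raise ConfigurationError(f"unsupported event format {fmt!r} (use json or csv)")

    events = []
    for i, row in enumerate(rows):
        try:
            events.append(
                InterruptionEvent(
                    start_frame=int(row["start_frame"]),
                    end_frame=int(row["end_frame"]),
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    duration_s=float(row["duration_s"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: event {i}: {exc}") from exc
    return events


# ---------------------------------------------------------------------------
# Phase annotations


def read_phase_annotations(path: str | Path) -> list[PhaseAnnotation]:
    """Read a CSV of phase annotations (columns phase, start_s, end_s).

    Returns annotations sorted by ``start_s``. Overlapping intervals or
    unknown phase labels raise :class:`ValidationError` listing the
    offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file does not exist: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"phase", "start_s", "end_s"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    annotations = []
    bad_rows = []
    for i, row in df.iterrows():
        try:
            annotations.append(
                PhaseAnnotation(
                    phase=str(row["phase"]),
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            bad_rows.append(f"row {i}: {exc}")
    if bad_rows:
        raise ValidationError(f"{path}: invalid annotations: " + "; ".join(bad_rows))
    annotations.sort(key=lambda a: a.start_s)
    overlaps = [
        f"rows ({a.phase} {a.start_s}-{a.end_s}) and ({b.phase} {b.start_s}-{b.end_s})"
        for a, b in zip(annotations, annotations[1:])
        if b.start_s < a.end_s
    ]
    if overlaps:
        raise ValidationError(f"{path}: overlapping intervals: " + "; ".join(overlaps))
    return annotations


def write_phase_annotations(annotations: Iterable[PhaseAnnotation], path: str | Path) -> None:
    pd.DataFrame([asdict(a) for a in annotations], columns=["phase", "start_s", "end_s"]).to_csv(
        Path(path), index=False
    )
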