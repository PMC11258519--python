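"""Shared test utilities: tiny frame builders and brute-force oracles.

The oracles here deliberately re-derive results by naive enumeration so the
library implementations are checked against independent logic.
"""

from __future__ import annotations

import numpy as np

from endofluency import FrameColorProfile, FrameRecord, InterruptionEvent
from endofluency.synthetic_data import DEFAULT_PALETTE

MUCOSA = DEFAULT_PALETTE["mucosa"]
DRAPE = DEFAULT_PALETTE["drape"]
INSTRUMENT = DEFAULT_PALETTE["instrument"]


def solid_frame(color, index=0, fps=30.0, height=20, width=20) -> FrameRecord:
    pixels = np.tile(np.asarray(color, dtype=np.uint8), (height, width, 1))
    return FrameRecord(frame_index=index, time_s=index / fps, pixels=pixels)


def profiles_from_r_series(r_pct_series, fps=30.0) -> list[FrameColorProfile]:
    """Profile series with the given red percentages (rest goes to B-G)."""
    return [
        FrameColorProfile(i, i / fps, 0.0, float(r), 100.0 - float(r))
        for i, r in enumerate(r_pct_series)
    ]


def brute_force_segment(flags, r_pct, config) -> list[tuple[int, int]]:
    """Naive O(n^2) re-derivation of event segmentation.

    Enumerate maximal OUT runs (a run opens at a flagged frame and extends
    until red recovers), merge runs with small gaps by explicit pairwise
    scanning, then drop short runs.
    """
    n = len(flags)
    runs = []
    i = 0
    while i < n:
        if flags[i]:
            j = i + 1
            while j < n and r_pct[j] < config.reentry_r_pct:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= config.merge_gap_frames:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [(a, b) for a, b in merged if b - a >= config.min_event_frames]


def brute_force_confusion(predicted, truth, n_frames) -> tuple[int, int, int, int]:
    """Per-frame confusion by scanning every frame against every event."""

    def covered(frame, events):
        return any(e.start_frame <= frame < e.end_frame for e in events)

    tp = fp = fn = tn = 0
    for frame in range(n_frames):
        p, t = covered(frame, predicted), covered(frame, truth)
        tp += p and t
        fp += p and not t
        fn += t and not p
        tn += not p and not t
    return tp, fp, fn, tn


def random_event_list(rng, n_frames, max_events=5, min_len=1) -> list[InterruptionEvent]:
    """Sorted, disjoint random events within [0, n_frames)."""
    events = []
    cursor = 0
    for _ in range(rng.integers(0, max_events + 1)):
        if cursor + min_len + 1 >= n_frames:
            break
        start = int(rng.integers(cursor, n_frames - min_len))
        end = int(rng.integers(start + min_len, min(n_frames, start + n_frames // 3) + 1))
        events.append(InterruptionEvent.from_frames(start, end, 30.0))
        cursor = end + 1
    return events
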