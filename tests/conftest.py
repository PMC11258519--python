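from __future__ import annotations

import pytest

from endofluency import InterruptionEvent
from endofluency.synthetic_data import palette_reference

from helpers import solid_frame


@pytest.fixture
def reference():
    """Exact-knowledge reference: centroids at the synthetic palette means."""
    return palette_reference()


@pytest.fixture
def event_factory():
    """Build an event from frame bounds at a given fps (default 30)."""

    def make(start_frame: int, end_frame: int, fps: float = 30.0) -> InterruptionEvent:
        return InterruptionEvent.from_frames(start_frame, end_frame, fps)

    return make


@pytest.fixture
def make_solid_frame():
    return solid_frame
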