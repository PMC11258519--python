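import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endofluency import (
    ColorDeltas,
    ConfigurationError,
    DetectionConfig,
    compute_color_deltas,
    detect,
    detect_candidate_frames,
    segment_interruptions,
)
from endofluency.synthetic_data import SceneSchedule, palette_reference, render_clip

from helpers import brute_force_segment, profiles_from_r_series


def deltas_from(d_list):
    return [ColorDeltas(i, d_s, d_r, d_bg) for i, (d_s, d_r, d_bg) in enumerate(d_list)]


class TestDeltas:
    def test_constant_series_gives_zero_deltas(self):
        profiles = profiles_from_r_series([80.0] * 5)
        deltas = compute_color_deltas(profiles, lookback=1)
        assert all(d.d_s == d.d_r == d.d_bg == 0.0 for d in deltas)

    def test_withdrawal_step_lookback_one(self):
        from endofluency import FrameColorProfile

        # (s, r, bg): (5, 90, 5), (5, 90, 5), (5, 20, 75)
        profiles = [
            FrameColorProfile(0, 0.0, 5.0, 90.0, 5.0),
            FrameColorProfile(1, 1 / 30, 5.0, 90.0, 5.0),
            FrameColorProfile(2, 2 / 30, 5.0, 20.0, 75.0),
        ]
        deltas = compute_color_deltas(profiles, lookback=1)
        assert deltas[2].d_r == pytest.approx(-70.0)
        assert deltas[2].d_bg == pytest.approx(70.0)

    def test_lookback_beyond_series_yields_all_zero(self):
        profiles = profiles_from_r_series([90.0, 10.0])
        deltas = compute_color_deltas(profiles, lookback=2)
        assert all(d.d_s == d.d_r == d.d_bg == 0.0 for d in deltas)

    @given(
        r=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=60),
        lookback=st.integers(1, 5),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_delta_conservation(self, r, lookback):
        """d_s + d_r + d_bg == 0: deltas of a partition sum to zero."""
        deltas = compute_color_deltas(profiles_from_r_series(r), lookback)
        for d in deltas:
            assert d.d_s + d.d_r + d.d_bg == pytest.approx(0.0, abs=1e-9)


class TestCandidateRule:
    def test_withdrawal_signature_is_flagged(self):
        profiles = profiles_from_r_series([90, 20])
        deltas = deltas_from([(0, 0, 0), (0, -70, 70)])
        flags = detect_candidate_frames(profiles, deltas, DetectionConfig())
        assert list(flags) == [False, True]

    def test_high_silver_suppresses_the_claim(self):
        # same color swing, but 40% silver: moving-instrument exclusion
        from endofluency import FrameColorProfile

        profiles = [
            FrameColorProfile(0, 0.0, 40.0, 55.0, 5.0),
            FrameColorProfile(1, 1 / 30, 40.0, 5.0, 55.0),
        ]
        deltas = deltas_from([(0, 0, 0), (0, -50, 50)])
        flags = detect_candidate_frames(profiles, deltas, DetectionConfig())
        assert not flags.any()

    def test_zero_deltas_never_flag(self):
        profiles = profiles_from_r_series([50.0] * 4)
        deltas = deltas_from([(0, 0, 0)] * 4)
        assert not detect_candidate_frames(profiles, deltas, DetectionConfig()).any()

    def test_literal_rule_accepts_small_r_change(self):
        """The as-printed inequality dR < T(dr) fires without an R decrease;
        the default (decrease) semantics does not."""
        profiles = profiles_from_r_series([30, 35])
        deltas = deltas_from([(0, 0, 0), (-45, 5, 40)])
        default_flags = detect_candidate_frames(profiles, deltas, DetectionConfig())
        literal_flags = detect_candidate_frames(
            profiles, deltas, DetectionConfig(literal_rule=True)
        )
        assert not default_flags.any()
        assert list(literal_flags) == [False, True]

    def test_raising_t_dbg_never_adds_flags(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 100, size=300)
        profiles = profiles_from_r_series(r)
        deltas = compute_color_deltas(profiles, 1)
        previous = None
        for t_dbg in (10, 30, 50, 70, 90):
            flags = detect_candidate_frames(
                profiles, deltas, DetectionConfig(t_dbg=t_dbg)
            )
            if previous is not None:
                assert not (flags & ~previous).any()
            previous = flags


class TestSegmentation:
    def test_state_machine_trace(self):
        """OUT at the flagged frame, IN when red recovers: event [100, 220)."""
        r = np.full(300, 90.0)
        r[100:220] = 10.0
        profiles = profiles_from_r_series(r)
        flags = np.zeros(300, dtype=bool)
        flags[100] = True
        events = segment_interruptions(profiles, flags, DetectionConfig())
        assert [(e.start_frame, e.end_frame) for e in events] == [(100, 220)]
        assert events[0].duration_s == pytest.approx(4.0)

    def test_short_run_discarded(self):
        r = np.full(100, 90.0)
        r[40:52] = 10.0  # 12-frame run < min_event_frames=30
        profiles = profiles_from_r_series(r)
        flags = np.zeros(100, dtype=bool)
        flags[40] = True
        assert segment_interruptions(profiles, flags, DetectionConfig()) == []

    def test_nearby_runs_merge(self):
        r = np.full(300, 90.0)
        r[100:160] = 10.0
        r[165:230] = 10.0
        profiles = profiles_from_r_series(r)
        flags = np.zeros(300, dtype=bool)
        flags[[100, 165]] = True
        events = segment_interruptions(
            profiles, flags, DetectionConfig(merge_gap_frames=10)
        )
        assert [(e.start_frame, e.end_frame) for e in events] == [(100, 230)]

    def test_stream_end_truncates_open_event(self, caplog):
        r = np.full(200, 90.0)
        r[150:] = 10.0
        profiles = profiles_from_r_series(r)
        flags = np.zeros(200, dtype=bool)
        flags[150] = True
        with caplog.at_level(logging.WARNING):
            events = segment_interruptions(profiles, flags, DetectionConfig())
        assert [(e.start_frame, e.end_frame) for e in events] == [(150, 200)]
        assert any("truncat" in rec.message for rec in caplog.records)

    def test_raising_min_event_frames_never_adds_events(self):
        rng = np.random.default_rng(5)
        r = rng.choice([90.0, 10.0], size=1000, p=[0.7, 0.3])
        profiles = profiles_from_r_series(r)
        flags = rng.random(1000) < 0.1
        counts = [
            len(segment_interruptions(profiles, flags, DetectionConfig(min_event_frames=m)))
            for m in (1, 10, 30, 60, 120)
        ]
        assert counts == sorted(counts, reverse=True)

    @given(
        seed=st.integers(0, 2**20),
        n=st.integers(1, 400),
        flag_p=st.floats(0.01, 0.5),
        merge_gap=st.integers(0, 20),
        min_frames=st.integers(1, 40),
    )
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_matches_brute_force_enumeration(self, seed, n, flag_p, merge_gap, min_frames):
        rng = np.random.default_rng(seed)
        r = rng.choice([90.0, 10.0], size=n)
        flags = rng.random(n) < flag_p
        config = DetectionConfig(merge_gap_frames=merge_gap, min_event_frames=min_frames)
        events = segment_interruptions(profiles_from_r_series(r), flags, config)
        expected = brute_force_segment(flags, r, config)
        assert [(e.start_frame, e.end_frame) for e in events] == expected


class TestDetectPipeline:
    def test_no_withdrawals_yields_no_events(self, reference):
        schedule = SceneSchedule(fps=30, n_frames=200)
        clip = render_clip(schedule)
        result = detect(clip, reference=reference)
        assert result.events == []
        assert list(result.profiles.columns) == [
            "frame_index", "time_s", "s_pct", "r_pct", "bg_pct",
            "d_s", "d_r", "d_bg", "candidate",
        ]

    def test_scripted_withdrawals_recovered_exactly(self, reference):
        schedule = SceneSchedule(
            fps=30, n_frames=600, withdrawals=[(100, 180), (300, 360), (450, 520)]
        )
        clip = render_clip(schedule)
        result = detect(clip, reference=reference)
        assert [(e.start_frame, e.end_frame) for e in result.events] == \
            schedule.withdrawals

    def test_instrument_occlusion_without_withdrawal_is_ignored(self, reference):
        schedule = SceneSchedule(
            fps=30, n_frames=300, occlusions=[((100, 200), 0.6)]
        )
        clip = render_clip(schedule)
        assert detect(clip, reference=reference).events == []

    def test_detect_is_deterministic(self, reference):
        schedule = SceneSchedule(fps=30, n_frames=300, withdrawals=[(100, 180)])
        clip = render_clip(schedule, noise_sd=15, seed=4)
        first = detect(clip, reference=reference)
        second = detect(clip, reference=reference)
        assert first.events == second.events
        pd.testing.assert_frame_equal(first.profiles, second.profiles)

    def test_one_shot_iterator_without_reference_is_an_error(self, reference):
        schedule = SceneSchedule(fps=30, n_frames=40)
        frames = render_clip(schedule).iter_frames()  # generator, not re-iterable
        with pytest.raises(ConfigurationError, match="one-shot"):
            detect(frames)
        assert detect(frames, reference=reference).events == []


class TestConfig:
    def test_defaults_are_the_published_thresholds(self):
        config = DetectionConfig()
        assert (config.t_dbg, config.t_dr, config.t_s) == (35.0, 22.0, 32.0)
        assert config.min_event_frames == 30

    def test_yaml_round_trip_and_unknown_key(self, tmp_path):
        config = DetectionConfig(t_dbg=40, merge_gap_frames=5)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert DetectionConfig.from_yaml(path) == config
        path.write_text("t_dgb: 40\n")  # typo'd key
        with pytest.raises(ConfigurationError, match="t_dgb"):
            DetectionConfig.from_yaml(path)

    @pytest.mark.parametrize(
        "kwargs", [{"t_dbg": 120}, {"min_event_frames": 0}, {"fps": 0}, {"lookback": 0}]
    )
    def test_out_of_range_values_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            DetectionConfig(**kwargs)
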