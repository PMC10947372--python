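"""Frame differencing, precedence masks, respiration filter, detector."""

import numpy as np
import pandas as pd
import pytest

from rbdmotion.depthio import DepthSequence, ROILayout, TrackSet
from rbdmotion.motion import (
    DetectorParams,
    detect_motion,
    effective_masks,
    frame_difference,
    respiration_suppress,
)
from rbdmotion.synthetic import (
    PlantedEvent,
    SceneConfig,
    generate_hypnogram,
    render_depth_video,
)
from rbdmotion.depthio import rem_intervals


def _seq(frames, fps=30.0):
    return DepthSequence(np.asarray(frames, dtype=np.uint16), fps=fps)


class TestFrameDifference:
    def test_identical_frames_give_zero_raster(self):
        f = np.full((3, 4, 4), 1000)
        assert not frame_difference(_seq(f), 10).any()

    def test_single_changed_pixel_is_marked(self):
        f = np.full((2, 4, 4), 1000)
        f[1, 2, 3] += 20  # 2x the threshold
        raster = frame_difference(_seq(f), 10)
        assert raster.sum() == 1 and raster[0, 2, 3]

    def test_single_frame_raises(self):
        with pytest.raises(ValueError, match="2 frames"):
            frame_difference(_seq(np.zeros((1, 4, 4))), 10)

    def test_subthreshold_noise_rarely_marks(self, rng):
        # noise sd = delta/5: marked-pixel rate is a > 5-sigma normal tail
        sigma, delta = 2.0, 10.0
        f = np.rint(1000 + rng.normal(0, sigma, size=(200, 32, 32))).astype(np.uint16)
        rate = frame_difference(_seq(f), delta).mean()
        assert rate < 0.01


@pytest.fixture
def simple_layout():
    return ROILayout(
        {
            "upper_body": [[4, 2], [28, 2], [28, 14], [4, 14]],
            "lower_body": [[6, 16], [26, 16], [26, 30], [6, 30]],
        }
    )


def _tracks(rows):
    return TrackSet(pd.DataFrame(rows, columns=list(TrackSet.COLUMNS)))


class TestEffectiveMasks:
    SHAPE = (32, 32)

    def test_no_valid_boxes_full_fallback(self, simple_layout):
        # detector dropout: head/hand movement counts as upper body
        masks = effective_masks(simple_layout, None, 0, self.SHAPE)
        assert not masks["HE"].any() and not masks["HAs"].any()
        assert np.array_equal(masks["UB"], simple_layout.mask("upper_body", self.SHAPE))

    def test_valid_head_box_subtracted_from_upper(self, simple_layout):
        tracks = _tracks([(0, "head", 10, 4, 6, 6, True)])
        masks = effective_masks(simple_layout, tracks, 0, self.SHAPE)
        ub_full = simple_layout.mask("upper_body", self.SHAPE)
        assert masks["HE"].sum() == 36
        assert masks["UB"].sum() == ub_full.sum() - 36
        assert not (masks["HE"] & masks["UB"]).any()

    def test_dropped_hands_stay_in_upper_body(self, simple_layout):
        tracks = _tracks(
            [(0, "head", 10, 4, 6, 6, True), (0, "hand", 20, 6, 4, 4, False)]
        )
        masks = effective_masks(simple_layout, tracks, 0, self.SHAPE)
        assert not masks["HAs"].any()
        assert masks["UB"][6:10, 20:24].all()  # hand pixels fall back to UB

    def test_masks_partition_changed_pixels(self, simple_layout):
        tracks = _tracks(
            [
                (0, "head", 10, 4, 6, 6, True),
                (0, "hand", 20, 6, 4, 4, True),
                (0, "hand", 8, 20, 4, 4, True),  # overlaps lower body
            ]
        )
        masks = effective_masks(simple_layout, tracks, 0, self.SHAPE)
        stack = np.stack(list(masks.values())).astype(int)
        assert stack.sum(axis=0).max() == 1  # pairwise disjoint


class TestRespirationSuppress:
    FPS = 30.0

    def test_pure_respiration_tone_removed(self):
        t = np.arange(0, 600, 1 / self.FPS)
        x = np.sin(2 * np.pi * 0.25 * t + 0.4)
        out = respiration_suppress(x, self.FPS, (0.15, 0.4))
        assert np.sqrt((out**2).mean()) <= 0.1 * np.sqrt((x**2).mean())

    @pytest.mark.parametrize("freq", [0.2, 0.3, 0.45])
    def test_in_band_tones_attenuated_20db(self, freq):
        t = np.arange(0, 600, 1 / self.FPS)
        x = np.sin(2 * np.pi * freq * t)
        out = respiration_suppress(x, self.FPS)
        assert np.sqrt((out**2).mean()) <= 0.1 * np.sqrt((x**2).mean())

    def test_transient_pulse_preserved(self):
        x = np.zeros(18000)
        x[9000:9030] = 1.0  # 1-s rectangular pulse
        out = respiration_suppress(x, self.FPS)
        assert out.max() >= 0.7

    def test_pulse_on_top_of_respiration_survives(self):
        t = np.arange(0, 600, 1 / self.FPS)
        x = 100 * np.sin(2 * np.pi * 0.25 * t) + 200.0
        x[9000:9030] += 80.0
        out = respiration_suppress(x, self.FPS)
        assert out[9000:9030].max() >= 0.7 * 80.0
        assert np.abs(out[:8000]).max() < 20.0

    def test_white_noise_essentially_untouched(self, rng):
        x = rng.normal(0, 1, 18000)
        out = respiration_suppress(x, self.FPS)
        # band share of 0.15-0.5 Hz at fs=30 is ~2.3 % of the spectrum
        assert np.sqrt((out**2).mean()) >= 0.95 * np.sqrt((x**2).mean())

    def test_zero_signal_passes_through(self):
        assert np.allclose(respiration_suppress(np.zeros(1000), self.FPS), 0.0)

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            respiration_suppress(np.zeros(1000), self.FPS, (0.15, 20.0))

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="4 s"):
            respiration_suppress(np.zeros(60), self.FPS)


class TestDetectMotion:
    def test_planted_event_recovered_within_one_frame(self, small_scene):
        h = generate_hypnogram(30, 0.5, 1, seed=1)
        s0, _ = rem_intervals(h)[0]
        ev = PlantedEvent("LB", s0 + 5.0, s0 + 6.0)
        seq, tracks = render_depth_video([ev], h, small_scene, seed=0)
        params = DetectorParams(min_area_px={"HE": 10, "HAs": 10, "UB": 25, "LB": 25})
        trace = detect_motion(seq, small_scene.roi_geometry, tracks, params)
        runs = np.flatnonzero(trace.flag["LB"])
        assert runs.size > 0
        f0, f1 = int(round(ev.start_s * 30)), int(round(ev.end_s * 30))
        assert abs(runs.min() - f0) <= 1 and abs(runs.max() - (f1 - 1)) <= 1
        assert np.all(np.diff(runs) == 1)  # a single contiguous run
        for other in ("HE", "HAs", "UB"):
            assert not trace.flag[other].any()

    def test_head_event_with_valid_track_not_in_upper_body(self, small_scene):
        h = generate_hypnogram(30, 0.5, 1, seed=1)
        s0, _ = rem_intervals(h)[0]
        ev = PlantedEvent("HE", s0 + 5.0, s0 + 6.0)
        seq, tracks = render_depth_video([ev], h, small_scene, seed=0)
        params = DetectorParams(min_area_px={"HE": 10, "HAs": 10, "UB": 25, "LB": 25})
        trace = detect_motion(seq, small_scene.roi_geometry, tracks, params)
        assert trace.flag["HE"].any()
        assert not trace.flag["UB"].any()

    def test_head_event_without_track_falls_back_to_upper_body(self, small_scene):
        h = generate_hypnogram(30, 0.5, 1, seed=1)
        s0, _ = rem_intervals(h)[0]
        ev = PlantedEvent("HE", s0 + 5.0, s0 + 6.0)
        seq, _ = render_depth_video([ev], h, small_scene, seed=0)
        params = DetectorParams(min_area_px={"HE": 10, "HAs": 10, "UB": 25, "LB": 25})
        trace = detect_motion(seq, small_scene.roi_geometry, None, params)
        assert not trace.flag["HE"].any()
        assert trace.flag["UB"].any()

    def test_respiration_only_clip_yields_no_flags(self):
        # strong, slow chest oscillation with a permissive pixel threshold:
        # without suppression the chest triggers, with suppression it is quiet
        scene = SceneConfig(
            frame_width=64,
            frame_height=53,
            noise_sigma=0.0,
            respiration_amplitude=80.0,
            respiration_freq=0.25,
            track_dropout_prob=1.0,
        )
        h = generate_hypnogram(30, 0.5, 1, seed=1)
        seq, _ = render_depth_video([], h, scene, seed=0)
        base = dict(pixel_delta_mm=1.5, min_area_px={"HE": 10, "HAs": 10, "UB": 25, "LB": 25})
        raw = detect_motion(seq, scene.roi_geometry, None, DetectorParams(**base, resp_suppress=False))
        assert raw.flag["UB"].any()  # the oscillation is detectable at all
        filt = detect_motion(seq, scene.roi_geometry, None, DetectorParams(**base, resp_suppress=True))
        assert not any(filt.flag[r].any() for r in filt.flag)

    def test_min_area_monotonicity(self, small_scene):
        h = generate_hypnogram(30, 0.5, 1, seed=1)
        s0, _ = rem_intervals(h)[0]
        evs = [PlantedEvent("LB", s0 + 5.0, s0 + 6.0), PlantedEvent("LB", s0 + 20.0, s0 + 20.5)]
        seq, tracks = render_depth_video(evs, h, small_scene, seed=0)
        totals = []
        for area in (5, 25, 100, 10_000):
            params = DetectorParams(
                min_area_px={r: area for r in ("HE", "HAs", "UB", "LB")}, resp_suppress=False
            )
            trace = detect_motion(seq, small_scene.roi_geometry, tracks, params)
            totals.append(sum(trace.flag[r].sum() for r in trace.flag))
        assert totals == sorted(totals, reverse=True)

    def test_pixel_delta_monotonicity(self, rng):
        frames = np.rint(1500 + rng.normal(0, 8, size=(120, 32, 32))).astype(np.uint16)
        seq = DepthSequence(frames)
        layout = ROILayout(
            {
                "upper_body": [[2, 2], [30, 2], [30, 14], [2, 14]],
                "lower_body": [[2, 16], [30, 16], [30, 30], [2, 30]],
            }
        )
        totals = []
        for delta in (5, 10, 20, 40):
            params = DetectorParams(
                pixel_delta_mm=delta,
                min_area_px={r: 5 for r in ("HE", "HAs", "UB", "LB")},
                resp_suppress=False,
            )
            trace = detect_motion(seq, layout, None, params)
            totals.append(sum(trace.flag[r].sum() for r in trace.flag))
        assert totals == sorted(totals, reverse=True)
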