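"""Feature extractors: worked examples, invariants, and a brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsefuse.errors import InvalidInputError, InvalidWindowError
from drowsefuse.signal_features import (
    FeatureConfig,
    FrameStream,
    VehicleStream,
    blink_frequency,
    eye_closed_duration,
    lane_deviation_frequency,
    mean_eye_opened_level,
    percent_non_steering,
    speed_sd,
    steering_angle_sd,
    windowize,
    yawning_frequency,
)


def make_frames(
    closed,
    eyelid=None,
    mouth_h=None,
    mouth_w=None,
    fps=10.0,
    t0=0.0,
):
    closed = np.asarray(closed, dtype=bool)
    n = closed.size
    return FrameStream(
        t0 + np.arange(n) / fps,
        closed,
        np.asarray(eyelid if eyelid is not None else np.full(n, 10.0), dtype=float),
        np.asarray(mouth_h if mouth_h is not None else np.full(n, 10.0), dtype=float),
        np.asarray(mouth_w if mouth_w is not None else np.full(n, 50.0), dtype=float),
        fps,
    )


def make_vehicle(angle=None, rate=None, theta_l=None, theta_r=None, speed=None, hz=10.0, n=None):
    arrays = [a for a in (angle, rate, theta_l, theta_r, speed) if a is not None]
    n = n or (len(arrays[0]) if arrays else 10)
    return VehicleStream(
        np.arange(n) / hz,
        np.asarray(angle if angle is not None else np.zeros(n), dtype=float),
        np.asarray(theta_l if theta_l is not None else np.full(n, np.pi / 3), dtype=float),
        np.asarray(theta_r if theta_r is not None else np.full(n, 2 * np.pi / 3), dtype=float),
        np.asarray(speed if speed is not None else np.full(n, 100.0), dtype=float),
        steer_rate=None if rate is None else np.asarray(rate, dtype=float),
    )


class TestBlinkFrequency:
    @pytest.mark.parametrize(
        "closed, expected",
        [
            (np.ones(600, dtype=bool), 1.0),
            (np.zeros(600, dtype=bool), 0.0),
            (np.concatenate([np.ones(15), np.zeros(45)]).astype(bool), 0.25),
        ],
    )
    def test_closed_frame_ratio(self, closed, expected):
        assert blink_frequency(make_frames(closed)) == pytest.approx(expected)

    def test_empty_window_rejected(self):
        with pytest.raises(InvalidWindowError):
            blink_frequency(make_frames(np.zeros(0, dtype=bool)))


class TestEyeClosedDuration:
    def test_entire_window_closed(self):
        assert eye_closed_duration(make_frames(np.ones(600, dtype=bool))) == 1.0

    def test_short_closure_excluded(self):
        # one 1 s closure at 30 fps in a 60 s window: below the 2 s threshold
        closed = np.zeros(1800, dtype=bool)
        closed[300:330] = True
        assert eye_closed_duration(make_frames(closed, fps=30.0)) == 0.0

    def test_two_long_closures(self):
        # two separate 3 s closures at 10 fps in 60 s: 60 of 600 frames
        closed = np.zeros(600, dtype=bool)
        closed[50:80] = True
        closed[400:430] = True
        assert eye_closed_duration(make_frames(closed)) == pytest.approx(0.1)

    def test_exact_threshold_run_counts(self):
        closed = np.zeros(600, dtype=bool)
        closed[100:120] = True  # exactly 2 s at 10 fps
        assert eye_closed_duration(make_frames(closed)) == pytest.approx(20 / 600)


class TestMeanEyeOpenedLevel:
    @pytest.mark.parametrize(
        "heights, expected",
        [([12, 12, 12], 12.0), ([8, 12], 10.0), ([3, 4, 5, 8], 5.0)],
    )
    def test_mean_aperture(self, heights, expected):
        frames = make_frames(np.zeros(len(heights), dtype=bool), eyelid=heights)
        assert mean_eye_opened_level(frames) == pytest.approx(expected)


class TestYawningFrequency:
    def test_ratio_above_threshold_every_frame(self):
        frames = make_frames(np.zeros(10, dtype=bool), mouth_h=np.full(10, 40.0), mouth_w=np.full(10, 50.0))
        cfg = FeatureConfig(yawn_threshold=0.6)
        assert yawning_frequency(frames, cfg) == 1.0  # 0.8 >= 0.6

    def test_ratio_below_threshold(self):
        frames = make_frames(np.zeros(10, dtype=bool), mouth_h=np.full(10, 20.0), mouth_w=np.full(10, 50.0))
        assert yawning_frequency(frames, FeatureConfig(yawn_threshold=0.6)) == 0.0

    def test_zero_threshold_always_yawning(self):
        frames = make_frames(np.zeros(5, dtype=bool), mouth_h=np.zeros(5))
        assert yawning_frequency(frames, FeatureConfig(yawn_threshold=0.0)) == 1.0

    def test_zero_width_frames_excluded(self):
        mouth_w = np.array([50.0, 0.0, 50.0, 50.0])
        mouth_h = np.array([40.0, 40.0, 10.0, 10.0])
        frames = make_frames(np.zeros(4, dtype=bool), mouth_h=mouth_h, mouth_w=mouth_w)
        # frame 2 dropped: 1 yawning of 3 valid
        assert yawning_frequency(frames, FeatureConfig(yawn_threshold=0.6)) == pytest.approx(1 / 3)


class TestVehicleFeatures:
    def test_percent_non_steering(self):
        veh = make_vehicle(rate=[0.05, -0.2, 0.0, 0.3])
        assert percent_non_steering(veh) == pytest.approx(0.5)
        assert percent_non_steering(make_vehicle(rate=np.zeros(8))) == 1.0
        assert percent_non_steering(make_vehicle(rate=np.full(8, 5.0))) == 0.0

    @pytest.mark.parametrize(
        "angles, expected",
        [([7, 7, 7], 0.0), ([0, 10], 5.0), ([1, 2, 3, 4], np.sqrt(1.25))],
    )
    def test_steering_angle_sd_population(self, angles, expected):
        assert steering_angle_sd(make_vehicle(angle=angles)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "speeds, expected",
        [([100, 100, 100], 0.0), ([90, 110], 10.0), ([80, 100, 120], np.sqrt(800 / 3))],
    )
    def test_speed_sd_population(self, speeds, expected):
        assert speed_sd(make_vehicle(speed=speeds)) == pytest.approx(expected)

    def test_lane_symmetric_geometry_not_deviating(self):
        # theta_L = pi/3, theta_R = 2pi/3 gives xi = 1 on every frame
        veh = make_vehicle(n=20)
        assert lane_deviation_frequency(veh) == 0.0

    def test_lane_deviation_fires_on_large_xi(self):
        # xi = 2 on every frame: theta_L = pi/2 - 2*(theta_R - pi/2)
        theta_r = np.full(10, 2 * np.pi / 3)
        theta_l = np.pi / 2 - 2.0 * (theta_r - np.pi / 2)
        veh = make_vehicle(theta_l=theta_l, theta_r=theta_r)
        assert lane_deviation_frequency(veh) == 1.0

    def test_lane_right_deviation_symmetric_rule_only(self):
        # xi = 0.5 indicates right drift: caught by the symmetric rule,
        # invisible to the literal disjunction
        theta_r = np.full(10, 2 * np.pi / 3)
        theta_l = np.pi / 2 - 0.5 * (theta_r - np.pi / 2)
        veh = make_vehicle(theta_l=theta_l, theta_r=theta_r)
        assert lane_deviation_frequency(veh, FeatureConfig(lane_rule="symmetric")) == 1.0
        assert lane_deviation_frequency(veh, FeatureConfig(lane_rule="literal")) == 0.0

    def test_vertical_right_lane_excluded(self):
        theta_r = np.array([np.pi / 2, 2 * np.pi / 3, 2 * np.pi / 3, 2 * np.pi / 3])
        veh = make_vehicle(theta_r=theta_r, theta_l=np.full(4, np.pi / 3), n=4)
        assert lane_deviation_frequency(veh) == 0.0  # 0 of 3 valid frames

    def test_steer_rate_first_difference_fallback(self):
        # angles 0,1,2,... at 10 Hz -> rate 10 deg/s everywhere
        veh = make_vehicle(angle=np.arange(5, dtype=float))
        assert np.allclose(veh.steer_rate, 10.0)


class TestWindowize:
    def _streams(self, seconds, fps=10.0):
        n = int(seconds * fps)
        frames = make_frames(np.zeros(n, dtype=bool), fps=fps)
        veh = make_vehicle(n=n, hz=fps)
        return frames, veh

    def test_two_full_minutes(self):
        frames, veh = self._streams(120)
        assert len(windowize(frames, veh)) == 2

    def test_incomplete_minute_dropped(self):
        frames, veh = self._streams(59)
        assert len(windowize(frames, veh)) == 0

    def test_no_overlap_rejected(self):
        frames, _ = self._streams(60)
        late = make_vehicle(n=600)
        late.timestamps = late.timestamps + 500.0
        with pytest.raises(InvalidInputError):
            windowize(frames, late)

    def test_window_bf_matches_direct_ratio(self):
        rng = np.random.default_rng(11)
        closed = rng.uniform(size=1200) < 0.2
        frames = make_frames(closed)
        veh = make_vehicle(n=1200)
        windows = windowize(frames, veh)
        assert len(windows) == 2
        for i, w in enumerate(windows):
            assert w.bf == pytest.approx(closed[i * 600 : (i + 1) * 600].mean())


# ---------------------------------------------------------------------------
# Properties and the independent brute-force oracle


def _random_window(rng):
    n = int(rng.integers(20, 80))
    fps = float(rng.choice([5.0, 10.0, 25.0]))
    closed = rng.uniform(size=n) < rng.uniform(0.0, 0.6)
    frames = make_frames(
        closed,
        eyelid=rng.uniform(0, 15, n),
        mouth_h=rng.uniform(0, 40, n),
        mouth_w=rng.uniform(30, 60, n),
        fps=fps,
    )
    m = int(rng.integers(5, 40))
    theta_r = rng.uniform(np.pi / 2 + 0.1, np.pi - 0.1, m)
    veh = VehicleStream(
        np.arange(m) / 10.0,
        rng.normal(0, 10, m),
        rng.uniform(0.1, np.pi / 2 - 0.05, m),
        theta_r,
        rng.uniform(60, 130, m),
        steer_rate=rng.normal(0, 1, m),
    )
    return frames, veh


def _oracle(frames, veh, cfg):
    """Plain-python per-definition recomputation of all eight features."""
    n = len(frames)
    bf = sum(bool(c) for c in frames.eye_closed) / n
    # run-length scan for ECD
    n_c, run = 0, 0
    for c in list(frames.eye_closed) + [False]:
        if c:
            run += 1
        else:
            if run / frames.frame_rate >= cfg.ecd_min_closure:
                n_c += run
            run = 0
    ecd = n_c / n
    meol = sum(frames.eyelid_height) / n
    ratios = [
        h / w for h, w in zip(frames.mouth_height, frames.mouth_width) if w > 0
    ]
    yf = sum(r >= cfg.yawn_threshold for r in ratios) / len(ratios)
    m = len(veh)
    pns = sum(abs(r) <= cfg.nonsteer_band for r in veh.steer_rate) / m
    mean_a = sum(veh.steer_angle) / m
    sdsa = (sum((a - mean_a) ** 2 for a in veh.steer_angle) / m) ** 0.5
    mean_v = sum(veh.speed) / m
    sdvs = (sum((v - mean_v) ** 2 for v in veh.speed) / m) ** 0.5
    xis = [
        (np.pi / 2 - tl) / (tr - np.pi / 2)
        for tl, tr in zip(veh.lane_theta_left, veh.lane_theta_right)
        if abs(tr - np.pi / 2) > 1e-12
    ]
    fald = sum(x > cfg.lambda_left or x < 1 / cfg.lambda_right for x in xis) / len(xis)
    return bf, ecd, meol, yf, pns, sdsa, fald, sdvs


def test_features_match_brute_force_oracle():
    cfg = FeatureConfig()
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        frames, veh = _random_window(rng)
        expected = _oracle(frames, veh, cfg)
        actual = (
            blink_frequency(frames),
            eye_closed_duration(frames, cfg),
            mean_eye_opened_level(frames),
            yawning_frequency(frames, cfg),
            percent_non_steering(veh, cfg),
            steering_angle_sd(veh),
            lane_deviation_frequency(veh, cfg),
            speed_sd(veh),
        )
        assert actual == pytest.approx(expected)


def test_fraction_features_bounded_and_bf_dominates_ecd():
    rng = np.random.default_rng(5)
    for _ in range(200):
        frames, veh = _random_window(rng)
        bf = blink_frequency(frames)
        ecd = eye_closed_duration(frames)
        for v in (bf, ecd, yawning_frequency(frames), percent_non_steering(veh), lane_deviation_frequency(veh)):
            assert 0.0 <= v <= 1.0
        assert bf >= ecd  # ECD frames are a subset of closed frames


@settings(max_examples=100, derandomize=True)
@given(
    values=st.lists(st.floats(-50, 50), min_size=2, max_size=30),
    shift=st.floats(-100, 100),
    scale=st.floats(0.1, 10),
)
def test_sd_translation_invariant_scale_equivariant(values, shift, scale):
    base = make_vehicle(angle=values, speed=np.abs(values))
    shifted = make_vehicle(angle=np.asarray(values) + shift)
    scaled = make_vehicle(angle=np.asarray(values) * scale)
    sd = steering_angle_sd(base)
    assert steering_angle_sd(shifted) == pytest.approx(sd, abs=1e-9)
    assert steering_angle_sd(scaled) == pytest.approx(sd * scale, rel=1e-9, abs=1e-9)
    assert speed_sd(base) == pytest.approx(np.std(np.abs(values)))
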