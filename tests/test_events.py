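import numpy as np
import pytest

from wheelvault import synth
from wheelvault.errors import (
    EmptyMaskError,
    EventDetectionError,
    EventExtractionError,
    InputError,
    NoContactError,
    NoTakeoffError,
    NoThrustError,
    OrderingError,
)
from wheelvault.events import (
    EventSet,
    FlowSummary,
    barycenter,
    detect_contact_start,
    detect_pikemount,
    detect_takeoff,
    detect_thrust,
    extract_events,
    lower_body_mask,
    summarize_flow,
)
from wheelvault.ioformats import FlowField, MaskPair

# ---------------------------------------------------------------------------
# Helpers: summary construction and independent brute-force oracles
# ---------------------------------------------------------------------------

UP, DOWN, NONE = "u", "d", "n"


def S(code, mag=2.0, idx=0):
    if code == UP:
        return FlowSummary(idx, 90.0, mag, 10)
    if code == DOWN:
        return FlowSummary(idx, 270.0, mag, 10)
    return FlowSummary(idx, float("nan"), float("nan"), 0)


def seq(codes, mags=None):
    mags = mags if mags is not None else [2.0] * len(codes)
    return [S(c, m, i) for i, (c, m) in enumerate(zip(codes, mags))]


def random_summaries(rng, n):
    """Random direction/magnitude sequences, including undefined frames."""
    out = []
    for i in range(n):
        if rng.random() < 0.1:
            out.append(S(NONE, idx=i))
        else:
            direction = rng.uniform(0.0, 360.0)
            out.append(FlowSummary(i, direction, float(rng.uniform(0.0, 20.0)), 5))
    return out


def oracle_takeoff(summaries, window):
    n = len(summaries)
    for i in range(n - window + 1):
        if all(summaries[i + k].upward for k in range(window)) and (
            i == 0 or not summaries[i - 1].upward
        ):
            for j in range(i - 1, -1, -1):
                if summaries[j].downward:
                    return j
            return None
    return None


def oracle_thrust(summaries, contact, lookback, lo, hi):
    for t in range(len(summaries)):
        if t <= contact or t < lookback:
            continue
        if not summaries[t].upward:
            continue
        win = summaries[t - lookback : t]
        if all(s.downward for s in win):
            m = max(s.median_magnitude for s in win)
            if lo <= m <= hi:
                return t
    return None


def oracle_contact(flags, threshold_frames):
    n = len(flags)
    for i in range(n):
        if flags[i] and (i == 0 or not flags[i - 1]):
            run = 0
            while i + run < n and flags[i + run]:
                run += 1
            if run > threshold_frames:
                return i
    return None


def contact_pair(in_contact: bool, idx=0) -> MaskPair:
    """Tiny mask geometry realizing a chosen contact state (leftward travel)."""
    wheel = np.zeros((5, 9), bool)
    wheel[2, 7] = True
    gymnast = np.zeros((5, 9), bool)
    if in_contact:
        gymnast[2, 4] = gymnast[2, 6] = True  # lower-body pixel adjacent to wheel
    else:
        gymnast[2, 2] = gymnast[2, 4] = True
    return MaskPair(wheel=wheel, gymnast=gymnast, frame_index=idx)


META = synth.VideoMeta(fps=60.0, width=9, height=5, n_frames=1)


# ---------------------------------------------------------------------------
# summarize_flow
# ---------------------------------------------------------------------------

class TestSummarizeFlow:
    def test_uniform_upward(self):
        f = FlowField(np.zeros((4, 4)), np.full((4, 4), -2.0))
        s = summarize_flow(f, eps=1.0)
        assert s.median_direction == pytest.approx(90.0)
        assert s.median_magnitude == pytest.approx(2.0)
        assert s.upward and not s.downward

    def test_uniform_rightward(self):
        f = FlowField(np.ones((4, 4)), np.zeros((4, 4)))
        s = summarize_flow(f, eps=0.5)
        assert s.median_direction == pytest.approx(0.0)
        assert s.median_magnitude == pytest.approx(1.0)
        # exactly 0 degrees is neither upward nor downward
        assert not s.upward and not s.downward

    def test_zero_moving_pixels_flagged_undefined(self):
        f = FlowField(np.zeros((4, 4)), np.zeros((4, 4)))
        s = summarize_flow(f, eps=1.0)
        assert not s.defined and not s.upward and not s.downward
        assert s.n_moving_pixels == 0

    def test_matches_bruteforce_on_random_fields(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            u = rng.normal(0, 2, (8, 8))
            v = rng.normal(0, 2, (8, 8))
            eps = float(rng.uniform(0.0, 2.0))
            s = summarize_flow(FlowField(u, v), eps=eps)
            # per-pixel recomputation
            mags, dirs = [], []
            for r in range(8):
                for c in range(8):
                    m = np.hypot(u[r, c], v[r, c])
                    if m > eps:
                        mags.append(m)
                        dirs.append(np.degrees(np.arctan2(-v[r, c], u[r, c])) % 360)
            if not mags:
                assert not s.defined
            else:
                assert s.n_moving_pixels == len(mags)
                assert s.median_magnitude == pytest.approx(np.median(mags))
                assert s.median_direction == pytest.approx(np.median(dirs))

    def test_negative_eps_rejected(self):
        with pytest.raises(InputError):
            summarize_flow(FlowField(np.zeros((2, 2)), np.zeros((2, 2))), eps=-1)


# ---------------------------------------------------------------------------
# detect_takeoff
# ---------------------------------------------------------------------------

class TestDetectTakeoff:
    def test_forty_down_then_thirtyfive_up(self):
        s = seq([DOWN] * 40 + [UP] * 35)
        assert detect_takeoff(s, window=30) == 39

    def test_window_unmet(self):
        s = seq([DOWN] * 10 + [UP] * 20 + [DOWN] * 5 + [UP] * 20)
        with pytest.raises(NoTakeoffError):
            detect_takeoff(s, window=30)

    def test_run_at_start_without_preceding_downward(self):
        with pytest.raises(NoTakeoffError):
            detect_takeoff(seq([UP] * 40), window=30)

    def test_undefined_frames_break_runs_but_not_backscan(self):
        s = seq([DOWN] * 5 + [NONE] * 3 + [UP] * 30)
        assert detect_takeoff(s, window=30) == 4

    def test_default_window_is_half_second_at_60fps(self):
        from inspect import signature

        window = signature(detect_takeoff).parameters["window"].default
        assert window == 30
        assert window / 60.0 == 0.5

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            s = random_summaries(rng, rng.integers(5, 60))
            window = int(rng.integers(1, 8))
            expected = oracle_takeoff(s, window)
            if expected is None:
                with pytest.raises(NoTakeoffError):
                    detect_takeoff(s, window)
            else:
                assert detect_takeoff(s, window) == expected

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        base = seq([DOWN] * 6 + [UP] * 8)
        for k in (1, 5, 11):
            shifted = seq([NONE] * k + [DOWN] * 6 + [UP] * 8)
            assert detect_takeoff(shifted, 8) == detect_takeoff(base, 8) + k


# ---------------------------------------------------------------------------
# barycenter / lower_body_mask
# ---------------------------------------------------------------------------

class TestBarycenter:
    def test_single_pixel(self):
        m = np.zeros((10, 10), bool)
        m[10 - 1 - 4, 3] = True  # analysis (3, 4)
        assert barycenter(m) == (3.0, 4.0)

    def test_filled_rectangle_center(self):
        m = np.zeros((9, 9), bool)
        m[2:5, 3:8] = True
        x, y = barycenter(m)
        assert x == pytest.approx(5.0)
        assert y == pytest.approx(8 - 3.0)

    def test_matches_coordinate_sum_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20)            :
            m = rng.random((12, 15)) > 0.6
            if not m.any():
                continue
            x, y = barycenter(m)
            rows, cols = np.nonzero(m)
            assert x == pytest.approx(cols.sum() / len(cols))
            assert y == pytest.approx((11 - rows).sum() / len(rows))

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            barycenter(np.zeros((4, 4), bool))


class TestLowerBodyMask:
    def test_leftward_motion_keeps_right_half(self):
        m = np.zeros((3, 10), bool)
        m[1, 2:8] = True  # bar, barycenter x = 4.5
        lower = lower_body_mask(m, "leftward")
        rows, cols = np.nonzero(lower)
        assert set(cols) == {5, 6, 7}

    def test_rightward_motion_mirrors(self):
        m = np.zeros((3, 10), bool)
        m[1, 2:8] = True
        lower = lower_body_mask(m, "rightward")
        assert set(np.nonzero(lower)[1]) == {2, 3, 4}

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            m = rng.random((8, 8)) > 0.5
            if not m.any():
                continue
            kept = lower_body_mask(m, "leftward")
            discarded = m & ~kept
            np.testing.assert_array_equal(kept | discarded, m)
            assert not (kept & discarded).any()

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            lower_body_mask(np.zeros((4, 4), bool), "leftward")


# ---------------------------------------------------------------------------
# detect_contact_start
# ---------------------------------------------------------------------------

class TestDetectContactStart:
    def test_contact_run_50_to_120(self):
        flags = [False] * 50 + [True] * 71 + [False] * 10
        masks = [contact_pair(f, i) for i, f in enumerate(flags)]
        assert detect_contact_start(masks, META, 0.5) == 50

    def test_exactly_threshold_run_rejected(self):
        # 20 frames at 60 fps is not more than 0.5 s
        flags = [False] * 10 + [True] * 20 + [False] * 40
        masks = [contact_pair(f, i) for i, f in enumerate(flags)]
        with pytest.raises(NoContactError):
            detect_contact_start(masks, META, 0.5)

    def test_strict_inequality_at_exact_half_second(self):
        # a run of exactly 30 frames (0.5 s) must NOT qualify; 31 must
        flags30 = [True] * 30 + [False] * 5
        masks30 = [contact_pair(f, i) for i, f in enumerate(flags30)]
        with pytest.raises(NoContactError):
            detect_contact_start(masks30, META, 0.5)
        flags31 = [True] * 31 + [False] * 5
        masks31 = [contact_pair(f, i) for i, f in enumerate(flags31)]
        assert detect_contact_start(masks31, META, 0.5) == 0

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            flags = (rng.random(rng.integers(5, 50)) > 0.4).tolist()
            min_s = float(rng.uniform(0.01, 0.2))
            masks = [contact_pair(f, i) for i, f in enumerate(flags)]
            expected = oracle_contact(flags, min_s * META.fps)
            if expected is None:
                with pytest.raises(NoContactError):
                    detect_contact_start(masks, META, min_s)
            else:
                assert detect_contact_start(masks, META, min_s) == expected


# ---------------------------------------------------------------------------
# detect_pikemount
# ---------------------------------------------------------------------------

def height_pair(height_row: int, idx=0) -> MaskPair:
    g = np.zeros((30, 9), bool)
    g[height_row, 4] = True
    return MaskPair(wheel=np.zeros((30, 9), bool), gymnast=g, frame_index=idx)


class TestDetectPikemount:
    def test_peak_at_42(self):
        rows = [20] * 60
        rows[42] = 2  # low row index = high y-up
        masks = [height_pair(r, i) for i, r in enumerate(rows)]
        assert detect_pikemount(masks, takeoff=30, contact_start=55) == 42

    def test_tie_resolves_to_earliest(self):
        rows = [20] * 60
        rows[40] = rows[44] = 5
        masks = [height_pair(r, i) for i, r in enumerate(rows)]
        assert detect_pikemount(masks, 30, 50) == 40

    def test_monotone_rise_gives_last_frame_before_contact(self):
        def tall_pair(row, idx):
            g = np.zeros((70, 9), bool)
            g[row, 4] = True
            return MaskPair(wheel=np.zeros((70, 9), bool), gymnast=g, frame_index=idx)

        rows = [65 - i for i in range(60)]  # strictly rising height
        masks = [tall_pair(r, i) for i, r in enumerate(rows)]
        assert detect_pikemount(masks, 10, 40) == 39

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            rows = rng.integers(0, 30, size=40).tolist()
            masks = [height_pair(r, i) for i, r in enumerate(rows)]
            takeoff, contact = 3, 37
            heights = [29 - r for r in rows]
            best = max(range(takeoff + 1, contact), key=lambda t: (heights[t], -t))
            assert detect_pikemount(masks, takeoff, contact) == best

    def test_empty_range_rejected(self):
        masks = [height_pair(10, i) for i in range(5)]
        with pytest.raises(OrderingError):
            detect_pikemount(masks, 3, 4)


# ---------------------------------------------------------------------------
# detect_thrust
# ---------------------------------------------------------------------------

class TestDetectThrust:
    def test_ten_down_then_up(self):
        codes = [NONE] * 20 + [DOWN] * 10 + [UP] * 3
        mags = [0.0] * 20 + [8.0] * 10 + [3.0] * 3
        s = seq(codes, mags)
        assert detect_thrust(s, contact_start=5, lookback=10, mag_lo=5.5, mag_hi=15) == 30

    def test_magnitude_above_band_rejected(self):
        codes = [NONE] * 20 + [DOWN] * 10 + [UP] * 3
        mags = [0.0] * 20 + [20.0] * 10 + [3.0] * 3
        s = seq(codes, mags)
        with pytest.raises(NoThrustError):
            detect_thrust(s, 5, 10, 5.5, 15)

    def test_default_band_is_5p5_to_15(self):
        from inspect import signature

        params = signature(detect_thrust).parameters
        assert params["mag_lo"].default == 5.5
        assert params["mag_hi"].default == 15.0

    def test_scan_starts_after_contact(self):
        # a qualifying pattern before contact_start must be ignored
        codes = [DOWN] * 10 + [UP] * 2 + [NONE] * 10 + [DOWN] * 10 + [UP]
        mags = [8.0] * len(codes)
        s = seq(codes, mags)
        assert detect_thrust(s, contact_start=15, lookback=10, mag_lo=5.5, mag_hi=15) == 32

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            s = random_summaries(rng, int(rng.integers(10, 60)))
            contact = int(rng.integers(0, 10))
            lookback = int(rng.integers(1, 6))
            lo, hi = sorted(rng.uniform(0, 20, 2).tolist())
            expected = oracle_thrust(s, contact, lookback, lo, hi)
            if expected is None:
                with pytest.raises(NoThrustError):
                    detect_thrust(s, contact, lookback, lo, hi)
            else:
                assert detect_thrust(s, contact, lookback, lo, hi) == expected


# ---------------------------------------------------------------------------
# extract_events (composition on the simulator)
# ---------------------------------------------------------------------------

class TestExtractEvents:
    def test_zero_noise_matches_ground_truth(
        self, zero_noise_performance, synth_event_params
    ):
        series, truth = zero_noise_performance
        ev = extract_events(series, synth_event_params)
        gt = truth.event_frames
        diffs = np.abs(np.array(ev.as_tuple()) - np.array(gt.as_tuple()))
        assert diffs.max() <= 1
        series.clear_cache()

    def test_truncated_series_fails_with_stage(
        self, zero_noise_config, synth_event_params
    ):
        series, _ = synth.simulate_performance(
            zero_noise_config, 1, np.random.default_rng(0)
        )
        truncated = synth.FrameSeries(
            series.keypoints[:115], zero_noise_config.meta, flow_noise_sd=0.0
        )
        with pytest.raises(EventExtractionError) as err:
            extract_events(truncated, synth_event_params)
        assert err.value.stage is not None

    def test_shuffled_series_fails(self, zero_noise_config, synth_event_params):
        series, _ = synth.simulate_performance(
            zero_noise_config, 1, np.random.default_rng(0)
        )
        shuffled = synth.FrameSeries(
            np.random.default_rng(1).permutation(series.keypoints, axis=0),
            zero_noise_config.meta,
            flow_noise_sd=0.0,
        )
        with pytest.raises(EventDetectionError):
            extract_events(shuffled, synth_event_params)


class TestEventSet:
    def test_ordering_enforced(self):
        with pytest.raises(OrderingError):
            EventSet(takeoff=10, pikemount=5, contact_start=20, thrust=30)

    def test_round_trip_dict(self):
        e = EventSet(1, 2, 3, 4)
        assert EventSet(**e.as_dict()) == e
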