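import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from motorcap.features import (
    FeatureConfig,
    arm_synchrony,
    average_rotation_energy,
    detect_heel_strikes,
    dominant_frequency,
    extract_task_features,
    gait_durations,
    movement_intensity,
    movement_intensity_variation,
    movement_interval,
    range_angular_velocity,
    smoothness,
    swab_segment,
)
from motorcap.preprocess import magnitude
from motorcap.synth import simulate_gait, simulate_session, simulate_wheelchair
from motorcap.types import (
    GaitEvents,
    ImpairmentProfile,
    IMUTrace,
    Placement,
    SessionRecording,
    Side,
    TaskClass,
    TaskSegment,
    feature_layout,
)

FS = 100.0


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def naive_mi(accel):
    return sum(np.sqrt(a[0] ** 2 + a[1] ** 2 + a[2] ** 2) for a in accel) / len(accel)


def naive_miv(accel):
    mags = [np.sqrt(a[0] ** 2 + a[1] ** 2 + a[2] ** 2) for a in accel]
    mean = sum(mags) / len(mags)
    return np.sqrt(sum((m - mean) ** 2 for m in mags) / len(mags))


def naive_are(gyro):
    return sum(g[0] ** 2 + g[1] ** 2 + g[2] ** 2 for g in gyro) / len(gyro)


def naive_rang(gyro_mag):
    s = sorted(gyro_mag)
    return s[-1] - s[0]


def dft_energy(series):
    """Direct O(n^2) DFT energy spectrum, DC removed, positive bins."""
    x = np.asarray(series, float)
    x = x - x.mean()
    n = len(x)
    k = np.arange(n // 2 + 1)
    W = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    spec = W @ x
    freqs = k / n * FS
    return freqs[1:], np.abs(spec[1:]) ** 2


def dft_df_sm(series):
    freqs, energy = dft_energy(series)
    i = int(np.argmax(energy >= (1 - 1e-9) * energy.max()))
    df = freqs[i]
    band = np.abs(freqs - df) <= 0.1 + 1e-12
    return df, energy[band].sum() / energy.sum()


@pytest.mark.parametrize("seed", range(10))
def test_scalar_features_match_naive_oracles(seed):
    rng = np.random.default_rng(seed)
    accel = rng.normal(0, 0.5, (200, 3)) + [0, 0, 1]
    gyro = rng.normal(0, 30.0, (200, 3))
    assert movement_intensity(accel) == pytest.approx(naive_mi(accel), rel=1e-12)
    assert movement_intensity_variation(accel) == pytest.approx(
        naive_miv(accel), rel=1e-12
    )
    assert average_rotation_energy(gyro) == pytest.approx(naive_are(gyro), rel=1e-9)
    gm = np.linalg.norm(gyro, axis=1)
    assert range_angular_velocity(gm) == pytest.approx(naive_rang(gm), rel=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_spectral_features_match_direct_dft(seed):
    rng = np.random.default_rng(100 + seed)
    series = 1.0 + rng.normal(0, 0.2, 200)
    df_o, sm_o = dft_df_sm(series)
    assert dominant_frequency(series, FS) == pytest.approx(df_o, abs=1e-9)
    assert smoothness(series, FS) == pytest.approx(sm_o, rel=1e-9)


# ---------------------------------------------------------------------------
# closed-form cases
# ---------------------------------------------------------------------------


class TestClosedForms:
    def test_mi_constant_gravity(self):
        accel = np.tile([0.0, 0.0, 1.0], (100, 1))
        assert movement_intensity(accel) == pytest.approx(1.0)

    def test_mi_is_arithmetic_mean(self):
        accel = np.zeros((100, 3))
        accel[::2, 2] = 0.5
        accel[1::2, 2] = 1.5
        assert movement_intensity(accel) == pytest.approx(1.0)

    def test_miv_zero_for_constant(self):
        accel = np.tile([0.3, 0.4, 0.0], (64, 1))
        assert movement_intensity_variation(accel) == pytest.approx(0.0, abs=1e-15)

    def test_miv_alternating_half_g(self):
        accel = np.zeros((100, 3))
        accel[::2, 2] = 0.5
        accel[1::2, 2] = 1.5
        assert movement_intensity_variation(accel) == pytest.approx(0.5)

    def test_df_single_tone(self):
        t = np.arange(1000) / FS
        x = 1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t)
        assert dominant_frequency(x, FS) == pytest.approx(2.0, abs=0.1)

    def test_df_dominant_of_two_tones(self):
        t = np.arange(1000) / FS
        x = 1.0 + 0.3 * np.sin(2 * np.pi * 2 * t) + 0.1 * np.sin(2 * np.pi * 5 * t)
        assert dominant_frequency(x, FS) == pytest.approx(2.0, abs=1e-12)

    def test_df_tie_breaks_to_lowest(self):
        t = np.arange(1000) / FS
        x = 1.0 + 0.3 * np.cos(2 * np.pi * 2 * t) + 0.3 * np.cos(2 * np.pi * 5 * t)
        assert dominant_frequency(x, FS) == pytest.approx(2.0, abs=1e-12)

    def test_sm_pure_tone_near_one(self):
        t = np.arange(1000) / FS
        x = 1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t)
        assert smoothness(x, FS) >= 0.99

    def test_sm_tone_plus_noise_between(self, rng):
        t = np.arange(1000) / FS
        tone = 0.3 * np.sin(2 * np.pi * 2.0 * t)
        noise = rng.normal(0, np.std(tone), 1000)
        sm_mix = smoothness(1.0 + tone + noise, FS)
        assert smoothness(1.0 + noise, FS) < sm_mix < smoothness(1.0 + tone, FS)

    def test_white_noise_sm_matches_selection_bias_expectation(self):
        # flat spectrum over N bins: the DF band holds the argmax bin plus
        # two neighbours; E[max of N iid Exp] = ln N + gamma
        vals = [
            smoothness(np.random.default_rng(s).normal(size=1000), FS)
            for s in range(100)
        ]
        n_bins = 500
        expected = (np.log(n_bins) + np.euler_gamma + 2.0) / n_bins
        assert np.mean(vals) == pytest.approx(expected, rel=0.5)

    def test_are_constant_rotation(self):
        gyro = np.tile([0.0, 10.0, 0.0], (50, 1))
        assert average_rotation_energy(gyro) == pytest.approx(100.0)
        assert average_rotation_energy(np.zeros((50, 3))) == pytest.approx(0.0)

    def test_rang_ramp(self):
        assert range_angular_velocity(np.linspace(0, 100, 500)) == pytest.approx(100.0)
        assert range_angular_velocity(np.full(100, 7.0)) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# invariant properties
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(20, 400))
def test_feature_bounds_hold(seed, n):
    rng = np.random.default_rng(seed)
    accel = rng.normal(0, 0.5, (n, 3))
    mags = np.linalg.norm(accel, axis=1)
    miv = movement_intensity_variation(accel)
    assert miv**2 <= np.mean(mags**2) + 1e-12  # variance bound
    if n >= 2:
        assert 0.0 <= smoothness(mags, FS) <= 1.0 + 1e-12
    assert range_angular_velocity(mags) >= 0.0


def test_extracted_features_rotation_invariant(rng):
    result = simulate_session(
        ImpairmentProfile(level=0.4),
        task_list=[(TaskClass.CARDS, Side.RIGHT)],
        seed=7,
    )
    rec = result.recording
    R = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
    rotated = SessionRecording(
        subject_id=rec.subject_id,
        week=rec.week,
        traces={
            p: IMUTrace(t.sample_rate, p, t.accel @ R.T, t.gyro @ R.T)
            for p, t in rec.traces.items()
        },
        segments=rec.segments,
    )
    fv0 = extract_task_features(rec, rec.segments[0])
    fv1 = extract_task_features(rotated, rec.segments[0])
    for name in fv0.names:
        assert fv0.values[name] == pytest.approx(fv1.values[name], rel=1e-6, abs=1e-9)


# ---------------------------------------------------------------------------
# movement interval (TIME)
# ---------------------------------------------------------------------------


class TestMovementInterval:
    def test_burst_recovered(self, rng):
        n = 1000
        mag = 1.0 + rng.normal(0, 0.01, n)
        t = np.arange(400) / FS
        mag[200:600] += 0.3 * np.sin(2 * np.pi * 1.5 * t + 1.0)
        mi = movement_interval(mag, FS)
        assert mi is not None
        assert mi.time_s == pytest.approx(4.0, abs=0.06)

    def test_constant_series_reports_no_movement(self):
        assert movement_interval(np.ones(1000), FS) is None

    def test_quiet_noise_reports_no_movement(self, rng):
        assert movement_interval(1.0 + rng.normal(0, 0.01, 1000), FS) is None

    def test_saturated_burst_with_explicit_threshold(self, rng):
        # burst spanning the whole series: every window active, interval
        # saturates at the full duration minus one window
        t = np.arange(1000) / FS
        mag = 1.0 + 0.3 * np.sin(2 * np.pi * 2 * t) + rng.normal(0, 0.01, 1000)
        mi = movement_interval(mag, FS, threshold=0.05)
        assert mi.time_s == pytest.approx(10.0, abs=0.55)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            movement_interval(np.ones(10), FS)


# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------


class TestGait:
    def test_flat_series_yields_empty_events(self):
        ev = detect_heel_strikes(np.ones(2000), FS)
        assert ev.n_strikes == 0 and len(ev.lift_offs) == 0

    def test_detection_rate_non_increasing_in_noise(self):
        rates = []
        for noise in (0.02, 0.4, 1.0):
            hit = tot = 0
            for seed in range(8):
                traces, gt = simulate_gait(1.2, 1.2, 0.6, 8, FS, noise, seed)
                ev = detect_heel_strikes(magnitude(traces[1], "accel"), FS)
                for s in gt.heel_strike_times["left"]:
                    tot += 1
                    hit += bool(len(ev.heel_strikes)) and np.min(
                        np.abs(ev.heel_strikes - s)
                    ) <= 2
            rates.append(hit / tot)
        assert rates[0] >= rates[1] - 0.02 >= rates[2] - 0.04

    def test_gait_durations_hand_listed_events(self):
        left = GaitEvents(heel_strikes=[0, 100, 200], lift_offs=[60, 160])
        right = GaitEvents(heel_strikes=[50, 150, 250], lift_offs=[110, 210])
        out = gait_durations(left, right, FS)
        assert out["T_step_avg"] == pytest.approx(1.0)
        assert out["T_step_ratio"] == pytest.approx(1.0)
        assert out["T_stance_avg"] == pytest.approx(0.6)
        assert out["T_stance_ratio"] == pytest.approx(1.0)

    def test_asymmetric_step_ratio_recovered(self):
        traces, _ = simulate_gait(1.0, 1.4, 0.6, 10, FS, 0.01, 3)
        ev_l = detect_heel_strikes(magnitude(traces[1], "accel"), FS)
        ev_r = detect_heel_strikes(magnitude(traces[2], "accel"), FS)
        out = gait_durations(ev_l, ev_r, FS)
        assert out["T_step_ratio"] == pytest.approx(1.4, abs=0.05)

    def test_insufficient_events_names_the_foot(self):
        ok = GaitEvents(heel_strikes=[0, 100], lift_offs=[60])
        empty = GaitEvents(heel_strikes=[], lift_offs=[])
        with pytest.raises(ValueError, match="right"):
            gait_durations(ok, empty, FS)


# ---------------------------------------------------------------------------
# wheelchair: SWAB regimes and arm synchrony
# ---------------------------------------------------------------------------


def _push_train(n, fs, cycle, lag, rng):
    t = np.arange(n) / fs
    mag = 1.0 + rng.normal(0, 0.01, n)
    for k in range(int(n / fs / cycle)):
        mag += 0.8 * np.exp(-0.5 * ((t - (k + 0.3) * cycle - lag) / 0.05) ** 2)
    return mag


class TestArmSync:
    def test_identical_traces_zero_lag(self, rng):
        left = _push_train(1500, FS, 1.0, 0.0, rng)
        res = arm_synchrony(left, left.copy(), FS)
        assert res.push_lag == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("lag", [0.1, 0.25])
    def test_programmed_lag_recovered(self, lag, rng):
        left = _push_train(1500, FS, 1.0, 0.0, rng)
        right = _push_train(1500, FS, 1.0, lag, np.random.default_rng(9))
        res = arm_synchrony(left, right, FS)
        assert res.push_lag == pytest.approx(lag, abs=0.02)

    def test_too_few_cycles_is_explicit_failure(self, rng):
        flat = 1.0 + rng.normal(0, 0.01, 300)
        with pytest.raises(ValueError, match="push cycles"):
            arm_synchrony(flat, flat.copy(), FS)


class TestSwabSegment:
    def test_constant_series_single_segment(self):
        blocks = swab_segment(np.ones(500), FS)
        assert blocks == [(0, 500, "straight")]

    def test_straight_turn_straight_recovered(self):
        traces, gt = simulate_wheelchair(1.0, 0.1, 8, 3.0, FS, seed=2)
        lmag = magnitude(traces[1], "accel")
        rmag = magnitude(traces[2], "accel")
        blocks = swab_segment(0.5 * (lmag + rmag), FS)
        labels = [b[2] for b in blocks]
        assert labels == ["straight", "turn", "straight"]
        b1, b2 = gt.segment_breakpoints
        assert abs(blocks[0][1] - b1) / FS <= 0.5
        assert abs(blocks[1][1] - b2) / FS <= 0.5


# ---------------------------------------------------------------------------
# task-level dispatch
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def full_session():
    return simulate_session(
        ImpairmentProfile(level=0.5, side_affected="left"), week=1, seed=21
    )


class TestExtractTaskFeatures:
    @pytest.mark.parametrize(
        "task, n",
        [
            (TaskClass.CARDS, 7),
            (TaskClass.BIG_OBJECTS, 14),
            (TaskClass.TUG_WALK, 11),
            (TaskClass.TUG_WHEELCHAIR, 8),
        ],
    )
    def test_layouts_match_task_class(self, full_session, task, n):
        seg = next(s for s in full_session.recording.segments if s.task_class == task)
        fv = extract_task_features(full_session.recording, seg)
        assert fv.names == feature_layout(task)
        assert len(fv.names) == n

    def test_wheelchair_includes_armsync(self, full_session):
        seg = next(
            s
            for s in full_session.recording.segments
            if s.task_class == TaskClass.TUG_WHEELCHAIR
        )
        fv = extract_task_features(full_session.recording, seg)
        assert "ArmSync" in fv.names
        assert 0.0 <= fv.values["ArmSync"] <= 0.5

    def test_gait_includes_both_ratios(self, full_session):
        seg = next(
            s
            for s in full_session.recording.segments
            if s.task_class == TaskClass.TUG_WALK
        )
        fv = extract_task_features(full_session.recording, seg)
        assert {"T_step_ratio", "T_stance_ratio"} <= set(fv.names)

    def test_time_bounded_by_segment_duration(self, full_session):
        rec = full_session.recording
        for seg in rec.segments:
            fv = extract_task_features(rec, seg)
            key = "TIME_L" if seg.task_class == TaskClass.BIG_OBJECTS else "TIME"
            if key in fv.values:
                assert fv.values[key] <= seg.n_samples / rec.sample_rate + 1e-9

    def test_missing_placement_names_task_and_sensor(self, full_session):
        rec = full_session.recording
        seg = next(s for s in rec.segments if s.task_class == TaskClass.TUG_WALK)
        traces = {p: t for p, t in rec.traces.items() if p != Placement.FOOT_L}
        broken = SessionRecording(rec.subject_id, rec.week, traces, rec.segments)
        with pytest.raises(KeyError, match="tug_walk.*foot_L"):
            extract_task_features(broken, seg)
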