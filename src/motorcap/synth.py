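"""Synthetic IMU sessions with known ground truth.

Generates wrist traces for cyclic manual tasks, hip/foot traces for gait,
bilateral wrist traces for wheelchair propulsion, and a labeling-sensor
trace with single/double rotation bursts bracketing each task.  A latent
impairment level in [0, 1] drives the signal statistics the analysis is
sensitive to: higher impairment lengthens the active window, narrows the
acceleration spread, disperses spectral energy away from the movement
frequency, and shrinks the angular-velocity range.  Expert-style ratings are
produced as a known affine function of the extracted features plus Gaussian
noise, so the regression stage can be tested for exact recovery.

All generators are deterministic given their seed; there is no global
random state.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from . import features as _features
from .types import (
    BIMANUAL_TASKS,
    GAIT_TASKS,
    SINGLE_HAND_TASKS,
    WHEELCHAIR_TASKS,
    FeatureVector,
    GroundTruth,
    IMUTrace,
    ImpairmentProfile,
    Placement,
    RatedInstance,
    SessionRecording,
    Side,
    TaskClass,
    TaskSegment,
    feature_layout,
)

__all__ = [
    "simulate_manual_task",
    "simulate_gait",
    "simulate_wheelchair",
    "simulate_labeling_trace",
    "simulate_session",
    "SessionResult",
    "default_task_list",
    "default_rating_weights",
    "rating_from_level",
]

#: Nominal movement cycle frequency (Hz) and duration hint (s) per manual task.
MANUAL_TASK_PARAMS: dict[TaskClass, tuple[float, float]] = {
    TaskClass.CARDS: (1.2, 5.0),
    TaskClass.SMALL_OBJECTS: (0.9, 7.0),
    TaskClass.DOMINOS: (1.0, 6.0),
    TaskClass.BOTTLE: (0.8, 6.0),
    TaskClass.KEY: (0.7, 5.0),
    TaskClass.NHPT: (1.1, 8.0),
    TaskClass.BIG_OBJECTS: (0.6, 7.0),
    TaskClass.BALL: (0.5, 8.0),
}

_ACCEL_NOISE_SD = 0.008  # g, quiescent accelerometer noise floor
_GYRO_NOISE_SD = 1.5  # deg/s


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]])


def _subject_key(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode()) & 0x7FFFFFFF


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _movement_direction(rng: np.random.Generator) -> np.ndarray:
    """Unit direction with a substantial vertical component.

    The acceleration magnitude is, to first order, 1 g plus the dynamic
    component along gravity; a near-horizontal direction would make the
    movement nearly invisible to the magnitude pipeline, which is not how
    reaching/grasping movements behave.
    """
    z = rng.uniform(0.55, 0.85)
    az = rng.uniform(0, 2 * np.pi)
    r = np.sqrt(1 - z * z)
    return np.array([r * np.cos(az), r * np.sin(az), z * np.sign(rng.normal() + 10)])


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float) -> np.ndarray:
    """Unit-variance low-passed white noise (movement-band broadband signal)."""
    if n < 12:
        return rng.normal(size=n)
    sos = _signal.butter(2, min(cutoff, 0.45 * fs), btype="low", fs=fs, output="sos")
    x = _signal.sosfilt(sos, rng.normal(size=n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _quiescent(rng: np.random.Generator, n: int, noise_sd: float = _ACCEL_NOISE_SD):
    accel = np.column_stack(
        [
            rng.normal(0, noise_sd, n),
            rng.normal(0, noise_sd, n),
            1.0 + rng.normal(0, noise_sd, n),
        ]
    )
    gyro = rng.normal(0, _GYRO_NOISE_SD, (n, 3))
    return accel, gyro


def _ramp_envelope(n: int, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    """Raised-cosine on/off ramps; 1.0 on the plateau."""
    r = min(int(round(ramp_s * fs)), n // 2)
    env = np.ones(n)
    if r > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = up
        env[n - r :] = up[::-1]
    return env


# ---------------------------------------------------------------------------
# manual tasks
# ---------------------------------------------------------------------------


def _manual_wrist(
    rng: np.random.Generator,
    level: float,
    cycle_freq: float,
    n_lead: int,
    n_active: int,
    n_tail: int,
    fs: float,
    placement: Placement,
) -> IMUTrace:
    """One wrist trace: quiescent lead-in, cyclic active window, lead-out.

    Impairment is expressed through partly independent facets (movement
    amplitude, spectral dispersion, rotation range): a given capacity level
    does not degrade every aspect of movement equally from trial to trial.
    """
    n = n_lead + n_active + n_tail
    accel, gyro = _quiescent(rng, n)

    def facet() -> float:
        return float(np.clip(level + rng.uniform(-0.15, 0.15), 0.0, 1.0))

    t = np.arange(n_active) / fs
    env = _ramp_envelope(n_active, fs)
    amp = 0.35 * (1.0 - 0.6 * facet())  # dynamic scale: spread narrows
    tone_amp = amp * (1.0 - 0.5 * facet())  # energy leaves the cycle freq
    broad_amp = amp * (0.12 + 0.75 * facet())
    phase = rng.uniform(0, 2 * np.pi)
    tone = tone_amp * np.sin(2 * np.pi * cycle_freq * t + phase)
    tone += 0.10 * tone_amp * np.sin(2 * np.pi * 2 * cycle_freq * t + 2.1 * phase)
    broad = broad_amp * _smooth_noise(rng, n_active, fs, cutoff=6.0)
    d1, d2 = _movement_direction(rng), _movement_direction(rng)
    active = env[:, None] * (tone[:, None] * d1 + broad[:, None] * d2)
    accel[n_lead : n_lead + n_active] += active

    gyro_amp = 170.0 * (1.0 - 0.7 * facet())
    g_axis = _unit_vector(rng)
    g_tone = gyro_amp * np.sin(2 * np.pi * cycle_freq * t + phase + 0.8)
    g_broad = 12.0 * (1.0 + level) * _smooth_noise(rng, n_active, fs, cutoff=6.0)
    gyro[n_lead : n_lead + n_active] += env[:, None] * (
        g_tone[:, None] * g_axis + g_broad[:, None] * _unit_vector(rng)
    )
    return IMUTrace(sample_rate=fs, placement=placement, accel=accel, gyro=gyro)


def simulate_manual_task(
    profile: ImpairmentProfile,
    task_class: TaskClass = TaskClass.CARDS,
    duration_hint: float | None = None,
    fs: float = 100.0,
    seed: int = 0,
    side: Side = Side.RIGHT,
    week: int = 1,
    lead_s: float = 2.0,
) -> tuple[list[IMUTrace], GroundTruth]:
    """Simulate the wrist trace(s) of one cyclic manual task.

    Returns one trace (the performing wrist) for single-hand tasks, two
    (left then right wrist) for bimanual ones, plus the ground truth with
    the exact active interval and cycle frequency.

    The active duration stretches with the impairment level (an impaired
    hand takes up to twice as long), while amplitude, spectral
    concentration, and angular-velocity range shrink.
    """
    task_class = TaskClass(task_class)
    if task_class not in SINGLE_HAND_TASKS | BIMANUAL_TASKS:
        raise ValueError(f"{task_class.value} is not a manual task")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    f0, default_dur = MANUAL_TASK_PARAMS[task_class]
    if duration_hint is None:
        duration_hint = default_dur
    if duration_hint <= 0:
        raise ValueError(f"duration_hint must be positive, got {duration_hint}")

    rng = _rng(seed, 11)
    bimanual = task_class in BIMANUAL_TASKS
    sides = (Side.LEFT, Side.RIGHT) if bimanual else (side,)
    # one shared cycle frequency and active window per task execution
    lead_level = profile.level_for(sides[-1], week)
    # trial-to-trial variability: execution speed and rate vary ~10% between
    # repetitions of the same task even at a fixed capacity level
    cycle_freq = f0 * (1.0 - 0.25 * lead_level) * (1.0 + rng.uniform(-0.12, 0.12))
    active_s = duration_hint * (1.0 + lead_level) * (1.0 + rng.uniform(-0.12, 0.12))
    n_lead = int(round(lead_s * fs))
    n_active = int(round(active_s * fs))
    n_tail = n_lead
    if n_active < 4:
        raise ValueError("active window is shorter than 4 samples; increase duration_hint")

    traces = []
    for k, sd in enumerate(sides):
        placement = Placement.WRIST_L if sd == Side.LEFT else Placement.WRIST_R
        # the two hands of a bimanual task are near- but not perfectly
        # synchronous: detune each wrist's rate slightly
        detune = 1.0 + rng.uniform(-0.05, 0.05) if bimanual else 1.0
        traces.append(
            _manual_wrist(
                _rng(seed, 11, k + 1),
                profile.level_for(sd, week),
                cycle_freq * detune,
                n_lead,
                n_active,
                n_tail,
                fs,
                placement,
            )
        )
    gt = GroundTruth(
        active_interval=(n_lead, n_lead + n_active), cycle_freq=float(cycle_freq)
    )
    return traces, gt


# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------


def _foot_trace(
    rng: np.random.Generator,
    strikes_s: np.ndarray,
    stance_s: float,
    n_total: int,
    fs: float,
    noise_sd: float,
    spike_amp: float,
    placement: Placement,
) -> IMUTrace:
    """Foot magnitude: impact spike, ~1 g stance plateau, elevated swing."""
    mag = 1.0 + rng.normal(0, noise_sd, n_total)

    def add_pulse(center_s: float, sigma_samples: float, amp: float) -> None:
        ic = int(round(center_s * fs))
        half = int(np.ceil(4 * sigma_samples))
        idx = np.arange(max(0, ic - half), min(ic + half + 1, n_total))
        if len(idx):
            mag[idx] += amp * np.exp(-0.5 * ((idx - ic) / sigma_samples) ** 2)

    for k, ts in enumerate(strikes_s):
        # impact transient ~30 ms wide, peak exactly at the strike sample
        add_pulse(ts, 0.0075 * fs, spike_amp)
        lift = ts + stance_s
        # sharp toe-off transient: departs the plateau right at lift-off
        add_pulse(lift + 0.01, 0.006 * fs, 0.6)
        nxt = strikes_s[k + 1] if k + 1 < len(strikes_s) else lift + 0.4
        sw0, sw1 = lift + 0.04, nxt - 0.02
        i0, i1 = int(round(sw0 * fs)), int(round(sw1 * fs))
        if i1 > i0:
            u = np.linspace(0, 1, i1 - i0)
            idx = np.arange(i0, min(i1, n_total))
            mag[idx] += 0.30 * np.sin(np.pi * u[: len(idx)]) ** 2

    accel = np.column_stack([np.zeros(n_total), np.zeros(n_total), mag])
    gyro = rng.normal(0, _GYRO_NOISE_SD, (n_total, 3))
    for k, ts in enumerate(strikes_s):
        lift = ts + stance_s
        nxt = strikes_s[k + 1] if k + 1 < len(strikes_s) else lift + 0.4
        i0, i1 = int(round(lift * fs)), min(int(round(nxt * fs)), n_total)
        if i1 > i0:
            u = np.linspace(0, 1, i1 - i0)
            gyro[i0:i1, 1] += 150.0 * np.sin(np.pi * u)
    return IMUTrace(sample_rate=fs, placement=placement, accel=accel, gyro=gyro)


def simulate_gait(
    step_dur_left: float = 1.2,
    step_dur_right: float = 1.2,
    stance_frac: float = 0.6,
    n_steps: int = 10,
    fs: float = 100.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    stance_frac_right: float | None = None,
    spike_amp: float = 2.0,
    lead_s: float = 1.0,
    foot_placements: tuple[Placement, Placement] = (Placement.FOOT_L, Placement.FOOT_R),
) -> tuple[list[IMUTrace], GroundTruth]:
    """Simulate walking: hip trace plus two foot traces with known events.

    Each foot shows a sharp impact transient at every heel strike, a near-1 g
    plateau during stance, and elevated magnitude during swing.  Step
    durations (consecutive same-foot strikes) and stance fractions are
    programmable per foot; ground truth lists the exact strike samples and
    per-foot stance/step durations.
    """
    if not 0 < stance_frac < 1:
        raise ValueError(f"stance_frac must lie in (0, 1), got {stance_frac}")
    sfr = stance_frac if stance_frac_right is None else stance_frac_right
    if not 0 < sfr < 1:
        raise ValueError(f"stance_frac_right must lie in (0, 1), got {sfr}")
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    if fs <= 0 or step_dur_left <= 0 or step_dur_right <= 0:
        raise ValueError("fs and step durations must be positive")

    t0 = lead_s
    strikes_l = t0 + step_dur_left * np.arange(n_steps)
    strikes_r = t0 + 0.5 * step_dur_right + step_dur_right * np.arange(n_steps)
    stance_l = stance_frac * step_dur_left
    stance_r = sfr * step_dur_right
    t_end = max(strikes_l[-1] + stance_l, strikes_r[-1] + stance_r) + 0.6 + lead_s
    n_total = int(round(t_end * fs))

    foot_l = _foot_trace(
        _rng(seed, 21), strikes_l, stance_l, n_total, fs, noise_sd, spike_amp,
        foot_placements[0],
    )
    foot_r = _foot_trace(
        _rng(seed, 22), strikes_r, stance_r, n_total, fs, noise_sd, spike_amp,
        foot_placements[1],
    )
    rng = _rng(seed, 23)
    t = np.arange(n_total) / fs
    hip_mag = 1.0 + rng.normal(0, noise_sd, n_total)
    cadence = 2.0 / (0.5 * (step_dur_left + step_dur_right))
    active = (t >= t0) & (t <= t_end - lead_s)
    hip_mag[active] += 0.08 * np.sin(2 * np.pi * cadence * t[active])
    hip_accel = np.column_stack([np.zeros(n_total), np.zeros(n_total), hip_mag])
    hip_gyro = rng.normal(0, _GYRO_NOISE_SD, (n_total, 3))
    hip_gyro[active, 2] += 25.0 * np.sin(2 * np.pi * 0.5 * cadence * t[active])
    hip = IMUTrace(sample_rate=fs, placement=Placement.HIP, accel=hip_accel, gyro=hip_gyro)

    gt = GroundTruth(
        heel_strike_times={
            "left": np.round(strikes_l * fs).astype(int),
            "right": np.round(strikes_r * fs).astype(int),
        },
        stance_durations={
            "left": np.full(n_steps, stance_l),
            "right": np.full(n_steps, stance_r),
        },
        step_durations={
            "left": np.full(n_steps - 1, step_dur_left),
            "right": np.full(n_steps - 1, step_dur_right),
        },
    )
    return [hip, foot_l, foot_r], gt


# ---------------------------------------------------------------------------
# wheelchair propulsion
# ---------------------------------------------------------------------------


def simulate_wheelchair(
    cycle_dur: float = 1.0,
    lag_frac: float = 0.1,
    n_cycles: int = 8,
    turn_dur: float = 3.0,
    fs: float = 100.0,
    seed: int = 0,
    noise_sd: float = 0.01,
) -> tuple[list[IMUTrace], GroundTruth]:
    """Simulate wheelchair propulsion: hip plus two wrist traces.

    Layout is straight (``n_cycles`` push cycles) -> turn (``turn_dur`` s of
    low-activity signal) -> straight (``n_cycles``).  Each push cycle has a
    forward-push acceleration peak and a smaller hands-back release peak on
    each wrist; the right wrist lags the left by ``lag_frac * cycle_dur``.
    """
    if not 0 <= lag_frac <= 0.5:
        raise ValueError(f"lag_frac must lie in [0, 0.5], got {lag_frac}")
    if n_cycles < 2:
        raise ValueError(f"n_cycles must be >= 2, got {n_cycles}")
    if cycle_dur <= 0 or turn_dur < 0 or fs <= 0:
        raise ValueError("cycle_dur and fs must be positive, turn_dur non-negative")

    straight_dur = n_cycles * cycle_dur
    t_break1 = straight_dur
    t_break2 = straight_dur + turn_dur
    t_end = 2 * straight_dur + turn_dur
    n_total = int(round(t_end * fs))
    t = np.arange(n_total) / fs

    def gauss(center: float, sigma: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center) / sigma) ** 2)

    def wrist(rng: np.random.Generator, lag_s: float, placement: Placement) -> IMUTrace:
        mag = 1.0 + rng.normal(0, noise_sd, n_total)
        for start in (0.0, t_break2):
            for k in range(n_cycles):
                push = start + (k + 0.25) * cycle_dur + lag_s
                release = start + (k + 0.62) * cycle_dur + lag_s
                mag += 0.85 * gauss(push, 0.05 * cycle_dur)
                mag += 0.30 * gauss(release, 0.09 * cycle_dur)
        in_turn = (t >= t_break1) & (t < t_break2)
        mag[in_turn] += 0.03 * np.sin(2 * np.pi * 0.4 * t[in_turn])
        accel = np.column_stack([np.zeros(n_total), np.zeros(n_total), mag])
        gyro = rng.normal(0, _GYRO_NOISE_SD, (n_total, 3))
        in_straight = ~in_turn
        gyro[in_straight, 0] += 80.0 * np.sin(
            2 * np.pi * (t[in_straight] - lag_s) / cycle_dur
        )
        return IMUTrace(sample_rate=fs, placement=placement, accel=accel, gyro=gyro)

    wrist_l = wrist(_rng(seed, 31), 0.0, Placement.WRIST_L)
    wrist_r = wrist(_rng(seed, 32), lag_frac * cycle_dur, Placement.WRIST_R)

    rng = _rng(seed, 33)
    hip_mag = 1.0 + rng.normal(0, noise_sd, n_total)
    in_turn = (t >= t_break1) & (t < t_break2)
    hip_mag[~in_turn] += 0.12 * np.sin(2 * np.pi * t[~in_turn] / cycle_dur)
    hip_accel = np.column_stack([np.zeros(n_total), np.zeros(n_total), hip_mag])
    hip_gyro = rng.normal(0, _GYRO_NOISE_SD, (n_total, 3))
    hip_gyro[in_turn, 2] += 45.0
    hip = IMUTrace(sample_rate=fs, placement=Placement.HIP, accel=hip_accel, gyro=hip_gyro)

    gt = GroundTruth(
        push_cycle_lag=float(lag_frac),
        cycle_freq=1.0 / cycle_dur,
        segment_breakpoints=(int(round(t_break1 * fs)), int(round(t_break2 * fs))),
    )
    return [hip, wrist_l, wrist_r], gt


# ---------------------------------------------------------------------------
# labeling sensor
# ---------------------------------------------------------------------------


def simulate_labeling_trace(
    task_intervals: list[tuple[float, float]],
    fs: float = 100.0,
    seed: int = 0,
    total_duration: float | None = None,
) -> IMUTrace:
    """Labeling-sensor trace: a single rotation burst at each task start and
    a double burst at each end, on the gyroscope x-axis over low noise.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    intervals = [(float(a), float(b)) for a, b in task_intervals]
    for a, b in intervals:
        if b <= a:
            raise ValueError(f"interval ({a}, {b}) is empty or reversed")
    for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
        if a1 < b0:
            raise ValueError(
                f"task intervals overlap or are unsorted: ({a0}, {b0}) vs ({a1}, {b1})"
            )
    if total_duration is None:
        total_duration = (intervals[-1][1] + 2.0) if intervals else 5.0
    n = int(round(total_duration * fs))
    rng = _rng(seed, 41)
    accel, gyro = _quiescent(rng, n)

    def burst(t0: float) -> None:
        i0 = int(round(t0 * fs))
        m = max(2, int(round(0.16 * fs)))
        idx = np.arange(i0, min(i0 + m, n))
        if len(idx):
            gyro[idx, 0] += 500.0 * np.sin(np.pi * (idx - i0) / m)

    for a, b in intervals:
        burst(a)  # single burst: task start
        burst(b)  # double burst: task end
        burst(b + 0.4)
    return IMUTrace(sample_rate=fs, placement=Placement.LABELER, accel=accel, gyro=gyro)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------


def rating_from_level(level: float) -> float:
    """Deterministic capacity rating implied by an impairment level (1 = normal)."""
    return float(np.clip(0.97 - 0.9 * level, 0.0, 1.0))


def default_rating_weights(task_class: TaskClass) -> tuple[float, dict[str, float]]:
    """Generating weights of the synthetic expert rating, per task class.

    The rating is ``clip(w0 + sum_j w_j x_j + noise, 0, 1)`` over the
    extracted features; signs follow the expected clinical directions
    (longer TIME -> worse; higher SM, ARE, RANG -> better).
    """
    task_class = TaskClass(task_class)
    if task_class in SINGLE_HAND_TASKS:
        return 0.10, {
            "TIME": -0.030,
            "MI": 0.05,
            "MIV": 0.80,
            "DF": 0.050,
            "SM": 0.45,
            "ARE": 3.0e-6,
            "RANG": 0.0009,
        }
    if task_class in BIMANUAL_TASKS:
        w0, w = default_rating_weights(TaskClass.CARDS)
        half = {f"{k}_L": v / 2 for k, v in w.items()}
        half.update({f"{k}_R": v / 2 for k, v in w.items()})
        return w0, half
    if task_class in GAIT_TASKS:
        # the stance-ratio's direction depends on which side is affected, so
        # the linear rating leans on cadence and hip smoothness instead
        w = {k: 0.0 for k in feature_layout(task_class)}
        w.update({"T_step_avg": -1.2, "T_stance_avg": -0.25, "SM": 0.2})
        return 2.30, w
    if task_class in WHEELCHAIR_TASKS:
        w = {k: 0.0 for k in feature_layout(task_class)}
        w.update({"ArmSync": -2.0, "MIV": 0.5})
        return 1.00, w
    raise ValueError(f"no rating weights for task class {task_class!r}")


def default_task_list(
    include_locomotion: bool = True, manual_tasks: tuple[TaskClass, ...] | None = None
) -> list[tuple[TaskClass, Side]]:
    """Standard session protocol: single-hand tasks on both sides, bimanual
    tasks once, plus the locomotion tasks."""
    if manual_tasks is None:
        manual_tasks = (
            TaskClass.CARDS,
            TaskClass.SMALL_OBJECTS,
            TaskClass.DOMINOS,
            TaskClass.BOTTLE,
            TaskClass.KEY,
            TaskClass.NHPT,
        )
    tasks: list[tuple[TaskClass, Side]] = []
    for tc in manual_tasks:
        if tc in SINGLE_HAND_TASKS:
            tasks.append((tc, Side.RIGHT))
            tasks.append((tc, Side.LEFT))
        else:
            tasks.append((tc, Side.BOTH))
    tasks.append((TaskClass.BIG_OBJECTS, Side.BOTH))
    tasks.append((TaskClass.BALL, Side.BOTH))
    if include_locomotion:
        tasks.append((TaskClass.TUG_WALK, Side.NA))
        tasks.append((TaskClass.TUG_WHEELCHAIR, Side.NA))
    return tasks


@dataclass
class SessionResult:
    """Everything a simulated weekly assessment produced."""

    recording: SessionRecording
    instances: list[RatedInstance]
    ground_truths: list[GroundTruth]
    rating_weights: dict[TaskClass, tuple[float, dict[str, float]]]


def simulate_session(
    profile: ImpairmentProfile,
    week: int = 1,
    task_list: list[tuple[TaskClass, Side]] | None = None,
    rating_weights: dict[TaskClass, tuple[float, dict[str, float]]] | None = None,
    rating_noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = 100.0,
    subject_id: str = "S01",
    gap_s: float = 2.5,
    feature_config: "_features.FeatureConfig | None" = None,
) -> SessionResult:
    """Simulate one weekly assessment session.

    Tasks are laid out on a common timeline with quiescent gaps; the
    labeling sensor carries a single rotation burst at each task start and a
    double burst at each end.  Ratings are a known affine function of the
    features extracted from the generated traces, plus optional Gaussian
    noise, clipped to [0, 1]; the weights used are returned so regression
    recovery is checkable.
    """
    if task_list is None:
        task_list = default_task_list()
    if rating_noise_sd < 0:
        raise ValueError(f"rating_noise_sd must be >= 0, got {rating_noise_sd}")
    weights = dict(rating_weights or {})
    for tc, _ in task_list:
        tc = TaskClass(tc)
        if tc not in weights:
            weights[tc] = default_rating_weights(tc)
        w0, w = weights[tc]
        layout = feature_layout(tc)
        if tuple(w.keys()) != layout:
            raise ValueError(
                f"rating weights for task class {tc.value} do not match its "
                f"feature layout {layout}"
            )

    skey = _subject_key(subject_id)
    level = profile.level_at(week)
    lam = lambda lo, hi: lo + (hi - lo) * level  # noqa: E731

    task_traces: list[dict[Placement, IMUTrace]] = []
    ground_truths: list[GroundTruth] = []
    for i, (tc, side) in enumerate(task_list):
        tc, side = TaskClass(tc), Side(side)
        sub_seed = int(_rng(seed, skey, week, i).integers(0, 2**31 - 1))
        if tc in SINGLE_HAND_TASKS | BIMANUAL_TASKS:
            traces, gt = simulate_manual_task(
                profile, tc, None, fs, sub_seed, side=side, week=week, lead_s=0.8
            )
        elif tc in GAIT_TASKS:
            placements = (
                (Placement.FOOT_L, Placement.FOOT_R)
                if tc == TaskClass.TUG_WALK
                else (Placement.UPPER_LEG_L, Placement.UPPER_LEG_R)
            )
            affected_right = profile.side_affected == "right"
            jrng = _rng(sub_seed, 5)
            sf_l = 0.60 + (0.0 if affected_right else 0.10 * level) + jrng.uniform(-0.02, 0.02)
            sf_r = 0.60 + (0.10 * level if affected_right else 0.0) + jrng.uniform(-0.02, 0.02)
            traces, gt = simulate_gait(
                step_dur_left=lam(1.1, 1.5) * (1.0 + jrng.uniform(-0.04, 0.04)),
                step_dur_right=lam(1.1, 1.5) * (1.0 + jrng.uniform(-0.04, 0.04)),
                stance_frac=sf_l,
                stance_frac_right=sf_r,
                n_steps=8,
                fs=fs,
                noise_sd=0.01,
                seed=sub_seed,
                foot_placements=placements,
            )
        elif tc in WHEELCHAIR_TASKS:
            jrng = _rng(sub_seed, 6)
            traces, gt = simulate_wheelchair(
                cycle_dur=lam(1.0, 1.3) * (1.0 + jrng.uniform(-0.06, 0.06)),
                lag_frac=float(
                    np.clip(0.04 + 0.30 * level + jrng.uniform(-0.03, 0.03), 0.0, 0.45)
                ),
                n_cycles=6,
                turn_dur=3.0 + jrng.uniform(-0.5, 0.5),
                fs=fs,
                seed=sub_seed,
            )
        else:  # pragma: no cover
            raise ValueError(f"unsupported task class {tc!r}")
        gt.true_rating = rating_from_level(level)
        task_traces.append({tr.placement: tr for tr in traces})
        ground_truths.append(gt)

    # timeline layout
    n_gap = int(round(gap_s * fs))
    segments: list[TaskSegment] = []
    cursor = n_gap
    for (tc, side), traces in zip(task_list, task_traces):
        n_task = next(iter(traces.values())).n_samples
        segments.append(TaskSegment(TaskClass(tc), Side(side), cursor, cursor + n_task))
        cursor += n_task + n_gap
    n_total = cursor + n_gap

    placements_needed = sorted(
        {p for traces in task_traces for p in traces},
        key=lambda p: p.value,
    )
    full: dict[Placement, IMUTrace] = {}
    for p in placements_needed:
        accel, gyro = _quiescent(_rng(seed, skey, week, 1000 + hash_placement(p)), n_total)
        for seg, traces in zip(segments, task_traces):
            if p in traces:
                accel[seg.start : seg.end] = traces[p].accel
                gyro[seg.start : seg.end] = traces[p].gyro
        full[p] = IMUTrace(sample_rate=fs, placement=p, accel=accel, gyro=gyro)
    intervals_s = [(seg.start / fs, seg.end / fs) for seg in segments]
    full[Placement.LABELER] = simulate_labeling_trace(
        intervals_s, fs, seed=int(_rng(seed, skey, week, 999).integers(0, 2**31 - 1)),
        total_duration=n_total / fs,
    )

    recording = SessionRecording(
        subject_id=subject_id, week=week, traces=full, segments=segments
    )

    rng_rate = _rng(seed, skey, week, 77)
    instances: list[RatedInstance] = []
    cfg = feature_config or _features.FeatureConfig()
    for seg, gt in zip(segments, ground_truths):
        fv = _features.extract_task_features(recording, seg, cfg)
        w0, w = weights[seg.task_class]
        raw = w0 + sum(w[name] * fv.values[name] for name in fv.names)
        raw += rng_rate.normal(0, rating_noise_sd) if rating_noise_sd > 0 else 0.0
        target = float(np.clip(raw, 0.0, 1.0))
        gt.true_features = dict(fv.values)
        instances.append(
            RatedInstance(
                subject_id=subject_id,
                week=week,
                task_class=seg.task_class,
                side=seg.side,
                features=fv,
                target=target,
            )
        )
    return SessionResult(
        recording=recording,
        instances=instances,
        ground_truths=ground_truths,
        rating_weights=weights,
    )


_PLACEMENT_ORDER = {p: i for i, p in enumerate(Placement)}


def hash_placement(p: Placement) -> int:
    """Stable small integer per placement (seed derivation)."""
    return _PLACEMENT_ORDER[Placement(p)]
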