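"""Per-task movement features from magnitude signals.

The seven base features quantify how a task was executed, all computed from
orientation-invariant magnitude series of a single sensor:

* ``TIME`` — task completion time (s), from a sliding-window activity
  detector on the acceleration magnitude.
* ``MI`` — movement intensity (g): mean instantaneous acceleration magnitude.
* ``MIV`` — movement intensity variation (g): RMS deviation of the magnitude
  about its mean (population form).
* ``DF`` — dominant frequency (Hz): spectral bin of maximal energy.
* ``SM`` — smoothness of movement: fraction of spectral energy within the
  0.2 Hz band around DF; in [0, 1], higher = more periodic.
* ``ARE`` — average rotation energy ((deg/s)^2): mean squared angular-velocity
  magnitude.
* ``RANG`` — range of angular velocity (deg/s): max - min of the gyro
  magnitude.

Locomotion tasks add step/stance durations and their right/left ratios from
heel-strike detection; wheelchair propulsion adds the bilateral arm-synchrony
lag measured over straight-driving segments found by SWAB segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import swab as _swab
from .preprocess import lowpass, magnitude
from .types import (
    BASE_FEATURES,
    BIMANUAL_TASKS,
    GAIT_TASKS,
    SINGLE_HAND_TASKS,
    WHEELCHAIR_TASKS,
    FeatureVector,
    GaitEvents,
    IMUTrace,
    Placement,
    SessionRecording,
    Side,
    TaskClass,
    TaskSegment,
)

__all__ = [
    "FeatureConfig",
    "MovementInterval",
    "ArmSyncResult",
    "sliding_window_std",
    "movement_interval",
    "movement_intensity",
    "movement_intensity_variation",
    "energy_spectrum",
    "dominant_frequency",
    "smoothness",
    "average_rotation_energy",
    "range_angular_velocity",
    "swab_segment",
    "arm_synchrony",
    "detect_heel_strikes",
    "gait_durations",
    "extract_task_features",
]


@dataclass
class FeatureConfig:
    """Tunable thresholds of the extraction stage (defaults used throughout)."""

    lowpass_cutoff: float = 45.0  # Hz; None disables filtering
    time_window: float = 0.5  # s, activity-detector window
    time_overlap: float = 0.49  # s, window overlap (step = window - overlap)
    time_threshold: float | None = None  # g; None = automatic (see movement_interval)
    strike_threshold: float = 1.8  # g, heel-strike peak height
    strike_refractory: float = 0.4  # s, min spacing between strikes
    swing_threshold: float = 0.15  # g, departure from the 1 g stance plateau
    swab_max_error: float | None = None  # None = automatic
    swab_smooth_window: float = 1.0  # s, envelope window for regime detection


@dataclass
class MovementInterval:
    """Detected movement onset/offset (samples) and completion time (s)."""

    onset: int
    offset: int
    time_s: float


@dataclass
class ArmSyncResult:
    """Bilateral push-cycle synchrony; the feature value is ``push_lag``."""

    push_lag: float
    release_lag: float | None
    n_cycles: int
    cycle_duration: float


def sliding_window_std(
    series: np.ndarray, fs: float, window: float = 0.5, overlap: float = 0.49
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window standard deviation of a series.

    Returns ``(centers, stds)`` where ``centers`` are fractional sample
    indices of the window midpoints.  Window and overlap are in seconds;
    the step is ``window - overlap`` (10 ms at the defaults and 100 Hz).
    """
    series = np.asarray(series, dtype=float)
    w = int(round(window * fs))
    step = max(1, int(round((window - overlap) * fs)))
    if w < 2:
        raise ValueError(f"window of {window} s is shorter than 2 samples at fs={fs}")
    if len(series) < w:
        raise ValueError(
            f"series of {len(series)} samples is shorter than the {w}-sample window"
        )
    starts = np.arange(0, len(series) - w + 1, step)
    # vectorized window std via cumulative sums (population form)
    c1 = np.concatenate([[0.0], np.cumsum(series)])
    c2 = np.concatenate([[0.0], np.cumsum(series**2)])
    s1 = c1[starts + w] - c1[starts]
    s2 = c2[starts + w] - c2[starts]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    return starts + (w - 1) / 2.0, np.sqrt(var)


def movement_interval(
    accel_magnitude: np.ndarray,
    fs: float,
    window: float = 0.5,
    overlap: float = 0.49,
    threshold: float | None = None,
) -> MovementInterval | None:
    """Movement onset/offset from the windowed std of the acceleration magnitude.

    A window is "active" when its std exceeds ``threshold``; onset and
    offset are the midpoints of the first and last active windows.

    With ``threshold=None`` the detector is self-calibrating and two-stage.
    The coarse stage smooths the windowed *variance* series with a centered
    0.7 s moving average (the 0.5 s window holds less than one movement
    cycle, so its raw std oscillates with the cycle phase) and thresholds it
    at the midpoint between the quiet floor and the local active plateau.
    A windowed statistic can only localize an edge to a fraction of the
    window, so a fine stage then snaps each edge to the first/last sample
    near it whose deviation from the quiet baseline is confirmed above a
    robust amplitude threshold.

    Returns ``None`` ("no movement") when no window is active, which is
    distinct from a zero-length interval.
    """
    series = np.asarray(accel_magnitude, dtype=float)
    centers, stds = sliding_window_std(series, fs, window, overlap)
    if threshold is not None:
        active = np.flatnonzero(stds > threshold)
        if len(active) == 0:
            return None
        onset = int(round(centers[active[0]]))
        offset = int(round(centers[active[-1]]))
        return MovementInterval(onset=onset, offset=offset, time_s=(offset - onset) / fs)

    from scipy.ndimage import uniform_filter1d

    step_s = max(window - overlap, 1.0 / fs)
    k = max(1, int(round(0.7 / step_s)))
    var = uniform_filter1d(stds**2, size=k, mode="nearest")
    # quiet floor from the lowest percentile: the quiet fraction of a tightly
    # bracketed task segment can be small
    lo, hi = np.percentile(var, [1, 90])
    if hi <= 4.0 * lo:  # no contrast between quiet and active windows
        return None
    a = int(np.argmax(var > 0.5 * (lo + hi)))
    b = len(var) - 1 - int(np.argmax(var[::-1] > 0.5 * (lo + hi)))
    # re-threshold each edge against its local plateau: the activity level
    # may differ between movement start and end
    m = max(1, int(round(0.45 / step_s)))
    for _ in range(3):
        mid = (a + b) // 2
        pa = np.median(var[min(a + m, mid) : max(a + 3 * m, mid + 1)])
        pb = np.median(var[min(b - 3 * m, mid) : max(b - m, mid + 1)])
        a = int(np.argmax(var > 0.5 * (lo + pa)))
        b = len(var) - 1 - int(np.argmax(var[::-1] > 0.5 * (lo + pb)))
        if b <= a:
            a, b = min(a, b), max(a, b)
            break
    onset = int(round(centers[a]))
    offset = int(round(centers[b]))

    # fine stage: snap to confirmed supra-baseline samples near each edge
    half = int(round(0.6 * fs))
    quiet = np.ones(len(series), dtype=bool)
    quiet[max(0, onset - half) : min(len(series), offset + half)] = False
    if quiet.sum() >= 10:
        base = np.median(series[quiet])
        mad = np.median(np.abs(series[quiet] - base))
        amp_thr = max(4.0 * 1.4826 * mad, 1e-12)
        dev = np.abs(series - base) > amp_thr
        confirm = np.convolve(dev.astype(int), np.ones(3, int), mode="same") >= 2
        onset = _snap_edge(confirm, onset, half, first=True)
        offset = _snap_edge(confirm, offset, half, first=False)
    if offset < onset:
        onset = offset
    return MovementInterval(onset=onset, offset=offset, time_s=(offset - onset) / fs)


def _snap_edge(confirm: np.ndarray, guess: int, half: int, first: bool) -> int:
    lo = max(0, guess - half)
    hi = min(len(confirm), guess + half + 1)
    idx = np.flatnonzero(confirm[lo:hi])
    if len(idx) == 0:
        return guess
    return int(lo + (idx[0] if first else idx[-1]))


def movement_intensity(accel: np.ndarray) -> float:
    """MI (g): mean instantaneous acceleration magnitude over the task."""
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3 or len(accel) == 0:
        raise ValueError("accel must be a non-empty (n, 3) array")
    return float(np.mean(np.linalg.norm(accel, axis=1)))


def movement_intensity_variation(accel: np.ndarray) -> float:
    """MIV (g): RMS deviation of the magnitude about its mean (divisor n)."""
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3 or len(accel) == 0:
        raise ValueError("accel must be a non-empty (n, 3) array")
    mi_t = np.linalg.norm(accel, axis=1)
    return float(np.sqrt(np.mean((mi_t - mi_t.mean()) ** 2)))


def energy_spectrum(series: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Positive-frequency energy spectrum after mean (DC) removal.

    Energy is the squared FFT amplitude per bin.  The DC bin is excluded:
    gravity would otherwise dominate every acceleration spectrum and pin the
    dominant frequency at 0 instead of at the movement rate.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    spec = np.fft.rfft(series - series.mean())
    freqs = np.fft.rfftfreq(len(series), d=1.0 / fs)
    return freqs[1:], np.abs(spec[1:]) ** 2


def _argmax_lowest(energy: np.ndarray, rtol: float = 1e-9) -> int:
    """Index of the maximal bin; near-exact ties resolve to the lowest bin."""
    return int(np.argmax(energy >= (1.0 - rtol) * energy.max()))


def dominant_frequency(series: np.ndarray, fs: float) -> float:
    """DF (Hz): frequency bin of maximal energy; ties break to the lowest bin."""
    freqs, energy = energy_spectrum(series, fs)
    return float(freqs[_argmax_lowest(energy)])


def smoothness(series: np.ndarray, fs: float, bandwidth: float = 0.2) -> float:
    """SM in [0, 1]: energy within ``bandwidth`` around DF over total energy.

    The band is ``DF +/- bandwidth/2`` inclusive of boundary bins.  The fixed
    absolute bandwidth makes SM comparable across tasks of different duration
    (and hence different spectral resolution); for series shorter than
    ``1/ (bandwidth/2)`` s the band degenerates to the DF bin itself.
    """
    freqs, energy = energy_spectrum(series, fs)
    total = energy.sum()
    if total <= 0:
        return 0.0
    df = freqs[_argmax_lowest(energy)]
    half = bandwidth / 2.0
    in_band = np.abs(freqs - df) <= half + 1e-12
    return float(energy[in_band].sum() / total)


def average_rotation_energy(gyro: np.ndarray) -> float:
    """ARE ((deg/s)^2): mean squared angular-velocity magnitude over the task."""
    gyro = np.asarray(gyro, dtype=float)
    if gyro.ndim != 2 or gyro.shape[1] != 3 or len(gyro) == 0:
        raise ValueError("gyro must be a non-empty (n, 3) array")
    return float(np.mean(np.sum(gyro**2, axis=1)))


def range_angular_velocity(gyro_magnitude: np.ndarray) -> float:
    """RANG (deg/s): max minus min of the angular-velocity magnitude."""
    g = np.asarray(gyro_magnitude, dtype=float)
    if g.ndim != 1 or len(g) == 0:
        raise ValueError("gyro magnitude must be a non-empty 1-D array")
    return float(g.max() - g.min())


# ---------------------------------------------------------------------------
# wheelchair propulsion: straight/turn segmentation and arm synchrony
# ---------------------------------------------------------------------------


def swab_segment(
    series: np.ndarray,
    fs: float,
    max_error: float | None = None,
    smooth_window: float = 1.0,
    env_rate: float = 10.0,
) -> list[tuple[int, int, str]]:
    """Label a propulsion trace into ``straight`` / ``turn`` regime blocks.

    The acceleration magnitude is reduced to an activity envelope (sliding
    std over ``smooth_window`` s, sampled at ``env_rate`` Hz), segmented
    piecewise-linearly with SWAB, and each segment labeled ``straight``
    (high envelope: rhythmic pushing) or ``turn`` (low envelope).  Adjacent
    same-label segments are merged; the blocks partition the series.

    ``max_error`` is the per-segment SSE cap of the SWAB merge; the default
    scales with the envelope's short-range variability.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) == 0:
        raise ValueError("series must be a non-empty 1-D array")
    n = len(series)
    w = int(round(smooth_window * fs))
    if n <= w + 2:
        return [(0, n, "straight")]
    step = max(1, int(round(fs / env_rate)))
    centers, env = sliding_window_std(
        series, fs, window=smooth_window, overlap=smooth_window - step / fs
    )
    if env.max() - env.min() < 1e-12:
        return [(0, n, "straight")]
    if max_error is None:
        # cap ~ short-range envelope variance accumulated over a nominal
        # segment; keeps within-regime ripple merged but splits regime steps
        sigma2 = float(np.var(np.diff(env))) / 2.0
        nominal = max(10, len(env) // 8)
        max_error = max(4.0 * sigma2 * nominal, 1e-12)
    segs = _swab.swab(env, max_error)

    lo_env, hi_env = np.percentile(env, [10, 90])
    split = 0.5 * (lo_env + hi_env)
    labeled: list[tuple[int, int, str]] = []
    for s, e in segs:
        lab = "straight" if env[s:e].mean() >= split else "turn"
        # map envelope indices back to original samples via window centers
        s0 = 0 if s == 0 else int(round(centers[s] - (w - 1) / 2 + w / 2))
        e0 = n if e >= len(env) else int(round(centers[e] - (w - 1) / 2 + w / 2))
        labeled.append((s0, e0, lab))
    merged: list[tuple[int, int, str]] = []
    for s0, e0, lab in labeled:
        if merged and merged[-1][2] == lab:
            merged[-1] = (merged[-1][0], e0, lab)
        else:
            merged.append((s0, e0, lab))
    merged[0] = (0, merged[0][1], merged[0][2])
    merged[-1] = (merged[-1][0], n, merged[-1][2])
    return merged


def _push_peaks(series: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Push-phase acceleration peaks and the estimated cycle duration (s).

    The cycle duration is the median inter-peak interval (the spectral peak
    of a pulse train can sit on a harmonic, so it is not used here).
    """
    x = series - np.median(series)
    # require genuine push transients: the upper amplitude tail must stand
    # well clear of the robust noise level
    sigma = 1.4826 * np.median(np.abs(x)) + 1e-12
    p98 = np.percentile(np.abs(x), 98)
    if p98 < 5.0 * sigma:
        return np.array([], dtype=int), np.nan
    prom = 0.6 * p98
    peaks, _ = signal.find_peaks(x, prominence=prom)
    if len(peaks) < 2:
        return peaks, np.nan
    cycle = float(np.median(np.diff(peaks))) / fs
    peaks, _ = signal.find_peaks(
        x, prominence=prom, distance=max(1, int(round(0.6 * cycle * fs)))
    )
    return peaks, cycle


def arm_synchrony(
    left_magnitude: np.ndarray,
    right_magnitude: np.ndarray,
    fs: float,
    straight_segments: list[tuple[int, int]] | None = None,
) -> ArmSyncResult:
    """Normalized lag between left and right wrist push peaks.

    Push cycles are detected on the leading wrist within the straight-driving
    segments; per cycle the absolute time difference between the left and
    right acceleration peaks is normalized by the cycle duration.  The
    feature value is the mean over push phases; the release-phase lag is
    measured the same way from the secondary peak between pushes and reported
    separately as a diagnostic.

    Raises ``ValueError`` when fewer than two push cycles are found.
    """
    left = np.asarray(left_magnitude, dtype=float)
    right = np.asarray(right_magnitude, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("left and right magnitude series must be equal-length 1-D")
    if straight_segments is None:
        straight_segments = [(0, len(left))]

    push_lags: list[float] = []
    release_lags: list[float] = []
    n_cycles = 0
    cycle_est = np.nan
    for s, e in straight_segments:
        lseg, rseg = left[s:e], right[s:e]
        if len(lseg) < fs:  # need at least ~1 s of signal
            continue
        lp, lcyc = _push_peaks(lseg, fs)
        rp, _ = _push_peaks(rseg, fs)
        if len(lp) < 2 or len(rp) < 2 or not np.isfinite(lcyc):
            continue
        # leading wrist = the one whose matched peaks come first on average
        d_lr = _matched_offsets(lp, rp, int(round(0.5 * lcyc * fs)))
        if len(d_lr) == 0:
            continue
        cycle_est = lcyc
        for k in range(len(lp)):
            m = _nearest(rp, lp[k], int(round(0.5 * lcyc * fs)))
            if m is None:
                continue
            push_lags.append(abs(lp[k] - m) / fs / lcyc)
            n_cycles += 1
        # release peaks: strongest local max between consecutive pushes
        lr = _release_peaks(lseg, lp)
        rr = _release_peaks(rseg, rp)
        for k in range(len(lr)):
            m = _nearest(rr, lr[k], int(round(0.5 * lcyc * fs)))
            if m is not None:
                release_lags.append(abs(lr[k] - m) / fs / lcyc)
    if n_cycles < 2:
        raise ValueError(
            f"fewer than two push cycles detected ({n_cycles}); cannot measure synchrony"
        )
    return ArmSyncResult(
        push_lag=float(np.clip(np.mean(push_lags), 0.0, 0.5)),
        release_lag=float(np.mean(release_lags)) if release_lags else None,
        n_cycles=n_cycles,
        cycle_duration=float(cycle_est),
    )


def _nearest(candidates: np.ndarray, target: int, max_dist: int) -> int | None:
    if len(candidates) == 0:
        return None
    k = int(np.argmin(np.abs(candidates - target)))
    return int(candidates[k]) if abs(candidates[k] - target) <= max_dist else None


def _matched_offsets(a: np.ndarray, b: np.ndarray, max_dist: int) -> np.ndarray:
    out = []
    for x in a:
        m = _nearest(b, x, max_dist)
        if m is not None:
            out.append(m - x)
    return np.asarray(out)


def _release_peaks(seg: np.ndarray, push_peaks: np.ndarray) -> np.ndarray:
    """Largest secondary peak strictly between consecutive push peaks."""
    out = []
    for a, b in zip(push_peaks[:-1], push_peaks[1:]):
        lo = a + (b - a) // 4
        hi = b - (b - a) // 4
        if hi - lo < 3:
            continue
        out.append(lo + int(np.argmax(seg[lo:hi])))
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------


def detect_heel_strikes(
    foot_magnitude: np.ndarray,
    fs: float,
    strike_threshold: float = 1.8,
    swing_threshold: float = 0.15,
    refractory_s: float = 0.4,
) -> GaitEvents:
    """Heel-strike and lift-off events from one foot's acceleration magnitude.

    Heel strikes are supra-threshold impact peaks with a refractory spacing.
    After each strike the magnitude settles onto the ~1 g stance plateau;
    the lift-off is the first sample after that settling where the magnitude
    departs the plateau by more than ``swing_threshold``.

    A trace with no supra-threshold peaks yields empty events, not an error.
    """
    mag = np.asarray(foot_magnitude, dtype=float)
    if mag.ndim != 1 or len(mag) == 0:
        raise ValueError("foot magnitude must be a non-empty 1-D array")
    strikes, _ = signal.find_peaks(
        mag, height=strike_threshold, distance=max(1, int(round(refractory_s * fs)))
    )
    if len(strikes) == 0:
        return GaitEvents(heel_strikes=np.array([], int), lift_offs=np.array([], int))

    lift_offs = []
    settle = max(1, int(round(0.05 * fs)))  # require 50 ms on the plateau
    for i, s in enumerate(strikes):
        end = strikes[i + 1] if i + 1 < len(strikes) else len(mag)
        dev = np.abs(mag[s:end] - 1.0) > swing_threshold
        # find the first settled plateau run after the impact transient
        j = s
        run = 0
        plateau_start = None
        for k in range(s, end):
            run = run + 1 if not dev[k - s] else 0
            if run >= settle:
                plateau_start = k
                break
        if plateau_start is None:
            continue
        off = np.flatnonzero(dev[plateau_start - s :])
        if len(off) == 0:
            continue
        j = plateau_start + off[0]
        if j < end:
            lift_offs.append(int(j))
    return GaitEvents(
        heel_strikes=np.asarray(strikes, int), lift_offs=np.asarray(lift_offs, int)
    )


def gait_durations(
    events_left: GaitEvents, events_right: GaitEvents, fs: float
) -> dict[str, float]:
    """Average step/stance durations and their right/left ratios.

    Step duration is the time between two consecutive heel strikes of the
    same foot; stance duration runs from a heel strike to the following
    lift-off of that foot.  Averages pool both feet; ratios divide the right
    foot's per-foot mean by the left's.
    """
    per_foot: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, ev in (("left", events_left), ("right", events_right)):
        if ev.n_strikes < 2:
            raise ValueError(
                f"{name} foot has {ev.n_strikes} heel strikes; need at least 2"
            )
        steps = np.diff(ev.heel_strikes) / fs
        stances = []
        for k, s in enumerate(ev.heel_strikes):
            nxt = ev.heel_strikes[k + 1] if k + 1 < ev.n_strikes else np.inf
            los = ev.lift_offs[(ev.lift_offs > s) & (ev.lift_offs < nxt)]
            if len(los):
                stances.append((los[0] - s) / fs)
        if not stances:
            raise ValueError(f"{name} foot has no stance (strike -> lift-off) events")
        per_foot[name] = (steps, np.asarray(stances))

    step_l, stance_l = per_foot["left"]
    step_r, stance_r = per_foot["right"]
    return {
        "T_step_avg": float(np.mean(np.concatenate([step_l, step_r]))),
        "T_step_ratio": float(np.mean(step_r) / np.mean(step_l)),
        "T_stance_avg": float(np.mean(np.concatenate([stance_l, stance_r]))),
        "T_stance_ratio": float(np.mean(stance_r) / np.mean(stance_l)),
    }


# ---------------------------------------------------------------------------
# task-level dispatch
# ---------------------------------------------------------------------------


def _filtered(trace: IMUTrace, cfg: FeatureConfig) -> IMUTrace:
    if cfg.lowpass_cutoff is None:
        return trace
    acc = np.column_stack(
        [lowpass(trace.accel[:, k], trace.sample_rate, cfg.lowpass_cutoff) for k in range(3)]
    )
    gyr = np.column_stack(
        [lowpass(trace.gyro[:, k], trace.sample_rate, cfg.lowpass_cutoff) for k in range(3)]
    )
    return IMUTrace(trace.sample_rate, trace.placement, acc, gyr)


def _base_feature_block(trace: IMUTrace, cfg: FeatureConfig, meta: dict) -> dict[str, float]:
    fs = trace.sample_rate
    acc_mag = magnitude(trace, "accel")
    gyro_mag = magnitude(trace, "gyro")
    mi = movement_interval(
        acc_mag, fs, cfg.time_window, cfg.time_overlap, cfg.time_threshold
    )
    if mi is None:
        meta["no_movement"] = True
        time_s = 0.0
    else:
        time_s = mi.time_s
    if trace.duration < 5.0:
        meta["sm_lowres"] = True  # spectral resolution coarser than the SM band
    return {
        "TIME": time_s,
        "MI": movement_intensity(trace.accel),
        "MIV": movement_intensity_variation(trace.accel),
        "DF": dominant_frequency(acc_mag, fs),
        "SM": smoothness(acc_mag, fs),
        "ARE": average_rotation_energy(trace.gyro),
        "RANG": range_angular_velocity(gyro_mag),
    }


def _require(session: SessionRecording, placement: Placement, task: TaskClass) -> IMUTrace:
    if placement not in session.traces:
        raise KeyError(
            f"task {task.value} requires the {placement.value} sensor, "
            f"which is missing from the session"
        )
    return session.traces[placement]


def extract_task_features(
    session: SessionRecording,
    segment: TaskSegment,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Assemble the task-class-specific feature vector for one task segment.

    Single-hand tasks: 7 features from the performing wrist.  Bimanual: a
    left then a right wrist block (14).  Gait tasks: 7 hip features plus 4
    step/stance features from the feet (level walking) or upper legs
    (stairs), 11 total.  Wheelchair: 7 hip features plus ArmSync from both
    wrists (8).
    """
    cfg = config or FeatureConfig()
    task = segment.task_class
    meta: dict = {}

    def sub(placement: Placement) -> IMUTrace:
        return _filtered(
            _require(session, placement, task).slice(segment.start, segment.end), cfg
        )

    if task in SINGLE_HAND_TASKS:
        wrist = Placement.WRIST_L if segment.side == Side.LEFT else Placement.WRIST_R
        values = _base_feature_block(sub(wrist), cfg, meta)
    elif task in BIMANUAL_TASKS:
        left = _base_feature_block(sub(Placement.WRIST_L), cfg, meta)
        right = _base_feature_block(sub(Placement.WRIST_R), cfg, meta)
        values = {f"{k}_L": v for k, v in left.items()}
        values.update({f"{k}_R": v for k, v in right.items()})
    elif task in GAIT_TASKS:
        values = _base_feature_block(sub(Placement.HIP), cfg, meta)
        if task == TaskClass.TUG_WALK:
            pl_l, pl_r = Placement.FOOT_L, Placement.FOOT_R
        else:  # stairs: the same step/stance machinery on the upper-leg sensors
            pl_l, pl_r = Placement.UPPER_LEG_L, Placement.UPPER_LEG_R
        ev = {}
        for name, pl in (("left", pl_l), ("right", pl_r)):
            tr = sub(pl)
            ev[name] = detect_heel_strikes(
                magnitude(tr, "accel"),
                tr.sample_rate,
                cfg.strike_threshold,
                cfg.swing_threshold,
                cfg.strike_refractory,
            )
        values.update(gait_durations(ev["left"], ev["right"], session.sample_rate))
    elif task in WHEELCHAIR_TASKS:
        values = _base_feature_block(sub(Placement.HIP), cfg, meta)
        lmag = magnitude(sub(Placement.WRIST_L), "accel")
        rmag = magnitude(sub(Placement.WRIST_R), "accel")
        fs = session.sample_rate
        blocks = swab_segment(
            0.5 * (lmag + rmag), fs, cfg.swab_max_error, cfg.swab_smooth_window
        )
        straight = [(s, e) for s, e, lab in blocks if lab == "straight"]
        sync = arm_synchrony(lmag, rmag, fs, straight)
        values["ArmSync"] = sync.push_lag
        meta["release_lag"] = sync.release_lag
        meta["n_push_cycles"] = sync.n_cycles
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unsupported task class {task!r}")

    return FeatureVector(task_class=task, side=segment.side, values=values, meta=meta)
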