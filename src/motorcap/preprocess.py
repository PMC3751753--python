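"""Signal conditioning and automatic task labeling.

Raw multi-sensor recordings are reduced to orientation-invariant magnitude
series (so that sensor displacement between or within sessions does not
matter), low-pass filtered, and cut into task segments using the rotation
bursts of a dedicated labeling sensor: the experiment leader marks each task
start with a fast single rotation and each task end with a double rotation
about the labeler's x-axis.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import IMUTrace, Placement

__all__ = [
    "magnitude",
    "lowpass",
    "detect_task_boundaries",
    "detect_sync_clap",
    "BoundaryDetectionError",
]

#: Placements excluded from feature extraction: upper-arm sensors add no
#: information beyond the wrists and are dropped by default.
EXCLUDED_PLACEMENTS = frozenset({Placement.OTHER})


class BoundaryDetectionError(RuntimeError):
    """Task start/end bursts could not be paired up."""


def magnitude(trace: IMUTrace, channel: str = "accel") -> np.ndarray:
    """Per-sample Euclidean norm of a trace's 3-axis channel.

    Parameters
    ----------
    trace : IMUTrace
    channel : {"accel", "gyro"}
        Which 3-axis stream to reduce; result is in g or deg/s accordingly.

    The norm is invariant to any fixed rotation of the sensor axes, which is
    what makes the downstream features robust to sensor (re)placement.
    """
    if channel == "accel":
        data = trace.accel
    elif channel == "gyro":
        data = trace.gyro
    else:
        raise ValueError(f"channel must be 'accel' or 'gyro', got {channel!r}")
    return np.linalg.norm(data, axis=1)


def lowpass(series: np.ndarray, fs: float, cutoff: float = 45.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter with unit DC gain.

    ``cutoff`` must lie strictly below the Nyquist frequency ``fs / 2``; the
    default 45 Hz at 100 Hz sampling suppresses only the topmost band, so the
    filter is nearly a pass-through for movement signals (a few Hz).
    Zero-phase filtering (forward-backward) keeps detected event times from
    shifting.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if not 0 < cutoff < fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff}"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, series)


def _find_bursts(
    gyro_x_abs: np.ndarray,
    fs: float,
    threshold_mad_mult: float,
    refractory_s: float,
    min_threshold: float,
) -> np.ndarray:
    """Supra-threshold rotation bursts: peak sample indices, refractory-spaced."""
    med = np.median(gyro_x_abs)
    mad = np.median(np.abs(gyro_x_abs - med))
    threshold = max(med + threshold_mad_mult * mad, min_threshold)
    peaks, _ = signal.find_peaks(
        gyro_x_abs, height=threshold, distance=max(1, int(round(refractory_s * fs)))
    )
    return peaks


def detect_task_boundaries(
    labeler_trace: IMUTrace,
    threshold_mad_mult: float = 6.0,
    refractory_s: float = 0.25,
    double_burst_window_s: float = 1.0,
    min_threshold: float = 50.0,
) -> list[tuple[int, int]]:
    """Recover task intervals from the labeling sensor's rotation bursts.

    A task start is marked by one sharp rotation burst, the end by two bursts
    in quick succession. Bursts are found on ``|gyro_x|`` above a robust
    threshold (median + ``threshold_mad_mult`` * MAD, floored at
    ``min_threshold`` deg/s); bursts closer than ``double_burst_window_s``
    are grouped into one event, whose multiplicity decides start vs end.

    Returns sorted, non-overlapping half-open sample intervals.

    Raises
    ------
    BoundaryDetectionError
        If events cannot be paired start-end-start-end..., listing orphan
        event times.
    """
    if labeler_trace.placement != Placement.LABELER:
        raise ValueError(
            f"boundary detection requires the labeler trace, got placement "
            f"{labeler_trace.placement.value}"
        )
    fs = labeler_trace.sample_rate
    gx = np.abs(labeler_trace.gyro[:, 0])
    peaks = _find_bursts(gx, fs, threshold_mad_mult, refractory_s, min_threshold)
    if len(peaks) == 0:
        return []

    # group peaks separated by < double_burst_window_s into one event
    events: list[tuple[int, int]] = []  # (first peak sample, multiplicity)
    group = [peaks[0]]
    gap = double_burst_window_s * fs
    for p in peaks[1:]:
        if p - group[-1] < gap:
            group.append(p)
        else:
            events.append((group[0], len(group)))
            group = [p]
    events.append((group[0], len(group)))

    intervals: list[tuple[int, int]] = []
    open_start: int | None = None
    orphans: list[float] = []
    for sample, mult in events:
        is_start = mult == 1
        if is_start:
            if open_start is not None:
                orphans.append(open_start / fs)
            open_start = sample
        else:
            if open_start is None:
                orphans.append(sample / fs)
            else:
                intervals.append((open_start, sample))
                open_start = None
    if open_start is not None:
        orphans.append(open_start / fs)
    if orphans:
        raise BoundaryDetectionError(
            "unpaired start/end rotation bursts at t = "
            + ", ".join(f"{t:.2f} s" for t in orphans)
        )
    return intervals


def detect_sync_clap(
    accel_magnitude: np.ndarray, fs: float, threshold: float = 2.5
) -> int:
    """Sample index of the synchronization clap.

    The calibration pose ends with a hand clap that shows up as the single
    largest acceleration transient; returns the index of the largest sample
    above ``threshold`` (g).

    Raises
    ------
    ValueError
        "no clap found" when no sample exceeds the threshold.
    """
    series = np.asarray(accel_magnitude, dtype=float)
    if series.ndim != 1 or len(series) == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if series.max() <= threshold:
        raise ValueError(f"no clap found: no sample above {threshold} g")
    return int(np.argmax(series))
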