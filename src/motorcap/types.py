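"""Core data containers shared across the pipeline.

Units are fixed throughout the package: acceleration in g, angular velocity
in deg/s, time in seconds, sample indices 0-based, intervals half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Placement",
    "TaskClass",
    "Side",
    "IMUTrace",
    "TaskSegment",
    "SessionRecording",
    "FeatureVector",
    "RatedInstance",
    "GaitEvents",
    "GroundTruth",
    "ImpairmentProfile",
    "SINGLE_HAND_TASKS",
    "BIMANUAL_TASKS",
    "GAIT_TASKS",
    "WHEELCHAIR_TASKS",
    "BASE_FEATURES",
    "GAIT_FEATURES",
    "feature_layout",
]


class Placement(str, Enum):
    """Body location of a sensor unit."""

    WRIST_L = "wrist_L"
    WRIST_R = "wrist_R"
    HIP = "hip"
    FOOT_L = "foot_L"
    FOOT_R = "foot_R"
    UPPER_LEG_L = "upper_leg_L"
    UPPER_LEG_R = "upper_leg_R"
    TRUNK = "trunk"
    LABELER = "labeler"
    OTHER = "other"


class TaskClass(str, Enum):
    """Standardized assessment tasks."""

    CARDS = "cards"
    SMALL_OBJECTS = "small_objects"
    DOMINOS = "dominos"
    BIG_OBJECTS = "big_objects"
    BOTTLE = "bottle"
    KEY = "key"
    NHPT = "nhpt"
    BALL = "ball"
    TUG_WALK = "tug_walk"
    TUG_WHEELCHAIR = "tug_wheelchair"
    STAIRS_UP = "stairs_up"
    STAIRS_DOWN = "stairs_down"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"
    NA = "n/a"


#: Tasks performed with one hand; features come from the performing wrist.
SINGLE_HAND_TASKS = frozenset(
    {
        TaskClass.CARDS,
        TaskClass.SMALL_OBJECTS,
        TaskClass.DOMINOS,
        TaskClass.BOTTLE,
        TaskClass.KEY,
        TaskClass.NHPT,
    }
)
#: Tasks performed with both hands; features from both wrists.
BIMANUAL_TASKS = frozenset({TaskClass.BIG_OBJECTS, TaskClass.BALL})
#: Locomotion tasks scored with hip features plus step/stance asymmetry.
GAIT_TASKS = frozenset({TaskClass.TUG_WALK, TaskClass.STAIRS_UP, TaskClass.STAIRS_DOWN})
#: Wheelchair propulsion: hip features plus bilateral arm synchrony.
WHEELCHAIR_TASKS = frozenset({TaskClass.TUG_WHEELCHAIR})

#: The seven per-sensor movement features, in canonical order.
BASE_FEATURES = ("TIME", "MI", "MIV", "DF", "SM", "ARE", "RANG")
#: Step/stance features appended for gait tasks.
GAIT_FEATURES = ("T_step_avg", "T_step_ratio", "T_stance_avg", "T_stance_ratio")


def feature_layout(task_class: TaskClass) -> tuple[str, ...]:
    """Ordered feature names for a task class.

    Single-hand tasks carry the 7 base features of the performing wrist;
    bimanual tasks a left block then a right block (14); gait tasks the 7
    hip features plus 4 step/stance features (11); wheelchair the 7 hip
    features plus ArmSync (8).
    """
    task_class = TaskClass(task_class)
    if task_class in SINGLE_HAND_TASKS:
        return BASE_FEATURES
    if task_class in BIMANUAL_TASKS:
        return tuple(f"{n}_L" for n in BASE_FEATURES) + tuple(
            f"{n}_R" for n in BASE_FEATURES
        )
    if task_class in GAIT_TASKS:
        return BASE_FEATURES + GAIT_FEATURES
    if task_class in WHEELCHAIR_TASKS:
        return BASE_FEATURES + ("ArmSync",)
    raise ValueError(f"no feature layout for task class {task_class!r}")


@dataclass
class IMUTrace:
    """One sensor's stream of 3-axis acceleration (g) and angular velocity (deg/s)."""

    sample_rate: float
    placement: Placement
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        for name, arr in (("accel", self.accel), ("gyro", self.gyro)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must have shape (n, 3), got {arr.shape}")
        if len(self.accel) != len(self.gyro):
            raise ValueError(
                f"accel ({len(self.accel)}) and gyro ({len(self.gyro)}) lengths differ"
            )
        if len(self.accel) == 0:
            raise ValueError("trace must contain at least one sample")
        if not (np.isfinite(self.accel).all() and np.isfinite(self.gyro).all()):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.accel)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sample_rate

    def slice(self, start: int, end: int) -> "IMUTrace":
        """Sub-trace over sample interval ``[start, end)``."""
        if not (0 <= start < end <= self.n_samples):
            raise ValueError(
                f"invalid slice [{start}, {end}) for trace of {self.n_samples} samples"
            )
        return IMUTrace(
            sample_rate=self.sample_rate,
            placement=self.placement,
            accel=self.accel[start:end],
            gyro=self.gyro[start:end],
        )


@dataclass
class TaskSegment:
    """A labeled half-open sample interval ``[start, end)`` within a session."""

    task_class: TaskClass
    side: Side
    start: int
    end: int

    def __post_init__(self) -> None:
        self.task_class = TaskClass(self.task_class)
        self.side = Side(self.side)
        if self.start >= self.end:
            raise ValueError(
                f"segment start ({self.start}) must precede end ({self.end})"
            )
        if self.task_class in SINGLE_HAND_TASKS and self.side not in (
            Side.LEFT,
            Side.RIGHT,
        ):
            raise ValueError(
                f"single-handed task {self.task_class.value} requires side left/right, "
                f"got {self.side.value}"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class SessionRecording:
    """All sensor traces and task segments of one weekly assessment."""

    subject_id: str
    week: int
    traces: dict[Placement, IMUTrace]
    segments: list[TaskSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.week < 1:
            raise ValueError(f"week must be >= 1, got {self.week}")
        self.traces = {Placement(k): v for k, v in self.traces.items()}
        lengths = {p: t.n_samples for p, t in self.traces.items()}
        rates = {t.sample_rate for t in self.traces.values()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"trace lengths differ across sensors: {lengths}")
        if len(rates) > 1:
            raise ValueError(f"sample rates differ across sensors: {sorted(rates)}")
        n = self.n_samples
        for seg in self.segments:
            if seg.end > n:
                raise ValueError(
                    f"segment [{seg.start}, {seg.end}) exceeds trace length {n}"
                )

    @property
    def n_samples(self) -> int:
        return next(iter(self.traces.values())).n_samples if self.traces else 0

    @property
    def sample_rate(self) -> float:
        return next(iter(self.traces.values())).sample_rate

    @property
    def session_key(self) -> tuple[str, int]:
        return (self.subject_id, self.week)


@dataclass
class FeatureVector:
    """Named per-task features laid out per :func:`feature_layout`."""

    task_class: TaskClass
    side: Side
    values: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.task_class = TaskClass(self.task_class)
        self.side = Side(self.side)
        layout = feature_layout(self.task_class)
        if tuple(self.values.keys()) != layout:
            raise ValueError(
                f"feature names {tuple(self.values)} do not match the "
                f"{self.task_class.value} layout {layout}"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values.keys())

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


@dataclass
class RatedInstance:
    """One task execution: features plus the normalized expert rating in [0, 1]."""

    subject_id: str
    week: int
    task_class: TaskClass
    side: Side
    features: FeatureVector
    target: float

    def __post_init__(self) -> None:
        self.task_class = TaskClass(self.task_class)
        self.side = Side(self.side)
        if not 0.0 <= self.target <= 1.0:
            raise ValueError(f"target must lie in [0, 1], got {self.target}")

    @property
    def session_key(self) -> tuple[str, int]:
        return (self.subject_id, self.week)


@dataclass
class GaitEvents:
    """Heel-strike and lift-off sample indices of one foot."""

    heel_strikes: np.ndarray
    lift_offs: np.ndarray

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.lift_offs = np.asarray(self.lift_offs, dtype=int)
        if np.any(np.diff(self.heel_strikes) <= 0):
            raise ValueError("heel strikes must be strictly increasing")
        if np.any(np.diff(self.lift_offs) <= 0):
            raise ValueError("lift-offs must be strictly increasing")
        # each lift-off must fall between consecutive strikes of the same foot
        for lo in self.lift_offs:
            k = np.searchsorted(self.heel_strikes, lo)
            if k == 0:
                raise ValueError(f"lift-off at {lo} precedes the first heel strike")

    @property
    def n_strikes(self) -> int:
        return len(self.heel_strikes)


@dataclass
class GroundTruth:
    """Known event structure of a simulated trace, used for recovery tests."""

    active_interval: tuple[int, int] | None = None
    cycle_freq: float | None = None
    heel_strike_times: dict[str, np.ndarray] = field(default_factory=dict)
    stance_durations: dict[str, np.ndarray] = field(default_factory=dict)
    step_durations: dict[str, np.ndarray] = field(default_factory=dict)
    push_cycle_lag: float | None = None
    segment_breakpoints: tuple[int, ...] = ()
    true_rating: float | None = None
    true_features: dict[str, float] = field(default_factory=dict)


@dataclass
class ImpairmentProfile:
    """Latent impairment driving the synthetic signal statistics.

    ``level`` is dimensionless in [0, 1] (0 = unimpaired); ``week_trend`` is
    the per-week decrement of the level, emulating recovery over weeks.
    """

    level: float = 0.0
    side_affected: str = "none"
    week_trend: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"level must lie in [0, 1], got {self.level}")
        if self.week_trend < 0:
            raise ValueError(f"week_trend must be >= 0, got {self.week_trend}")
        if self.side_affected not in ("left", "right", "none"):
            raise ValueError(f"side_affected must be left/right/none, got {self.side_affected}")

    def level_at(self, week: int) -> float:
        """Impairment level at a given week (week 1 = ``level``), clamped to [0, 1]."""
        if week < 1:
            raise ValueError(f"week must be >= 1, got {week}")
        return float(np.clip(self.level - self.week_trend * (week - 1), 0.0, 1.0))

    def level_for(self, side: Side, week: int) -> float:
        """Effective level for a body side: affected side carries the full level."""
        lvl = self.level_at(week)
        if self.side_affected == "none":
            return lvl
        affected = Side.LEFT if self.side_affected == "left" else Side.RIGHT
        return lvl if side == affected else 0.15 * lvl
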