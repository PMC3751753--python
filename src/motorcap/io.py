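"""Reading and writing sessions, segments, and feature tables.

On-disk layout of a session directory::

    <dir>/
      manifest.yaml        subject, week, sample rate, sensor files, tasks
      <placement>.csv      one file per sensor: time_s, ax_g, ay_g, az_g,
                           gx_dps, gy_dps, gz_dps
      ground_truth.json    optional simulation sidecar

All files are plain delimited / structured text; floats are written with
repr-level precision so a re-run with the same seed produces byte-identical
output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    FeatureVector,
    IMUTrace,
    Placement,
    RatedInstance,
    SessionRecording,
    Side,
    TaskClass,
    TaskSegment,
    feature_layout,
)

__all__ = [
    "write_session",
    "read_session",
    "read_manifest",
    "write_segments",
    "read_segments",
    "write_feature_table",
    "read_feature_table",
]

_TRACE_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]
_FLOAT_FMT = "%.10g"


def write_session(
    recording: SessionRecording,
    out_dir: str | Path,
    ratings: dict[int, float] | None = None,
    ground_truth: list[dict] | None = None,
) -> Path:
    """Write a session directory; returns the manifest path.

    ``ratings`` maps segment index -> normalized expert rating and is stored
    with the task list in the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = recording.sample_rate
    for placement, trace in sorted(recording.traces.items(), key=lambda kv: kv[0].value):
        t = np.arange(trace.n_samples) / fs
        df = pd.DataFrame(
            np.column_stack([t, trace.accel, trace.gyro]), columns=_TRACE_COLUMNS
        )
        df.to_csv(out_dir / f"{placement.value}.csv", index=False, float_format=_FLOAT_FMT)
    tasks = []
    for i, seg in enumerate(recording.segments):
        entry = {
            "task_class": seg.task_class.value,
            "side": seg.side.value,
            "start_s": round(seg.start / fs, 6),
            "end_s": round(seg.end / fs, 6),
        }
        if ratings is not None and i in ratings:
            entry["rating"] = round(float(ratings[i]), 10)
        tasks.append(entry)
    manifest = {
        "subject_id": recording.subject_id,
        "week": int(recording.week),
        "sample_rate": float(fs),
        "traces": {
            p.value: f"{p.value}.csv"
            for p in sorted(recording.traces, key=lambda p: p.value)
        },
        "tasks": tasks,
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    if ground_truth is not None:
        (out_dir / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=1, sort_keys=True)
        )
    return manifest_path


def read_manifest(manifest_path: str | Path) -> dict:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("subject_id", "week", "sample_rate", "traces"):
        if key not in manifest:
            raise ValueError(f"manifest {manifest_path} is missing key {key!r}")
    return manifest


def _read_trace(path: Path, fs: float, placement: Placement) -> IMUTrace:
    if not path.exists():
        raise FileNotFoundError(
            f"trace file for placement {placement.value} not found: {path}"
        )
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing columns {missing}")
    data = df[_TRACE_COLUMNS[1:]].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(data).all(axis=1))
    if len(bad):
        raise ValueError(
            f"{path} contains non-finite values at row index {int(bad[0])}"
            + (f" (+{len(bad) - 1} more)" if len(bad) > 1 else "")
        )
    return IMUTrace(
        sample_rate=fs, placement=placement, accel=data[:, :3], gyro=data[:, 3:]
    )


def read_session(manifest_path: str | Path) -> SessionRecording:
    """Load and validate a session directory written by :func:`write_session`."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    fs = float(manifest["sample_rate"])
    base = manifest_path.parent
    traces: dict[Placement, IMUTrace] = {}
    for name, fname in manifest["traces"].items():
        try:
            placement = Placement(name)
        except ValueError:
            raise ValueError(f"unknown sensor placement {name!r} in {manifest_path}")
        traces[placement] = _read_trace(base / fname, fs, placement)
    segments = []
    for entry in manifest.get("tasks", []):
        if "start_s" in entry and "end_s" in entry:
            segments.append(
                TaskSegment(
                    task_class=TaskClass(entry["task_class"]),
                    side=Side(entry["side"]),
                    start=int(round(entry["start_s"] * fs)),
                    end=int(round(entry["end_s"] * fs)),
                )
            )
    return SessionRecording(
        subject_id=str(manifest["subject_id"]),
        week=int(manifest["week"]),
        traces=traces,
        segments=segments,
    )


def write_segments(segments: list[TaskSegment], fs: float, path: str | Path) -> None:
    """Segments table: task_class, side, start_s, end_s (CSV)."""
    rows = [
        {
            "task_class": s.task_class.value,
            "side": s.side.value,
            "start_s": s.start / fs,
            "end_s": s.end / fs,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=["task_class", "side", "start_s", "end_s"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_segments(path: str | Path, fs: float) -> list[TaskSegment]:
    # keep_default_na: the side column legitimately holds the string "n/a"
    df = pd.read_csv(path, keep_default_na=False)
    return [
        TaskSegment(
            task_class=TaskClass(r.task_class),
            side=Side(r.side),
            start=int(round(r.start_s * fs)),
            end=int(round(r.end_s * fs)),
        )
        for r in df.itertuples()
    ]


def write_feature_table(instances: list[RatedInstance], path: str | Path) -> None:
    """One row per task instance: ids, target, then named features (CSV)."""
    rows = []
    for inst in instances:
        row = {
            "subject_id": inst.subject_id,
            "week": inst.week,
            "task_class": inst.task_class.value,
            "side": inst.side.value,
            "target": inst.target,
        }
        row.update(inst.features.values)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path) -> list[RatedInstance]:
    df = pd.read_csv(path, keep_default_na=False)
    instances = []
    for _, row in df.iterrows():
        task_class = TaskClass(row["task_class"])
        names = feature_layout(task_class)
        fv = FeatureVector(
            task_class=task_class,
            side=Side(row["side"]),
            values={n: float(row[n]) for n in names},
        )
        instances.append(
            RatedInstance(
                subject_id=str(row["subject_id"]),
                week=int(row["week"]),
                task_class=task_class,
                side=Side(row["side"]),
                features=fv,
                target=float(row["target"]),
            )
        )
    return instances
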