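"""End-to-end orchestration: simulate -> preprocess -> extract -> fit -> report.

Every stage reads and writes plain-text files under one output directory, so
partial re-runs (e.g. extraction on existing traces) reproduce the full
run's corresponding outputs.  All randomness derives from the config seed;
re-running with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .features import FeatureConfig, extract_task_features
from .preprocess import detect_task_boundaries
from .regress import loso_cv, pooled_generalization
from .synth import default_task_list, simulate_session
from .types import ImpairmentProfile, RatedInstance, TaskClass

__all__ = ["PipelineConfig", "run_pipeline", "simulate_stage", "preprocess_stage",
           "extract_stage", "fit_stage"]

log = logging.getLogger("motorcap")


@dataclass
class PipelineConfig:
    """Declarative configuration of the demo pipeline.

    Every analysis threshold that the method leaves open lives here with its
    default, so the choices are visible and overridable in one place.
    """

    out_dir: str = "motorcap_run"
    n_subjects: int = 4
    weeks: int = 4
    sample_rate: float = 100.0
    seed: int = 0
    rating_noise_sd: float = 0.02
    alpha: float = 0.05
    gate_scope: str = "fold"  # 'dataset' reproduces whole-dataset selection
    selection: str = "backward"  # stepwise elimination; 'single' = one-shot gate
    include_locomotion: bool = True
    # below this residual dof in a training fold, feature selection moves
    # from per-fold to whole-dataset
    min_fold_gate_dof: int = 8
    impairment_levels: tuple[float, ...] | None = None  # default: spread over subjects
    week_trend: float = 0.06
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.features.lowpass_cutoff is not None and not (
            0 < self.features.lowpass_cutoff < self.sample_rate / 2
        ):
            raise ValueError(
                f"lowpass cutoff {self.features.lowpass_cutoff} Hz must lie below "
                f"the Nyquist frequency {self.sample_rate / 2} Hz"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_subjects < 1 or self.weeks < 1:
            raise ValueError("n_subjects and weeks must be >= 1")
        if self.gate_scope not in ("fold", "dataset"):
            raise ValueError("gate_scope must be 'fold' or 'dataset'")
        if self.selection not in ("single", "backward"):
            raise ValueError("selection must be 'single' or 'backward'")


def _profiles(cfg: PipelineConfig) -> dict[str, ImpairmentProfile]:
    if cfg.impairment_levels is None:
        levels = np.linspace(0.15, 0.85, cfg.n_subjects)
    else:
        levels = list(cfg.impairment_levels)
        if len(levels) != cfg.n_subjects:
            raise ValueError("impairment_levels length must equal n_subjects")
    sides = ["left", "right"]
    return {
        f"S{i + 1:02d}": ImpairmentProfile(
            level=float(levels[i]), side_affected=sides[i % 2], week_trend=cfg.week_trend
        )
        for i in range(cfg.n_subjects)
    }


def simulate_stage(cfg: PipelineConfig) -> list[Path]:
    """Generate and write all sessions; returns the manifest paths."""
    cfg.validate()
    out = Path(cfg.out_dir) / "sessions"
    task_list = default_task_list(include_locomotion=cfg.include_locomotion)
    manifests = []
    for subject_id, profile in _profiles(cfg).items():
        for week in range(1, cfg.weeks + 1):
            result = simulate_session(
                profile,
                week=week,
                task_list=task_list,
                rating_noise_sd=cfg.rating_noise_sd,
                seed=cfg.seed,
                fs=cfg.sample_rate,
                subject_id=subject_id,
                feature_config=cfg.features,
            )
            ratings = {i: inst.target for i, inst in enumerate(result.instances)}
            sdir = out / f"{subject_id}_w{week}"
            manifests.append(
                mio.write_session(result.recording, sdir, ratings=ratings)
            )
            log.info("simulated %s week %d -> %s", subject_id, week, sdir)
    return manifests


def preprocess_stage(cfg: PipelineConfig, manifests: list[Path] | None = None) -> list[Path]:
    """Detect task boundaries from the labeling sensor and write segment tables.

    Detected intervals are paired in order with the manifest's task list;
    a count mismatch is an error naming the session.
    """
    cfg.validate()
    if manifests is None:
        manifests = sorted(Path(cfg.out_dir).glob("sessions/*/manifest.yaml"))
    from .types import Placement, TaskSegment, Side

    seg_paths = []
    for mpath in manifests:
        recording = mio.read_session(mpath)
        manifest = mio.read_manifest(mpath)
        labeler = recording.traces.get(Placement.LABELER)
        if labeler is None:
            raise ValueError(f"session {mpath.parent.name} has no labeling sensor")
        intervals = detect_task_boundaries(labeler)
        tasks = manifest.get("tasks", [])
        if len(intervals) != len(tasks):
            raise ValueError(
                f"session {mpath.parent.name}: detected {len(intervals)} task "
                f"intervals but the manifest lists {len(tasks)} tasks"
            )
        segments = [
            TaskSegment(
                task_class=TaskClass(task["task_class"]),
                side=Side(task["side"]),
                start=s,
                end=e,
            )
            for task, (s, e) in zip(tasks, intervals)
        ]
        spath = mpath.parent / "segments.csv"
        mio.write_segments(segments, recording.sample_rate, spath)
        seg_paths.append(spath)
        log.info("labeled %d segments in %s", len(segments), mpath.parent.name)
    return seg_paths


def extract_stage(cfg: PipelineConfig, manifests: list[Path] | None = None) -> Path:
    """Compute feature vectors for every detected segment; write the feature table."""
    cfg.validate()
    if manifests is None:
        manifests = sorted(Path(cfg.out_dir).glob("sessions/*/manifest.yaml"))
    instances: list[RatedInstance] = []
    for mpath in manifests:
        recording = mio.read_session(mpath)
        manifest = mio.read_manifest(mpath)
        seg_path = mpath.parent / "segments.csv"
        segments = (
            mio.read_segments(seg_path, recording.sample_rate)
            if seg_path.exists()
            else recording.segments
        )
        tasks = manifest.get("tasks", [])
        if len(tasks) != len(segments):
            raise ValueError(
                f"session {mpath.parent.name}: {len(segments)} segments vs "
                f"{len(tasks)} manifest tasks"
            )
        for seg, task in zip(segments, tasks):
            if "rating" not in task:
                raise ValueError(
                    f"session {mpath.parent.name}: task {task['task_class']} has no rating"
                )
            fv = extract_task_features(recording, seg, cfg.features)
            instances.append(
                RatedInstance(
                    subject_id=recording.subject_id,
                    week=recording.week,
                    task_class=seg.task_class,
                    side=seg.side,
                    features=fv,
                    target=float(task["rating"]),
                )
            )
    fpath = Path(cfg.out_dir) / "features.csv"
    mio.write_feature_table(instances, fpath)
    log.info("wrote %d feature rows to %s", len(instances), fpath)
    return fpath


def fit_stage(cfg: PipelineConfig, feature_table: Path | None = None) -> Path:
    """LOSO-evaluate one gated linear model per task class; write results JSON."""
    cfg.validate()
    if feature_table is None:
        feature_table = Path(cfg.out_dir) / "features.csv"
    instances = mio.read_feature_table(feature_table)
    results = {}
    for tc in TaskClass:
        sub = [i for i in instances if i.task_class == tc]
        if not sub:
            continue
        n_sessions = len({i.session_key for i in sub})
        n_feat = len(sub[0].features.names)
        if n_sessions < 3 or len(sub) <= n_feat + 1:
            results[tc.value] = {
                "skipped": f"insufficient data: {n_sessions} sessions, {len(sub)} instances"
            }
            continue
        # per-fold significance gating needs residual degrees of freedom to
        # spare; on small tasks select features once on the whole dataset
        from collections import Counter

        max_fold = max(Counter(i.session_key for i in sub).values())
        scope = cfg.gate_scope
        if len(sub) - max_fold - n_feat - 1 < cfg.min_fold_gate_dof:
            scope = "dataset"
        res = loso_cv(
            sub, task_class=tc, alpha=cfg.alpha, gate_scope=scope,
            selection=cfg.selection,
        )
        results[tc.value] = res.to_dict()
        results[tc.value]["gate_scope"] = scope
        log.info("task %s: rmse=%.4f r=%s", tc.value, res.rmse, f"{res.r:.3f}")

    pooled = pooled_generalization(instances)
    out = {
        "results": results,
        "pooled_single_hand": pooled.to_dict(orient="records"),
        "config": _config_dict(cfg),
    }
    rpath = Path(cfg.out_dir) / "results.json"
    rpath.write_text(json.dumps(out, indent=1, sort_keys=True))
    return rpath


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["impairment_levels"] = (
        None if cfg.impairment_levels is None else list(cfg.impairment_levels)
    )
    return d


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Full run; returns the results path.  Deterministic under a fixed seed."""
    cfg.validate()
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    manifests = simulate_stage(cfg)
    preprocess_stage(cfg, manifests)
    extract_stage(cfg, manifests)
    rpath = fit_stage(cfg)
    (Path(cfg.out_dir) / "run_config.json").write_text(
        json.dumps(_config_dict(cfg), indent=1, sort_keys=True)
    )
    return rpath
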