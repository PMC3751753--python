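import numpy as np
import pytest

from motorcap.types import ImpairmentProfile, Side, TaskClass

FS = 100.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def manual_task_list():
    """Two-instance (left/right) single-hand protocol for small regressions."""
    return [(TaskClass.CARDS, Side.RIGHT), (TaskClass.CARDS, Side.LEFT)]


def make_instances(
    task_list,
    noise_sd: float,
    seed: int,
    n_subjects: int = 5,
    weeks: int = 3,
    week_trend: float = 0.05,
):
    """Simulate a small multi-subject dataset of rated task instances."""
    from motorcap.synth import simulate_session

    instances = []
    for si, lvl in enumerate(np.linspace(0.1, 0.9, n_subjects)):
        profile = ImpairmentProfile(
            level=float(lvl), side_affected="left", week_trend=week_trend
        )
        for wk in range(1, weeks + 1):
            result = simulate_session(
                profile,
                week=wk,
                task_list=task_list,
                rating_noise_sd=noise_sd,
                seed=seed,
                subject_id=f"P{si}",
            )
            instances.extend(result.instances)
    return instances
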