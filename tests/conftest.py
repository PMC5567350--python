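import numpy as np
import pytest

from plethys import (
    CohortConfig,
    SelectionCriteria,
    SimulationConfig,
    generate_cohort,
    generate_trace,
)
from plethys.trace_io import ConditionSchedule, ScheduleBlock

# Scaled problem sizes used throughout the suite: 250 Hz sampling and
# 120-180 s blocks with a proportionally scaled selection window keep the
# runs fast while exercising every stage at realistic breathing statistics.
SCALED_FS = 250.0
SCALED_CRITERIA = SelectionCriteria(min_segment=10.0, cumulative_target=60.0, window_s=120.0)


def single_block_schedule(duration: float = 120.0, label: str = "room_air") -> ConditionSchedule:
    return ConditionSchedule([ScheduleBlock(label, "pre", 0.0, duration)])


@pytest.fixture(scope="session")
def default_sim():
    """A 120 s default-parameter animal trace with ground truth."""
    config = SimulationConfig(sampling_rate=SCALED_FS, seed=3)
    schedule = single_block_schedule(120.0)
    trace, truth = generate_trace(config, schedule)
    return config, schedule, trace, truth


@pytest.fixture(scope="session")
def clean_sim():
    """As default_sim but without artifacts, for detector-accuracy checks."""
    config = SimulationConfig(sampling_rate=SCALED_FS, artifact_rate=0.0, seed=5)
    schedule = single_block_schedule(120.0)
    trace, truth = generate_trace(config, schedule)
    return config, schedule, trace, truth


@pytest.fixture(scope="session")
def hypercapnic_cohort():
    """A small scaled hypercapnic cohort with a post-CNO slowing of
    breathing injected into experimental animals."""
    config = CohortConfig(
        n_experimental=4,
        n_control=4,
        block_s=180.0,
        base=SimulationConfig(sampling_rate=SCALED_FS),
        effect_map={
            ("room_air", "post"): {"ibi": 1.4, "vo2": 0.85},
            ("hypercapnia", "post"): {"ibi": 1.4, "vo2": 0.85},
        },
        seed=17,
    )
    return generate_cohort(config)


def match_onsets(detected: np.ndarray, truth: np.ndarray, tol: float = 0.010) -> float:
    """Fraction of ground-truth onsets with a detection within +/- tol s."""
    if truth.size == 0:
        return np.nan
    d = np.abs(detected[None, :] - truth[:, None]).min(axis=1)
    return float(np.mean(d <= tol))
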