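import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cisim import CohortConfig, cohort_truths, stimulus_grid
from cisim.cap_pipeline import analyze_synthetic_cohort
from cisim.cli import cohort_metrics_frame
from cisim.group_stats import run_study_contrasts

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_grid():
    return stimulus_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Reduced lattice for fast waveform-level tests."""
    return stimulus_grid(2000, 8000, 1, 20, 80, 20)


@pytest.fixture(scope="session")
def default_cohort_run(default_grid):
    """The default calibrated 24-ear cohort (seeded), analysed end-to-end,
    with per-ear insertion metrics and the full contrast table."""
    config = CohortConfig()
    truths = cohort_truths(config, COHORT_SEED)
    results = analyze_synthetic_cohort(truths, default_grid)
    metrics = cohort_metrics_frame([t.to_dict() for t in truths])
    stats = run_study_contrasts(results.thresholds, results.shifts, metrics=metrics)
    return {
        "config": config,
        "truths": truths,
        "results": results,
        "metrics": metrics,
        "stats": stats,
    }
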