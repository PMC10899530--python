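import numpy as np
import pytest

from ktrq import AcquisitionSchedule, AnalysisWindows
from ktrq.synth import SimParams, simulate_trace_ensemble


@pytest.fixture(scope="session")
def schedule():
    """Default acquisition schedule: 6-min frames, 4 h baseline, 15 h post."""
    return AcquisitionSchedule()

@pytest.fixture(scope="session")
def windows():
    return AnalysisWindows()


@pytest.fixture(scope="session")
def short_schedule():
    """Small schedule for fast rendering tests (on the same 6-min grid)."""
    return AcquisitionSchedule(baseline_duration=60, post_duration=120,
                               meki_duration=36, meki_window=18)


@pytest.fixture(scope="session")
def noiseless_class3(schedule):
    """Deterministic all-responder sustained ensemble without noise."""
    params = SimParams(response_class=3, n_cells=30, noise_sigma=0.0,
                       responder_pmax=1.0, responder_ec50=1e-9,
                       amplitude_cv=0.0, seed=11)
    return simulate_trace_ensemble(params, schedule)
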