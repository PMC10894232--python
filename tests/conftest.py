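import numpy as np
import pandas as pd
import pytest

from rnaid import AnalysisConfig, SimParams, analyze_trace, load_fixture, simulate_trace


@pytest.fixture(scope="session")
def linear_design():
    return load_fixture("linear")[0]


@pytest.fixture(scope="session")
def circular_design():
    return load_fixture("circular")[0]


@pytest.fixture(scope="session")
def linear_params():
    design, sim = load_fixture("linear")
    return SimParams(seed=11, p_fold=0.0).with_overrides(sim)


@pytest.fixture(scope="session")
def circular_params():
    design, sim = load_fixture("circular")
    return SimParams(seed=13).with_overrides(sim)


@pytest.fixture(scope="session")
def noiseless_params():
    """Constant speed, no noise, no drift: renders events exactly."""
    return SimParams(
        seed=7, noise_sd_pA=0.0, speed_cv=0.0, intra_event_drift=0.0, p_fold=0.0, p_reverse=0.0
    )


@pytest.fixture(scope="session")
def linear_run(linear_design, linear_params):
    """Seeded 200-event unfolded linear-fixture simulation plus analysis."""
    trace, truth = simulate_trace(linear_design, linear_params, 200)
    result = analyze_trace(trace, linear_design)
    return trace, truth, result


@pytest.fixture(scope="session")
def circular_run(circular_design, circular_params):
    """Seeded 200-event circular-fixture simulation plus analysis."""
    trace, truth = simulate_trace(circular_design, circular_params, 200)
    result = analyze_trace(trace, circular_design)
    return trace, truth, result


def match_events_to_truth(events_df: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Index of the truth row containing each event's midpoint (-1 if none)."""
    mids = (events_df["start_ms"] + events_df["duration_ms"] / 2).to_numpy()
    starts = truth["start_ms"].to_numpy()
    ends = starts + truth["duration_ms"].to_numpy()
    out = np.full(len(mids), -1, dtype=int)
    for i, m in enumerate(mids):
        hit = np.flatnonzero((starts <= m) & (m <= ends))
        if hit.size:
            out[i] = hit[0]
    return out


@pytest.fixture(scope="session")
def matcher():
    return match_events_to_truth
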