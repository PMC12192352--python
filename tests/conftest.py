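import numpy as np
import pytest

import casim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_bundle():
    """Three-cell hand-built session: events, traces, centroids, no trials."""
    events = casim.EventTrains(
        times={
            "a": np.array([0.5, 2.0, 4.5]),
            "b": np.array([1.0, 3.0]),
            "c": np.array([], dtype=float),
        },
        amplitudes={
            "a": np.array([1.0, 0.5, 2.0]),
            "b": np.array([1.5, 1.5]),
            "c": np.array([], dtype=float),
        },
        segment=(0.0, 6.0),
    )
    traces = casim.events_to_traces(events, noise_sd=0.0)
    cell_map = casim.CellMap({"a": (0.0, 0.0), "b": (30.0, 40.0), "c": (100.0, 0.0)})
    return casim.SessionBundle(events, traces, cell_map)


@pytest.fixture
def spontaneous_session():
    """Twenty independent Poisson cells, 600 s at 0.05 events/s."""
    cfg = casim.SimConfig(
        n_cells=20, duration_s=600.0, base_rate_hz=0.05, seed=7, make_traces=False
    )
    return casim.generate_session(cfg)


@pytest.fixture
def task_session():
    """Task session with planted tuned, untuned-responsive, and null cells."""
    tuning = [
        casim.TuningSpec(0, "left"),
        casim.TuningSpec(1, "right"),
        casim.TuningSpec(2, None),
    ]
    cfg = casim.SimConfig(
        n_cells=10,
        duration_s=520.0,
        base_rate_hz=0.5,
        task="one_target",
        n_trials=90,
        tuning_spec=tuning,
        seed=11,
    )
    return casim.generate_session(cfg)
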