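import numpy as np
import pandas as pd
import pytest

from dfcstates.config import PipelineConfig
from dfcstates.types import DFCWindowSeries, StateSequence, SubjectTimeSeries, WindowSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """A clean 60x5 subject time series."""
    return SubjectTimeSeries(
        subject_id="s1",
        data=rng.standard_normal((60, 5)),
        node_labels=[f"n{i}" for i in range(5)],
    )


@pytest.fixture
def fast_cfg():
    return PipelineConfig(replicates=10, max_iter=100, seed=7)


def make_window_series(edges, subject_id="s1", valid=None, node_labels=None):
    """Wrap an (W, E) edge matrix as a DFCWindowSeries."""
    edges = np.asarray(edges, dtype=float)
    W, E = edges.shape
    N = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    return DFCWindowSeries(
        subject_id=subject_id,
        windows=[WindowSpec(start=i, length=22, index=i) for i in range(W)],
        edges=edges,
        valid=np.ones(W, dtype=bool) if valid is None else np.asarray(valid, bool),
        node_labels=node_labels or [f"n{i + 1}" for i in range(N)],
    )


def make_sequence(labels, subject_id="s1"):
    labels = np.asarray(labels, dtype=int)
    return StateSequence(
        subject_id=subject_id,
        labels=labels,
        window_indices=np.arange(len(labels)),
    )


@pytest.fixture
def toy_cohort():
    return pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d"],
            "group": ["control", "control", "patient", "patient"],
            "site": ["s1", "s1", "s1", "s1"],
            "age": [30.0, 40.0, 35.0, 45.0],
            "sex": ["M", "F", "M", "F"],
            "mean_fd": [0.08, 0.09, 0.1, 0.11],
        }
    )
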