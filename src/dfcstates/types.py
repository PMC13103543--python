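"""Core containers for the dynamic-connectivity state pipeline.

The pipeline moves through a fixed chain of artifacts: a per-subject ROI
time-series matrix, its sequence of windowed Fisher-z connectivity edge
vectors, a fitted k-means state model, the per-subject state-label sequence,
and the per-subject temporal metrics derived from it. Each stage's container
is a plain dataclass so artifacts serialize to flat TSV tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SubjectTimeSeries:
    """One subject's ROI signal matrix: rows are time points, columns nodes."""

    subject_id: str
    data: np.ndarray  # (T, N), BOLD-like arbitrary units
    node_labels: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D (time x node) matrix")
        if self.data.shape[1] != len(self.node_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.node_labels)} node labels"
            )
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 nodes")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """One sliding-window placement: 0-based inclusive start, length, ordinal."""

    start: int
    length: int
    index: int

    @property
    def stop(self) -> int:
        """Exclusive end of the window."""
        return self.start + self.length


@dataclass
class DFCWindowSeries:
    """Ordered windowed connectivity for one subject.

    ``edges`` holds one Fisher-z edge vector per window (row-major upper
    triangle, i<j, node order = input column order). ``valid`` flags windows
    whose correlations were all defined; invalid windows keep their slot (the
    edge row may contain NaN) so downstream stages decide how to handle them.
    """

    subject_id: str
    windows: list[WindowSpec]
    edges: np.ndarray  # (W, E) with E = N(N-1)/2
    valid: np.ndarray  # (W,) bool
    node_labels: list[str]

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def valid_edges(self) -> np.ndarray:
        return self.edges[self.valid]


@dataclass
class StateModel:
    """k-means state model: k centroid edge-vectors plus fit provenance."""

    k: int
    centroids: np.ndarray  # (k, E) Fisher-z values
    wcss: float
    seed: int
    replicates: int
    stage1_exemplar_count: int
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid row count must equal k")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.wcss < 0:
            raise ValueError("wcss must be non-negative")


@dataclass
class StateSequence:
    """Per-subject ordered state labels (1..k) over the subject's valid windows."""

    subject_id: str
    labels: np.ndarray  # (n_valid,) ints in 1..k
    window_indices: np.ndarray  # original 0-based window ordinals retained

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.window_indices = np.asarray(self.window_indices, dtype=int)
        if self.labels.shape != self.window_indices.shape:
            raise ValueError("labels and window_indices must align")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TemporalMetrics:
    """Per-subject temporal summary of a state sequence.

    Dwell entries and per-state FC means are NaN where the state was never
    visited (excluded listwise from group statistics, never treated as zero).
    """

    subject_id: str
    occupancy: np.ndarray  # (k,) fractions
    dwell: np.ndarray  # (k,) mean run length in windows; NaN if unvisited
    transitions: int
    pair_counts: np.ndarray  # (k, k) ints, zero diagonal
    n_windows: int
    state_mean_fc: dict[str, np.ndarray] = field(default_factory=dict)
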