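"""Temporal metrics of state sequences.

Fractional occupancy is the fraction of a subject's windows assigned to each
state; mean dwell time is the average length (in windows) of maximal runs of
a state, including the final censored run; the transition count is the number
of adjacent window pairs with differing labels, split by ordered state pair
in the pairwise matrix (self-transitions excluded by construction). States a
subject never visits get dwell/FC entries of NaN and are excluded listwise
from group statistics. Where invalid windows were removed before sequence
construction, a transition across the gap is counted only if the labels
differ.
"""
from __future__ import annotations

import numpy as np

from .types import DFCWindowSeries, StateSequence, TemporalMetrics


def _check_nonempty(seq: StateSequence) -> None:
    if len(seq) == 0:
        raise ValueError(f"subject {seq.subject_id}: empty state sequence")


def fractional_occupancy(seq: StateSequence, k: int) -> np.ndarray:
    _check_nonempty(seq)
    counts = np.bincount(seq.labels, minlength=k + 1)[1 : k + 1]
    return counts / len(seq)


def run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encoding: list of (state, length) for maximal runs."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(labels)]))
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def mean_dwell_time(seq: StateSequence, k: int) -> np.ndarray:
    """Mean run length per state in window units; NaN where never visited."""
    _check_nonempty(seq)
    sums = np.zeros(k)
    counts = np.zeros(k)
    for state, length in run_lengths(seq.labels):
        sums[state - 1] += length
        counts[state - 1] += 1
    with np.errstate(invalid="ignore"):
        dwell = sums / counts
    dwell[counts == 0] = np.nan
    return dwell


def count_transitions(seq: StateSequence) -> int:
    _check_nonempty(seq)
    return int(np.sum(np.diff(seq.labels) != 0))


def pairwise_transition_counts(seq: StateSequence, k: int) -> np.ndarray:
    """k x k ordered transition counts; diagonal fixed at zero."""
    _check_nonempty(seq)
    mat = np.zeros((k, k), dtype=int)
    a, b = seq.labels[:-1], seq.labels[1:]
    moved = a != b
    np.add.at(mat, (a[moved] - 1, b[moved] - 1), 1)
    return mat


def state_mean_fc(
    series: DFCWindowSeries,
    seq: StateSequence,
    k: int,
    node_subset: list[str] | None = None,
) -> np.ndarray:
    """Per-state mean Fisher-z over a node subset's edges; NaN if unvisited.

    With ``node_subset=None`` the full edge vector is used. For each state the
    subset-restricted edge values are first averaged within each window
    assigned to that state, then across those windows.
    """
    _check_nonempty(seq)
    cols = _subset_edge_columns(series.node_labels, node_subset)
    window_means = series.edges[seq.window_indices][:, cols].mean(axis=1)
    out = np.full(k, np.nan)
    for s in range(1, k + 1):
        mask = seq.labels == s
        if mask.any():
            out[s - 1] = window_means[mask].mean()
    return out


def _subset_edge_columns(
    node_labels: list[str], node_subset: list[str] | None
) -> np.ndarray:
    N = len(node_labels)
    if node_subset is None:
        return np.arange(N * (N - 1) // 2)
    unknown = [n for n in node_subset if n not in node_labels]
    if unknown:
        raise ValueError(f"unknown node labels: {unknown}")
    if len(node_subset) < 2:
        raise ValueError("node subset needs at least 2 nodes")
    idx = {n: i for i, n in enumerate(node_labels)}
    members = np.zeros(N, dtype=bool)
    members[[idx[n] for n in node_subset]] = True
    iu = np.triu_indices(N, k=1)
    keep = members[iu[0]] & members[iu[1]]
    return np.flatnonzero(keep)


def compute_metrics(
    series: DFCWindowSeries,
    seq: StateSequence,
    k: int,
    node_subsets: dict[str, list[str]] | None = None,
) -> TemporalMetrics:
    """All temporal metrics for one subject, with internal identity checks."""
    occ = fractional_occupancy(seq, k)
    dwell = mean_dwell_time(seq, k)
    trans = count_transitions(seq)
    pairs = pairwise_transition_counts(seq, k)
    # invariants asserted on every subject in every run
    assert abs(occ.sum() - 1.0) < 1e-12
    assert pairs.sum() == trans
    runs = run_lengths(seq.labels)
    total = sum(length for _, length in runs)
    assert total == len(seq)
    fc = {"all": state_mean_fc(series, seq, k, None)}
    for name, nodes in (node_subsets or {}).items():
        fc[name] = state_mean_fc(series, seq, k, nodes)
    return TemporalMetrics(
        subject_id=seq.subject_id,
        occupancy=occ,
        dwell=dwell,
        transitions=trans,
        pair_counts=pairs,
        n_windows=len(seq),
        state_mean_fc=fc,
    )


def metrics_to_row(m: TemporalMetrics) -> dict:
    """Flatten one subject's metrics to a table row (NaN stays missing)."""
    k = len(m.occupancy)
    row: dict = {"subject_id": m.subject_id, "n_windows": m.n_windows}
    for s in range(k):
        row[f"occupancy_s{s + 1}"] = m.occupancy[s]
    for s in range(k):
        row[f"dwell_s{s + 1}"] = m.dwell[s]
    row["transitions"] = m.transitions
    for a in range(k):
        for b in range(k):
            if a != b:
                row[f"t_{a + 1}to{b + 1}"] = int(m.pair_counts[a, b])
    for name, vec in m.state_mean_fc.items():
        for s in range(k):
            row[f"mean_fc_{name}_s{s + 1}"] = vec[s]
    return row
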