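"""Connectivity-state identification by two-stage k-means.

Stage 1 clusters "exemplar" windows — local maxima of the across-edge
variance signal within each subject — pooled over subjects, taking the best
of many randomly initialized Lloyd runs (lowest within-cluster sum of
squares). Stage 2 runs a single Lloyd pass over *all* pooled windows,
initialized at the stage-1 centroids, which desensitizes the final model to
random starting conditions. Model order is chosen by the elbow criterion on
the WCSS-vs-k curve; every valid window is then assigned to the nearest
centroid (squared Euclidean distance, ties to the lowest state id).
"""
from __future__ import annotations

import logging

import numpy as np

from .types import DFCWindowSeries, StateModel, StateSequence

logger = logging.getLogger(__name__)


# --- exemplar selection -----------------------------------------------------

def exemplar_windows(
    series: DFCWindowSeries, variance_mode: str = "across_edges"
) -> np.ndarray:
    """Indices (into the subject's valid windows) of exemplar windows.

    The exemplar signal is, per valid window, the population variance over
    its E edge values ("across_edges"); the alternative reading uses each
    window's contribution to the per-edge temporal variance, summed over
    edges ("per_edge_time"). Exemplars are strict local maxima of this
    signal (endpoints excluded); if none exists the global argmax (first of
    a plateau) is returned so at least one exemplar always exists.
    """
    valid_edges = series.valid_edges()
    if valid_edges.shape[0] < 3:
        raise ValueError(
            f"subject {series.subject_id}: need >= 3 valid windows, "
            f"have {valid_edges.shape[0]}"
        )
    if variance_mode == "across_edges":
        signal = valid_edges.var(axis=1)  # population variance across edges
    elif variance_mode == "per_edge_time":
        dev = valid_edges - valid_edges.mean(axis=0, keepdims=True)
        signal = (dev**2).sum(axis=1)
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    interior = np.arange(1, len(signal) - 1)
    is_max = (signal[interior] > signal[interior - 1]) & (
        signal[interior] > signal[interior + 1]
    )
    idx = interior[is_max]
    if idx.size == 0:
        idx = np.array([int(np.argmax(signal))])
    return idx


def pool_exemplars(
    series_list: list[DFCWindowSeries], variance_mode: str = "across_edges"
) -> np.ndarray:
    """Stack every subject's exemplar windows into one (n_exemplars, E) matrix."""
    rows = []
    for s in series_list:
        ve = s.valid_edges()
        rows.append(ve[exemplar_windows(s, variance_mode)])
    return np.vstack(rows)


def pool_valid_windows(series_list: list[DFCWindowSeries]) -> np.ndarray:
    return np.vstack([s.valid_edges() for s in series_list])


# --- Lloyd's algorithm ------------------------------------------------------

def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels (ties to lowest id) and squared distances."""
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ centroids.T
        + (centroids**2).sum(axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    return d2.argmin(axis=1), d2


def lloyd(
    X: np.ndarray,
    init_centroids: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Plain Lloyd iteration from explicit initial centroids.

    Returns (centroids, labels, wcss). Runs until the partition is stable,
    the squared centroid shift falls below ``tol`` relative to the data
    scale, or ``max_iter`` sweeps. An empty cluster is re-seeded at the
    point farthest from its assigned centroid.
    """
    k = init_centroids.shape[0]
    centroids = init_centroids.astype(float).copy()
    labels = np.full(X.shape[0], -1)
    scale = float((X**2).sum(axis=1).mean()) + 1e-300
    for _ in range(max_iter):
        new_labels, d2 = _assign(X, centroids)
        point_d2 = d2[np.arange(X.shape[0]), new_labels]
        prev_centroids = centroids.copy()
        for j in range(k):
            mask = new_labels == j
            if mask.any():
                centroids[j] = X[mask].mean(axis=0)
            else:
                far = int(np.argmax(point_d2))
                logger.debug("empty cluster %d re-seeded at point %d", j, far)
                centroids[j] = X[far]
                new_labels[far] = j
                point_d2[far] = 0.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        shift = float(((centroids - prev_centroids) ** 2).sum())
        if shift < tol * scale:
            break
    labels, d2 = _assign(X, centroids)
    wcss = float(d2[np.arange(X.shape[0]), labels].sum())
    return centroids, labels, wcss


def _replicate_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(X.shape[0], size=k, replace=False)
    return X[idx]


def best_of_replicates(
    X: np.ndarray,
    k: int,
    replicates: int,
    max_iter: int,
    seed: int,
    extra_inits: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lowest-WCSS Lloyd solution over seeded random restarts.

    Each replicate draws k distinct data points as initial centroids from its
    own substream of the master seed, so the replicate stream has the prefix
    property: increasing ``replicates`` can only keep or lower the best WCSS.
    """
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available points")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(replicates)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for init in extra_inits or []:
        sol = lloyd(X, init, max_iter)
        if best is None or sol[2] < best[2]:
            best = sol
    for child in streams:
        rng = np.random.default_rng(child)
        sol = lloyd(X, _replicate_init(X, k, rng), max_iter)
        if best is None or sol[2] < best[2]:
            best = sol
    assert best is not None
    return best


def kmeans_two_stage(
    exemplars: np.ndarray,
    all_windows: np.ndarray,
    k: int,
    replicates: int = 500,
    max_iter: int = 500,
    seed: int = 0,
    node_labels: list[str] | None = None,
) -> StateModel:
    """Exemplar-initialized two-stage k-means; deterministic given the seed."""
    exemplars = np.asarray(exemplars, dtype=float)
    all_windows = np.asarray(all_windows, dtype=float)
    if exemplars.shape[1] != all_windows.shape[1]:
        raise ValueError("exemplars and windows must share the edge dimension")
    if k > exemplars.shape[0]:
        raise ValueError(f"infeasible: k={k} > {exemplars.shape[0]} exemplars")
    stage1_centroids, _, _ = best_of_replicates(exemplars, k, replicates, max_iter, seed)
    centroids, _, wcss = lloyd(all_windows, stage1_centroids, max_iter)
    return StateModel(
        k=k,
        centroids=centroids,
        wcss=wcss,
        seed=seed,
        replicates=replicates,
        stage1_exemplar_count=exemplars.shape[0],
        node_labels=node_labels,
    )


# --- model selection --------------------------------------------------------

def elbow_curve(
    all_windows: np.ndarray,
    k_range: tuple[int, int],
    replicates: int = 50,
    max_iter: int = 500,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """WCSS as a function of k over ``k_range`` (inclusive).

    Each k is fitted best-of-replicates; k+1 additionally warm-starts from
    k's solution plus a split (the point farthest from its centroid), which
    keeps the curve non-increasing in k up to replicate noise.
    """
    X = np.asarray(all_windows, dtype=float)
    lo, hi = k_range
    if lo < 1 or hi > X.shape[0]:
        raise ValueError("k_range must lie within [1, number of windows]")
    curve: list[tuple[int, float]] = []
    prev_centroids: np.ndarray | None = None
    for k in range(lo, hi + 1):
        extra = []
        if prev_centroids is not None:
            labels, d2 = _assign(X, prev_centroids)
            far = int(np.argmax(d2[np.arange(X.shape[0]), labels]))
            extra.append(np.vstack([prev_centroids, X[far]]))
        centroids, _, wcss = best_of_replicates(
            X, k, replicates, max_iter, seed + k, extra_inits=extra
        )
        curve.append((k, wcss))
        prev_centroids = centroids
    return curve


def elbow_knee(curve: list[tuple[int, float]]) -> int:
    """Knee suggestion: the k after which WCSS drops become negligible.

    Implemented as the maximum ratio of successive WCSS drops (the second
    difference of the log drop sequence). A raw second difference is
    dominated by the absolute WCSS scale: when isotropic within-state noise
    carries most of the variance the curve is nearly flat and the huge
    k=1 -> 2 drop masks the true inflection, while the drop *ratio* still
    spikes at the planted k. The suggestion is advisory only.
    """
    if len(curve) < 3:
        return curve[-1][0]
    ks = [k for k, _ in curve]
    w = np.array([wcss for _, wcss in curve])
    drops = np.maximum(w[:-1] - w[1:], 0.0)
    floor = max(w[0], 1e-300) * 1e-12
    ratios = (drops[:-1] + floor) / (drops[1:] + floor)
    return ks[1 + int(np.argmax(ratios))]


# --- assignment and state-label conventions ---------------------------------

def assign_states(series: DFCWindowSeries, model: StateModel) -> StateSequence:
    """Label each valid window with its nearest centroid (1-based states)."""
    if series.n_edges != model.centroids.shape[1]:
        raise ValueError(
            f"series has E={series.n_edges} but model has "
            f"E={model.centroids.shape[1]}"
        )
    ve = series.valid_edges()
    labels, _ = _assign(ve, model.centroids)
    return StateSequence(
        subject_id=series.subject_id,
        labels=labels + 1,
        window_indices=np.array([w.index for w in series.windows])[series.valid],
    )


def reporting_order(model: StateModel) -> np.ndarray:
    """Permutation mapping internal state order to reporting labels.

    States are first ordered by ascending centroid mean z; for k = 3 the
    reporting convention labels that ascending order [2, 1, 3] — the
    hypoconnected state is "State 2", the moderate one "State 1", the
    hyperconnected one "State 3". Other k keep the ascending order 1..k.

    Returns ``new_label`` such that internal state i (0-based) is reported
    as state ``new_label[i]`` (1-based).
    """
    means = model.centroids.mean(axis=1)
    rank = np.empty(model.k, dtype=int)
    rank[np.argsort(means, kind="stable")] = np.arange(model.k)
    if model.k == 3:
        rename = np.array([2, 1, 3])
    else:
        rename = np.arange(1, model.k + 1)
    return rename[rank]


def relabel_model(model: StateModel) -> StateModel:
    """Reorder centroid rows so row s-1 is reported state s."""
    new_label = reporting_order(model)
    order = np.argsort(new_label)
    return StateModel(
        k=model.k,
        centroids=model.centroids[order],
        wcss=model.wcss,
        seed=model.seed,
        replicates=model.replicates,
        stage1_exemplar_count=model.stage1_exemplar_count,
        node_labels=model.node_labels,
    )
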