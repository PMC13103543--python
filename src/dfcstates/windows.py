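"""Sliding-window dynamic connectivity.

Each subject's time series is segmented into overlapping rectangular windows
(default 22 TR advanced by 1 TR). Within each window the Pearson correlation
is computed between every node pair, clamped away from +/-1 by a small
epsilon, and Fisher r-to-z transformed; the upper-triangular entries
(row-major, i<j, diagonal excluded) form the window's edge vector. A window
is invalid when any pairwise correlation is undefined (a node with zero
variance in the window) — invalid windows keep their slot and are flagged,
never silently dropped.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import PipelineConfig
from .types import DFCWindowSeries, SubjectTimeSeries, WindowSpec


def enumerate_windows(T: int, window_length: int, step: int) -> list[WindowSpec]:
    """All window placements: floor((T - L)/step) + 1 windows starting at 0."""
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if T < window_length:
        raise ValueError(
            f"insufficient data: T={T} is shorter than window length {window_length}"
        )
    n = (T - window_length) // step + 1
    return [WindowSpec(start=i * step, length=window_length, index=i) for i in range(n)]


def fisher_z(r: np.ndarray | float, epsilon: float = 1e-7) -> np.ndarray | float:
    """artanh with boundary values shifted away from +/-1 by epsilon."""
    r = np.clip(r, -1.0 + epsilon, 1.0 - epsilon)
    return np.arctanh(r)


def window_connectivity(
    ts: SubjectTimeSeries, spec: WindowSpec, epsilon: float = 1e-7
) -> tuple[np.ndarray, bool]:
    """Fisher-z edge vector for one window, plus a validity flag."""
    if spec.start < 0 or spec.stop > ts.n_timepoints:
        raise ValueError(f"window {spec} exceeds series of length {ts.n_timepoints}")
    if not (0 < epsilon <= 1e-3):
        raise ValueError("epsilon must lie in (0, 1e-3]")
    seg = ts.data[spec.start : spec.stop]
    edges, valid = _segment_edges(seg[None, :, :], epsilon)
    return edges[0], bool(valid[0])


def build_dfc_series(ts: SubjectTimeSeries, cfg: PipelineConfig) -> DFCWindowSeries:
    """Windowed Fisher-z connectivity series for one subject.

    Preserves window order and records validity flags; never drops window
    slots (downstream stages decide what to do with invalid windows).
    """
    specs = enumerate_windows(ts.n_timepoints, cfg.window_length_tr, cfg.step_tr)
    if cfg.step_tr == 1:
        segs = sliding_window_view(ts.data, cfg.window_length_tr, axis=0)
        segs = np.moveaxis(segs, -1, 1)  # (W, L, N)
    else:
        segs = np.stack([ts.data[s.start : s.stop] for s in specs])
    edges, valid = _segment_edges(segs, cfg.fisher_epsilon)
    return DFCWindowSeries(
        subject_id=ts.subject_id,
        windows=specs,
        edges=edges,
        valid=valid,
        node_labels=list(ts.node_labels),
    )


def _segment_edges(segs: np.ndarray, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-window Pearson + Fisher z over (W, L, N) segments."""
    W, L, N = segs.shape
    centered = segs - segs.mean(axis=1, keepdims=True)
    # cross-products and per-node sums of squares
    cov = np.einsum("wli,wlj->wij", centered, centered)
    ss = np.einsum("wli,wli->wi", centered, centered)
    denom = np.sqrt(ss[:, :, None] * ss[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    iu = np.triu_indices(N, k=1)
    r_edges = r[:, iu[0], iu[1]]
    valid = np.isfinite(r_edges).all(axis=1)
    z = np.arctanh(np.clip(r_edges, -1.0 + epsilon, 1.0 - epsilon))
    z[~valid] = np.nan
    return z, valid


def edge_to_matrix(edge_vector: np.ndarray, N: int) -> np.ndarray:
    """Inverse of upper-triangle vectorization: symmetric N x N, zero diagonal."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    E = N * (N - 1) // 2
    if edge_vector.shape != (E,):
        raise ValueError(f"expected edge vector of length {E}, got {edge_vector.shape}")
    mat = np.zeros((N, N))
    iu = np.triu_indices(N, k=1)
    mat[iu] = edge_vector
    mat = mat + mat.T
    return mat


def matrix_to_edges(mat: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (i<j) vectorization of a symmetric matrix."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu].copy()
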