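"""Tabular I/O for every pipeline artifact.

All artifacts are tab-separated text with one header row: subject time
series (rows = time points, columns = ROI nodes), the cohort metadata table,
per-subject window dumps, centroid tables, state sequences, metrics and
statistics tables. Readers never reorder rows or columns, and writing then
reading any artifact reproduces it to the declared precision. Missing
optional metadata is an empty cell, surfaced as a pandas missing value,
never as zero.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import DFCWindowSeries, StateModel, StateSequence, SubjectTimeSeries

SEP = "\t"
FLOAT_FMT = "%.12g"

REQUIRED_META_COLS = ["subject_id", "group", "site", "age", "sex", "mean_fd"]
OPTIONAL_META_COLS = ["hamd", "illness_duration_months", "medication", "episode"]
GROUP_LEVELS = {"control", "patient"}
SEX_LEVELS = {"M", "F"}
MEDICATION_LEVELS = {"medicated", "unmedicated"}
EPISODE_LEVELS = {"first", "recurrent"}


def read_timeseries(
    path: str | Path,
    expected_nodes: int | None = None,
    tr_seconds: float = 2.0,
    subject_id: str | None = None,
) -> SubjectTimeSeries:
    """Read one subject's ROI-by-time matrix from a TSV with node-label header.

    The reader validates shape and numeric content but does not judge signal
    content (constant columns etc. are a QC matter downstream).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need >= 2 node columns, found {df.shape[1]}")
    if expected_nodes is not None and df.shape[1] != expected_nodes:
        raise ValueError(
            f"{path}: expected {expected_nodes} node columns, found {df.shape[1]}"
        )
    try:
        data = df.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for a useful message
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at row {i + 1}, "
                        f"column {col!r} (index {j})"
                    ) from None
        raise
    if np.isnan(data).all(axis=0).any() or np.isnan(data).all(axis=1).any():
        raise ValueError(f"{path}: a row or column is entirely missing")
    return SubjectTimeSeries(
        subject_id=subject_id if subject_id is not None else path.stem,
        data=data,
        node_labels=list(df.columns),
        tr_seconds=tr_seconds,
    )


def write_timeseries(ts: SubjectTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.node_labels).to_csv(
        path, sep=SEP, index=False, float_format=FLOAT_FMT
    )
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort table.

    Required columns: subject_id, group (control/patient), site, age, sex
    (M/F), mean_fd. Optional: hamd, illness_duration_months, medication
    (medicated/unmedicated), episode (first/recurrent); empty cells are
    missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, header=0, dtype={"subject_id": str, "site": str})
    missing = [c for c in REQUIRED_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject_id values {dups}")
    bad_group = set(df["group"].dropna()) - GROUP_LEVELS
    if bad_group:
        raise ValueError(f"{path}: unknown group labels {sorted(bad_group)}")
    bad_sex = set(df["sex"].dropna()) - SEX_LEVELS
    if bad_sex:
        raise ValueError(f"{path}: unknown sex labels {sorted(bad_sex)}")
    for col, levels in (("medication", MEDICATION_LEVELS), ("episode", EPISODE_LEVELS)):
        if col in df.columns:
            bad = set(df[col].dropna()) - levels
            if bad:
                raise ValueError(f"{path}: unknown {col} labels {sorted(bad)}")
    for col in ("age", "mean_fd"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("hamd", "illness_duration_months"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep=SEP, index=False, float_format=FLOAT_FMT)
    return path


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any tabular artifact; round-trip safe at 12 significant digits."""
    path = Path(path)
    df.to_csv(path, sep=SEP, index=False, float_format=FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, header=0)


# --- windowed-connectivity dumps -------------------------------------------

def edge_names(node_labels: list[str]) -> list[str]:
    iu = np.triu_indices(len(node_labels), k=1)
    return [f"{node_labels[i]}__{node_labels[j]}" for i, j in zip(*iu)]


def write_window_dump(series: DFCWindowSeries, path: str | Path) -> Path:
    """Per-subject window dump: window_index, start, valid, then E edge columns."""
    cols = {
        "window_index": [w.index for w in series.windows],
        "start": [w.start for w in series.windows],
        "valid": series.valid.astype(int),
    }
    df = pd.DataFrame(cols)
    edges = pd.DataFrame(series.edges, columns=edge_names(series.node_labels))
    return write_table(pd.concat([df, edges], axis=1), path)


def read_window_dump(path: str | Path, subject_id: str | None = None) -> DFCWindowSeries:
    from .types import WindowSpec

    path = Path(path)
    df = read_table(path)
    meta_cols = ["window_index", "start", "valid"]
    edge_cols = [c for c in df.columns if c not in meta_cols]
    node_labels = _nodes_from_edge_names(edge_cols)
    length_guess = None
    starts = df["start"].to_numpy(int)
    if len(starts) > 1:
        length_guess = int(starts[1] - starts[0])
    windows = [
        WindowSpec(start=int(s), length=length_guess or 0, index=int(i))
        for s, i in zip(starts, df["window_index"])
    ]
    return DFCWindowSeries(
        subject_id=subject_id if subject_id is not None else path.stem,
        windows=windows,
        edges=df[edge_cols].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        node_labels=node_labels,
    )


def _nodes_from_edge_names(edge_cols: list[str]) -> list[str]:
    nodes: list[str] = []
    for name in edge_cols:
        a, b = name.split("__")
        for n in (a, b):
            if n not in nodes:
                nodes.append(n)
    return nodes


# --- state model / sequences / metrics -------------------------------------

def write_centroids(model: StateModel, path: str | Path) -> Path:
    """k x E edge table; one row per state (labels 1..k)."""
    labels = model.node_labels or [f"n{i + 1}" for i in range(_n_from_e(model.centroids.shape[1]))]
    df = pd.DataFrame(model.centroids, columns=edge_names(labels))
    df.insert(0, "state", np.arange(1, model.k + 1))
    return write_table(df, path)


def read_centroids(path: str | Path, seed: int = 0) -> StateModel:
    df = read_table(path)
    edge_cols = [c for c in df.columns if c != "state"]
    centroids = df[edge_cols].to_numpy(float)
    return StateModel(
        k=centroids.shape[0],
        centroids=centroids,
        wcss=0.0,
        seed=seed,
        replicates=0,
        stage1_exemplar_count=0,
        node_labels=_nodes_from_edge_names(edge_cols),
    )


def _n_from_e(e: int) -> int:
    n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n * (n - 1) // 2 != e:
        raise ValueError(f"{e} is not a triangular number N(N-1)/2")
    return n


def write_state_sequences(seqs: list[StateSequence], path: str | Path) -> Path:
    """Long table: subject_id, window_index (1-based in reports), state."""
    rows = []
    for s in seqs:
        for wi, lab in zip(s.window_indices, s.labels):
            rows.append((s.subject_id, int(wi) + 1, int(lab)))
    return write_table(
        pd.DataFrame(rows, columns=["subject_id", "window_index", "state"]), path
    )


def read_state_sequences(path: str | Path) -> list[StateSequence]:
    df = read_table(path)
    seqs = []
    for sid, sub in df.groupby("subject_id", sort=False):
        seqs.append(
            StateSequence(
                subject_id=str(sid),
                labels=sub["state"].to_numpy(int),
                window_indices=sub["window_index"].to_numpy(int) - 1,
            )
        )
    return seqs
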