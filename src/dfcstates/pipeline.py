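"""End-to-end orchestration: dFC -> harmonize -> cluster -> metrics -> stats.

`run_cohort` drives the full analysis on in-memory objects (what the tests
and the acceptance script use); `run_pipeline` wraps it with disk I/O and a
run manifest so reruns with the same inputs, config and seed reproduce the
state-sequence files byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cluster as clus
from . import io as dio
from . import metrics as met
from . import stats as st
from .config import PipelineConfig
from .harmonize import BatchDesign, combat_adjust
from .types import DFCWindowSeries, StateModel, StateSequence, SubjectTimeSeries
from .windows import build_dfc_series, edge_to_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    series: list[DFCWindowSeries]
    model: StateModel
    sequences: list[StateSequence]
    metrics: pd.DataFrame
    stats: dict[str, pd.DataFrame]
    statewise_anova: dict | None
    elbow: list[tuple[int, float]] | None
    engagement: pd.DataFrame
    harmonized: bool
    combat_report: pd.DataFrame | None = None
    timings: dict[str, float] = field(default_factory=dict)


def temporal_metric_columns(k: int) -> list[str]:
    return (
        ["transitions"]
        + [f"occupancy_s{s}" for s in range(1, k + 1)]
        + [f"dwell_s{s}" for s in range(1, k + 1)]
    )


def transition_metric_columns(k: int) -> list[str]:
    return [f"t_{a}to{b}" for a in range(1, k + 1) for b in range(1, k + 1) if a != b]


def harmonize_series(
    series: list[DFCWindowSeries],
    cohort: pd.DataFrame,
    level: str = "window",
) -> tuple[list[DFCWindowSeries], pd.DataFrame]:
    """ComBat-harmonize windowed features across sites.

    "window" level treats every valid windowed edge vector as one
    observation carrying its subject's site, age and sex; "subject" level
    fits the adjustment on per-subject window means and applies the
    resulting location shift to that subject's windows.
    """
    info = cohort.set_index("subject_id")
    if level == "window":
        blocks, sites, ages, sexes = [], [], [], []
        for s in series:
            ve = s.valid_edges()
            blocks.append(ve)
            row = info.loc[s.subject_id]
            sites += [row["site"]] * len(ve)
            ages += [row["age"]] * len(ve)
            sexes += [1.0 if row["sex"] == "M" else 0.0] * len(ve)
        X = np.vstack(blocks)
        design = BatchDesign(
            batch=np.array(sites),
            covariates=pd.DataFrame({"age": ages, "sex": sexes}),
        )
        adjusted, params = combat_adjust(X, design)
        out = []
        pos = 0
        for s in series:
            n = int(s.valid.sum())
            edges = s.edges.copy()
            edges[s.valid] = adjusted[pos : pos + n]
            pos += n
            out.append(
                DFCWindowSeries(
                    subject_id=s.subject_id,
                    windows=s.windows,
                    edges=edges,
                    valid=s.valid,
                    node_labels=s.node_labels,
                )
            )
        return out, params.report()
    # subject level: adjust window-mean vectors, shift windows by the delta
    means = np.vstack([s.valid_edges().mean(axis=0) for s in series])
    rows = info.loc[[s.subject_id for s in series]]
    design = BatchDesign(
        batch=rows["site"].to_numpy(),
        covariates=pd.DataFrame(
            {
                "age": rows["age"].to_numpy(float),
                "sex": (rows["sex"] == "M").to_numpy(float),
            }
        ),
    )
    adjusted, params = combat_adjust(means, design)
    out = []
    for i, s in enumerate(series):
        edges = s.edges.copy()
        edges[s.valid] += adjusted[i] - means[i]
        out.append(
            DFCWindowSeries(
                subject_id=s.subject_id,
                windows=s.windows,
                edges=edges,
                valid=s.valid,
                node_labels=s.node_labels,
            )
        )
    return out, params.report()


def engagement_counts(
    sequences: list[StateSequence], cohort: pd.DataFrame, k: int
) -> pd.DataFrame:
    """Subjects per group who visit each state at least once."""
    grp = cohort.set_index("subject_id")["group"]
    rows = []
    for g in sorted(grp.unique()):
        counts = np.zeros(k, dtype=int)
        n_group = 0
        for seq in sequences:
            if grp.get(seq.subject_id) != g:
                continue
            n_group += 1
            for s in np.unique(seq.labels):
                counts[s - 1] += 1
        for s in range(k):
            rows.append(
                {"group": g, "state": s + 1, "n_engaged": int(counts[s]), "n_group": n_group}
            )
    return pd.DataFrame(rows)


def run_cohort(
    inputs: list[SubjectTimeSeries] | list[DFCWindowSeries],
    cohort: pd.DataFrame,
    cfg: PipelineConfig,
) -> PipelineResult:
    """The full analysis on in-memory inputs.

    ``inputs`` may be subject time series (windowing is applied) or
    pre-computed window series (windowing is skipped).
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if inputs and isinstance(inputs[0], SubjectTimeSeries):
        series = [build_dfc_series(ts, cfg) for ts in inputs]  # type: ignore[arg-type]
    else:
        series = list(inputs)  # type: ignore[assignment]
    for s in series:
        dropped = int((~s.valid).sum())
        if dropped:
            logger.info("subject %s: %d invalid windows flagged", s.subject_id, dropped)
    timings["dfc"] = time.perf_counter() - t0

    combat_report = None
    harmonized = False
    t0 = time.perf_counter()
    n_sites = cohort["site"].nunique()
    if cfg.harmonize and n_sites > 1:
        series, combat_report = harmonize_series(series, cohort, cfg.harmonize_level)
        harmonized = True
    elif cfg.harmonize:
        logger.info("single site: harmonization skipped")
    timings["harmonize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    exemplars = clus.pool_exemplars(series, cfg.exemplar_variance)
    all_windows = clus.pool_valid_windows(series)
    elbow = None
    if cfg.k == "auto":
        elbow = clus.elbow_curve(
            all_windows, cfg.k_range, replicates=min(cfg.replicates, 50),
            max_iter=cfg.max_iter, seed=cfg.seed,
        )
        k = clus.elbow_knee(elbow)
        logger.info("elbow criterion suggests k=%d", k)
    else:
        k = int(cfg.k)
    model = clus.kmeans_two_stage(
        exemplars, all_windows, k,
        replicates=cfg.replicates, max_iter=cfg.max_iter, seed=cfg.seed,
        node_labels=series[0].node_labels,
    )
    model = clus.relabel_model(model)
    timings["cluster"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sequences = [clus.assign_states(s, model) for s in series]
    all_metrics = [
        met.compute_metrics(s, q, k, cfg.node_subsets)
        for s, q in zip(series, sequences)
    ]
    metrics_df = pd.DataFrame([met.metrics_to_row(m) for m in all_metrics])
    timings["metrics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats_tables: dict[str, pd.DataFrame] = {}
    stats_tables["temporal"] = st.welch_family(
        metrics_df, cohort, temporal_metric_columns(k), family="temporal"
    )
    stats_tables["transitions"] = st.welch_family(
        metrics_df, cohort, transition_metric_columns(k), family="transitions"
    )
    fc_cols = [f"mean_fc_all_s{s}" for s in range(1, k + 1)]
    fc_mat = metrics_df[fc_cols].to_numpy(float)
    statewise_anova = None
    try:
        F, df1, df2, p, eps = st.rm_anova_gg(fc_mat)
        statewise_anova = {"F": F, "df1_gg": df1, "df2_gg": df2, "p": p, "epsilon": eps}
        stats_tables["statewise_posthoc"] = st.paired_posthoc(fc_mat)
    except ValueError as exc:
        logger.warning("state-wise RM-ANOVA skipped: %s", exc)
    try:
        stats_tables["adjusted"] = st.adjusted_family(
            metrics_df, cohort, temporal_metric_columns(k), family="temporal_adjusted"
        )
    except ValueError as exc:
        logger.warning("adjusted models skipped: %s", exc)
    for strata in ("medication", "episode"):
        if strata in cohort.columns and cohort[strata].notna().any():
            try:
                res = st.stratified_compare(
                    metrics_df, cohort, strata, temporal_metric_columns(k)
                )
                if not res.empty:
                    stats_tables[f"stratified_{strata}"] = res
            except ValueError as exc:
                logger.warning("stratified analysis %s skipped: %s", strata, exc)
    timings["stats"] = time.perf_counter() - t0

    return PipelineResult(
        config=cfg,
        series=series,
        model=model,
        sequences=sequences,
        metrics=metrics_df,
        stats=stats_tables,
        statewise_anova=statewise_anova,
        elbow=elbow,
        engagement=engagement_counts(sequences, cohort, k),
        harmonized=harmonized,
        combat_report=combat_report,
        timings=timings,
    )


# --- disk front-end ----------------------------------------------------------

def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_result(result: PipelineResult, output_dir: str | Path) -> dict[str, str]:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _save(name: str, df: pd.DataFrame) -> None:
        p = dio.write_table(df, out / name)
        artifacts[name] = str(p)

    dio.write_centroids(result.model, out / "centroids_edges.tsv")
    artifacts["centroids_edges.tsv"] = str(out / "centroids_edges.tsv")
    n_nodes = len(result.model.node_labels or [])
    if n_nodes:
        for s in range(result.model.k):
            mat = edge_to_matrix(result.model.centroids[s], n_nodes)
            _save(
                f"centroid_state{s + 1}.tsv",
                pd.DataFrame(mat, columns=result.model.node_labels),
            )
    dio.write_state_sequences(result.sequences, out / "state_sequences.tsv")
    artifacts["state_sequences.tsv"] = str(out / "state_sequences.tsv")
    _save("metrics.tsv", result.metrics)
    for name, df in result.stats.items():
        _save(f"stats_{name}.tsv", df)
    if result.statewise_anova is not None:
        _save("statewise_anova.tsv", pd.DataFrame([result.statewise_anova]))
    if result.elbow is not None:
        _save("elbow.tsv", pd.DataFrame(result.elbow, columns=["k", "wcss"]))
    if result.combat_report is not None:
        _save("combat_report.tsv", result.combat_report)
    _save("engagement.tsv", result.engagement)
    return artifacts


def run_pipeline(
    cfg: PipelineConfig, input_dir: str | Path, output_dir: str | Path
) -> dict:
    """Disk-to-disk run; returns (and writes) the run manifest."""
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    meta_path = input_dir / "metadata.tsv"
    cohort = dio.read_metadata(meta_path)
    ts_dir = input_dir / "timeseries"
    inputs = []
    hashes = {str(meta_path): _file_hash(meta_path)}
    for sid in cohort["subject_id"]:
        p = ts_dir / f"{sid}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"no time-series file for subject {sid}: {p}")
        inputs.append(dio.read_timeseries(p, tr_seconds=cfg.tr_seconds, subject_id=sid))
        hashes[str(p)] = _file_hash(p)
    result = run_cohort(inputs, cohort, cfg)
    artifacts = write_result(result, output_dir)
    manifest = {
        "config": cfg.to_dict(),
        "inputs": hashes,
        "seed": cfg.seed,
        "harmonized": result.harmonized,
        "k": result.model.k,
        "wcss": result.model.wcss,
        "stage_timings_s": {k: round(v, 3) for k, v in result.timings.items()},
        "versions": {
            "dfcstates": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": artifacts,
    }
    with open(output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
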