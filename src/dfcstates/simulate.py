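"""Synthetic cohorts with planted Markov-switching connectivity regimes.

The generator emulates the structure the pipeline is built to recover:
each subject's ROI signal alternates between k latent connectivity regimes
(a Markov chain at time-point resolution with a minimum segment length so
that sliding windows are regime-dominated); each regime is a zero-mean
multivariate Gaussian whose correlation matrix is Monte-Carlo calibrated so
the expected windowed mean Fisher-z matches that regime's target (defaults
0.198 / 0.106 / 0.288 for the moderate / hypoconnected / hyperconnected
states). Groups differ only in their transition matrices (patients have an
elevated self-transition for the hypoconnected regime), and sites perturb
the signal with a shared common-signal gain and extra white noise, which
induce additive and multiplicative shifts on the windowed edge features.

A companion window-level generator draws edge vectors directly from
Gaussian regime blobs (per-edge noise sd 1/sqrt(L-3), the Fisher-z sampling
sd at window length L) for clustering-recovery experiments where window
smearing at regime boundaries is not the object of study.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import io as dio
from .types import DFCWindowSeries, SubjectTimeSeries, WindowSpec

DEFAULT_TARGET_MEAN_Z = (0.198, 0.106, 0.288)  # states 1 (moderate), 2 (hypo), 3 (hyper)


@dataclass
class RegimeSpec:
    """Targets and construction parameters for the k connectivity regimes."""

    target_mean_z: tuple[float, ...] = DEFAULT_TARGET_MEAN_Z
    jitter: float = 0.04  # sd of off-diagonal pattern perturbation
    noise_sd: float = 0.2  # independent observation noise added to the signal
    window_length: int = 22  # window the calibration targets

    @property
    def k(self) -> int:
        return len(self.target_mean_z)


def _default_transition(k: int, self_stay: np.ndarray, hypo_pref: float = 0.65) -> np.ndarray:
    """Transition matrix with given self-transitions; off-mass favors state 2."""
    P = np.zeros((k, k))
    for s in range(k):
        off = 1.0 - self_stay[s]
        others = [j for j in range(k) if j != s]
        if k == 3 and s != 1:
            w = {1: hypo_pref}
            rest = (1.0 - hypo_pref) / (len(others) - 1)
            probs = [w.get(j, rest) for j in others]
        else:
            probs = [1.0 / len(others)] * len(others)
        P[s, s] = self_stay[s]
        for j, pj in zip(others, probs):
            P[s, j] = off * pj
    return P


@dataclass
class GroupDynamics:
    """Per-group Markov regime dynamics at time-point resolution."""

    transition: np.ndarray
    initial: np.ndarray | None = None
    min_segment: int = 10  # TRs; keeps 22-TR windows regime-dominated

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        k = self.transition.shape[0]
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix must be square")
        if (self.transition < 0).any() or not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must be non-negative and sum to 1")
        if self.initial is None:
            self.initial = _stationary(self.transition)
        else:
            self.initial = np.asarray(self.initial, dtype=float)

    @property
    def k(self) -> int:
        return self.transition.shape[0]

    @classmethod
    def control_default(cls) -> "GroupDynamics":
        return cls(_default_transition(3, np.array([0.90, 0.93, 0.90])))

    @classmethod
    def patient_default(cls) -> "GroupDynamics":
        return cls(_default_transition(3, np.array([0.90, 0.97, 0.90])))


def _stationary(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


@dataclass
class SiteModel:
    """Per-site signal perturbations inducing feature-level site effects.

    ``common_gain`` adds a site-specific shared signal component (raises all
    pairwise correlations, an additive shift on edge z); ``noise_gain`` adds
    site-specific white noise (attenuates correlations, a multiplicative
    compression of edge z). ``allocation`` gives per-site cohort fractions.
    """

    common_gain: tuple[float, ...] = (0.0, 0.3, 0.0)
    noise_gain: tuple[float, ...] = (0.0, 0.0, 0.35)
    allocation: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.common_gain) != len(self.noise_gain):
            raise ValueError("common_gain and noise_gain must have equal length")
        if self.allocation is None:
            self.allocation = tuple([1.0 / self.n_sites] * self.n_sites)
        if len(self.allocation) != self.n_sites or not np.isclose(sum(self.allocation), 1.0):
            raise ValueError("site allocation must have one fraction per site summing to 1")

    @property
    def n_sites(self) -> int:
        return len(self.common_gain)

    @classmethod
    def single_site(cls) -> "SiteModel":
        return cls(common_gain=(0.0,), noise_gain=(0.0,))


# --- regime covariance calibration -----------------------------------------

_CALIBRATION_CACHE: dict[tuple, np.ndarray] = {}


def _mc_mean_windowed_z(
    chol: np.ndarray, noise_sd: float, L: int, n_windows: int, rng: np.random.Generator
) -> float:
    N = chol.shape[0]
    x = rng.standard_normal((n_windows, L, N)) @ chol.T
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    xc = x - x.mean(axis=1, keepdims=True)
    cov = np.einsum("wli,wlj->wij", xc, xc)
    ss = np.einsum("wli,wli->wi", xc, xc)
    r = cov / np.sqrt(ss[:, :, None] * ss[:, None, :])
    iu = np.triu_indices(N, k=1)
    z = np.arctanh(np.clip(r[:, iu[0], iu[1]], -0.999999, 0.999999))
    return float(z.mean())


def _jittered_correlation(rho: float, N: int, rng: np.random.Generator, jitter: float) -> np.ndarray:
    R = np.full((N, N), rho)
    np.fill_diagonal(R, 1.0)
    if jitter > 0:
        G = rng.standard_normal((N, N)) * jitter
        G = (G + G.T) / 2.0
        np.fill_diagonal(G, 0.0)
        R = R + G
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 0.05, None)
    R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def build_regime_covariances(
    spec: RegimeSpec, N: int, seed: int, mc_windows: int = 10_000
) -> list[np.ndarray]:
    """Calibrated per-regime correlation matrices.

    Each regime's base correlation is tuned by Monte-Carlo (>= mc_windows
    windows of the target length through the full observation model, noise
    included) so the expected windowed mean edge z lands within +/-0.02 of
    the regime target. Results are cached per parameter set.
    """
    if N < 2:
        raise ValueError("need N >= 2 nodes")
    key = (spec.target_mean_z, spec.jitter, spec.noise_sd, spec.window_length, N, seed, mc_windows)
    if key in _CALIBRATION_CACHE:
        return [m.copy() for m in _CALIBRATION_CACHE[key]]
    out = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424243]))
    for regime_idx, target in enumerate(spec.target_mean_z):
        scale = 1.0 + spec.noise_sd**2  # white noise attenuates correlations
        rho = float(np.tanh(target)) * scale
        if not (-0.99 < rho < 0.99):
            raise ValueError(f"target mean z {target} infeasible for a PD correlation")
        R = None
        realized = np.inf
        for _ in range(6):
            R = _jittered_correlation(
                rho, N,
                np.random.default_rng(np.random.SeedSequence([seed, 7, regime_idx])),
                spec.jitter,
            )
            chol = np.linalg.cholesky(R)
            realized = _mc_mean_windowed_z(chol, spec.noise_sd, spec.window_length, mc_windows, rng)
            if abs(realized - target) < 0.005:
                break
            rho = float(np.clip(rho - (realized - target) * scale, -0.98, 0.98))
        if abs(realized - target) > 0.02:
            raise ValueError(
                f"calibration failed for target {target}: realized {realized:.3f}"
            )
        out.append(R)
    _CALIBRATION_CACHE[key] = [m.copy() for m in out]
    return out


# --- subject- and cohort-level generators -----------------------------------

def _sample_regime_path(
    dynamics: GroupDynamics, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Regime index (1-based) per time point, with a minimum segment length."""
    P = dynamics.transition
    k = dynamics.k
    path = np.empty(T, dtype=int)
    state = int(rng.choice(k, p=dynamics.initial))
    t = 0
    while t < T:
        p_stay = P[state, state]
        if p_stay >= 1.0:
            dur = T - t
        else:
            dur = dynamics.min_segment + int(rng.geometric(1.0 - p_stay)) - 1
        dur = min(dur, T - t)
        path[t : t + dur] = state + 1
        t += dur
        if t < T:
            off = P[state].copy()
            off[state] = 0.0
            off = off / off.sum()
            state = int(rng.choice(k, p=off))
    return path


def simulate_subject(
    dynamics: GroupDynamics,
    covariances: list[np.ndarray],
    T: int,
    seed: int | np.random.SeedSequence,
    noise_sd: float = 0.2,
    subject_id: str = "sim",
    node_labels: list[str] | None = None,
    common_gain: float = 0.0,
    noise_gain: float = 0.0,
) -> tuple[SubjectTimeSeries, np.ndarray]:
    """One subject's signal plus the planted regime path (1-based, length T)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    N = covariances[0].shape[0]
    labels = node_labels or [f"n{i + 1:02d}" for i in range(N)]
    chols = [np.linalg.cholesky(C) for C in covariances]
    path = _sample_regime_path(dynamics, T, rng)
    x = np.empty((T, N))
    z = rng.standard_normal((T, N))
    for s in range(1, dynamics.k + 1):
        mask = path == s
        if mask.any():
            x[mask] = z[mask] @ chols[s - 1].T
    x += noise_sd * rng.standard_normal((T, N))
    if common_gain != 0.0:
        x += common_gain * rng.standard_normal((T, 1))
    if noise_gain != 0.0:
        x += noise_gain * rng.standard_normal((T, N))
    ts = SubjectTimeSeries(subject_id=subject_id, data=x, node_labels=labels)
    return ts, path


def _draw_covariates(
    rng: np.random.Generator, group: str
) -> dict:
    age = float(np.clip(rng.normal(36.0, 13.5), 18, 65))
    sex = "M" if rng.random() < 0.37 else "F"
    mean_fd = float(np.clip(abs(rng.normal(0.09, 0.04)), 0.01, 0.199))
    row = {"age": age, "sex": sex, "mean_fd": mean_fd}
    if group == "patient":
        row["hamd"] = float(np.clip(rng.normal(21.2, 5.8), 8, 52))
        row["illness_duration_months"] = float(rng.exponential(55.0))
        if rng.random() < 0.70:  # clinical metadata available for a subset only
            row["medication"] = "medicated" if rng.random() < 0.47 else "unmedicated"
        if rng.random() < 0.70:
            row["episode"] = "first" if rng.random() < 0.78 else "recurrent"
    return row


def _path_window_stats(path: np.ndarray, k: int) -> dict:
    occ = np.bincount(path, minlength=k + 1)[1 : k + 1] / len(path)
    trans = int(np.sum(np.diff(path) != 0))
    out = {f"planted_occupancy_s{s + 1}": occ[s] for s in range(k)}
    out["planted_transitions"] = trans
    return out


def simulate_cohort(
    n_per_group: tuple[int, int],
    regime_spec: RegimeSpec | None = None,
    control_dynamics: GroupDynamics | None = None,
    patient_dynamics: GroupDynamics | None = None,
    site_model: SiteModel | None = None,
    T: int = 230,
    N: int = 21,
    seed: int = 0,
    noise_sd: float | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[SubjectTimeSeries], pd.DataFrame, pd.DataFrame, dict[str, np.ndarray]]:
    """Full synthetic cohort with planted truth.

    Returns (time series list, cohort metadata, truth table, regime paths);
    with ``out_dir`` set, also writes every artifact in the package's TSV
    formats plus truth_table.tsv and per-subject regime paths.
    """
    n_control, n_patient = n_per_group
    if n_control < 1 or n_patient < 1:
        raise ValueError("need at least one subject per group")
    regime_spec = regime_spec or RegimeSpec()
    control_dynamics = control_dynamics or GroupDynamics.control_default()
    patient_dynamics = patient_dynamics or GroupDynamics.patient_default()
    site_model = site_model or SiteModel.single_site()
    noise_sd = regime_spec.noise_sd if noise_sd is None else noise_sd
    k = regime_spec.k
    covs = build_regime_covariances(regime_spec, N, seed)

    n_total = n_control + n_patient

    def _alloc(n_group: int) -> np.ndarray:
        counts = np.floor(np.asarray(site_model.allocation) * n_group).astype(int)
        counts[0] += n_group - counts.sum()
        if counts.sum() != n_group or (counts < 0).any():
            raise ValueError("site allocation does not cover the cohort")
        return np.repeat(np.arange(site_model.n_sites), counts)

    # sites stratified within group: every site sees both groups, so site
    # adjustment cannot absorb the group effect
    site_of = np.concatenate([_alloc(n_control), _alloc(n_patient)])

    ss = np.random.SeedSequence([seed, 90210])
    subj_seeds = ss.spawn(n_total)
    cov_rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))

    series: list[SubjectTimeSeries] = []
    meta_rows, truth_rows = [], []
    paths: dict[str, np.ndarray] = {}
    for i in range(n_total):
        group = "control" if i < n_control else "patient"
        dyn = control_dynamics if group == "control" else patient_dynamics
        sid = f"{'con' if group == 'control' else 'pat'}{i + 1:04d}"
        site = int(site_of[i])
        ts, path = simulate_subject(
            dyn,
            covs,
            T,
            subj_seeds[i],
            noise_sd=noise_sd,
            subject_id=sid,
            common_gain=site_model.common_gain[site],
            noise_gain=site_model.noise_gain[site],
        )
        series.append(ts)
        paths[sid] = path
        row = {"subject_id": sid, "group": group, "site": f"site{site + 1}"}
        row.update(_draw_covariates(cov_rng, group))
        meta_rows.append(row)
        truth = {"subject_id": sid}
        truth.update(_path_window_stats(path, k))
        truth["regime_path_file"] = f"regime_paths/{sid}.tsv"
        truth_rows.append(truth)

    meta_cols = dio.REQUIRED_META_COLS + dio.OPTIONAL_META_COLS
    cohort = pd.DataFrame(meta_rows).reindex(columns=meta_cols)
    truth = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "timeseries").mkdir(parents=True, exist_ok=True)
        (out_dir / "regime_paths").mkdir(parents=True, exist_ok=True)
        for ts in series:
            dio.write_timeseries(ts, out_dir / "timeseries" / f"{ts.subject_id}.tsv")
        for sid, path in paths.items():
            dio.write_table(
                pd.DataFrame({"t": np.arange(1, len(path) + 1), "regime": path}),
                out_dir / "regime_paths" / f"{sid}.tsv",
            )
        dio.write_metadata(cohort, out_dir / "metadata.tsv")
        dio.write_table(truth, out_dir / "truth_table.tsv")
    return series, cohort, truth, paths


# --- window-level regime blobs ----------------------------------------------

def simulate_edge_windows(
    n_subjects: int,
    n_windows: int = 209,
    N: int = 21,
    target_mean_z: tuple[float, ...] = DEFAULT_TARGET_MEAN_Z,
    window_length: int = 22,
    pattern_sd: float = 0.03,
    self_stay: float = 0.9,
    seed: int = 0,
) -> tuple[list[DFCWindowSeries], dict[str, np.ndarray]]:
    """Edge vectors drawn directly from Gaussian regime blobs in E dims.

    Each regime's centroid is its target mean z plus a fixed zero-mean
    per-edge pattern; per-window noise is iid with sd 1/sqrt(L-3), the
    Fisher-z sampling sd at window length L. Regime labels follow a
    window-level Markov chain. Returns the per-subject window series and
    the planted window labels.
    """
    k = len(target_mean_z)
    E = N * (N - 1) // 2
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31337]))
    patterns = rng.standard_normal((k, E)) * pattern_sd
    patterns -= patterns.mean(axis=1, keepdims=True)
    centroids = np.asarray(target_mean_z)[:, None] + patterns
    sigma = 1.0 / np.sqrt(window_length - 3)
    dyn = GroupDynamics(_default_transition(k, np.full(k, self_stay)), min_segment=1)
    node_labels = [f"n{i + 1:02d}" for i in range(N)]
    series_list, labels = [], {}
    for i in range(n_subjects):
        sid = f"sub{i + 1:04d}"
        path = _sample_regime_path(dyn, n_windows, rng)
        edges = centroids[path - 1] + sigma * rng.standard_normal((n_windows, E))
        series_list.append(
            DFCWindowSeries(
                subject_id=sid,
                windows=[WindowSpec(start=j, length=window_length, index=j) for j in range(n_windows)],
                edges=edges,
                valid=np.ones(n_windows, dtype=bool),
                node_labels=node_labels,
            )
        )
        labels[sid] = path
    return series_list, labels


# --- recovery evaluation -----------------------------------------------------

def match_states(planted: np.ndarray, recovered: np.ndarray, k: int) -> dict[int, int]:
    """Best bijection planted regime -> recovered state (max label agreement)."""
    conf = np.zeros((k, k))
    for a, b in zip(planted, recovered):
        conf[a - 1, b - 1] += 1
    rows, cols = linear_sum_assignment(-conf)
    return {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index between two label vectors (pair-counting form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    conf = np.zeros((len(ua), len(ub)))
    np.add.at(conf, (ia, ib), 1)
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(conf).sum()
    sum_a = comb(conf.sum(axis=1)).sum()
    sum_b = comb(conf.sum(axis=0)).sum()
    total = comb(len(a))
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
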