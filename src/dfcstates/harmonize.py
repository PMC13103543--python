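"""Multisite harmonization of windowed connectivity features.

Implements the classic parametric empirical-Bayes location/scale batch
adjustment ("ComBat"): per feature, observations are standardized against a
covariate-adjusted grand model; per-batch location (gamma) and scale
(delta^2) estimates are shrunk toward pooled normal / inverse-gamma priors
by an iterative EB fixed point; the adjusted data subtract the shrunken
batch effects and restore the covariate model. Site is the batch variable
and age (standardized) and sex are the protected covariates, so biological
covariate effects survive the adjustment while additive and multiplicative
site effects are removed.

Observations here are windowed edge vectors, each carrying its subject's
site label (the default), or per-subject window means when harmonizing at
the subject level.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class BatchDesign:
    """Observation-to-batch assignment plus protected covariates.

    ``covariates`` columns are used as-is apart from ``age``, which is
    standardized to zero mean / unit variance for numerical conditioning
    (``sex`` is expected 0/1 coded).
    """

    batch: np.ndarray  # (n_obs,) site labels
    covariates: pd.DataFrame | None = None  # aligned to observations

    def __post_init__(self) -> None:
        self.batch = np.asarray(self.batch)
        if self.covariates is not None:
            if len(self.covariates) != len(self.batch):
                raise ValueError("covariates and batch must align")
            cov = self.covariates.astype(float).copy()
            if "age" in cov.columns:
                a = cov["age"]
                sd = a.std(ddof=0)
                cov["age"] = (a - a.mean()) / (sd if sd > 0 else 1.0)
            if not np.all(np.isfinite(cov.to_numpy())):
                raise ValueError("covariates must be finite")
            self.covariates = cov
        levels, counts = np.unique(self.batch, return_counts=True)
        if (counts < 2).any():
            small = levels[counts < 2].tolist()
            raise ValueError(f"every batch needs >= 2 observations; too small: {small}")
        self.levels = levels


@dataclass
class CombatParams:
    """Fitted per-batch EB parameters (for reporting)."""

    levels: list[str]
    gamma_star: np.ndarray  # (n_batch, n_features)
    delta_sq_star: np.ndarray  # (n_batch, n_features)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.levels,
                "mean_gamma_star": self.gamma_star.mean(axis=1),
                "mean_delta_star": np.sqrt(self.delta_sq_star).mean(axis=1),
            }
        )


def _eb_fixed_point(
    z_batch: np.ndarray,
    g_hat: np.ndarray,
    d_hat_sq: np.ndarray,
    g_bar: float,
    tau_sq: float,
    a_prior: float,
    b_prior: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB solution for one batch's gamma*, delta^2* across features."""
    n = z_batch.shape[0]
    g_star = g_hat.copy()
    d_star = d_hat_sq.copy()
    for _ in range(max_iter):
        g_new = (n * tau_sq * g_hat + d_star * g_bar) / (n * tau_sq + d_star)
        ss = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * ss + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_star) / np.maximum(np.abs(g_star), 1e-12)),
            np.max(np.abs(d_new - d_star) / np.maximum(np.abs(d_star), 1e-12)),
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


def combat_adjust(
    features: np.ndarray,
    design: BatchDesign,
    parametric: bool = True,
) -> tuple[np.ndarray, CombatParams]:
    """EB location/scale batch adjustment of an observations x features matrix.

    Returns the adjusted matrix (same shape and ordering as the input) and
    the fitted per-batch parameters. With a single batch the input is
    returned unchanged with a warning. A batch with zero variance in some
    feature falls back to location-only adjustment for that feature/batch.
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB variant is implemented")
    Y = np.asarray(features, dtype=float)
    if Y.ndim != 2:
        raise ValueError("features must be observations x features")
    if not np.all(np.isfinite(Y)):
        raise ValueError("features must be finite")
    levels = design.levels
    n_obs, n_feat = Y.shape
    if len(levels) < 2:
        warnings.warn("single batch: returning input unchanged", stacklevel=2)
        params = CombatParams(
            levels=list(map(str, levels)),
            gamma_star=np.zeros((1, n_feat)),
            delta_sq_star=np.ones((1, n_feat)),
        )
        return Y.copy(), params

    batch_onehot = (design.batch[:, None] == levels[None, :]).astype(float)
    n_per_batch = batch_onehot.sum(axis=0)
    if design.covariates is not None:
        X_cov = design.covariates.to_numpy(float)
        X = np.hstack([batch_onehot, X_cov])
    else:
        X_cov = np.zeros((n_obs, 0))
        X = batch_onehot
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    # grand model: per-feature OLS on batch one-hots + covariates
    B_hat, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_batch = len(levels)
    grand_mean = (n_per_batch / n_obs) @ B_hat[:n_batch]
    stand_mean = grand_mean[None, :] + X_cov @ B_hat[n_batch:]
    resid = Y - X @ B_hat
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.where(var_pooled <= 0, 1.0, var_pooled)
    sd_pooled = np.sqrt(var_pooled)

    Z = (Y - stand_mean) / sd_pooled

    gamma_star = np.zeros((n_batch, n_feat))
    delta_sq_star = np.ones((n_batch, n_feat))
    for i, level in enumerate(levels):
        mask = design.batch == level
        Zi = Z[mask]
        g_hat = Zi.mean(axis=0)
        d_hat_sq = Zi.var(axis=0, ddof=1)
        zero_var = d_hat_sq <= 0
        if zero_var.any():
            logger.warning(
                "batch %s: %d zero-variance features; location-only adjustment",
                level,
                int(zero_var.sum()),
            )
        g_bar = float(g_hat.mean())
        tau_sq = float(g_hat.var(ddof=1))
        m = float(d_hat_sq.mean())
        s2 = float(d_hat_sq.var(ddof=1))
        if s2 <= 0 or tau_sq <= 0:
            # no across-feature spread to pool over; use raw estimates
            g_star, d_star = g_hat, np.where(zero_var, 1.0, d_hat_sq)
        else:
            a_prior = (2.0 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            g_star, d_star = _eb_fixed_point(
                Zi, g_hat, np.where(zero_var, 1.0, d_hat_sq), g_bar, tau_sq,
                a_prior, b_prior,
            )
            d_star = np.where(zero_var, 1.0, d_star)
        gamma_star[i] = g_star
        delta_sq_star[i] = d_star

    adjusted = Z.copy()
    for i, level in enumerate(levels):
        mask = design.batch == level
        adjusted[mask] = (Z[mask] - gamma_star[i]) / np.sqrt(delta_sq_star[i])
    adjusted = adjusted * sd_pooled + stand_mean
    params = CombatParams(
        levels=list(map(str, levels)), gamma_star=gamma_star, delta_sq_star=delta_sq_star
    )
    return adjusted, params


def site_f_statistics(features: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Per-feature one-way ANOVA F statistic for the site factor.

    Used to quantify how much site-related variance harmonization removed.
    """
    Y = np.asarray(features, dtype=float)
    batch = np.asarray(batch)
    levels = np.unique(batch)
    n = Y.shape[0]
    grand = Y.mean(axis=0)
    ss_between = np.zeros(Y.shape[1])
    ss_within = np.zeros(Y.shape[1])
    for level in levels:
        Yi = Y[batch == level]
        mi = Yi.mean(axis=0)
        ss_between += Yi.shape[0] * (mi - grand) ** 2
        ss_within += ((Yi - mi) ** 2).sum(axis=0)
    df1 = len(levels) - 1
    df2 = n - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    return F
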