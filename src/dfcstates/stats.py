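"""Group-level statistical battery.

Between-group comparisons use Welch's two-sample t-test (unequal variances,
Satterthwaite degrees of freedom) with Benjamini-Hochberg FDR correction
within explicit test families and Hedges' g effect sizes (reported as
magnitudes; direction is carried by the sign of t, first group minus
second). Within-subject state comparisons use one-way repeated-measures
ANOVA with the Greenhouse-Geisser sphericity correction followed by paired
post-hoc t-tests (BH within the pair family). Covariate-adjusted group
effects come from OLS with age, sex, mean framewise displacement and site
dummies; exploratory stratified analyses compare each patient stratum
(medication / episode status) against the full control group.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group on one metric."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_values(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        return cls(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch's t, Satterthwaite df, two-sided p. Sign: first minus second."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        raise ZeroDivisionError("both group variances are zero; t undefined")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def hedges_g(a: GroupSummary, b: GroupSummary) -> float:
    """Bias-corrected standardized mean difference, reported as a magnitude."""
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if pooled_var == 0:
        raise ZeroDivisionError("pooled sd is zero; effect size undefined")
    d = abs(a.mean - b.mean) / np.sqrt(pooled_var)
    J = 1.0 - 3.0 / (4.0 * (a.n + b.n) - 9.0)
    return float(d * J)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return q


def chisq_2x2(table: np.ndarray, yates: bool = True) -> tuple[float, float, float]:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=yates)
    return float(chi2), float(df), float(p)


# --- repeated measures ------------------------------------------------------

def gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions."""
    values = np.asarray(values, dtype=float)
    k = values.shape[1]
    S = np.cov(values, rowvar=False, ddof=1)
    # double-center the covariance matrix
    row = S.mean(axis=0, keepdims=True)
    Sd = S - row - row.T + S.mean()
    num = np.trace(Sd) ** 2
    den = (k - 1) * np.sum(Sd**2)
    if den <= 0:  # identical conditions: no sphericity to correct
        return 1.0
    return float(num / den)


def rm_anova_gg(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """One-way within-subject ANOVA with GG-corrected degrees of freedom.

    ``values`` is subjects x conditions; rows with any missing value are
    dropped (listwise). Returns (F, df1_gg, df2_gg, p, epsilon).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix with >= 2 conditions")
    values = values[np.isfinite(values).all(axis=1)]
    n, k = values.shape
    if n < 3 or k < 3:
        raise ValueError("need >= 3 complete subjects and >= 3 conditions")
    grand = values.mean()
    cond_means = values.mean(axis=0)
    subj_means = values.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = values - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    total_ss = np.sum((values - grand) ** 2)
    if ss_cond <= 1e-12 * max(total_ss, 1e-300):  # identical condition means
        eps = gg_epsilon(values)
        return 0.0, eps * df1, eps * df2, 1.0, eps
    F = (ss_cond / df1) / (ss_err / df2)
    eps = gg_epsilon(values)
    p = float(sps.f.sf(F, eps * df1, eps * df2))
    return float(F), float(eps * df1), float(eps * df2), p, eps


def paired_posthoc(values: np.ndarray, state_names: list[str] | None = None) -> pd.DataFrame:
    """All pairwise paired t-tests between conditions, BH within the family.

    Uses pairwise-complete subjects per pair. Returns one row per ordered
    pair (a < b) with t, df, p, q, and the paired effect size d_z
    (mean difference / sd of differences, magnitude).
    """
    values = np.asarray(values, dtype=float)
    k = values.shape[1]
    names = state_names or [f"State {i + 1}" for i in range(k)]
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            pair = values[:, [a, b]]
            pair = pair[np.isfinite(pair).all(axis=1)]
            if pair.shape[0] < 2:
                raise ValueError(f"fewer than 2 complete pairs for {names[a]} vs {names[b]}")
            diff = pair[:, 0] - pair[:, 1]
            sd = diff.std(ddof=1)
            if sd == 0:
                # degenerate pair: zero spread of differences
                t_stat = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
                p_val = 1.0 if diff.mean() == 0 else 0.0
                dz = 0.0
            else:
                res = sps.ttest_rel(pair[:, 0], pair[:, 1])
                t_stat, p_val = float(res.statistic), float(res.pvalue)
                dz = abs(diff.mean()) / sd
            rows.append(
                {
                    "pair": f"{names[a]} vs {names[b]}",
                    "n": pair.shape[0],
                    "mean_diff": diff.mean(),
                    "t": t_stat,
                    "df": pair.shape[0] - 1,
                    "p": p_val,
                    "d_z": dz,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


# --- between-group batteries ------------------------------------------------

def welch_family(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    metric_cols: list[str],
    family: str,
    group_col: str = "group",
    first: str = "control",
    second: str = "patient",
) -> pd.DataFrame:
    """Welch t + Hedges g + BH-FDR over one family of metrics.

    Missing metric values (e.g. dwell of an unvisited state) are excluded
    listwise per metric. Sign convention: first group minus second.
    """
    merged = metrics.merge(cohort[["subject_id", group_col]], on="subject_id")
    rows = []
    for col in metric_cols:
        ga = merged.loc[merged[group_col] == first, col].to_numpy(float)
        gb = merged.loc[merged[group_col] == second, col].to_numpy(float)
        ga, gb = ga[np.isfinite(ga)], gb[np.isfinite(gb)]
        row = {
            "family": family,
            "metric": col,
            f"n_{first}": len(ga),
            f"mean_{first}": ga.mean() if len(ga) else np.nan,
            f"sd_{first}": ga.std(ddof=1) if len(ga) > 1 else np.nan,
            f"n_{second}": len(gb),
            f"mean_{second}": gb.mean() if len(gb) else np.nan,
            f"sd_{second}": gb.std(ddof=1) if len(gb) > 1 else np.nan,
            "t": np.nan,
            "df": np.nan,
            "p": np.nan,
            "g": np.nan,
        }
        if len(ga) >= 2 and len(gb) >= 2:
            sa, sb = GroupSummary.from_values(ga), GroupSummary.from_values(gb)
            try:
                row["t"], row["df"], row["p"] = welch_t(sa, sb)
                row["g"] = hedges_g(sa, sb)
            except ZeroDivisionError:
                pass
        rows.append(row)
    out = pd.DataFrame(rows)
    finite = np.isfinite(out["p"].to_numpy(float))
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite] = bh_fdr(out.loc[finite, "p"].to_numpy(float))
    out["q"] = q
    out["significant"] = out["q"] < 0.05
    return out


def _design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group indicator + age + sex + mean FD + site dummies (largest site ref)."""
    X = pd.DataFrame(index=cohort.index)
    X["group_patient"] = (cohort["group"] == "patient").astype(float)
    X["age"] = cohort["age"].astype(float)
    X["sex_M"] = (cohort["sex"] == "M").astype(float)
    X["mean_fd"] = cohort["mean_fd"].astype(float)
    sites = cohort["site"].astype(str)
    ref = sites.value_counts().idxmax()
    for s in sorted(sites.unique()):
        if s != ref:
            X[f"site_{s}"] = (sites == s).astype(float)
    return sm.add_constant(X, has_constant="add")


def adjusted_group_effect(
    y: np.ndarray, cohort: pd.DataFrame, metric: str
) -> dict:
    """OLS of one metric on group + age + sex + mean FD + site dummies."""
    y = np.asarray(y, dtype=float)
    cohort = cohort.reset_index(drop=True)
    keep = np.isfinite(y)
    X = _design_matrix(cohort[keep].reset_index(drop=True))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {metric}: columns {list(X.columns)}"
        )
    fit = sm.OLS(y[keep], X).fit()
    beta = fit.params["group_patient"]
    ci = fit.conf_int().loc["group_patient"]
    return {
        "metric": metric,
        "n": int(keep.sum()),
        "beta": float(beta),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p": float(fit.pvalues["group_patient"]),
    }


def adjusted_family(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    metric_cols: list[str],
    family: str,
) -> pd.DataFrame:
    """Covariate-adjusted group effects over one family, BH within it."""
    merged = metrics.merge(
        cohort[["subject_id", "group", "site", "age", "sex", "mean_fd"]],
        on="subject_id",
    ).reset_index(drop=True)
    rows = [
        adjusted_group_effect(merged[col].to_numpy(float), merged, col)
        for col in metric_cols
    ]
    out = pd.DataFrame(rows)
    out.insert(0, "family", family)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def stratified_compare(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    strata_col: str,
    metric_cols: list[str],
    adjusted: bool = True,
) -> pd.DataFrame:
    """Each patient stratum vs the full control group, FDR within stratum.

    Patients with a missing stratum label are excluded from the stratified
    runs only (they stay in the primary comparison). An empty stratum is
    skipped. Results stack the unadjusted Welch/Hedges family and, when
    requested, the covariate-adjusted family per stratum.
    """
    if strata_col not in cohort.columns:
        raise ValueError(f"cohort has no column {strata_col!r}")
    controls = cohort[cohort["group"] == "control"]
    out = []
    levels = sorted(cohort.loc[cohort["group"] == "patient", strata_col].dropna().unique())
    for level in levels:
        sub_pat = cohort[(cohort["group"] == "patient") & (cohort[strata_col] == level)]
        if sub_pat.empty:
            continue
        sub_cohort = pd.concat([controls, sub_pat], ignore_index=True)
        fam = f"{strata_col}={level}"
        res = welch_family(metrics, sub_cohort, metric_cols, family=fam)
        res.insert(1, "analysis", "unadjusted")
        out.append(res)
        if adjusted:
            adj = adjusted_family(metrics, sub_cohort, metric_cols, family=fam)
            adj.insert(1, "analysis", "adjusted")
            out.append(adj)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)
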