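import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from dfcstates.stats import (
    GroupSummary,
    adjusted_family,
    adjusted_group_effect,
    bh_fdr,
    chisq_2x2,
    gg_epsilon,
    hedges_g,
    paired_posthoc,
    rm_anova_gg,
    stratified_compare,
    welch_family,
    welch_t,
)


class TestWelch:
    def test_matches_scipy_summary_oracle(self, rng):
        for _ in range(25):
            x = rng.standard_normal(rng.integers(3, 30)) * rng.uniform(0.5, 3)
            y = rng.standard_normal(rng.integers(3, 30)) + rng.uniform(-1, 1)
            a, b = GroupSummary.from_values(x), GroupSummary.from_values(y)
            t, df, p = welch_t(a, b)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_group_swap_flips_sign_keeps_p(self, rng):
        a = GroupSummary(20, 1.2, 0.8)
        b = GroupSummary(35, 0.7, 1.5)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_identical_summaries(self):
        s = GroupSummary(30, 2.0, 1.0)
        t, _, p = welch_t(s, s)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_both_variances_zero(self):
        with pytest.raises(ZeroDivisionError):
            welch_t(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))


def brute_force_bh(p):
    """Textbook step-up: q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank, m + 1)), 1.0
        )
    return q


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.2])), [0.2])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        assert np.all(q >= p - 1e-15)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=9)
        perm = rng.permutation(9)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-15)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestHedges:
    def test_equal_means_zero(self):
        assert hedges_g(GroupSummary(10, 1.0, 0.5), GroupSummary(12, 1.0, 0.7)) == 0.0

    def test_zero_pooled_sd(self):
        with pytest.raises(ZeroDivisionError):
            hedges_g(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))

    def test_magnitude_and_small_sample_correction(self):
        g = hedges_g(GroupSummary(10, 1.0, 1.0), GroupSummary(10, 0.0, 1.0))
        assert g == pytest.approx(1.0 * (1 - 3 / (4 * 20 - 9)), abs=1e-12)
        # magnitude convention: order does not change g
        assert g == hedges_g(GroupSummary(10, 0.0, 1.0), GroupSummary(10, 1.0, 1.0))


class TestChiSquare:
    def test_diagonal_table_uncorrected(self):
        chi2, df, _ = chisq_2x2(np.array([[10, 0], [0, 10]]), yates=False)
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_proportional_table_is_zero(self):
        chi2, _, p = chisq_2x2(np.array([[20, 40], [10, 20]]), yates=False)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2(np.array([[0, 0], [5, 5]]))


class TestRMAnova:
    def test_matches_pingouin_oracle(self, rng):
        """F, GG epsilon and corrected p agree with pingouin's RM-ANOVA."""
        n, k = 25, 4
        values = rng.standard_normal((n, k)) + np.array([0.0, 0.3, 0.1, 0.5])
        F, df1, df2, p, eps = rm_anova_gg(values)
        long = pd.DataFrame(
            {
                "y": values.ravel(),
                "subject": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                          correction=True)
        assert F == pytest.approx(ref["F"].iloc[0], rel=1e-8)
        assert eps == pytest.approx(ref["eps"].iloc[0], rel=1e-6)
        assert p == pytest.approx(ref["p_GG_corr"].iloc[0], rel=1e-6)

    def test_compound_symmetry_epsilon_near_one(self, rng):
        n, k = 400, 3
        subject = rng.standard_normal((n, 1))
        values = subject + rng.standard_normal((n, k))
        _, df1, _, _, eps = rm_anova_gg(values)
        assert eps == pytest.approx(1.0, abs=0.02)
        assert df1 == pytest.approx(eps * (k - 1))

    def test_identical_columns_F_zero(self, rng):
        col = rng.standard_normal(20)
        F, _, _, p, _ = rm_anova_gg(np.column_stack([col, col, col]))
        assert F == 0.0
        assert p == pytest.approx(1.0)

    @given(hst.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_epsilon_bounds(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(3, 6))
        values = r.standard_normal((int(r.integers(5, 30)), k))
        eps = gg_epsilon(values)
        assert 1.0 / (k - 1) - 1e-9 <= eps <= 1.0 + 1e-9

    def test_listwise_deletion(self, rng):
        values = rng.standard_normal((30, 3))
        with_nan = values.copy()
        with_nan[::7, 1] = np.nan
        F1, *_ = rm_anova_gg(with_nan)
        F2, *_ = rm_anova_gg(values[~np.isnan(with_nan).any(axis=1)])
        assert F1 == pytest.approx(F2)


class TestPairedPosthoc:
    def test_equals_one_sample_t_on_differences(self, rng):
        values = rng.standard_normal((40, 3))
        res = paired_posthoc(values)
        for _, row in res.iterrows():
            i, j = [int(s.split()[1]) - 1 for s in row["pair"].split(" vs ")]
            ref = sps.ttest_1samp(values[:, i] - values[:, j], 0.0)
            assert row["t"] == pytest.approx(ref.statistic, abs=1e-10)
            assert row["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_columns_p_one(self, rng):
        a = rng.standard_normal(15)
        values = np.column_stack([a, a, rng.standard_normal(15)])
        res = paired_posthoc(values)
        row = res[res["pair"] == "State 1 vs State 2"].iloc[0]
        assert np.isnan(row["t"]) or row["p"] == pytest.approx(1.0)

    def test_planted_ordering_all_pairs_significant(self, rng):
        """State means spaced like the observed FC-strength levels separate
        cleanly in the within-subject post-hocs at cohort scale."""
        n = 600
        subject = rng.standard_normal((n, 1)) * 0.02
        means = np.array([0.198, 0.106, 0.288])
        values = means + subject + rng.standard_normal((n, 3)) * 0.04
        res = paired_posthoc(values)
        assert (res["q"] < 0.001).all()
        # and the planted ordering is visible in the mean differences
        ordered = values.mean(axis=0)
        assert ordered[1] < ordered[0] < ordered[2]


class TestAdjustedModels:
    def _cohort(self, rng, n, n_sites=3):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": rng.permutation(["control", "patient"] * (n // 2)),
                "site": [f"site{i % n_sites}" for i in range(n)],
                "age": rng.uniform(18, 65, n),
                "sex": rng.choice(["M", "F"], n),
                "mean_fd": rng.uniform(0.02, 0.2, n),
            }
        )

    def test_orthogonal_covariates_equal_mean_difference(self, rng):
        # balanced design: covariates identical across groups by construction
        n = 40
        cohort = self._cohort(rng, n, n_sites=1)
        half = cohort.copy()
        cohort["group"] = ["control"] * (n // 2) + ["patient"] * (n // 2)
        cohort["age"] = np.tile(rng.uniform(20, 60, n // 2), 2)
        cohort["sex"] = np.tile(rng.choice(["M", "F"], n // 2), 2)
        cohort["mean_fd"] = np.tile(rng.uniform(0.05, 0.15, n // 2), 2)
        y = rng.standard_normal(n)
        res = adjusted_group_effect(y, cohort, "m")
        pat = y[(cohort["group"] == "patient").to_numpy()]
        con = y[(cohort["group"] == "control").to_numpy()]
        assert res["beta"] == pytest.approx(pat.mean() - con.mean(), abs=1e-10)

    def test_planted_effect_with_site_confounding_is_covered(self, rng):
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 240
            cohort = self._cohort(rng, n)
            site_shift = cohort["site"].map({"site0": 0.0, "site1": 1.5, "site2": -1.0})
            y = (
                -2.0 * (cohort["group"] == "patient").to_numpy(float)
                + site_shift.to_numpy(float)
                + 0.05 * cohort["age"].to_numpy(float)
                + rng.standard_normal(n) * 2.0
            )
            res = adjusted_group_effect(y, cohort, "m")
            if res["ci_low"] <= -2.0 <= res["ci_high"]:
                hits += 1
        assert hits / reps >= 0.85  # nominal 95% coverage

    def test_rank_deficiency_reported(self, rng):
        cohort = self._cohort(rng, 20, n_sites=1)
        cohort["mean_fd"] = cohort["age"]  # perfectly collinear
        with pytest.raises(ValueError, match="rank-deficient"):
            adjusted_group_effect(rng.standard_normal(20), cohort, "m")

    def test_null_type_I_error_near_alpha(self, rng):
        rejections = 0
        reps = 400
        n = 80
        for _ in range(reps):
            cohort = self._cohort(rng, n)
            y = rng.standard_normal(n)
            if adjusted_group_effect(y, cohort, "m")["p"] < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.025)


class TestStratified:
    def _metrics(self, rng, cohort, effect_stratum=None):
        y = rng.standard_normal(len(cohort))
        if effect_stratum is not None:
            mask = (cohort["group"] == "patient") & (
                cohort["medication"] == effect_stratum
            )
            y = y + 2.0 * mask.to_numpy(float)
        return pd.DataFrame({"subject_id": cohort["subject_id"], "m": y})

    def _cohort(self, rng, n_control=150, n_patient=150):
        n = n_control + n_patient
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["control"] * n_control + ["patient"] * n_patient,
                "site": [f"site{i % 2}" for i in range(n)],
                "age": rng.uniform(18, 65, n),
                "sex": rng.choice(["M", "F"], n),
                "mean_fd": rng.uniform(0.02, 0.2, n),
            }
        )
        med = np.array([None] * n, dtype=object)
        med[n_control:] = rng.choice(
            ["medicated", "unmedicated", None], n_patient, p=[0.4, 0.4, 0.2]
        )
        df["medication"] = med
        return df

    def test_effect_only_in_affected_stratum(self, rng):
        cohort = self._cohort(rng)
        metrics = self._metrics(rng, cohort, effect_stratum="unmedicated")
        res = stratified_compare(metrics, cohort, "medication", ["m"], adjusted=False)
        unmed = res[(res["family"] == "medication=unmedicated")]
        med = res[(res["family"] == "medication=medicated")]
        assert (unmed["q"] < 0.05).all()
        assert (med["q"] > 0.05).all()

    def test_full_patient_stratum_reproduces_primary(self, rng):
        cohort = self._cohort(rng)
        cohort["medication"] = np.where(
            cohort["group"] == "patient", "medicated", None
        )
        metrics = self._metrics(rng, cohort)
        strat = stratified_compare(metrics, cohort, "medication", ["m"], adjusted=False)
        primary = welch_family(metrics, cohort, ["m"], family="primary")
        assert strat["t"].iloc[0] == pytest.approx(primary["t"].iloc[0])

    def test_missing_status_excluded_from_strata_only(self, rng):
        cohort = self._cohort(rng)
        metrics = self._metrics(rng, cohort)
        res = stratified_compare(metrics, cohort, "medication", ["m"], adjusted=False)
        n_in_strata = res.loc[res["analysis"] == "unadjusted", "n_patient"].sum()
        n_with_status = cohort.loc[
            (cohort["group"] == "patient") & cohort["medication"].notna()
        ].shape[0]
        assert n_in_strata == n_with_status
        primary = welch_family(metrics, cohort, ["m"], family="primary")
        assert primary["n_patient"].iloc[0] == (cohort["group"] == "patient").sum()
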