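"""KM/log-rank, Cox, adjusted KM, bootstrap lasso-Cox, chi-square, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sig32.errors import InputError
from sig32.survival import (
    adjusted_km,
    anova_oneway,
    chisq_independence,
    contingency,
    cox_fit,
    km_logrank,
    lasso_cox_bootstrap,
)

# Printed stratified counts used throughout: rows are categories, columns the
# four molecular subtypes of the 567-patient discovery cohort.
AGE_TABLE = [[43, 53, 90, 89], [71, 76, 72, 73]]
SEX_TABLE = [[77, 93, 114, 102], [37, 36, 48, 60]]
STAGE_TABLE = [[10, 3, 7, 1], [33, 36, 33, 45], [69, 87, 115, 108], [2, 3, 7, 8]]
ICI_TABLE = [[10, 2, 7, 4], [11, 22, 7, 27]]


class TestKMLogrank:
    def test_identical_groups_give_null_statistic(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(50, 40)
        e = (rng.random(40) < 0.7).astype(int)
        time = np.r_[t, t]
        event = np.r_[e, e]
        group = np.r_[np.zeros(40), np.ones(40)]
        _, stat, p = km_logrank(time, event, group)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            km_logrank(np.ones(5), np.ones(5, dtype=int), np.ones(5))

    def test_power_at_hazard_ratio_two(self):
        """HR 2 with n=250/group and ~40% censoring is detected at p<0.01."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            t1 = rng.exponential(100, 250)
            t2 = rng.exponential(50, 250)
            c = rng.uniform(0, 240, 500)
            time = np.minimum(np.r_[t1, t2], c)
            event = (np.r_[t1, t2] <= c).astype(int)
            group = np.r_[np.zeros(250), np.ones(250)]
            _, _, p = km_logrank(time, event, group)
            hits += p < 0.01
        assert hits >= 95

    def test_two_group_statistic_matches_chi2_tail(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(60, 120)
        event = np.ones(120, dtype=int)
        group = rng.integers(0, 2, 120)
        _, stat, p = km_logrank(time, event, group)
        assert p == pytest.approx(stats.chi2.sf(stat, df=1), rel=1e-9)

    def test_planted_prognosis_ordering_on_default_cohort(self, default_cohort):
        from sig32.survival import km_at

        clin = default_cohort.clinical
        sub = default_cohort.true_subtype
        surv5 = [
            km_at(clin["time_months"][sub == g], clin["event"][sub == g], 60.0)
            for g in (1, 2, 3, 4)
        ]
        assert surv5 == sorted(surv5, reverse=True)


class TestCox:
    def test_null_covariate_ci_coverage(self):
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(rep)
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(50, n)
            e = (rng.random(n) < 0.7).astype(int)
            res = cox_fit(t, e, pd.DataFrame({"x": x}))
            lo, hi = res.summary.loc[0, ["ci_lower", "ci_upper"]]
            hits += lo <= 1.0 <= hi
        assert hits >= 180  # nominal 95% with Monte-Carlo slack

    def test_recovers_rate_ratio_two(self):
        rng = np.random.default_rng(42)
        n = 1000
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.where(g == 1, 50, 100))
        e = np.ones(n, dtype=int)
        res = cox_fit(t, e, pd.DataFrame({"g": g.astype(float)}))
        assert 1.8 <= res.summary.loc[0, "hazard_ratio"] <= 2.2

    def test_reference_level_convention(self):
        rng = np.random.default_rng(2)
        n = 150
        grp = rng.choice(["1", "2", "3"], n)
        t = rng.exponential(50, n)
        e = np.ones(n, dtype=int)
        res = cox_fit(t, e, pd.DataFrame({"group": grp}), reference={"group": "1"})
        assert res.reference_levels == {"group": "1"}
        assert set(res.summary["term"]) == {"group[2]", "group[3]"}

    def test_constant_covariate_rejected(self):
        with pytest.raises(InputError):
            cox_fit(np.arange(1.0, 11.0), np.ones(10, dtype=int),
                    pd.DataFrame({"x": np.ones(10)}))


class TestAdjustedKM:
    def test_matches_unadjusted_prediction_without_confounders(self):
        rng = np.random.default_rng(3)
        n = 200
        arm = rng.integers(0, 2, n)
        t = rng.exponential(np.where(arm == 1, 80, 40))
        e = (rng.random(n) < 0.8).astype(int)
        curves = adjusted_km(t, e, arm.astype(str))
        # with treatment as the only covariate the marginal curve equals the
        # Cox-predicted curve of any single subject in that arm
        fit = cox_fit(t, e, pd.DataFrame({"treatment": arm.astype(str)}))
        for level in ("0", "1"):
            design = fit.design.iloc[:1].copy()
            design.iloc[0] = 1.0 if level == "1" else 0.0
            pred = fit.model.predict_survival_function(design).iloc[:, 0]
            got = curves[curves["treatment"] == level].set_index("time")["survival"]
            assert np.allclose(got.to_numpy(), pred.to_numpy(), atol=1e-6)

    def test_balanced_confounder_matches_km(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(4)
        n = 2000
        z = rng.integers(0, 2, n)  # balanced covariate, independent of arm
        arm = rng.integers(0, 2, n)
        rate = 0.01 * np.exp(0.7 * z - 0.5 * arm)
        t = rng.exponential(1 / rate)
        e = np.ones(n, dtype=int)
        curves = adjusted_km(t, e, arm.astype(str),
                             covariates=pd.DataFrame({"z": z.astype(str)}))
        for level in ("0", "1"):
            kmf = KaplanMeierFitter().fit(t[arm == int(level)], e[arm == int(level)])
            adj = curves[curves["treatment"] == level].set_index("time")["survival"]
            km_on_grid = kmf.survival_function_at_times(adj.index.to_numpy()).to_numpy()
            assert np.abs(adj.to_numpy() - km_on_grid).max() < 0.03

    def test_treatment_effect_recovered_in_stratum(self):
        """Planted treatment log-HR log(0.28) is inside the Cox CI >= 90% of reps."""
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(500 + rep)
            n = 150
            treated = rng.random(n) < 0.5
            age = rng.integers(0, 2, n)
            rate = 0.02 * np.exp(np.log(0.28) * treated + 0.3 * age)
            death = rng.exponential(1 / rate)
            censor = rng.uniform(0, 120, n)
            e = (death <= censor).astype(int)
            t = np.minimum(death, censor)
            res = cox_fit(t, e, pd.DataFrame({
                "treatment": np.where(treated, "FU+platinum", "none"),
                "age": age.astype(str)}), reference={"treatment": "none"})
            row = res.summary.set_index("term").loc["treatment[FU+platinum]"]
            hits += row["ci_lower"] <= 0.28 <= row["ci_upper"]
        assert hits >= 45


class TestLassoCoxBootstrap:
    @staticmethod
    def _data(n=300, seed=0, signal=0.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"x{i}" for i in range(5)])
        rate = 0.02 * np.exp(signal * X["x0"].to_numpy())
        death = rng.exponential(1 / rate)
        censor = rng.uniform(0, 150, n)
        e = (death <= censor).astype(int)
        return np.minimum(death, censor), e, X

    def test_single_resample_degenerate_ci(self):
        t, e, X = self._data(n=150, seed=1)
        out = lasso_cox_bootstrap(t, e, X, B=1, seed=2)
        assert np.allclose(out["ci_lower"], out["ci_upper"])

    def test_null_covariates_rarely_significant(self):
        t, e, X = self._data(n=300, seed=3, signal=0.0)
        out = lasso_cox_bootstrap(t, e, X, B=200, seed=4)
        assert (out["p"] > 0.05).mean() >= 0.9

    def test_signal_covariate_detected(self):
        t, e, X = self._data(n=400, seed=5, signal=0.8)
        out = lasso_cox_bootstrap(t, e, X, B=100, seed=6).set_index("term")
        assert out.loc["x0", "hazard_ratio"] > 1.3
        assert out.loc["x0", "p"] < 0.05

    def test_zero_resamples_rejected(self):
        t, e, X = self._data(n=60, seed=7)
        with pytest.raises(InputError):
            lasso_cox_bootstrap(t, e, X, B=0)


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, expected_p",
        [(AGE_TABLE, 0.003), (SEX_TABLE, 0.346), (STAGE_TABLE, 0.021), (ICI_TABLE, 0.001)],
    )
    def test_printed_tables_reproduced(self, table, expected_p):
        _, _, p = chisq_independence(np.array(table))
        assert round(p, 3) == expected_p

    def test_proportional_rows_independent(self):
        _, _, p = chisq_independence(np.array([[10, 20, 30], [20, 40, 60]]))
        assert p == pytest.approx(1.0)

    def test_permutation_invariance_and_integer_scaling(self):
        table = np.array(STAGE_TABLE)
        s0, df0, _ = chisq_independence(table)
        s1, df1, _ = chisq_independence(table[::-1, ::-1])
        assert s1 == pytest.approx(s0) and df1 == df0
        s3, df3, _ = chisq_independence(3 * table)
        assert s3 == pytest.approx(3 * s0) and df3 == df0

    def test_zero_marginal_rejected(self):
        with pytest.raises(InputError):
            chisq_independence(np.array([[0, 0], [1, 2]]))

    def test_missing_rows_excluded_before_tabulation(self):
        clin = pd.DataFrame({
            "lauren": ["Diffuse", "Intestinal", "Missing", "Diffuse", None],
            "group": [1, 1, 2, 2, 2],
        })
        table = contingency(clin, "lauren", "group")
        assert int(table.to_numpy().sum()) == 3


class TestANOVA:
    def test_identical_groups_near_null(self):
        x = np.r_[np.arange(10.0), np.arange(10.0)]
        g = np.repeat([0, 1], 10)
        f, p = anova_oneway(x, g)
        assert f == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_power_two_sd_shift(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            x = np.r_[rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
            g = np.repeat([0, 1], 50)
            _, p = anova_oneway(x, g)
            hits += p < 1e-6
        assert hits >= 49

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=60)
        g = np.repeat([0, 1], 30)
        f, p_f = anova_oneway(x, g)
        t, p_t = stats.ttest_ind(x[g == 0], x[g == 1])
        assert f == pytest.approx(t**2, abs=1e-9)
        assert p_f == pytest.approx(p_t, abs=1e-9)

    def test_degenerate_equal_constant_groups(self):
        f, p = anova_oneway(np.zeros(10), np.repeat([0, 1], 5))
        assert (f, p) == (0.0, 1.0)
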