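"""Statistical kernels against closed forms, enumeration and permutation nulls."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from akipipe.errors import DegenerateTableError
from akipipe.stats import (
    ContingencyTable,
    chi_square,
    km_logrank,
    logistic_fit,
    percentage,
    power_simulation,
    rate_table,
    rate_table_from_counts,
    wilcoxon_rank_sum,
)
from helpers_oracles import chi2_permutation_p, rank_sum_enumeration


class TestRateTable:
    # printed row counts: stratum, n, aki, deaths_aki, deaths_no_aki
    PRINTED = pd.DataFrame(
        [
            ("All", 8564, 6034, 353, 22),
            ("OPCAB", 3990, 2593, 65, 2),
            ("ON-CABG", 234, 201, 24, 2),
            ("Aortic surgery", 244, 187, 18, 0),
            ("AV-Repair", 75, 40, 1, 0),
            ("AV-Replacement", 733, 504, 13, 1),
            ("MV-Repair", 472, 230, 2, 0),
            ("MV-Replacement", 143, 109, 11, 0),
            ("TV-Surgery", 39, 29, 3, 0),
        ],
        columns=["stratum", "n", "aki", "deaths_aki", "deaths_no_aki"],
    )

    def test_reproduces_printed_percentages(self):
        out = rate_table_from_counts(self.PRINTED).set_index("stratum")
        expect_aki = {
            "All": 70.5, "OPCAB": 65.0, "ON-CABG": 85.9, "Aortic surgery": 76.6,
            "AV-Repair": 53.3, "AV-Replacement": 68.8, "MV-Repair": 48.7,
            "MV-Replacement": 76.2, "TV-Surgery": 74.4,
        }
        for stratum, pct in expect_aki.items():
            assert round(out.loc[stratum, "aki_pct"], 1) == pct
        expect_mort_aki = {
            "All": 5.9, "OPCAB": 2.5, "ON-CABG": 11.9, "Aortic surgery": 9.6,
            "AV-Repair": 2.5, "AV-Replacement": 2.6, "MV-Repair": 0.9,
            "MV-Replacement": 10.1, "TV-Surgery": 10.3,
        }
        for stratum, pct in expect_mort_aki.items():
            assert round(out.loc[stratum, "mortality_aki_pct"], 1) == pct
        assert round(out.loc["All", "mortality_no_aki_pct"], 1) == 0.9
        assert round(out.loc["All", "mortality_pct"], 1) == 4.4
        assert round(out.loc["All", "no_aki_pct"], 1) == 29.5

    def test_empty_stratum_is_na_not_zero(self):
        counts = pd.DataFrame(
            [("empty", 0, 0, 0, 0)],
            columns=["stratum", "n", "aki", "deaths_aki", "deaths_no_aki"],
        )
        out = rate_table_from_counts(counts)
        assert np.isnan(out["aki_pct"].iloc[0])
        assert np.isnan(out["mortality_aki_pct"].iloc[0])

    def test_percentage_helper(self):
        assert percentage(1, 4) == 25.0
        assert np.isnan(percentage(0, 0))

    def test_aggregation_from_episode_frame(self):
        frame = pd.DataFrame(
            {
                "procedure": ["A", "A", "A", "B"],
                "aki": [True, True, False, False],
                "death": [True, False, False, False],
            }
        )
        out = rate_table(frame).set_index("stratum")
        assert out.loc["All", "n"] == 4 and out.loc["All", "aki"] == 2
        assert out.loc["A", "aki_pct"] == pytest.approx(100 * 2 / 3)
        assert out.loc["A", "mortality_aki_pct"] == pytest.approx(50.0)
        assert np.isnan(out.loc["B", "mortality_aki_pct"])


class TestChiSquare:
    def test_identical_rows_statistic_zero(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], [[10, 20], [10, 20]])
        stat, df, p = chi_square(t)
        assert stat == pytest.approx(0.0)
        assert df == 1 and p == pytest.approx(1.0)

    def test_printed_mortality_comparison(self):
        """5.9% vs 0.9% mortality on the printed 2x2 is overwhelmingly significant."""
        t = ContingencyTable(
            ["AKI", "no AKI"], ["died", "survived"], [[353, 5681], [22, 2508]]
        )
        stat, df, p = chi_square(t)
        assert p < 0.0001
        assert stat > 0

    def test_zero_expected_raises(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], [[0, 5], [0, 7]])
        with pytest.raises(DegenerateTableError):
            chi_square(t)

    def test_matches_scipy(self):
        from scipy.stats import chi2_contingency

        counts = [[12, 8], [5, 25]]
        stat, df, p = chi_square(ContingencyTable(["a", "b"], ["x", "y"], counts))
        ref = chi2_contingency(np.array(counts), correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_against_permutation_null(self, rng):
        """Asymptotic p tracks the permutation mid-p on small tables.

        A discrete conditional null cannot agree with the continuous
        chi-square reference to Monte-Carlo error; the mid-p adjustment
        bounds the residual discreteness gap at ~0.1 in this size range.
        """
        for _ in range(3):
            counts = rng.integers(8, 18, size=(2, 2))
            stat, df, p = chi_square(ContingencyTable(["a", "b"], ["x", "y"], counts))
            p_perm = chi2_permutation_p(counts, reps=20_000, seed=int(rng.integers(1 << 30)))
            mc_se = math.sqrt(max(p_perm * (1 - p_perm), 1e-6) / 20_000)
            assert abs(p - p_perm) <= max(0.10, 4 * mc_se)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        w, p = wilcoxon_rank_sum([1, 1, 1], [1, 1, 1])
        assert p == 1.0

    def test_statistic_matches_enumeration(self):
        w, _ = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        w_enum, _ = rank_sum_enumeration([1, 2, 3], [4, 5, 6])
        assert w == w_enum == 6.0

    def test_matches_scipy_mannwhitney(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 25)
        w, p = wilcoxon_rank_sum(x, y)
        u = mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(u.pvalue, rel=1e-6)
        assert w == pytest.approx(u.statistic + 20 * 21 / 2)

    def test_power_close_to_exact_test(self, rng):
        """Under a shift alternative, rejection tracks the exact test."""
        reject_approx = reject_exact = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(0, 1, 12)
            y = rng.normal(1.2, 1, 12)
            _, p = wilcoxon_rank_sum(x, y)
            p_exact = mannwhitneyu(x, y, method="exact").pvalue
            reject_approx += p < 0.05
            reject_exact += p_exact < 0.05
        assert abs(reject_approx - reject_exact) / reps < 0.06


class TestKaplanMeier:
    def test_no_events_survival_one_logrank_na(self):
        est = km_logrank([5, 6, 7, 8], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert (est.curves["survival"] == 1.0).all()
        assert np.isnan(est.logrank_stat) and np.isnan(est.logrank_p)

    def test_no_censoring_equals_empirical_survivor(self, rng):
        times = rng.integers(1, 20, 40).astype(float)
        events = np.ones(40, dtype=int)
        est = km_logrank(times, events)
        for _, row in est.curves.iterrows():
            if row["time"] == 0:
                continue
            empirical = (times > row["time"]).mean()
            assert row["survival"] == pytest.approx(empirical)

    def test_hand_computed_product_limit(self):
        # deaths at t=1,2,4; censored at t=3
        est = km_logrank([1, 2, 3, 4], [1, 1, 0, 1], None)
        surv = dict(zip(est.curves["time"], est.curves["survival"]))
        assert surv[1.0] == pytest.approx(0.75)
        assert surv[2.0] == pytest.approx(0.5)
        assert surv[4.0] == pytest.approx(0.0)

    def test_two_strata_logrank_significant(self):
        times = [1, 2, 3, 4, 20, 21, 22, 23]
        events = [1, 1, 1, 1, 1, 1, 1, 1]
        strata = ["x"] * 4 + ["y"] * 4
        est = km_logrank(times, events, strata)
        assert est.logrank_p < 0.05

    def test_survival_monotone_within_stratum(self, rng):
        times = rng.exponential(5, 50)
        events = rng.integers(0, 2, 50)
        strata = rng.choice(["a", "b"], 50)
        est = km_logrank(times, events, strata)
        for _, grp in est.curves.groupby("stratum"):
            s = grp.sort_values("time")["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((s >= 0) & (s <= 1))


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70, dtype=float)
        result = logistic_fit(y, pd.DataFrame(index=range(100)))
        assert result.terms.loc["intercept", "coef"] == pytest.approx(
            math.log(0.3 / 0.7), abs=1e-8
        )

    def test_two_by_two_cross_product_ratio(self):
        a, b, c, d = 20, 30, 10, 40  # exposed-dead, exposed-alive, unexp-dead, unexp-alive
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        result = logistic_fit(y, pd.DataFrame({"x": x}))
        assert result.terms.loc["x", "coef"] == pytest.approx(
            math.log(a * d / (b * c)), abs=1e-8
        )
        assert result.terms.loc["x", "or"] == pytest.approx(a * d / (b * c), abs=1e-7)
        assert not result.separated

    def test_wald_ci_brackets_or(self):
        y = np.array([1] * 25 + [0] * 25 + [1] * 10 + [0] * 40, dtype=float)
        x = np.array([1] * 50 + [0] * 50, dtype=float)
        result = logistic_fit(y, pd.DataFrame({"x": x}))
        row = result.terms.loc["x"]
        assert row["ci_low"] <= row["or"] <= row["ci_high"]
        assert row["or"] == pytest.approx(math.exp(row["coef"]))

    def test_complete_separation_flagged_no_ci(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        y = x.copy()
        result = logistic_fit(y, pd.DataFrame({"x": x}))
        assert result.separated
        assert np.isnan(result.terms.loc["x", "ci_low"])
        assert np.isnan(result.terms.loc["x", "p"])

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.integers(0, 2, n).astype(float)})
        eta = -1.0 + 0.8 * X["a"] - 0.5 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        mine = logistic_fit(y, X)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert mine.terms["coef"].to_numpy() == pytest.approx(ref.params.to_numpy(), abs=1e-6)
        assert mine.terms["se"].to_numpy() == pytest.approx(ref.bse.to_numpy(), abs=1e-6)


class TestPowerSimulation:
    def test_null_rejection_near_alpha(self):
        result = power_simulation(
            n=8564, exposure_prev=0.705, overall_mortality=0.044,
            odds_ratio=1.0, alpha=0.05, reps=2000, seed=4,
        )
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(result.power - 0.05) <= 3 * se

    def test_large_effect_power_near_one(self):
        result = power_simulation(
            n=8564, exposure_prev=0.705, overall_mortality=0.044,
            odds_ratio=3.0, alpha=0.05, reps=500, seed=1,
        )
        assert result.power > 0.99

    def test_against_two_proportion_normal_approximation(self):
        from scipy.special import expit, logit
        from scipy.stats import norm

        n, prev, mort, or_, alpha = 8564, 0.705, 0.044, 1.30, 0.005
        result = power_simulation(n, prev, mort, or_, alpha=alpha, reps=4000, seed=2)
        # closed-form two-proportion Wald approximation at the same calibration
        from akipipe.stats import _calibrate_intercept

        a = _calibrate_intercept(prev, mort, math.log(or_))
        p1, p0 = expit(a + math.log(or_)), expit(a)
        n1, n0 = n * prev, n * (1 - prev)
        se = math.sqrt(
            1 / (n1 * p1) + 1 / (n1 * (1 - p1)) + 1 / (n0 * p0) + 1 / (n0 * (1 - p0))
        )
        z_a = norm.ppf(1 - alpha / 2)
        effect = abs(math.log(or_))
        analytic = norm.sf(z_a - effect / se) + norm.cdf(-z_a - effect / se)
        assert result.power == pytest.approx(analytic, abs=0.05)

    def test_se_formula(self):
        result = power_simulation(1000, 0.5, 0.1, 1.5, reps=400, seed=3)
        assert result.mc_se == pytest.approx(
            math.sqrt(result.power * (1 - result.power) / 400)
        )
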