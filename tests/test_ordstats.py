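"""Proportional-odds regression, its assumption check, and the
supporting nonparametric tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcdyn.ordstats import (fit_proportional_odds, measure_correlations,
                            proportional_odds_check, rank_sum_compare,
                            run_cohort_analysis)

from _oracles import logistic_newton, ranksum_exact_z


def _po_sample(rng, n, beta=1.0, thresholds=(-0.8, 1.0)):
    x = rng.standard_normal(n)
    z = beta * x + rng.logistic(size=n)
    return np.digitize(z, thresholds), x


class TestFit:
    def test_binary_outcome_matches_newton_logistic_oracle(self):
        """With two levels the cumulative-logit MLE reduces to ordinary
        logistic regression; compare against a hand-rolled Newton solver."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(400)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.random(400) < p).astype(int)
        res = fit_proportional_odds(y, x, standardize=False)
        a_or, b_or = logistic_newton(x.tolist(), y.tolist())
        # P(Y<=0) = logistic(zeta - x beta) vs P(y=1) = logistic(a + b x)
        assert res.beta[0] == pytest.approx(b_or, abs=1e-4)
        assert res.intercepts[0] == pytest.approx(-a_or, abs=1e-4)

    def test_reversed_order_inverts_odds_ratio_exactly(self):
        rng = np.random.default_rng(1)
        y, x = _po_sample(rng, 300)
        labels = np.array(["lo", "mid", "hi"])[y]
        fwd = fit_proportional_odds(labels, x, order=["lo", "mid", "hi"])
        rev = fit_proportional_odds(labels, x, order=["hi", "mid", "lo"])
        # equality is exact at the MLE; agreement here is to optimizer
        # precision
        assert rev.beta[0] == pytest.approx(-fwd.beta[0], abs=1e-4)
        assert rev.odds_ratio[0] == pytest.approx(1 / fwd.odds_ratio[0],
                                                  rel=1e-3)

    def test_null_effect_gives_unit_odds_ratio(self):
        """beta=0 data: |OR - 1| < 0.15 on average over 50 seeds at n=500
        per level."""
        rng = np.random.default_rng(2)
        devs = []
        for _ in range(50):
            y, x = _po_sample(rng, 1500, beta=0.0)
            res = fit_proportional_odds(y, x)
            devs.append(abs(res.odds_ratio[0] - 1.0))
        assert np.mean(devs) < 0.15

    def test_recovers_planted_coefficient(self):
        """Latent-variable ordinal data with beta=1: bias below 0.1 at
        n=2000 (average over 10 seeds)."""
        rng = np.random.default_rng(3)
        betas = []
        for _ in range(10):
            y, x = _po_sample(rng, 2000, beta=1.0)
            res = fit_proportional_odds(y, x, standardize=False)
            betas.append(res.beta[0])
        assert abs(np.mean(betas) - 1.0) < 0.1

    def test_loglike_beats_intercept_only(self):
        rng = np.random.default_rng(4)
        y, x = _po_sample(rng, 500)
        res = fit_proportional_odds(y, x)
        _, counts = np.unique(y, return_counts=True)
        ll_null = float((counts * np.log(counts / counts.sum())).sum())
        assert res.loglike >= ll_null

    def test_one_sided_p_halved_when_direction_matches(self):
        rng = np.random.default_rng(5)
        y, x = _po_sample(rng, 400, beta=1.0)
        two = fit_proportional_odds(y, x, sided="two")
        greater = fit_proportional_odds(y, x, sided="greater")
        less = fit_proportional_odds(y, x, sided="less")
        assert greater.p_value[0] == pytest.approx(two.p_value[0] / 2)
        assert less.p_value[0] == pytest.approx(1 - two.p_value[0] / 2)

    def test_wald_ci_brackets_odds_ratio(self):
        rng = np.random.default_rng(6)
        y, x = _po_sample(rng, 300)
        res = fit_proportional_odds(y, x)
        assert res.ci_low[0] <= res.odds_ratio[0] <= res.ci_high[0]

    def test_single_level_outcome_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            fit_proportional_odds(np.zeros(20), np.random.default_rng(7)
                                  .standard_normal(20))


class TestProportionalOddsCheck:
    def test_lr_statistic_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            y, x = _po_sample(rng, 200)
            assert proportional_odds_check(y, x).lr_stat >= 0.0

    def test_type_one_error_near_nominal(self):
        """Under proportional-odds data (n=1000) the LR check rejects at
        5% within +/-2% over 200 simulations."""
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(200):
            y, x = _po_sample(rng, 1000)
            if proportional_odds_check(y, x).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 200 <= 0.07

    def test_power_against_non_parallel_slopes(self):
        """Grossly level-specific slopes are rejected in > 80% of runs."""
        rng = np.random.default_rng(10)
        rejections = 0
        n_sims = 30
        for _ in range(n_sims):
            n = 1000
            x = rng.standard_normal(n)
            f1 = 1 / (1 + np.exp(-(-0.8 - 0.0 * x)))
            f2 = 1 / (1 + np.exp(-(1.0 - 1.5 * x)))
            f2 = np.maximum(f1, f2)
            u = rng.random(n)
            y = np.where(u < f1, 0, np.where(u < f2, 1, 2))
            if proportional_odds_check(y, x).p_value < 0.05:
                rejections += 1
        assert rejections / n_sims > 0.8

    def test_two_level_outcome_has_no_relaxation(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 100)
        with pytest.raises(ValueError):
            proportional_odds_check(y, rng.standard_normal(100))


class TestCorrelationsAndRankSum:
    def test_self_and_monotone_transform_correlation(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal(30)
        table = pd.DataFrame({"a": a, "b": np.exp(a), "c":
                              rng.standard_normal(30)})
        rho, p = measure_correlations(table)
        assert rho.loc["a", "a"] == 1.0
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] < 1e-6

    def test_independent_columns_rarely_exceed_half(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(200):
            table = pd.DataFrame(rng.standard_normal((59, 2)),
                                 columns=["x", "y"])
            rho, _ = measure_correlations(table)
            hits += abs(rho.loc["x", "y"]) < 0.5
        assert hits / 200 > 0.95

    def test_constant_column_flagged(self):
        table = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.warns(UserWarning):
            rho, _ = measure_correlations(table)
        assert np.isnan(rho.loc["x", "y"])

    def test_identical_groups_null(self):
        z, p = rank_sum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(14)
        a = rng.standard_normal(12) + 10
        b = rng.standard_normal(12)
        _, p = rank_sum_compare(a, b)
        assert p < 0.001

    def test_matches_exact_enumeration_for_small_groups(self):
        """z equals the exhaustive-permutation z (ties included) for all
        group sizes up to 6."""
        rng = np.random.default_rng(15)
        for _ in range(10):
            n1, n2 = rng.integers(3, 7), rng.integers(3, 7)
            a = rng.integers(0, 5, n1).astype(float)
            b = rng.integers(0, 5, n2).astype(float)
            if np.unique(np.concatenate([a, b])).size == 1:
                continue
            z, _ = rank_sum_compare(a, b)
            assert z == pytest.approx(ranksum_exact_z(a.tolist(), b.tolist()),
                                      abs=1e-10)

    def test_all_tied_gives_p_one(self):
        z, p = rank_sum_compare(np.ones(5), np.ones(7))
        assert (z, p) == (0.0, 1.0)


class TestRunCohortAnalysis:
    @staticmethod
    def _table(rng, effect=1.0, n_per=(12, 11, 18, 18)):
        rows = []
        for rank, (cond, n) in enumerate(zip(("UWS", "MCS", "SED", "CON"),
                                             n_per)):
            for i in range(n):
                rows.append({"subject_id": f"{cond}-{i}", "condition": cond,
                             "measure": "m1",
                             "value": effect * rank + rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(16)
        res = run_cohort_analysis(self._table(rng),
                                  ["UWS", "MCS", "SED", "CON"])
        assert len(res) == 1
        assert res.loc[0, "odds_ratio"] > 1
        assert res.loc[0, "p_value"] < 0.01

    def test_single_condition_rejected(self):
        rng = np.random.default_rng(17)
        table = self._table(rng)
        table["condition"] = "CON"
        with pytest.raises(ValueError, match="2 levels"):
            run_cohort_analysis(table, ["UWS", "MCS", "SED", "CON"])

    def test_label_permutation_null_centres_odds_ratio(self):
        """Shuffling condition labels destroys the effect: the median OR
        over 50 permutations is near 1."""
        rng = np.random.default_rng(18)
        table = self._table(rng)
        ors = []
        for _ in range(50):
            shuffled = table.copy()
            shuffled["condition"] = rng.permutation(
                table["condition"].to_numpy())
            res = run_cohort_analysis(shuffled, ["UWS", "MCS", "SED", "CON"])
            ors.append(res.loc[0, "odds_ratio"])
        assert abs(np.log(np.median(ors))) < 0.35

    def test_joint_covariate_model(self):
        rng = np.random.default_rng(19)
        t1 = self._table(rng)
        t2 = t1.copy()
        t2["measure"] = "m2"
        t2["value"] = rng.standard_normal(len(t2))
        table = pd.concat([t1, t2], ignore_index=True)
        res = run_cohort_analysis(table, ["UWS", "MCS", "SED", "CON"],
                                  joint=[["m1", "m2"]])
        assert set(res["covariates"]) == {"m1", "m2", "m1+m2"}
        joint_rows = res[res["covariates"] == "m1+m2"]
        assert len(joint_rows) == 2
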