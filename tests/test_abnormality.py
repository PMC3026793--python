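"""Abnormality-score procedure: residuals, leave-one-out control models
(against brute-force per-fold refits), standardization, aggregation, and
the single-case modified t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import t as t_dist

from cpdeficits import abnormality, glmm, synthetic
from cpdeficits.calibration import NULL_SPEC, attach_covariates


class TestCaseResiduals:
    @pytest.fixture(scope="class")
    def fitted(self, control_data):
        return glmm.fit_glmm(NULL_SPEC, control_data)

    def test_zero_residual_when_observed_equals_expected(self):
        r = abnormality.Residual("p", "t", observed=0.75, expected=0.75)
        assert r.residual == 0.0

    def test_arithmetic(self):
        r = abnormality.Residual("p", "t", observed=0.60, expected=0.75)
        assert r.residual == pytest.approx(-0.15)

    def test_monotone_in_observed_performance(self, fitted, cohort):
        cases = cohort["data"][cohort["data"]["group"] == "CP"]
        one = cases[cases["participant_id"] == cases["participant_id"].iloc[0]].copy()
        res_low = abnormality.case_residuals(fitted, one)
        better = one.copy()
        better["correct"] = 1
        res_high = abnormality.case_residuals(fitted, better)
        assert res_high["residual"].iloc[0] > res_low["residual"].iloc[0]

    def test_response_scale_residual_is_proportion_difference(self, fitted, cohort):
        cases = cohort["data"][cohort["data"]["group"] == "CP"]
        res = abnormality.case_residuals(fitted, cases, scale="response")
        obs = cases.groupby("participant_id")["correct"].mean()
        assert np.allclose(res["observed"], obs.reindex(res.index))
        assert res["expected"].between(0, 1).all()
        assert np.allclose(res["residual"], res["observed"] - res["expected"])

    def test_out_of_support_covariates_flagged_not_refused(self, fitted, cohort):
        cases = cohort["data"][cohort["data"]["group"] == "CP"].copy()
        cases["age_c"] = 9.0  # age 130: far outside any control
        res = abnormality.case_residuals(fitted, cases)
        assert res["flagged"].all()
        assert res["residual"].notna().all()


class TestLOOResiduals:
    def test_identical_controls_give_zero_residuals(self):
        # 5 controls, identical covariates and identical performance
        rows = []
        for pid in "abcde":
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "correct": [1, 1, 1, 0] * 25,
                        "age_c": 0.0,
                    }
                )
            )
        data = pd.concat(rows, ignore_index=True)
        # identical covariates leave only the intercept estimable
        spec = glmm.ModelSpec(fixed=(), random_intercept=False)
        loo, _ = abnormality.loo_control_residuals(spec, data)
        assert np.allclose(loo["residual"], 0.0, atol=1e-8)

    def test_loo_mean_near_zero_and_variance_inflated(self):
        """Across simulated null cohorts the response-scale LOO residuals
        average to ~0 (their expectation under the marginal prediction)
        and their variance is at least the optimistic plug-in variance."""
        means, logit_means, loo_vars, plugin_vars = [], [], [], []
        cfg = synthetic.GenerativeConfig(n_controls=20, n_cp=0)
        design = synthetic.StudyDesign(repetitions_per_part=4)
        for rep in range(30):
            p = synthetic.generate_participants(cfg, seed=500 + rep)
            t = synthetic.simulate_experiment(p, design, cfg, seed=500 + rep)
            data = attach_covariates(t, p)
            loo, full = abnormality.loo_control_residuals(NULL_SPEC, data, scale="response")
            plug = abnormality.case_residuals(full, data, scale="response")
            loo_l, _ = abnormality.loo_control_residuals(NULL_SPEC, data, full_fit=full)
            means.append(loo["residual"].mean())
            logit_means.append(loo_l["residual"].mean())
            loo_vars.append(loo["residual"].var(ddof=1))
            plugin_vars.append(plug["residual"].var(ddof=1))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 0.005
        assert abs(np.mean(logit_means)) < 0.1  # small Jensen curvature only
        assert np.mean(loo_vars) >= np.mean(plugin_vars)

    def test_loo_matches_brute_force_refits(self):
        """Zero random variance, single covariate: every leave-one-out fold
        must agree with an independent direct likelihood maximization."""
        cfg = synthetic.GenerativeConfig(n_controls=8, n_cp=0, sigma_intercept=0.0)
        p = synthetic.generate_participants(cfg, seed=77)
        t = synthetic.simulate_experiment(
            p, synthetic.StudyDesign(repetitions_per_part=2), cfg, seed=77
        )
        data = attach_covariates(t, p)
        spec = glmm.ModelSpec(fixed=("age_c",), random_intercept=False)
        loo, _ = abnormality.loo_control_residuals(spec, data, scale="response")

        def brute_force(pid):
            rest = data[data["participant_id"] != pid]
            X = np.column_stack([np.ones(len(rest)), rest["age_c"]])
            y = rest["correct"].to_numpy()

            def nll(beta):
                eta = X @ beta
                return -(y * eta - np.logaddexp(0, eta)).sum()

            beta = minimize(nll, np.zeros(2), method="BFGS", options={"gtol": 1e-10}).x
            held = data[data["participant_id"] == pid]
            eta = beta[0] + beta[1] * held["age_c"].to_numpy()
            return held["correct"].mean() - expit(eta).mean()

        for pid in loo.index:
            assert loo.loc[pid, "residual"] == pytest.approx(brute_force(pid), abs=1e-6)

    def test_too_few_controls_rejected(self, control_data):
        two = control_data[control_data["participant_id"].isin(["C01", "C02"])]
        with pytest.raises(ValueError, match="at least 3"):
            abnormality.loo_control_residuals(NULL_SPEC, two)


class TestStandardize:
    def test_case_at_control_mean_maps_to_zero(self):
        ctl = pd.Series([0.1, 0.2, 0.3])
        z = abnormality.standardize(ctl, pd.Series([0.2]))
        assert z.iloc[0] == pytest.approx(0.0)

    def test_worked_example(self):
        ctl = pd.Series([-1.0, 0.0, 1.0])  # sample sd 1
        z = abnormality.standardize(ctl, pd.Series([-2.0]))
        assert z.iloc[0] == pytest.approx(-2.0)

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        ctl = pd.Series(rng.normal(size=12))
        allr = pd.Series(rng.normal(size=20))
        z1 = abnormality.standardize(ctl, allr)
        z2 = abnormality.standardize(a * ctl + b, a * allr + b)
        assert np.allclose(z1, z2, atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            abnormality.standardize(pd.Series([0.5, 0.5, 0.5]), pd.Series([1.0]))

    def test_control_columns_standardized_by_construction(self, control_data):
        loo, _ = abnormality.loo_control_residuals(NULL_SPEC, control_data)
        z = abnormality.standardize(loo["residual"], loo["residual"])
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestAggregation:
    def _cmap(self, aggregates):
        tests = {
            "t1": ("perceptual", "faces"), "t2": ("perceptual", "faces"),
            "t3": ("mnestic", "faces"),
        }
        return abnormality.CategoryMap(tests=tests, aggregates=aggregates)

    def test_single_column_aggregate_is_restandardized_member(self):
        rng = np.random.default_rng(2)
        ctl_ids = [f"C{i}" for i in range(10)]
        z = pd.DataFrame({"t1": rng.normal(size=12)}, index=ctl_ids + ["P1", "P2"])
        z["t1"] = abnormality.standardize(z.loc[ctl_ids, "t1"], z["t1"])
        out = abnormality.aggregate_scores(z, self._cmap({"agg": ("t1",)}), ctl_ids)
        assert np.allclose(out["agg"], out["t1"], atol=1e-10)

    def test_perfectly_correlated_members_collapse(self):
        rng = np.random.default_rng(3)
        ctl_ids = [f"C{i}" for i in range(10)]
        base = pd.Series(rng.normal(size=12), index=ctl_ids + ["P1", "P2"])
        base = abnormality.standardize(base.loc[ctl_ids], base)
        z = pd.DataFrame({"t1": base, "t2": base})
        out = abnormality.aggregate_scores(z, self._cmap({"agg": ("t1", "t2")}), ctl_ids)
        assert np.allclose(out["agg"], z["t1"], atol=1e-10)

    def test_fully_missing_participant_stays_missing(self):
        ctl_ids = [f"C{i}" for i in range(6)]
        rng = np.random.default_rng(4)
        z = pd.DataFrame(
            {"t1": rng.normal(size=7), "t2": rng.normal(size=7)}, index=ctl_ids + ["P1"]
        )
        z.loc["P1", ["t1", "t2"]] = np.nan
        out = abnormality.aggregate_scores(z, self._cmap({"agg": ("t1", "t2")}), ctl_ids)
        assert np.isnan(out.loc["P1", "agg"])
        assert out.loc[ctl_ids, "agg"].notna().all()

    def test_empty_aggregate_rejected(self):
        with pytest.raises(ValueError, match="zero columns"):
            self._cmap({"agg": ()}).validate()

    def test_default_map_is_consistent(self):
        cmap = abnormality.default_category_map()
        cmap.validate()
        assert set(cmap.aggregates["overall"]) == set(cmap.tests)


class TestDeficitTest:
    def test_zero_score_is_not_deficit(self):
        call = abnormality.crawford_deficit_test(0.0, 25)
        assert call.t_statistic == 0.0
        assert call.p == pytest.approx(0.5)
        assert not call.is_deficit

    def test_boundary_at_five_percent_quantile(self):
        n = 25
        t05 = t_dist.ppf(0.05, n - 1)
        z = t05 * np.sqrt((n + 1) / n)
        call = abnormality.crawford_deficit_test(z, n)
        assert call.p == pytest.approx(0.05, abs=1e-10)
        slightly_worse = abnormality.crawford_deficit_test(z - 1e-6, n)
        assert slightly_worse.is_deficit

    def test_far_tail_is_deficit(self):
        call = abnormality.crawford_deficit_test(-5.0, 25)
        assert call.is_deficit and call.p < 1e-4

    def test_supra_normal_performance_is_not_deficit(self):
        assert not abnormality.crawford_deficit_test(5.0, 25).is_deficit

    def test_small_control_sample_rejected(self):
        with pytest.raises(ValueError):
            abnormality.crawford_deficit_test(-2.0, 1)


def test_direction_flip_on_ingestion():
    """Reaction-time-like columns (larger = worse) must be negated so that
    negative z always means a deficit."""
    ctl_ids = [f"C{i}" for i in range(10)]
    rng = np.random.default_rng(5)
    scores = pd.DataFrame(
        {
            "participant_id": ctl_ids + ["P1"],
            "rt": np.concatenate([rng.normal(size=10), [4.0]]),  # P1 is very slow
        }
    )
    z = abnormality.ingest_external_z(scores, ctl_ids, higher_is_better={"rt": False})
    assert z.loc["P1", "rt"] < -2
    assert z.loc[ctl_ids, "rt"].mean() == pytest.approx(0.0, abs=1e-10)
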