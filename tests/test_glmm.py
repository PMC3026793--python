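"""Mixed-model machinery: design building, Laplace fits against external
oracles (statsmodels GLM, lme4 glmer), likelihood-ratio bookkeeping,
marginal prediction, and posterior summaries."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cpdeficits import glmm, synthetic
from cpdeficits.calibration import MAIN_SPEC, NULL_SPEC, attach_covariates


@pytest.fixture(scope="module")
def faces_data(cohort):
    return cohort["data"]


@pytest.fixture(scope="module")
def main_fit(faces_data):
    return glmm.fit_glmm(MAIN_SPEC, faces_data)


@pytest.fixture(scope="module")
def null_fit(faces_data):
    return glmm.fit_glmm(NULL_SPEC, faces_data)


class TestDesign:
    def test_treatment_coding_and_reference_levels(self, faces_data):
        X, names, _ = glmm.build_design(faces_data, MAIN_SPEC)
        assert names == [
            "(Intercept)", "age_c", "trial_type[target]", "rotation[rotated]", "group[CP]",
        ]
        assert set(np.unique(X[:, 2])) <= {0.0, 1.0}

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effect"):
            glmm.ModelSpec(fixed=("age_c", "group:trial_type"))

    def test_missing_covariate_rejected(self, faces_data):
        spec = glmm.ModelSpec(fixed=("nonexistent",))
        with pytest.raises(ValueError, match="covariate"):
            glmm.fit_glmm(spec, faces_data)


class TestFit:
    def test_determinism(self, faces_data, main_fit):
        again = glmm.fit_glmm(MAIN_SPEC, faces_data)
        assert np.array_equal(again.coef.to_numpy(), main_fit.coef.to_numpy())
        assert again.log_likelihood == main_fit.log_likelihood

    def test_glm_path_matches_statsmodels(self, faces_data):
        """With no random terms the fit is a plain logistic regression;
        statsmodels GLM is the independent oracle."""
        import statsmodels.api as sm

        spec = glmm.ModelSpec(fixed=MAIN_SPEC.fixed, random_intercept=False)
        fit = glmm.fit_glmm(spec, faces_data)
        X, names, _ = glmm.build_design(faces_data, spec)
        ref = sm.GLM(faces_data["correct"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coef.to_numpy(), ref.params, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_mixed_fit_matches_lme4(self, faces_data, main_fit, tmp_path):
        """lme4::glmer (Laplace) is the independent oracle for the mixed fit."""
        csv = tmp_path / "d.csv"
        faces_data[["participant_id", "correct", "age_c", "trial_type", "rotation", "group"]].to_csv(
            csv, index=False
        )
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$trial_type <- relevel(factor(d$trial_type), ref="distractor")
            d$rotation <- relevel(factor(d$rotation), ref="frontal")
            d$group <- relevel(factor(d$group), ref="control")
            m <- glmer(correct ~ age_c + trial_type + rotation + group + (1|participant_id),
                       data=d, family=binomial)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        )
        vals = [float(x) for x in out.stdout.split()]
        ref_coef, ref_sd, ref_ll = np.array(vals[:5]), vals[5], vals[6]
        assert np.allclose(main_fit.coef.to_numpy(), ref_coef, atol=0.03)
        assert main_fit.random_sd["participant"] == pytest.approx(ref_sd, abs=0.01)
        assert main_fit.log_likelihood == pytest.approx(ref_ll, abs=0.1)

    def test_parameter_recovery_within_ci(self):
        """A large cohort simulated at beta_CP = -1.0 recovers the group
        effect within its 95% confidence bound."""
        cfg = synthetic.GenerativeConfig(
            n_controls=100, n_cp=100, beta_cp=-1.0, beta_cp_trial=0.0,
            beta_cp_rotation=0.0, sigma_intercept=0.0,
        )
        p = synthetic.generate_participants(cfg, seed=21)
        design = synthetic.StudyDesign(repetitions_per_part=3)  # 120 trials each
        t = synthetic.simulate_experiment(p, design, cfg, seed=21)
        fit = glmm.fit_glmm(MAIN_SPEC, attach_covariates(t, p))
        est, se = fit.coef["group[CP]"], fit.coef_se["group[CP]"]
        assert abs(est - (-1.0)) < 1.96 * se + 0.05

    def test_random_slope_model_fits(self, cohort):
        spec = glmm.ModelSpec(
            fixed=("age_c", "trial_type", "rotation"), random_intercept=True,
            random_slope="trial_type",
        )
        cfg = synthetic.GenerativeConfig(sigma_trial_slope=0.8, n_controls=20, n_cp=0)
        p = synthetic.generate_participants(cfg, seed=31)
        t = synthetic.simulate_experiment(p, synthetic.StudyDesign(), cfg, seed=31)
        fit = glmm.fit_glmm(spec, attach_covariates(t, p))
        assert fit.converged
        assert set(fit.random_sd) == {"participant", "participant:trial_type"}
        # the slope variance is detectable and the intercept sd stays near truth
        assert fit.random_sd["participant:trial_type"] > 0.3
        assert abs(fit.random_sd["participant"] - cfg.sigma_intercept) < 0.5


class TestLRTest:
    def test_identical_fits_give_zero(self, null_fit):
        res = glmm.lr_test(null_fit, null_fit)
        assert res.D == 0.0 and res.p == 1.0 and res.df == 0

    def test_df_counts_added_terms(self, faces_data, null_fit):
        full = glmm.fit_glmm(
            glmm.ModelSpec(
                fixed=NULL_SPEC.fixed + ("group", "group:trial_type", "group:rotation")
            ),
            faces_data,
        )
        main = glmm.fit_glmm(
            glmm.ModelSpec(fixed=NULL_SPEC.fixed + ("group",)), faces_data
        )
        assert glmm.lr_test(null_fit, main).df == 1
        assert glmm.lr_test(main, full).df == 2

    def test_likelihood_monotone_in_parameters(self, faces_data, null_fit, main_fit):
        assert main_fit.log_likelihood >= null_fit.log_likelihood - 1e-6

    def test_non_nested_rejected(self, faces_data, main_fit):
        other = glmm.fit_glmm(glmm.ModelSpec(fixed=("age_c",)), faces_data.head(4000))
        with pytest.raises(ValueError):
            glmm.lr_test(other, main_fit)


class TestPredict:
    def test_zero_variance_is_plain_inverse_logit(self, faces_data):
        spec = glmm.ModelSpec(fixed=MAIN_SPEC.fixed, random_intercept=False)
        fit = glmm.fit_glmm(spec, faces_data)
        X, _, _ = glmm.build_design(faces_data.head(10), spec, fit.levels)
        assert np.allclose(
            glmm.predict_expected(fit, faces_data.head(10)),
            expit(X @ fit.coef.to_numpy()),
        )

    def test_symmetry_at_zero_linear_predictor(self, main_fit, faces_data):
        m = glmm.FittedModel(
            spec=main_fit.spec,
            coef=pd.Series(0.0, index=main_fit.coef.index),
            coef_se=main_fit.coef_se,
            random_sd={"participant": 1.3},
            log_likelihood=0.0, converged=True, n_obs=1, n_groups=1,
            levels=main_fit.levels,
        )
        p = glmm.predict_expected(m, faces_data.head(5))
        assert np.allclose(p, 0.5, atol=1e-10)

    def test_attenuation_matches_monte_carlo(self, main_fit, faces_data):
        """Marginalizing a positive linear predictor over a random intercept
        attenuates the probability toward 1/2; quadrature must match a
        brute-force Monte-Carlo integral."""
        row = faces_data.head(1)
        m = glmm.FittedModel(
            spec=main_fit.spec,
            coef=pd.Series(0.0, index=main_fit.coef.index),
            coef_se=main_fit.coef_se,
            random_sd={"participant": 1.0},
            log_likelihood=0.0, converged=True, n_obs=1, n_groups=1,
            levels=main_fit.levels,
        )
        m.coef["(Intercept)"] = 1.0
        # build_design gives eta = 1 + covariate terms; zero the rest via row choice
        pred = glmm.predict_expected(m, row)
        X, _, _ = glmm.build_design(row, m.spec, m.levels)
        eta = float((X @ m.coef.to_numpy())[0])
        rng = np.random.default_rng(0)
        mc = expit(eta + rng.normal(0, 1.0, 400_000)).mean()
        assert pred[0] == pytest.approx(mc, abs=2e-3)
        assert pred[0] < expit(eta)  # attenuation

    def test_unknown_level_rejected(self, main_fit, faces_data):
        bad = faces_data.head(3).copy()
        bad["group"] = "martian"
        with pytest.raises(ValueError, match="unknown level"):
            glmm.predict_expected(main_fit, bad)


class TestPosterior:
    @pytest.fixture(scope="class")
    def big_cohort(self):
        """Participant-rich cohort: the Bernstein-von Mises regime where
        the posterior concentrates around the MLE."""
        cfg = synthetic.GenerativeConfig(
            n_controls=75, n_cp=75, beta_cp=-0.8, beta_cp_trial=0.0,
            beta_cp_rotation=0.0, sigma_intercept=0.3,
        )
        p = synthetic.generate_participants(cfg, seed=55)
        t = synthetic.simulate_experiment(
            p, synthetic.StudyDesign(repetitions_per_part=2), cfg, seed=55
        )
        return attach_covariates(t, p)

    @pytest.fixture(scope="class")
    def post(self, big_cohort):
        return glmm.posterior_summary(
            MAIN_SPEC, big_cohort, coefficients=["group[CP]"],
            n_samples=4000, n_chains=3, burn=700, seed=5,
        )

    def test_mode_approaches_mle(self, post, big_cohort):
        """Flat-prior, data-rich limit: posterior mode ~ MLE."""
        mle = glmm.fit_glmm(MAIN_SPEC, big_cohort)
        s = post["group[CP]"]
        assert s.posterior_mode == pytest.approx(mle.coef["group[CP]"], abs=0.05)

    def test_hpdi_brackets_mode(self, post):
        s = post["group[CP]"]
        assert s.hpdi_low <= s.posterior_mode <= s.hpdi_high

    def test_seed_determinism(self, post, big_cohort):
        again = glmm.posterior_summary(
            MAIN_SPEC, big_cohort, coefficients=["group[CP]"],
            n_samples=4000, n_chains=3, burn=700, seed=5,
        )
        assert again["group[CP]"] == post["group[CP]"]


def test_hpdi_shortest_interval():
    rng = np.random.default_rng(1)
    x = rng.normal(size=20_000)
    lo, hi = glmm.hpdi(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.08)
    assert hi == pytest.approx(1.96, abs=0.08)
    # mass check
    assert ((x >= lo) & (x <= hi)).mean() == pytest.approx(0.95, abs=0.01)
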