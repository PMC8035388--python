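"""Model-layer checks against closed forms and independent implementations.

The linear mixed model is validated against a self-contained profiled-ML
oracle (closed-form GLS for a given variance ratio, 1-D grid/golden search
over the ratio) and against ordinary least squares when the random-intercept
variance is constrained to zero.  The quadrature GLMM is validated against
closed-form link-transformed means and against lme4's ``glmer`` (adaptive
Gauss-Hermite, nAGQ=9) run through Rscript on a small fixture.
"""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

from workloadcv import (
    BinomialMixedClassifier,
    LinearMixedRegressor,
    ModelSpec,
    PoissonMixedRegressor,
    ZeroInflatedPoissonRegressor,
    fit_glmm,
    fit_lmm,
    fit_tpm,
    information_criteria,
    predict_fixed,
)
from workloadcv.models import build_design


# ---------------------------------------------------------------------------
# Independent oracle: profiled ML for the random-intercept linear model


def _profiled_lmm_oracle(X, y, groups):
    """Exact ML via closed-form GLS at each variance ratio lambda."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    codes, idx = np.unique(groups, return_inverse=True)
    n = len(y)

    def profile(lam):
        c = 1.0 - 1.0 / np.sqrt(1.0 + lam * np.bincount(idx))
        ybar = np.bincount(idx, weights=y) / np.bincount(idx)
        yt = y - c[idx] * ybar[idx]
        Xt = X - c[idx, None] * (
            np.array(
                [np.bincount(idx, weights=X[:, j]) for j in range(X.shape[1])]
            ).T
            / np.bincount(idx)[:, None]
        )[idx]
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        rss = float(np.sum((yt - Xt @ beta) ** 2))
        sigma2 = rss / n
        llf = (
            -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
            - 0.5 * np.sum(np.log(1 + lam * np.bincount(idx)))
        )
        return llf, beta, sigma2

    res = minimize_scalar(
        lambda loglam: -profile(np.exp(loglam))[0],
        bounds=(-12, 6),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    llf, beta, sigma2 = profile(lam)
    llf0, beta0, sigma20 = profile(0.0)
    if llf0 >= llf:
        return {"llf": llf0, "beta": beta0, "resid_var": sigma20, "re_var": 0.0}
    return {"llf": llf, "beta": beta, "resid_var": sigma2, "re_var": lam * sigma2}


def _simulate_lmm(rng, n_groups=25, per_group=40, beta=(2.0, 0.5, -0.3),
                  re_sd=0.4, resid_sd=0.7):
    g = np.repeat(np.arange(n_groups), per_group)
    arr = np.column_stack(
        [np.ones(len(g))] + [rng.normal(size=len(g)) for _ in beta[1:]]
    )
    y = arr @ np.asarray(beta) + rng.normal(0, re_sd, n_groups)[g]
    y += rng.normal(0, resid_sd, len(g))
    X = pd.DataFrame(
        arr, columns=["Intercept"] + [f"x{j}" for j in range(1, len(beta))]
    )
    return X, y, g


class TestLinearMixed:
    def test_constant_response_gives_intercept_and_zero_variances(self):
        X = pd.DataFrame({"Intercept": np.ones(40)})
        y = np.full(40, 3.7)
        est = LinearMixedRegressor(fix_re_variance=0).fit(X, y)
        assert est.params_["Intercept"] == pytest.approx(3.7)
        assert est.re_var_ == 0.0
        assert est.resid_var_ == pytest.approx(0.0, abs=1e-20)

    def test_zero_variance_constraint_matches_ols(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        X, y, g = _simulate_lmm(rng)
        est = LinearMixedRegressor(fix_re_variance=0).fit(X, y, g)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert est.params_.to_numpy() == pytest.approx(beta_ols, rel=1e-8)
        # ML log-likelihood of OLS in closed form
        n = len(y)
        rss = float(np.sum((y - X @ beta_ols) ** 2))
        llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        assert est.llf_ == pytest.approx(llf, rel=1e-10)

    def test_ml_fit_matches_profiled_oracle(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        X, y, g = _simulate_lmm(rng)
        est = LinearMixedRegressor().fit(X, y, g)
        oracle = _profiled_lmm_oracle(X.to_numpy(), y, g)
        assert est.llf_ == pytest.approx(oracle["llf"], abs=1e-4)
        assert est.params_.to_numpy() == pytest.approx(oracle["beta"], abs=1e-5)
        assert est.re_var_ == pytest.approx(oracle["re_var"], rel=0.01)
        assert est.resid_var_ == pytest.approx(oracle["resid_var"], rel=0.01)

    def test_ml_fit_matches_statsmodels_mixedlm(self, rng_seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(rng_seed + 7)
        X, y, g = _simulate_lmm(rng)
        est = LinearMixedRegressor().fit(X, y, g)
        ref = sm.MixedLM(y, X.to_numpy(), groups=g).fit(reml=False)
        assert est.llf_ == pytest.approx(float(ref.llf), abs=1e-4)
        assert est.params_.to_numpy() == pytest.approx(
            np.asarray(ref.fe_params), abs=1e-5
        )
        assert est.re_var_ == pytest.approx(float(np.squeeze(ref.cov_re)), rel=0.01)
        assert est.bse_.to_numpy() == pytest.approx(
            np.asarray(ref.bse_fe), rel=0.02
        )

    def test_parameter_recovery_within_three_se(self, rng_seed):
        rng = np.random.default_rng(rng_seed + 1)
        beta = (2.0, 0.5, -0.3)
        X, y, g = _simulate_lmm(rng, n_groups=40, per_group=60, beta=beta)
        est = LinearMixedRegressor().fit(X, y, g)
        for b, bhat, se in zip(beta, est.params_, est.bse_):
            assert abs(bhat - b) < 3 * se


class TestQuadratureGLMM:
    def test_intercept_only_binomial_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        est = BinomialMixedClassifier().fit(
            pd.DataFrame({"Intercept": np.ones(100)}), y
        )
        assert est.params_["Intercept"] == pytest.approx(logit(0.3), abs=1e-6)

    def test_intercept_only_poisson_closed_form(self):
        y = np.r_[np.full(50, 1.0), np.full(50, 3.0)]  # mean 2
        est = PoissonMixedRegressor().fit(
            pd.DataFrame({"Intercept": np.ones(100)}), y
        )
        assert est.params_["Intercept"] == pytest.approx(np.log(2), abs=1e-6)

    def test_binomial_recovery_within_three_se(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        G, per = 30, 150
        g = np.repeat(np.arange(G), per)
        x = rng.normal(size=len(g))
        truth = (-1.0, 0.5)
        eta = truth[0] + truth[1] * x + rng.normal(0, 0.7, G)[g]
        y = (rng.random(len(g)) < expit(eta)).astype(float)
        X = pd.DataFrame({"Intercept": np.ones(len(g)), "x": x})
        est = BinomialMixedClassifier().fit(X, y, g)
        assert est.converged_
        for b, bhat, se in zip(truth, est.params_, est.bse_):
            assert abs(bhat - b) < 3 * se

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_binomial_glmm_matches_lme4(self, tmp_path, rng_seed):
        rng = np.random.default_rng(rng_seed)
        G, per = 15, 80
        g = np.repeat(np.arange(G), per)
        x = rng.normal(size=len(g))
        eta = -0.5 + 0.6 * x + rng.normal(0, 0.6, G)[g]
        y = (rng.random(len(g)) < expit(eta)).astype(float)
        pd.DataFrame({"y": y, "x": x, "g": g}).to_csv(
            tmp_path / "d.csv", index=False
        )
        est = BinomialMixedClassifier(nagq=9).fit(
            pd.DataFrame({"Intercept": np.ones(len(g)), "x": x}), y, g
        )
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{tmp_path / 'd.csv'}")
            m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=9)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        b0, b1, sigma, llf = map(float, out.stdout.strip().split("\n"))
        assert est.params_["Intercept"] == pytest.approx(b0, abs=2e-3)
        assert est.params_["x"] == pytest.approx(b1, abs=2e-3)
        assert np.sqrt(est.re_var_) == pytest.approx(sigma, abs=2e-3)
        assert est.llf_ == pytest.approx(llf, abs=1e-2)


class TestTwoPart:
    def test_zero_omissions_reduce_to_lmm(self, tiny_table):
        sub = tiny_table[tiny_table["day"] == 1].copy()
        sub["omission"] = 0
        sub["rt_ms"] = sub["rt_ms"].fillna(500.0)
        terms = ("difficulty", "block")
        tpm = fit_tpm(ModelSpec("log_rt", "two_part_lognormal", terms), sub)
        lmm = fit_lmm(ModelSpec("log_rt", "linear", terms), sub)
        for name, value in lmm.params.items():
            assert tpm.params[name] == pytest.approx(value, abs=1e-10)

    def test_likelihood_factorizes_exactly(self, tiny_table):
        sub = tiny_table[tiny_table["day"] == 1]
        terms = ("difficulty", "block")
        tpm = fit_tpm(ModelSpec("log_rt", "two_part_lognormal", terms), sub)
        occ = fit_glmm(ModelSpec("omission", "binomial", terms), sub)
        inten = fit_lmm(ModelSpec("log_rt", "linear", terms), sub)
        assert tpm.llf == pytest.approx(occ.llf + inten.llf, abs=1e-6)
        assert tpm.k == occ.k + inten.k

    def test_covariate_free_occurrence_intercept_is_logit_rate(self, tiny_table):
        sub = tiny_table[tiny_table["day"] == 1]
        spec = ModelSpec("log_rt", "two_part_lognormal", (), random_intercept=False)
        tpm = fit_tpm(spec, sub)
        rate = sub["omission"].mean()
        assert tpm.estimator.occurrence_.params_["Intercept"] == pytest.approx(
            logit(rate), abs=1e-6
        )

    def test_intensity_matches_lmm_on_synthetic_data(self, tiny_table):
        sub = tiny_table[tiny_table["day"] == 1]
        terms = ("difficulty", "block", "WeightFuel_z", "nHHO3s_z", "nFAR3s_z")
        tpm = fit_tpm(ModelSpec("log_rt", "two_part_lognormal", terms), sub)
        lmm = fit_lmm(ModelSpec("log_rt", "linear", terms), sub)
        for name, value in lmm.params.items():
            assert tpm.params[name] == pytest.approx(value, abs=1e-3)


class TestZeroInflated:
    def test_no_inflation_matches_plain_poisson(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        n = 3000
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.5 + 0.3 * x)).astype(float)
        X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
        zip_est = ZeroInflatedPoissonRegressor(random_intercept=False).fit(X, y)
        pois = PoissonMixedRegressor().fit(X, y)
        assert zip_est.params_["Intercept"] == pytest.approx(
            pois.params_["Intercept"], abs=0.02
        )
        assert zip_est.params_["x"] == pytest.approx(pois.params_["x"], abs=0.02)

    def test_all_zero_response_is_degenerate(self):
        X = pd.DataFrame({"Intercept": np.ones(50)})
        est = ZeroInflatedPoissonRegressor().fit(X, np.zeros(50))
        assert est.degenerate_

    def test_recovery_against_statsmodels_reference(self, rng_seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(rng_seed)
        n = 4000
        x = rng.normal(size=n)
        pi = expit(-0.8 + 0.4 * x)
        mu = np.exp(0.7 + 0.3 * x)
        y = np.where(rng.random(n) < pi, 0.0, rng.poisson(mu))
        Xd = np.column_stack([np.ones(n), x])
        mine = ZeroInflatedPoissonRegressor(random_intercept=False).fit(
            pd.DataFrame({"Intercept": Xd[:, 0], "x": x}), y
        )
        ref = sm.ZeroInflatedPoisson(y, Xd, exog_infl=Xd).fit(disp=0)
        assert mine.params_.to_numpy() == pytest.approx(
            np.asarray(ref.params), abs=1e-3
        )
        assert mine.llf_ == pytest.approx(ref.llf, abs=1e-3)

    def test_random_intercept_recovery_within_three_se(self, rng_seed):
        rng = np.random.default_rng(rng_seed + 2)
        G, per = 30, 120
        g = np.repeat(np.arange(G), per)
        x = rng.normal(size=len(g))
        truth_count = (0.5, 0.4)
        truth_zero = (-1.0, 0.3)
        b = rng.normal(0, 0.4, G)
        pi = expit(truth_zero[0] + truth_zero[1] * x)
        mu = np.exp(truth_count[0] + truth_count[1] * x + b[g])
        y = np.where(rng.random(len(g)) < pi, 0.0, rng.poisson(mu))
        est = ZeroInflatedPoissonRegressor().fit(
            pd.DataFrame({"Intercept": np.ones(len(g)), "x": x}), y, g
        )
        assert est.converged_
        expected = {
            "zi_Intercept": truth_zero[0],
            "zi_x": truth_zero[1],
            "Intercept": truth_count[0],
            "x": truth_count[1],
        }
        for name, value in expected.items():
            assert abs(est.params_[name] - value) < 3 * est.bse_[name]


class TestInformationCriteria:
    def _fake_fit(self, llf, k, n):
        from workloadcv.models import FitResult

        return FitResult(
            spec=ModelSpec("log_rt", "linear"),
            params={},
            se={},
            re_var=0.0,
            resid_var=1.0,
            llf=llf,
            aic=-2 * llf + 2 * k,
            bic=-2 * llf + k * np.log(n) if n else np.nan,
            n=n,
            k=k,
            converged=True,
        )

    def test_aic_arithmetic(self):
        fit = self._fake_fit(-100.0, 3, 100)
        assert information_criteria(fit)["aic"] == pytest.approx(206.0)

    def test_bic_arithmetic(self):
        fit = self._fake_fit(-100.0, 3, 100)
        assert information_criteria(fit)["bic"] == pytest.approx(
            200 + 3 * np.log(100)
        )

    def test_identical_models_have_zero_delta(self):
        a = self._fake_fit(-50.0, 2, 80)
        b = self._fake_fit(-50.0, 2, 80)
        out = information_criteria(a, comparison=[a, b])
        assert out["delta_aic"] == 0.0 and out["delta_bic"] == 0.0

    def test_zero_observations_invalid(self):
        with pytest.raises(ValueError):
            information_criteria(self._fake_fit(-1.0, 1, 0))

    def test_adding_a_predictor_never_lowers_loglik(self, tiny_table):
        sub = tiny_table[tiny_table["day"] == 1]
        base = fit_lmm(ModelSpec("log_rt", "linear", ("difficulty", "block")), sub)
        bigger = fit_lmm(
            ModelSpec("log_rt", "linear", ("difficulty", "block", "WeightFuel_z")),
            sub,
        )
        assert bigger.llf >= base.llf - 1e-6


class TestPredictFixed:
    def test_intercept_only_predicts_constant(self, tiny_table):
        sub = tiny_table[tiny_table["day"] == 1]
        fit = fit_lmm(ModelSpec("log_rt", "linear", ()), sub)
        preds = predict_fixed(fit, sub.head(10))
        assert np.allclose(preds, preds[0])

    def test_balanced_binomial_predicts_half(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        est = BinomialMixedClassifier().fit(
            pd.DataFrame({"Intercept": np.ones(100)}), y
        )
        assert est.predict_proba(
            pd.DataFrame({"Intercept": np.ones(3)})
        ) == pytest.approx(0.5, abs=1e-8)

    def test_prediction_ignores_participant_identity(self, tiny_table):
        sub = tiny_table[tiny_table["day"] == 1]
        fit = fit_lmm(ModelSpec("log_rt", "linear", ("difficulty", "block")), sub)
        row = sub.head(1).copy()
        a = predict_fixed(fit, row)
        row["participant_id"] = "someone-new"
        b = predict_fixed(fit, row)
        assert a == pytest.approx(b)

    def test_unseen_difficulty_level_rejected(self, tiny_table):
        sub = tiny_table[tiny_table["day"] == 1]
        fit = fit_lmm(ModelSpec("log_rt", "linear", ("difficulty",)), sub)
        bad = sub.head(1).copy()
        bad["difficulty"] = 9
        with pytest.raises(ValueError, match="unseen difficulty"):
            predict_fixed(fit, bad)


def test_design_matrix_reference_coding(tiny_table):
    X = build_design(tiny_table.head(50), ("difficulty", "day", "block"))
    assert list(X.columns) == ["Intercept", "diff5", "diff7", "day2", "block"]
    # 3 UAVs is the reference level: both dummies zero
    ref_rows = tiny_table.head(50)["difficulty"] == 3
    assert (X.loc[ref_rows.to_numpy(), ["diff5", "diff7"]].to_numpy() == 0).all()
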