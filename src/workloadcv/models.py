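"""Mixed-effects model families for DRT workload analysis.

All models share one structure: additive fixed effects plus a Gaussian
participant random intercept.  Four families cover the response types:

* :class:`LinearMixedRegressor` -- log reaction time (ms), fitted by maximum
  likelihood (ML, not REML, so information criteria are comparable across
  fixed-effect sets);
* :class:`BinomialMixedClassifier` / :class:`PoissonMixedRegressor` --
  omission indicators and event counts, fitted by adaptive Gauss-Hermite
  quadrature;
* :class:`TwoPartLogNormalRegressor` -- the semicontinuous two-part model:
  a logistic occurrence part for omissions and a log-normal intensity part
  for observed RTs, with independent random intercepts, whose joint
  log-likelihood factorizes exactly into the two parts;
* :class:`ZeroInflatedPoissonRegressor` -- crash counts in a short window
  after the prompt, mixing structural zeros (logit) with a Poisson count
  part that carries the random intercept.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, fitted attributes with a trailing underscore) and accept the
design as a DataFrame; out-of-sample prediction uses fixed effects only, so
it is well-defined for participants never seen in training.  The
``fit_lmm`` / ``fit_glmm`` / ``fit_tpm`` / ``fit_zip`` functions are thin
formula-level wrappers driven by :class:`ModelSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

from ._fitcore import fit_glmm_ml, fit_lmm_ml, fit_zip_ml

__all__ = [
    "ModelSpec",
    "FitResult",
    "LinearMixedRegressor",
    "BinomialMixedClassifier",
    "PoissonMixedRegressor",
    "TwoPartLogNormalRegressor",
    "ZeroInflatedPoissonRegressor",
    "build_design",
    "fit_lmm",
    "fit_glmm",
    "fit_tpm",
    "fit_zip",
    "information_criteria",
    "predict_fixed",
]

#: difficulty is a factor with 3 UAVs as the reference level
DIFFICULTY_DUMMIES = {5: "diff5", 7: "diff7"}


# ---------------------------------------------------------------------------
# Declarative model specification and design construction


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, family, and additive fixed effects.

    ``fixed_terms`` may contain the factor shorthands ``difficulty`` (dummy
    coded against the 3-UAV reference), ``day``, the numeric ``block``, the
    interactions ``difficulty:day`` and ``day:block`` (descriptive ladders
    only), or any numeric column of the data (e.g. ``WeightFuel_z``,
    ``nHHO3s_z``, ``HHO_3s``).
    """

    response: str
    family: str  # linear | binomial | poisson | two_part_lognormal | zero_inflated_poisson
    fixed_terms: tuple = ()
    random_intercept: bool = True

    def label(self) -> str:
        return "+".join(self.fixed_terms) if self.fixed_terms else "1"


def _term_columns(data: pd.DataFrame, term: str) -> dict[str, np.ndarray]:
    if term == "difficulty":
        return {
            name: (data["difficulty"].to_numpy() == level).astype(float)
            for level, name in DIFFICULTY_DUMMIES.items()
        }
    if term == "day":
        return {"day2": (data["day"].to_numpy() == 2).astype(float)}
    if term == "difficulty:day":
        day2 = (data["day"].to_numpy() == 2).astype(float)
        return {
            f"{name}:day2": (data["difficulty"].to_numpy() == level) * day2
            for level, name in DIFFICULTY_DUMMIES.items()
        }
    if term == "day:block":
        day2 = (data["day"].to_numpy() == 2).astype(float)
        return {"day2:block": day2 * data["block"].to_numpy(dtype=float)}
    if term not in data.columns:
        raise KeyError(f"unknown model term {term!r}")
    return {term: data[term].to_numpy(dtype=float)}


def build_design(data: pd.DataFrame, fixed_terms) -> pd.DataFrame:
    """Design frame (with explicit Intercept column) for a term list."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    for term in fixed_terms:
        cols.update(_term_columns(data, term))
    return pd.DataFrame(cols, index=data.index)


def _design_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Coerce estimator input to (array with intercept, names)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{j}" for j in range(arr.shape[1])]
    if "Intercept" not in names:
        arr = np.column_stack([np.ones(len(arr)), arr])
        names = ["Intercept"] + names
    return arr, names


# ---------------------------------------------------------------------------
# Estimators


class LinearMixedRegressor(BaseEstimator, RegressorMixin):
    """Random-intercept linear mixed model fitted by exact profiled ML.

    The marginal likelihood is profiled analytically over the fixed effects
    (closed-form GLS at each variance ratio) and the residual variance,
    leaving a 1-D search over the ratio of between-subject to residual
    variance; the boundary at zero variance is checked explicitly.

    Parameters
    ----------
    fix_re_variance : float or None
        If 0, the random-intercept variance is constrained to zero and the
        fit reduces to ordinary least squares (ML variant).  ``None`` (the
        default) estimates it.

    Attributes
    ----------
    params_ : pandas Series of fixed-effect estimates (incl. Intercept).
    bse_ : standard errors of the fixed effects.
    re_var_, resid_var_ : variance components.
    llf_, k_, n_, aic_, bic_ : fit statistics (k counts fixed effects plus
        estimated variance components).
    converged_, flags_ : convergence diagnostics.
    """

    def __init__(self, fix_re_variance: float | None = None):
        self.fix_re_variance = fix_re_variance

    def fit(self, X, y, groups=None):
        arr, names = _design_matrix(X)
        y = np.asarray(y, dtype=float)
        flags: list[str] = []
        no_groups = groups is None
        if no_groups:
            groups = np.zeros(len(y), dtype=int)
            if self.fix_re_variance not in (0, 0.0):
                flags.append("no groups given: fitted without random intercept")
        constrain = no_groups or self.fix_re_variance == 0
        res = fit_lmm_ml(
            arr, y, np.asarray(groups), names=names,
            fix_lambda=0.0 if constrain else None,
        )
        flags.extend(res.flags)
        self.feature_names_ = names
        self.params_ = pd.Series(res.params, index=names)
        self.bse_ = pd.Series(res.se, index=names)
        self.re_var_ = res.sigma_b**2
        self.resid_var_ = res.resid_var
        self.llf_ = res.llf
        self.k_ = res.k
        self.n_ = res.n
        self.aic_ = -2 * res.llf + 2 * res.k
        self.bic_ = -2 * res.llf + res.k * np.log(res.n)
        self.converged_ = res.converged
        self.flags_ = flags
        return self

    def predict(self, X):
        """Fixed-effects-only prediction (population-level log-RT)."""
        arr, names = _design_matrix(X)
        if names != self.feature_names_:
            raise ValueError("prediction design does not match training design")
        return arr @ self.params_.to_numpy()


class _QuadratureMixedModel(BaseEstimator):
    """Shared fitting logic for AGQ-based GLMMs."""

    family: str

    def __init__(self, nagq: int = 9, fix_re_sd: float | None = None):
        self.nagq = nagq
        self.fix_re_sd = fix_re_sd

    def fit(self, X, y, groups=None):
        arr, names = _design_matrix(X)
        y = np.asarray(y, dtype=float)
        if groups is None:
            groups = np.zeros(len(y), dtype=int)
            fix_sigma = 0.0
        else:
            fix_sigma = self.fix_re_sd
        res = fit_glmm_ml(
            arr, y, np.asarray(groups), self.family, names=names,
            nagq=self.nagq, fix_sigma=fix_sigma,
        )
        self.feature_names_ = names
        self.params_ = pd.Series(res.params, index=names)
        self.bse_ = pd.Series(res.se[: len(names)], index=names)
        self.re_var_ = res.sigma_b**2
        self.llf_ = res.llf
        self.k_ = res.k
        self.n_ = res.n
        self.aic_ = -2 * res.llf + 2 * res.k
        self.bic_ = -2 * res.llf + res.k * np.log(res.n)
        self.converged_ = res.converged
        self.flags_ = res.flags
        return self

    def _linear_predictor(self, X):
        arr, names = _design_matrix(X)
        if names != self.feature_names_:
            raise ValueError("prediction design does not match training design")
        return arr @ self.params_.to_numpy()


class BinomialMixedClassifier(_QuadratureMixedModel):
    """Random-intercept logistic mixed model (per-trial Bernoulli)."""

    family = "binomial"

    def predict_proba(self, X):
        """Population-level event probability for new participants."""
        return expit(self._linear_predictor(X))

    def predict(self, X):
        return (self.predict_proba(X) > 0.5).astype(int)


class PoissonMixedRegressor(_QuadratureMixedModel):
    """Random-intercept log-link Poisson mixed model."""

    family = "poisson"

    def predict(self, X):
        return np.exp(self._linear_predictor(X))


class TwoPartLogNormalRegressor(BaseEstimator, RegressorMixin):
    """Two-part (hurdle) model for semicontinuous RT data.

    The occurrence part is a logistic mixed model for the omission
    indicator; the intensity part is a linear mixed model for log RT on
    responded trials.  The sub-models have independent participant
    intercepts, so the joint log-likelihood is exactly the sum of the two
    parts.  ``predict`` returns the intensity-part log-RT (out-of-sample
    prediction is defined for the intensity variable only).
    """

    def __init__(self, nagq: int = 9):
        self.nagq = nagq

    def fit(self, X, y, groups=None):
        """``y`` must be a DataFrame with ``rt_ms`` and ``omission``."""
        omission = np.asarray(y["omission"], dtype=float)
        rt = np.asarray(y["rt_ms"], dtype=float)
        responded = omission == 0
        occ = BinomialMixedClassifier(nagq=self.nagq).fit(X, omission, groups)
        X_int = X[responded] if isinstance(X, pd.DataFrame) else np.asarray(X)[responded]
        grp_int = np.asarray(groups)[responded] if groups is not None else None
        inten = LinearMixedRegressor().fit(X_int, np.log(rt[responded]), grp_int)
        self.occurrence_ = occ
        self.intensity_ = inten
        self.feature_names_ = inten.feature_names_
        self.params_ = inten.params_  # intensity coefficients (log-RT scale)
        self.bse_ = inten.bse_
        self.llf_ = occ.llf_ + inten.llf_
        self.k_ = occ.k_ + inten.k_
        self.n_ = occ.n_
        self.aic_ = -2 * self.llf_ + 2 * self.k_
        self.bic_ = -2 * self.llf_ + self.k_ * np.log(self.n_)
        self.converged_ = occ.converged_ and inten.converged_
        self.flags_ = occ.flags_ + inten.flags_
        return self

    def predict(self, X):
        return self.intensity_.predict(X)

    def predict_omission_proba(self, X):
        return self.occurrence_.predict_proba(X)


class ZeroInflatedPoissonRegressor(BaseEstimator, RegressorMixin):
    """Zero-inflated Poisson with a participant intercept in the count part.

    Structural zeros come from a logistic sub-model sharing the covariates
    of the count part.  ``degenerate_`` is set (and no coefficients are
    available) when the response contains no positive count.
    """

    def __init__(self, nagq: int = 9, random_intercept: bool = True):
        self.nagq = nagq
        self.random_intercept = random_intercept

    def fit(self, X, y, groups=None):
        arr, names = _design_matrix(X)
        y = np.asarray(y, dtype=float)
        use_re = self.random_intercept and groups is not None
        res = fit_zip_ml(
            arr, y,
            np.asarray(groups) if groups is not None else np.zeros(len(y), int),
            names=names, nagq=self.nagq, random_intercept=use_re,
        )
        self.degenerate_ = any("degenerate" in f for f in res.flags)
        self.feature_names_ = names
        self.params_ = pd.Series(res.params, index=res.names)
        self.bse_ = pd.Series(res.se, index=res.names)
        self.re_var_ = res.sigma_b**2 if np.isfinite(res.sigma_b) else np.nan
        self.llf_ = res.llf
        self.k_ = res.k
        self.n_ = res.n
        self.aic_ = -2 * res.llf + 2 * res.k if np.isfinite(res.llf) else np.nan
        self.bic_ = (
            -2 * res.llf + res.k * np.log(res.n) if np.isfinite(res.llf) else np.nan
        )
        self.converged_ = res.converged
        self.flags_ = res.flags
        return self

    def predict(self, X):
        """Population-level expected count: (1 - pi) * mu."""
        arr, names = _design_matrix(X)
        if names != self.feature_names_:
            raise ValueError("prediction design does not match training design")
        p = len(names)
        gamma = self.params_.to_numpy()[:p]
        beta = self.params_.to_numpy()[p:]
        return (1.0 - expit(arr @ gamma)) * np.exp(arr @ beta)


# ---------------------------------------------------------------------------
# Formula-level wrappers


@dataclass
class FitResult:
    """Serializable summary of one fitted model."""

    spec: ModelSpec
    params: dict
    se: dict
    re_var: float
    resid_var: float | None
    llf: float
    aic: float
    bic: float
    n: int
    k: int
    converged: bool
    flags: list = field(default_factory=list)
    estimator: object = None

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "family": self.spec.family,
            "fixed_terms": list(self.spec.fixed_terms),
            "params": self.params,
            "se": self.se,
            "re_var": self.re_var,
            "resid_var": self.resid_var,
            "llf": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "k": self.k,
            "converged": self.converged,
            "flags": list(self.flags),
        }


def _response_vector(spec: ModelSpec, data: pd.DataFrame):
    if spec.response == "log_rt":
        return np.log(data["rt_ms"].to_numpy(dtype=float))
    return data[spec.response].to_numpy(dtype=float)


def _wrap(spec: ModelSpec, est) -> FitResult:
    return FitResult(
        spec=spec,
        params={k: float(v) for k, v in est.params_.items()},
        se={k: float(v) for k, v in est.bse_.items()},
        re_var=float(getattr(est, "re_var_", np.nan)),
        resid_var=float(getattr(est, "resid_var_", np.nan))
        if hasattr(est, "resid_var_")
        else None,
        llf=est.llf_,
        aic=est.aic_,
        bic=est.bic_,
        n=est.n_,
        k=est.k_,
        converged=est.converged_,
        flags=list(est.flags_),
        estimator=est,
    )


def _groups(spec: ModelSpec, data: pd.DataFrame):
    return data["participant_id"].to_numpy() if spec.random_intercept else None


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> FitResult:
    """Linear mixed model for a continuous response (log RT by default).

    For ``response='log_rt'`` omission rows are dropped before fitting.
    """
    if spec.response == "log_rt":
        data = data[data["omission"] == 0]
    X = build_design(data, spec.fixed_terms)
    est = LinearMixedRegressor(**kwargs).fit(
        X, _response_vector(spec, data), _groups(spec, data)
    )
    return _wrap(spec, est)


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, family: str | None = None,
             **kwargs) -> FitResult:
    """Binomial or Poisson mixed model (logit / log link)."""
    family = family or spec.family
    cls = {"binomial": BinomialMixedClassifier, "poisson": PoissonMixedRegressor}[
        family
    ]
    X = build_design(data, spec.fixed_terms)
    est = cls(**kwargs).fit(X, _response_vector(spec, data), _groups(spec, data))
    return _wrap(spec, est)


def fit_tpm(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> FitResult:
    """Two-part log-normal model for RT with omissions as a point mass."""
    X = build_design(data, spec.fixed_terms)
    est = TwoPartLogNormalRegressor(**kwargs).fit(
        X, data[["rt_ms", "omission"]], _groups(spec, data)
    )
    return _wrap(spec, est)


def fit_zip(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> FitResult:
    """Zero-inflated Poisson for post-prompt crash counts."""
    X = build_design(data, spec.fixed_terms)
    est = ZeroInflatedPoissonRegressor(**kwargs).fit(
        X, _response_vector(spec, data), _groups(spec, data)
    )
    return _wrap(spec, est)


def information_criteria(fit: FitResult, comparison=None) -> dict:
    """AIC/BIC for one fit, with deltas to the best model in a set.

    AIC = -2 llf + 2k and BIC = -2 llf + k ln n, where k counts all
    estimated parameters including variance components.
    """
    if fit.n == 0:
        raise ValueError("cannot compute information criteria with n = 0")
    out = {"aic": fit.aic, "bic": fit.bic}
    if comparison:
        out["delta_aic"] = fit.aic - min(f.aic for f in comparison)
        out["delta_bic"] = fit.bic - min(f.bic for f in comparison)
    return out


def predict_fixed(fit: FitResult, new_data: pd.DataFrame) -> np.ndarray:
    """Fixed-effects-only prediction for (possibly unseen) participants.

    Random intercepts of unseen participants are set to their population
    mean of zero.  Binomial fits return probabilities; linear and two-part
    fits return log-RT; Poisson/ZIP fits return expected counts.
    Raises for factor levels absent from the training data.
    """
    if "difficulty" in fit.spec.fixed_terms:
        seen = set(DIFFICULTY_DUMMIES) | {3}
        levels = set(np.unique(new_data["difficulty"]))
        if not levels <= seen:
            raise ValueError(f"unseen difficulty level(s) {sorted(levels - seen)}")
    X = build_design(new_data, fit.spec.fixed_terms)
    est = fit.estimator
    if isinstance(est, BinomialMixedClassifier):
        return est.predict_proba(X)
    return est.predict(X)
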