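"""Descriptive model-comparison ladders, effect-size summaries, the
WeightFuel exponent sweep, and the overload comparison.

Everything here is a thin consumer of the model layer: tables contain the
AIC/BIC values the fitted models report, with minima marked, and every
randomized analysis takes an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossval import enumerate_specs, make_folds, rank_and_stability, run_cv
from .models import ModelSpec, fit_glmm, fit_lmm, fit_tpm, fit_zip
from .pipeline import study_feature_table
from .simulate import StudyData

__all__ = [
    "LADDER_DIFF_DAY",
    "LADDER_BLOCK",
    "ladder_report",
    "effect_report",
    "exponent_sweep",
    "overload_comparison",
]

#: difficulty/day ladder: difficulty only, + additive day, + interaction
LADDER_DIFF_DAY = [
    ("M_diff", ("difficulty",)),
    ("M_diff+day", ("difficulty", "day")),
    ("M_diffxday", ("difficulty", "day", "difficulty:day")),
]

#: time-on-task ladder: + block, + day-by-block interaction
LADDER_BLOCK = [
    ("M_diff+day", ("difficulty", "day")),
    ("M_diff+day+block", ("difficulty", "day", "block")),
    ("M_diff+dayxblock", ("difficulty", "day", "block", "day:block")),
]

#: AIC/BIC difference guideline: 2-7 somewhat supported, > 7 unsupported
IC_GUIDELINE = (2.0, 7.0)

_FITTERS = {
    "linear": fit_lmm,
    "binomial": lambda spec, data: fit_glmm(spec, data, family="binomial"),
    "poisson": lambda spec, data: fit_glmm(spec, data, family="poisson"),
    "two_part_lognormal": fit_tpm,
}


def ladder_report(
    data: pd.DataFrame,
    responses: list[tuple[str, str, str]],
    ladder=LADDER_DIFF_DAY,
) -> pd.DataFrame:
    """AIC/BIC comparison table over a fixed ladder of nested models.

    ``responses`` is a list of (row label, response column, family) triples;
    every ladder model is fitted to each response and the table reports AIC
    and BIC per cell, flags the per-criterion minimum (``best_aic`` /
    ``best_bic``), and annotates the delta to the best model.  Failed fits
    leave NA cells.
    """
    rows = []
    for label, response, family in responses:
        fits = {}
        for model_label, terms in ladder:
            spec = ModelSpec(response=response, family=family, fixed_terms=terms)
            try:
                fits[model_label] = _FITTERS[family](spec, data)
            except Exception:
                fits[model_label] = None
        for criterion in ("aic", "bic"):
            values = {
                ml: (getattr(f, criterion) if f is not None else np.nan)
                for ml, f in fits.items()
            }
            best = min(
                (v for v in values.values() if np.isfinite(v)), default=np.nan
            )
            for ml, v in values.items():
                delta = v - best
                rows.append(
                    {
                        "response": label,
                        "criterion": criterion.upper(),
                        "model": ml,
                        "value": v,
                        "delta": delta,
                        "best": bool(np.isfinite(v) and delta == 0.0),
                        "support": _support_band(delta),
                    }
                )
    return pd.DataFrame(rows)


def _support_band(delta: float) -> str:
    if not np.isfinite(delta):
        return "NA"
    if delta == 0:
        return "best"
    if delta < IC_GUIDELINE[0]:
        return "comparable"
    if delta <= IC_GUIDELINE[1]:
        return "somewhat supported"
    return "not supported"


DEFAULT_EFFECT_PREDICTORS = (
    "WeightFuel_z",
    "nHHO3s_z",
    "nFAR3s_z",
    "block",
    "difficulty",
)


def effect_report(
    table: pd.DataFrame,
    predictors=DEFAULT_EFFECT_PREDICTORS,
    per_day: bool = True,
    n_blocks: int = 21,
) -> pd.DataFrame:
    """Unstandardized coefficients per predictor, day, and model family.

    Fits, separately per day when both are present, a two-part model and an
    LMM for log RT and a binomial mixed model for omissions, with the given
    predictors (continuous ones are expected pre-standardized within
    participant).  The block entry is also reported as the cumulative effect
    of completing all ``n_blocks`` blocks (coefficient x (n_blocks - 1)
    block increments), and log-RT effects get an approximate ms-scale
    translation at the baseline profile:
    delta_ms = exp(intercept + beta) - exp(intercept).
    """
    days = sorted(table["day"].unique()) if per_day else [None]
    rows = []
    for day in days:
        sub = table if day is None else table[table["day"] == day]
        spec = ModelSpec("log_rt", "linear", tuple(predictors))
        fits = {
            "tpm": fit_tpm(ModelSpec("log_rt", "two_part_lognormal", tuple(predictors)), sub),
            "lmm": fit_lmm(spec, sub),
            "glmm": fit_glmm(
                ModelSpec("omission", "binomial", tuple(predictors)), sub
            ),
        }
        for model_name, fit in fits.items():
            intercept = fit.params.get("Intercept", np.nan)
            for name, coef in fit.params.items():
                if name == "Intercept":
                    continue
                entry = {
                    "day": day,
                    "model": model_name,
                    "predictor": name,
                    "coef": coef,
                    "se": fit.se.get(name, np.nan),
                }
                delta = coef * (n_blocks - 1) if name == "block" else coef
                entry["cumulative_coef"] = delta
                if model_name in ("tpm", "lmm"):
                    entry["approx_ms"] = float(
                        np.exp(intercept + delta) - np.exp(intercept)
                    )
                else:
                    entry["approx_ms"] = np.nan
                rows.append(entry)
    return pd.DataFrame(rows)


def exponent_sweep(
    study: StudyData,
    exponents=(1 / 8, 1 / 4, 2.0, 4.0),
    day: int = 1,
    k: int = 5,
    seed: int = 0,
    family: str = "lmm",
    extra_predictors=("nHHO3s_z", "nFAR3s_z"),
) -> dict:
    """Re-run the refined cross-validation once per WeightFuel exponent.

    For each Minkowski order ``p`` the WeightFuel column is recomputed, the
    table rebuilt, and the CV repeated with the labelled variant
    ``WF p=<p>`` among the optional predictors.  The summary reports, per
    exponent, the mean NMSD of the best WeightFuel-including spec and the
    inclusion frequency of the variant among top-ranked specs.
    """
    out = {}
    for p in exponents:
        table = study_feature_table(study, exponent=p)
        day_table = table[table["day"] == day]
        wf_label = f"WFp{p:g}"
        day_table = day_table.rename(columns={"WeightFuel_z": wf_label})
        specs = enumerate_specs((wf_label,) + tuple(extra_predictors))
        plan = make_folds(day_table["participant_id"].unique(), k=k, seed=seed)
        result = run_cv(day_table, specs, plan, response="log_rt", family=family)
        summary = rank_and_stability(result)
        means = result.spec_means("nmsd")
        with_wf = [
            sid
            for sid in means.index
            if wf_label in result.specs[sid].fixed_terms
        ]
        out[p] = {
            "cv": result,
            "summary": summary,
            "wf_label": wf_label,
            "best_wf_nmsd": float(means[with_wf].min()) if with_wf else np.nan,
            "wf_inclusion_top": summary["inclusion"]["overall"].get(wf_label, np.nan),
        }
    return out


EVENT_BASED_TERMS = ("HHO_3s", "FAHO_3s", "FAR_3s", "HR_3s", "difficulty", "block")
REFINED_TERMS = ("WeightFuel_z", "nHHO3s_z", "nFAR3s_z", "difficulty", "block")


def overload_comparison(table: pd.DataFrame, per_day: bool = True) -> pd.DataFrame:
    """Event-based vs refined predictors for post-prompt crash counts.

    Fits two zero-inflated Poisson models for the number of UAV crashes in
    the 5 s after each prompt -- one with the simple event-occurrence flags,
    one with the refined fuel-awareness predictors, both with difficulty and
    block -- and reports AIC/BIC per day with the winner.  A degenerate
    response (no crashes) is flagged and propagated as NA.
    """
    days = sorted(table["day"].unique()) if per_day else [None]
    rows = []
    for day in days:
        sub = table if day is None else table[table["day"] == day]
        for label, terms in (
            ("event_based", EVENT_BASED_TERMS),
            ("refined", REFINED_TERMS),
        ):
            spec = ModelSpec("nMRpost", "zero_inflated_poisson", terms)
            fit = fit_zip(spec, sub)
            degenerate = any("degenerate" in f for f in fit.flags)
            rows.append(
                {
                    "day": day,
                    "model": label,
                    "aic": fit.aic if not degenerate else np.nan,
                    "bic": fit.bic if not degenerate else np.nan,
                    "degenerate": degenerate,
                    "converged": fit.converged,
                }
            )
    out = pd.DataFrame(rows)
    winners = []
    for day, grp in out.groupby("day", dropna=False):
        if grp["aic"].notna().all():
            winners.append((day, grp.loc[grp["aic"].idxmin(), "model"]))
        else:
            winners.append((day, "NA"))
    out = out.merge(
        pd.DataFrame(winners, columns=["day", "winner_aic"]), on="day", how="left"
    )
    return out
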