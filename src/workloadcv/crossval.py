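"""Between-subject cross-validated model selection.

Participants are split into k (default 5) folds of near-equal size.  In the
deliberately demanding "inverted" scheme, each fold in turn serves as the
*training* set (about 20% of participants) and the remaining folds, pooled,
are predicted (about 80%), using fixed effects only -- random intercepts of
unseen participants are set to their population mean of zero.

Predictive accuracy per (training fold, model) cell is the mean squared
deviation (MSD) between observed and predicted response (log RT, or omission
indicator vs predicted probability).  For display, MSD is re-centred by
subtracting the grand mean MSD over all cells of the analysis (NMSD); lower
is better, and the ranking of models is identical under MSD and NMSD.  An
alternative per-fold centring (subtracting each fold's mean across models)
is available behind a switch.

Model candidates are enumerated exhaustively: every subset of the optional
predictors, each together with the always-included difficulty and block
terms, plus four baselines (difficulty+block, block, difficulty,
intercept-only).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    BinomialMixedClassifier,
    LinearMixedRegressor,
    ModelSpec,
    TwoPartLogNormalRegressor,
    build_design,
)

__all__ = [
    "FoldPlan",
    "CVResult",
    "make_folds",
    "enumerate_specs",
    "run_cv",
    "normalize_msd",
    "rank_and_stability",
]

ALWAYS_TERMS = ("difficulty", "block")
BASELINES = {
    "baseline:difficulty+block": ("difficulty", "block"),
    "baseline:block": ("block",),
    "baseline:difficulty": ("difficulty",),
    "baseline:intercept": (),
}


@dataclass(frozen=True)
class FoldPlan:
    """Partition of participants into k near-equal folds."""

    k: int
    assignment: dict  # participant -> fold id (0..k-1)
    seed: int | None = None

    def members(self, fold: int) -> list:
        return [p for p, f in self.assignment.items() if f == fold]

    def sizes(self) -> list[int]:
        return [len(self.members(f)) for f in range(self.k)]


def make_folds(participants, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded random split of participants into k folds, sizes differing by <= 1."""
    participants = list(dict.fromkeys(participants))  # unique, order-stable
    if len(participants) < k:
        raise ValueError(f"need at least k={k} participants, got {len(participants)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(participants))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[participants[idx]] = pos % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def enumerate_specs(
    optional_predictors,
    always=ALWAYS_TERMS,
    response: str = "log_rt",
    family: str = "linear",
    include_baselines: bool = True,
) -> dict[str, ModelSpec]:
    """All 2^m optional-predictor subsets (with the always-included terms)
    plus the four baseline models; returns {spec_id: ModelSpec}."""
    optional = list(dict.fromkeys(optional_predictors))
    specs: dict[str, ModelSpec] = {}
    for r in range(len(optional) + 1):
        for combo in itertools.combinations(optional, r):
            terms = tuple(always) + combo
            spec_id = "+".join(combo) if combo else "(events:none)"
            specs[spec_id] = ModelSpec(
                response=response, family=family, fixed_terms=terms
            )
    if include_baselines:
        for spec_id, terms in BASELINES.items():
            specs[spec_id] = ModelSpec(
                response=response, family=family, fixed_terms=terms
            )
    return specs


@dataclass
class CVResult:
    """Per-(fold, spec) scores plus the spec table."""

    cells: pd.DataFrame  # columns: fold, spec_id, msd, n_train, n_test [, nmsd]
    specs: dict
    response: str
    family: str
    centering: str | None = None

    def spec_means(self, column: str = "nmsd") -> pd.Series:
        return (
            self.cells.groupby("spec_id")[column].mean().sort_values()
        )


def _spec_columns(terms) -> list[str]:
    cols = ["Intercept"]
    for term in terms:
        if term == "difficulty":
            cols += ["diff5", "diff7"]
        elif term == "day":
            cols += ["day2"]
        else:
            cols.append(term)
    return cols


def _make_estimator(family: str, nagq: int):
    if family == "lmm":
        return LinearMixedRegressor()
    if family == "tpm":
        return TwoPartLogNormalRegressor(nagq=nagq)
    if family == "glmm":
        return BinomialMixedClassifier(nagq=nagq)
    raise ValueError(f"unknown family {family!r}")


def run_cv(
    table: pd.DataFrame,
    specs: dict[str, ModelSpec],
    plan: FoldPlan,
    response: str = "log_rt",
    family: str = "lmm",
    nagq: int = 9,
    invert: bool = True,
) -> CVResult:
    """Train each spec on each fold; score fixed-effects predictions on the rest.

    ``invert=True`` (the default) is the demanding 20/80 scheme: the single
    fold trains and the pooled remainder tests.  ``invert=False`` gives the
    conventional 80/20 split.  For ``response='log_rt'`` the model is fitted
    and scored on responded trials only (the TPM path scores its intensity
    part, so cross-validation is limited to the RT variable); for
    ``response='omission'`` the squared deviation is between the 0/1
    indicator and the predicted probability.

    Failed fits leave a missing cell (NaN) with a warning; the cell is
    excluded from that spec's mean.
    """
    fold_of = table["participant_id"].map(plan.assignment)
    if fold_of.isna().any():
        raise ValueError("table contains participants missing from the fold plan")
    all_terms = sorted({t for s in specs.values() for t in s.fixed_terms})
    design = build_design(table, all_terms)
    # one complete-case restriction over the union of predictors, so every
    # spec is trained and scored on the same trials (MSD stays comparable)
    complete = design.notna().all(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} trials with missing predictor "
            "values (e.g. OrdFuel without an in-window hover)",
            stacklevel=2,
        )
        table = table[complete]
        design = design[complete]
        fold_of = fold_of[complete]

    if response == "log_rt" and family in ("lmm",):
        keep = table["omission"] == 0
        table_fit = table[keep]
        design_fit = design[keep]
        y_fit = np.log(table_fit["rt_ms"].to_numpy(dtype=float))
        fold_fit = fold_of[keep]
    else:
        table_fit = table
        design_fit = design
        fold_fit = fold_of
        if response == "log_rt":
            y_fit = None  # tpm: response frame passed separately
        else:
            y_fit = table_fit[response].to_numpy(dtype=float)

    groups_all = table_fit["participant_id"].to_numpy()
    rows = []
    for fold in range(plan.k):
        train_mask = (fold_fit == fold).to_numpy()
        if not invert:
            train_mask = ~train_mask
        test_mask = ~train_mask
        assert not np.any(train_mask & test_mask)
        for spec_id, spec in specs.items():
            cols = _spec_columns(spec.fixed_terms)
            X_train = design_fit.loc[train_mask, cols]
            X_test = design_fit.loc[test_mask, cols]
            est = _make_estimator(family, nagq)
            try:
                if family == "tpm":
                    est.fit(
                        X_train,
                        table_fit.loc[train_mask, ["rt_ms", "omission"]],
                        groups_all[train_mask],
                    )
                    resp_test = table_fit.loc[test_mask, "omission"].to_numpy() == 0
                    obs = np.log(
                        table_fit.loc[test_mask, "rt_ms"].to_numpy(dtype=float)[
                            resp_test
                        ]
                    )
                    pred = est.predict(X_test[resp_test])
                elif family == "glmm":
                    est.fit(X_train, y_fit[train_mask], groups_all[train_mask])
                    obs = y_fit[test_mask]
                    pred = est.predict_proba(X_test)
                else:
                    est.fit(X_train, y_fit[train_mask], groups_all[train_mask])
                    obs = y_fit[test_mask]
                    pred = est.predict(X_test)
                msd = float(np.mean((obs - pred) ** 2))
            except Exception as err:  # fit failure: flag the cell, keep going
                warnings.warn(
                    f"fit failed for fold {fold}, spec {spec_id}: {err}",
                    stacklevel=2,
                )
                msd = np.nan
            rows.append(
                {
                    "fold": fold,
                    "spec_id": spec_id,
                    "msd": msd,
                    "n_train": int(train_mask.sum()),
                    "n_test": int(test_mask.sum()),
                }
            )
    cells = pd.DataFrame(rows)
    return normalize_msd(
        CVResult(cells=cells, specs=specs, response=response, family=family)
    )


def normalize_msd(result: CVResult, centering: str = "grand") -> CVResult:
    """Attach NMSD = MSD minus a centring constant.

    ``centering='grand'`` subtracts the single grand mean MSD over all
    (fold, spec) cells of the analysis, preserving nonzero per-spec means;
    ``centering='per_fold'`` subtracts each fold's mean across specs, which
    removes between-fold level differences instead.  Either way the ordering
    of per-spec means is unchanged relative to MSD.
    """
    cells = result.cells.copy()
    if centering == "grand":
        cells["nmsd"] = cells["msd"] - cells["msd"].mean()
    elif centering == "per_fold":
        cells["nmsd"] = cells["msd"] - cells.groupby("fold")["msd"].transform("mean")
    else:
        raise ValueError(f"unknown centering {centering!r}")
    return CVResult(
        cells=cells,
        specs=result.specs,
        response=result.response,
        family=result.family,
        centering=centering,
    )


def rank_and_stability(
    result: CVResult, top_frac: float = 0.1
) -> dict:
    """Rank specs by mean NMSD and summarize per-fold consistency.

    Returns a dict with:

    * ``ranking`` -- DataFrame of specs sorted by mean NMSD (rank 1 best);
    * ``inclusion`` -- per optional predictor, its inclusion frequency among
      the top ``top_frac`` fraction of specs, overall and per fold;
    * ``best_per_fold`` -- the best spec id in each fold;
    * ``discordant_folds`` -- folds whose best spec differs from the overall
      best.
    """
    means = result.spec_means("nmsd")
    ranking = means.rename("mean_nmsd").reset_index()
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    n_top = max(1, int(round(top_frac * len(means))))
    predictors = sorted(
        {
            t
            for s in result.specs.values()
            for t in s.fixed_terms
            if t not in ALWAYS_TERMS
        }
    )

    def inclusion_freq(ordered_ids) -> dict:
        top = list(ordered_ids)[:n_top]
        freq = {}
        for pred in predictors:
            freq[pred] = float(
                np.mean(
                    [pred in result.specs[sid].fixed_terms for sid in top]
                )
            )
        return freq

    overall = inclusion_freq(means.index)
    per_fold = {}
    best_per_fold = {}
    for fold, grp in result.cells.groupby("fold"):
        ordered = grp.sort_values("nmsd")["spec_id"]
        per_fold[int(fold)] = inclusion_freq(ordered)
        best_per_fold[int(fold)] = ordered.iloc[0]
    overall_best = means.index[0]
    discordant = [f for f, sid in best_per_fold.items() if sid != overall_best]
    return {
        "ranking": ranking,
        "inclusion": {"overall": overall, "per_fold": per_fold},
        "best_per_fold": best_per_fold,
        "discordant_folds": discordant,
        "n_top": n_top,
    }
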