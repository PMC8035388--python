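"""Per-trial predictor construction for DRT workload analysis.

Each DRT trial (the interval between two prompts) is annotated with:

* windowed event flags -- did a FAHO/FAR/HHO/HR/MR event occur in the
  ``w`` seconds before the prompt, for window lengths 3, 4, and 5 s;
* event counts in the 3-s window (#HHO3s, #FAHO3s, #FAR3s);
* ``WeightFuel`` -- the power mean of order ``p`` (default 1/4) of all
  on-screen fuel fractions, which weights low fuel levels more heavily for
  ``p < 1``;
* ``OrdFuel`` -- the ascending rank of the last-hovered UAV's fuel among all
  on-screen fuels at the hover instant (1 = lowest, ties take the minimum
  rank), missing when no hover occurred in the window;
* ``MissPrevDRT`` -- whether the previous trial was an omission;
* optional within-participant z-standardization of continuous predictors.

Windows are half-open ``(prompt_t - w, prompt_t]``: an event coincident with
the prompt counts, because it precedes the response.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import EVENT_TYPES

__all__ = [
    "weight_fuel",
    "ord_fuel",
    "window_events",
    "miss_prev_drt",
    "zstandardize_within_participant",
    "reconstruct_fuel_features",
    "build_feature_table",
]

GROUP_KEYS = ["participant_id", "day", "block"]
COUNT_TYPES = ("HHO", "FAHO", "FAR")


def weight_fuel(fuels, p: float = 0.25) -> float:
    """Power mean of order ``p`` of the on-screen fuel fractions.

    ``(sum_k f_k^p / K) ** (1/p)`` for the K fuel levels ``f_k``.  For
    ``p < 1`` low fuel levels dominate the mean (several near-empty UAVs pull
    the summary down sharply); ``p = 1`` is the arithmetic mean.  NaN entries
    (absent UAV slots) are ignored.
    """
    fuels = np.asarray(fuels, dtype=float)
    fuels = fuels[~np.isnan(fuels)]
    if fuels.size == 0:
        raise ValueError("weight_fuel requires at least one fuel level")
    if p == 0:
        raise ValueError("exponent p must be nonzero")
    if (fuels < 0).any() or (fuels > 1).any():
        raise ValueError("fuel levels must lie in [0, 1]")
    if p < 0 and (fuels == 0).any():
        return 0.0
    return float(np.mean(fuels**p) ** (1.0 / p))


def ord_fuel(fuels_at_hover, hovered_index: int) -> int:
    """Ascending rank of the hovered UAV's fuel among all on-screen fuels.

    ``hovered_index`` is 0-based into ``fuels_at_hover``; NaN entries are
    ignored for ranking but invalidate ``hovered_index`` if it points at one.
    Ties take the minimum rank, so hovering any of several equally-lowest
    UAVs gives rank 1.
    """
    fuels = np.asarray(fuels_at_hover, dtype=float)
    if not 0 <= hovered_index < fuels.size or np.isnan(fuels[hovered_index]):
        raise ValueError(f"hovered_index {hovered_index!r} is not a valid UAV slot")
    valid = fuels[~np.isnan(fuels)]
    return int(1 + np.sum(valid < fuels[hovered_index]))


def miss_prev_drt(trial) -> bool:
    """Omission flag of the preceding trial within the same block.

    The first trial of a block has no predecessor; such trials must be
    excluded upstream before this predictor is used.
    """
    prev = trial["prev_omission"] if "prev_omission" in trial else None
    if prev is None or (np.isscalar(prev) and pd.isna(prev)):
        raise ValueError(
            "trial has no previous-trial information; run trial exclusion first"
        )
    return bool(prev)


def _group_codes(trials: pd.DataFrame, events: pd.DataFrame):
    """Shared integer codes for the (participant, day, block) keys."""
    combined = pd.concat(
        [trials[GROUP_KEYS], events[GROUP_KEYS]], ignore_index=True
    )
    codes, _ = pd.factorize(pd.MultiIndex.from_frame(combined))
    return codes[: len(trials)], codes[len(trials) :]


def window_events(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    w: float,
    types=EVENT_TYPES,
) -> pd.DataFrame:
    """Per-trial event counts and occurrence flags for one window length.

    An event at time ``t`` in the same (participant, day, block) counts for a
    trial when ``prompt_t - w < t <= prompt_t``.  Returns a DataFrame indexed
    like ``trials`` with ``count_<type>`` and ``flag_<type>`` columns.
    """
    if w <= 0:
        raise ValueError("window length must be > 0")
    tcodes, ecodes = _group_codes(trials, events)
    prompts = trials["prompt_t"].to_numpy(dtype=float)
    ev_t = events["t"].to_numpy(dtype=float)
    # composite sort key: group code, then time; the scale keeps groups apart
    scale = max(prompts.max(initial=0.0), ev_t.max(initial=0.0)) + w + 1.0
    hi_key = tcodes * scale + prompts
    lo_key = tcodes * scale + prompts - w
    ev_type = events["event_type"].to_numpy()
    result = pd.DataFrame(index=trials.index)
    for typ in types:
        keys = np.sort(ecodes[ev_type == typ] * scale + ev_t[ev_type == typ])
        result[f"count_{typ}"] = np.searchsorted(
            keys, hi_key, side="right"
        ) - np.searchsorted(keys, lo_key, side="right")
    for typ in types:
        result[f"flag_{typ}"] = (result[f"count_{typ}"] > 0).astype(int)
    return result


def zstandardize_within_participant(
    values: pd.Series,
    groups,
    ddof: int = 1,
) -> pd.Series:
    """Z-standardize a feature column within each participant.

    ``groups`` is a Series (or frame) of grouping keys aligned with
    ``values``.  Uses the sample (n-1) standard deviation.  A group with zero
    variance is set to 0 with a warning rather than producing NaN.
    """
    df = pd.DataFrame({"v": values.astype(float)})
    grouped = df.groupby(
        [groups] if isinstance(groups, pd.Series) else list(groups), sort=False
    )["v"]
    mean = grouped.transform("mean")
    sd = grouped.transform(lambda s: s.std(ddof=ddof))
    zero = (sd == 0) | sd.isna()
    if zero.any():
        warnings.warn(
            "zero-variance group(s) in within-participant standardization; "
            "values set to 0",
            stacklevel=2,
        )
        sd = sd.where(~zero, 1.0)
    z = (df["v"] - mean) / sd
    z[zero] = 0.0
    return z.rename(values.name)


def _snapshot_features(
    trials: pd.DataFrame,
    snapshots: pd.DataFrame,
    exponent: float,
    window: float,
) -> pd.DataFrame:
    """WeightFuel at prompt time and OrdFuel of the last in-window hover."""
    fuel_cols = [c for c in snapshots.columns if c.startswith("fuel_")]
    hfuel_cols = [c for c in snapshots.columns if c.startswith("hfuel_")]
    merged = trials.merge(
        snapshots,
        on=GROUP_KEYS + ["prompt_t", "difficulty"],
        how="left",
        validate="one_to_one",
    )
    fuels = merged[fuel_cols].to_numpy()
    # vectorized power mean; semantics identical to weight_fuel() per row
    if exponent == 0:
        raise ValueError("exponent p must be nonzero")
    with np.errstate(invalid="ignore", divide="ignore"):
        wf = np.nanmean(fuels**exponent, axis=1) ** (1.0 / exponent)
    wf[np.isnan(fuels).all(axis=1)] = np.nan
    hov_t = merged["hover_t"].to_numpy()
    hov_slot = merged["hover_slot"].to_numpy()
    prompts = merged["prompt_t"].to_numpy()
    hfuels = merged[hfuel_cols].to_numpy()
    of = np.full(len(merged), np.nan)
    in_window = (~np.isnan(hov_t)) & (hov_t > prompts - window) & (hov_t <= prompts)
    idx = np.flatnonzero(in_window)
    if len(idx):
        slots = hov_slot[idx].astype(int) - 1
        hovered = hfuels[idx, slots]
        of[idx] = 1 + np.nansum(hfuels[idx] < hovered[:, None], axis=1)
    return pd.DataFrame({"WeightFuel": wf, "OrdFuel": of}, index=trials.index)


def reconstruct_fuel_features(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    drain_rate: float = 0.05,
    exponent: float = 0.25,
    window: float = 3.0,
    max_age: float = 100.0,
    refuel_gain: float = 0.75,
) -> pd.DataFrame:
    """WeightFuel and OrdFuel from interaction-only logs.

    Real recordings log UAV fuel only when the operator interacts with a
    UAV.  Fuel at prompt time is therefore reconstructed per UAV by linear
    drain extrapolation from its most recent observation: hovers and
    false-alarm clicks observe the gauge directly; a successful refuel is
    imputed at the observed level plus the expected gain (75% of a tank,
    capped); a crash removes the UAV (its replacement is unknown until first
    observed).  Observations older than ``max_age`` are discarded, and the
    power mean runs over however many UAVs are currently known (NaN when
    none are).  OrdFuel ranks the hovered UAV's observed fuel among the
    reconstructed fuels of the other known UAVs at the hover instant.
    """
    out_wf = np.full(len(trials), np.nan)
    out_of = np.full(len(trials), np.nan)
    ev_by_group = dict(tuple(events.groupby(GROUP_KEYS, sort=False)))
    pos_of = pd.Series(np.arange(len(trials)), index=trials.index)
    for key, grp in trials.groupby(GROUP_KEYS, sort=False):
        ev = ev_by_group.get(key)
        if ev is None:
            continue
        ev = ev.sort_values("t", kind="stable")
        ev_t = ev["t"].to_numpy(dtype=float)
        ev_type = ev["event_type"].to_numpy()
        ev_uav = ev["uav_id"].to_numpy()
        ev_fuel = ev["fuel_at_event"].to_numpy(dtype=float)
        prompts = grp["prompt_t"].to_numpy(dtype=float)
        rows = pos_of.loc[grp.index].to_numpy()

        obs: dict = {}  # uav_id -> (t_obs, fuel_obs)
        last_hover = None  # (t, uav_id, fuel)
        e = 0
        for prompt, row in zip(prompts, rows):
            while e < len(ev_t) and ev_t[e] <= prompt:
                typ = ev_type[e]
                if typ in ("HHO", "FAHO"):
                    obs[ev_uav[e]] = (ev_t[e], ev_fuel[e])
                    last_hover = (ev_t[e], ev_uav[e], ev_fuel[e])
                elif typ == "FAR":
                    obs[ev_uav[e]] = (ev_t[e], ev_fuel[e])
                elif typ == "HR":
                    obs[ev_uav[e]] = (
                        ev_t[e],
                        min(1.0, ev_fuel[e] + refuel_gain),
                    )
                elif typ == "MR":
                    obs.pop(ev_uav[e], None)
                e += 1

            def fuels_at(when):
                vals = [
                    max(0.0, f - drain_rate * (when - t0))
                    for t0, f in obs.values()
                    if when - t0 <= max_age
                ]
                return np.asarray(vals)

            fuels = fuels_at(prompt)
            if fuels.size:
                out_wf[row] = np.mean(fuels**exponent) ** (1.0 / exponent)
            if last_hover is not None and prompt - window < last_hover[0] <= prompt:
                t_h, uav_h, f_h = last_hover
                others = np.asarray(
                    [
                        max(0.0, f - drain_rate * (t_h - t0))
                        for uid, (t0, f) in obs.items()
                        if uid != uav_h and t_h - t0 <= max_age
                    ]
                )
                out_of[row] = 1 + int(np.sum(others < f_h))
    return pd.DataFrame(
        {"WeightFuel": out_wf, "OrdFuel": out_of}, index=trials.index
    )


def build_feature_table(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    snapshots: pd.DataFrame | None = None,
    windows=(3.0, 4.0, 5.0),
    count_window: float = 3.0,
    exponent: float = 0.25,
    standardize=(),
    post_window: float = 5.0,
) -> pd.DataFrame:
    """Assemble the full per-trial predictor table.

    Parameters
    ----------
    trials, events : DataFrames
        Output of :func:`workloadcv.data.build_trials` and the event log.
    snapshots : DataFrame, optional
        Simulator state snapshots giving ground-truth fuel vectors.  When
        absent, WeightFuel and OrdFuel are reconstructed from the
        interaction log by linear drain extrapolation
        (:func:`reconstruct_fuel_features`).
    windows : sequence of float
        Window lengths for the per-type occurrence flags.
    count_window : float
        Window for the #HHO/#FAHO/#FAR counts (3 s by convention).
    exponent : float
        Power-mean order ``p`` for WeightFuel.
    standardize : sequence of str
        Columns to z-standardize within participant (adds ``<col>_z``).
    post_window : float
        Window after the prompt for the MR (crash) count used by the
        overload analysis (column ``nMRpost``).
    """
    table = trials.copy()
    for w in windows:
        wf = window_events(table, events, w)
        tag = f"{w:g}s"
        for typ in EVENT_TYPES:
            table[f"{typ}_{tag}"] = wf[f"flag_{typ}"]
    counts = window_events(table, events, count_window, types=COUNT_TYPES)
    tag = f"{count_window:g}s"
    for typ in COUNT_TYPES:
        table[f"n{typ}{tag}"] = counts[f"count_{typ}"]

    if snapshots is not None:
        table = table.join(
            _snapshot_features(table, snapshots, exponent, count_window)
        )
    else:
        table = table.join(
            reconstruct_fuel_features(
                table, events, exponent=exponent, window=count_window
            )
        )

    if "prev_omission" in table.columns:
        table["MissPrevDRT"] = table["prev_omission"].astype(float)

    # crashes shortly after the prompt: the overload outcome
    mr = window_events(
        table.assign(prompt_t=table["prompt_t"] + post_window),
        events,
        post_window,
        types=("MR",),
    )
    table["nMRpost"] = mr["count_MR"].to_numpy()

    for col in standardize:
        table[f"{col}_z"] = zstandardize_within_participant(
            table[col], table["participant_id"]
        )
    return table
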