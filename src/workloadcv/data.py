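"""Log I/O, trial construction, and exclusion filters.

The two primary inputs are delimited text logs:

* event log -- one row per scored game interaction, columns
  ``participant_id, day, block, difficulty, t, event_type, uav_id,
  fuel_at_event, points``;
* DRT log -- one row per prompt, columns ``participant_id, day, block,
  difficulty, prompt_t, rt_ms, omission`` (``rt_ms`` empty on omissions).

Trials are the intervals between consecutive prompts within a block.  Two
exclusion filters mirror standard practice for this paradigm:

* participant-days with omission rates above 45% in two or more difficulty
  conditions are dropped (insufficient secondary-task engagement);
* the first trial of each block (no previous-trial information) and trials
  whose most recent UAV interaction lies more than 100 s before the prompt
  (no usable task-state information) are dropped.

Every filter records an audit trail of counts removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EVENT_TYPES

__all__ = [
    "Dataset",
    "read_logs",
    "write_logs",
    "build_trials",
    "exclude_participants",
    "exclude_trials",
]

EVENT_COLUMNS = [
    "participant_id",
    "day",
    "block",
    "difficulty",
    "t",
    "event_type",
    "uav_id",
    "fuel_at_event",
    "points",
]
DRT_COLUMNS = [
    "participant_id",
    "day",
    "block",
    "difficulty",
    "prompt_t",
    "rt_ms",
    "omission",
]
KEYS = ["participant_id", "day", "block"]


class SchemaError(ValueError):
    """A log file violates the expected column schema or value domain."""


@dataclass
class Dataset:
    """Event log + DRT trials with a filter audit trail."""

    events: pd.DataFrame
    trials: pd.DataFrame
    provenance: list = field(default_factory=list)

    def copy(self) -> "Dataset":
        return Dataset(
            self.events.copy(), self.trials.copy(), list(self.provenance)
        )


def _validate_events(events: pd.DataFrame, source: str = "<memory>") -> None:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise SchemaError(f"{source}: event log missing columns {sorted(missing)}")
    bad = ~events["event_type"].isin(EVENT_TYPES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise SchemaError(
            f"{source}, line {line}: unknown event_type "
            f"{events.loc[bad].iloc[0]['event_type']!r}"
        )


def _validate_drt(drt: pd.DataFrame, source: str = "<memory>") -> None:
    missing = set(DRT_COLUMNS) - set(drt.columns)
    if missing:
        raise SchemaError(f"{source}: DRT log missing columns {sorted(missing)}")
    inconsistent = (drt["omission"] == 0) & drt["rt_ms"].isna()
    inconsistent |= (drt["omission"] == 1) & drt["rt_ms"].notna()
    if inconsistent.any():
        line = int(np.flatnonzero(inconsistent.to_numpy())[0]) + 2
        raise SchemaError(
            f"{source}, line {line}: rt_ms must be present exactly when "
            "omission is 0"
        )


def read_logs(event_path: str | Path, drt_path: str | Path) -> Dataset:
    """Read event and DRT logs and build the trial table.

    Raises :class:`SchemaError` (with the offending line number) for unknown
    event types or inconsistent RT/omission rows, and the underlying pandas
    parse error for malformed delimited text.
    """
    event_path, drt_path = Path(event_path), Path(drt_path)
    # round_trip parsing keeps write -> read -> write byte-stable
    events = pd.read_csv(event_path, float_precision="round_trip")
    drt = pd.read_csv(drt_path, float_precision="round_trip")
    if events.empty:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    if drt.empty:
        drt = pd.DataFrame(columns=DRT_COLUMNS)
    _validate_events(events, str(event_path))
    _validate_drt(drt, str(drt_path))
    trials = build_trials(drt)
    return Dataset(
        events=events,
        trials=trials,
        provenance=[{"step": "read", "events": len(events), "trials": len(trials)}],
    )


def write_logs(dataset: Dataset, event_path: str | Path, drt_path: str | Path) -> None:
    """Write the event log and the DRT log (prompt-level columns only).

    ``write_logs`` then :func:`read_logs` reproduces the dataset; writing the
    result of a read is byte-stable.
    """
    try:
        dataset.events[EVENT_COLUMNS].to_csv(event_path, index=False)
        dataset.trials[DRT_COLUMNS].to_csv(drt_path, index=False)
    except OSError as err:
        raise OSError(f"failed to write logs: {err}") from err


def build_trials(drt: pd.DataFrame) -> pd.DataFrame:
    """One trial per prompt, with block-wise index and previous-omission flag.

    Prompts must be sorted by time within each (participant, day, block);
    ``trial_index`` counts from 1 within the block and ``prev_omission`` is
    the preceding trial's omission flag (missing for the first trial).
    Duplicate prompt times within a block are a data error.
    """
    trials = drt.copy().reset_index(drop=True)
    if trials.empty:
        trials["trial_index"] = pd.Series(dtype=int)
        trials["prev_omission"] = pd.Series(dtype=float)
        return trials
    grouped = trials.groupby(KEYS, sort=False)
    if trials.duplicated(subset=KEYS + ["prompt_t"]).any():
        raise ValueError("duplicate prompt times within a block")
    diffs = grouped["prompt_t"].diff()
    if (diffs.dropna() <= 0).any():
        raise ValueError("prompts must be sorted by time within each block")
    trials["trial_index"] = grouped.cumcount() + 1
    trials["prev_omission"] = grouped["omission"].shift(1)
    return trials


def exclude_participants(
    dataset: Dataset,
    threshold: float = 0.45,
    min_conditions: int = 2,
) -> tuple[Dataset, pd.DataFrame]:
    """Drop participant-days with excessive omission rates.

    A participant-day is removed when its omission rate is strictly above
    ``threshold`` in at least ``min_conditions`` of the difficulty
    conditions.  Exclusion is day-wise: a participant may be kept on one day
    and dropped on the other.  Returns the filtered dataset and a removal
    report (one row per removed participant-day with the per-condition
    rates).
    """
    trials = dataset.trials
    if trials.empty:
        return dataset.copy(), pd.DataFrame(
            columns=["participant_id", "day", "n_conditions_above"]
        )
    rates = (
        trials.groupby(["participant_id", "day", "difficulty"])["omission"]
        .mean()
        .unstack("difficulty")
    )
    n_above = (rates > threshold).sum(axis=1)
    removed = n_above[n_above >= min_conditions].index
    report = rates.loc[removed].assign(
        n_conditions_above=n_above[removed]
    ).reset_index()

    mask = ~pd.MultiIndex.from_frame(trials[["participant_id", "day"]]).isin(removed)
    ev_mask = ~pd.MultiIndex.from_frame(
        dataset.events[["participant_id", "day"]]
    ).isin(removed)
    out = Dataset(
        events=dataset.events[ev_mask].reset_index(drop=True),
        trials=trials[mask].reset_index(drop=True),
        provenance=dataset.provenance
        + [
            {
                "step": "exclude_participants",
                "threshold": threshold,
                "min_conditions": min_conditions,
                "removed_participant_days": len(removed),
                "removed_trials": int((~mask).sum()),
                "per_day_removals": report.groupby("day")["participant_id"]
                .nunique()
                .to_dict()
                if len(report)
                else {},
            }
        ],
    )
    return out, report


def _time_since_last_event(trials: pd.DataFrame, events: pd.DataFrame) -> np.ndarray:
    """Seconds from the most recent same-block event to each prompt (NaN if none)."""
    from .features import _group_codes

    tcodes, ecodes = _group_codes(trials, events)
    prompts = trials["prompt_t"].to_numpy(dtype=float)
    ev_t = events["t"].to_numpy(dtype=float)
    scale = max(prompts.max(initial=0.0), ev_t.max(initial=0.0)) + 1.0
    order = np.argsort(ecodes * scale + ev_t, kind="stable")
    keys = (ecodes * scale + ev_t)[order]
    idx = np.searchsorted(keys, tcodes * scale + prompts, side="right") - 1
    out = np.full(len(trials), np.nan)
    valid = idx >= 0
    if valid.any():
        same_group = ecodes[order][idx[valid]] == tcodes[valid]
        pos = np.flatnonzero(valid)[same_group]
        out[pos] = prompts[pos] - ev_t[order][idx[valid]][same_group]
    return out


def exclude_trials(
    dataset: Dataset, max_gap: float = 100.0
) -> tuple[Dataset, dict]:
    """Drop first-of-block trials and trials with stale task information.

    Removes (a) the first trial of every block, whose previous-trial
    predictor is undefined, and (b) trials whose most recent UAV interaction
    is absent or more than ``max_gap`` seconds before the prompt, for which
    task-state predictors cannot be computed.  Returns the filtered dataset
    and an audit dict of removal counts.
    """
    trials = dataset.trials
    if trials.empty:
        return dataset.copy(), {"first_trial": 0, "stale": 0, "retained": 0}
    first = trials["trial_index"] == 1
    gap = _time_since_last_event(trials, dataset.events)
    stale = np.isnan(gap) | (gap > max_gap)
    drop = first | stale
    report = {
        "first_trial": int(first.sum()),
        "stale": int((stale & ~first).sum()),
        "removed": int(drop.sum()),
        "retained": int((~drop).sum()),
    }
    out = Dataset(
        events=dataset.events.copy(),
        trials=trials[~drop].reset_index(drop=True),
        provenance=dataset.provenance
        + [{"step": "exclude_trials", "max_gap": max_gap, **report}],
    )
    return out, report
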