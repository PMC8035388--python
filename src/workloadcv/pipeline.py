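"""End-to-end assembly: simulated (or read) logs -> analysis-ready table.

Chains trial construction, the participant- and trial-level exclusion
filters, predictor construction, and within-participant standardization into
one call, so tests, scripts, and the CLI all run the identical pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Dataset, build_trials, exclude_participants, exclude_trials
from .features import build_feature_table, zstandardize_within_participant
from .simulate import StudyData

__all__ = ["study_feature_table", "block_summary"]

#: continuous predictors standardized within participant-day by default
STANDARDIZE_COLS = ("WeightFuel", "nHHO3s", "nFAR3s")


def study_feature_table(
    study: StudyData,
    exponent: float = 0.25,
    windows=(3.0, 4.0, 5.0),
    standardize=STANDARDIZE_COLS,
    standardize_keys=("participant_id", "day"),
    exclusion_threshold: float = 0.45,
    max_gap: float = 100.0,
) -> pd.DataFrame:
    """Feature table for a simulated study after both exclusion filters.

    Standardization is within participant-day (each day is analyzed
    separately, so this matches within-participant standardization of a
    single day's data).  Returns the per-trial table with windowed flags,
    counts, WeightFuel/OrdFuel/MissPrevDRT, and ``<col>_z`` columns.
    """
    dataset = Dataset(events=study.events, trials=build_trials(study.drt))
    dataset, _ = exclude_participants(dataset, threshold=exclusion_threshold)
    dataset, _ = exclude_trials(dataset, max_gap=max_gap)
    table = build_feature_table(
        dataset.trials,
        dataset.events,
        snapshots=study.snapshots,
        windows=windows,
        exponent=exponent,
    )
    for col in standardize:
        table[f"{col}_z"] = zstandardize_within_participant(
            table[col], [table[k] for k in standardize_keys]
        )
    return table


def block_summary(study: StudyData) -> pd.DataFrame:
    """Per-block points and event counts (the descriptive-ladder input)."""
    counts = (
        study.events.groupby(
            ["participant_id", "day", "block", "difficulty", "event_type"]
        )
        .size()
        .unstack("event_type", fill_value=0)
        .reset_index()
    )
    out = study.block_scores.merge(
        counts,
        on=["participant_id", "day", "block", "difficulty"],
        how="left",
    )
    for typ in ("FAHO", "FAR", "HHO", "HR", "MR"):
        if typ not in out.columns:
            out[typ] = 0
        out[typ] = out[typ].fillna(0).astype(int)
    return out.rename(columns={"score": "points"})
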