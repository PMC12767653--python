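"""Descriptive behavioural analyses.

Per-cell (participant x eye x location x condition) accuracy and mean
perceived flash counts, the visible/invisible classification of visual-field
locations by flash-detection accuracy, Pearson correlations between matched
cell values (e.g. detection accuracy vs illusion strength, or accuracy vs
model BIC), and grouped summaries (mean +/- between-participant SE).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import DegenerateDataError
from .simulate import build_stimulus_grid
from .types import Condition

__all__ = [
    "accuracy_by_cell",
    "classify_visibility",
    "mean_count_by_cell",
    "correlate_paired",
    "group_summary",
]

_CELL_KEYS = ["participant_id", "eye", "location_id", "condition"]


def _frame(trials) -> pd.DataFrame:
    df = trials if isinstance(trials, pd.DataFrame) else pd.DataFrame(list(trials))
    return df


def accuracy_by_cell(trials) -> pd.DataFrame:
    """Fraction of trials whose reported count equals the true flash count.

    The truth is the number of flashes physically presented (0 or 1 from the
    condition code); detection yes/no reports are already coded as counts 1/0,
    so the same comparison applies.  Empty cells are simply absent.
    """
    df = _frame(trials)
    if df.empty:
        return pd.DataFrame(columns=_CELL_KEYS + ["value", "n_trials"])
    truth = df["condition"].map(lambda c: Condition.from_label(c).n_flashes)
    df = df.assign(_correct=(df["response"] == truth).astype(float))
    out = (
        df.groupby(_CELL_KEYS, as_index=False)
        .agg(value=("_correct", "mean"), n_trials=("_correct", "size"))
    )
    return out


def classify_visibility(accuracy_cells: pd.DataFrame) -> pd.DataFrame:
    """Label each (participant, eye, location) visible or invisible.

    Visible means flash-detection accuracy strictly above 50%; exactly 50%
    counts as invisible.  Input must be F1B0 detection-accuracy cells.
    """
    df = _frame(accuracy_cells)
    if not (df["condition"] == "F1B0").all():
        raise ValueError("visibility is defined on F1B0 detection accuracy cells")
    out = df[["participant_id", "eye", "location_id"]].copy()
    out["label"] = np.where(df["value"] > 0.5, "visible", "invisible")
    return out


def mean_count_by_cell(trials, condition_filter=None) -> pd.DataFrame:
    """Per-cell mean reported flash count, optionally for given conditions."""
    df = _frame(trials)
    if condition_filter is not None:
        if isinstance(condition_filter, str):
            condition_filter = [condition_filter]
        df = df[df["condition"].isin(condition_filter)]
    if df.empty:
        return pd.DataFrame(columns=_CELL_KEYS + ["value", "n_trials"])
    return (
        df.groupby(_CELL_KEYS, as_index=False)
        .agg(value=("response", "mean"), n_trials=("response", "size"))
    )


def correlate_paired(x_cells: pd.DataFrame, y_cells: pd.DataFrame, on=None):
    """Pearson correlation between two cell tables matched on their keys.

    Returns ``(r, p, n)`` with a two-sided p-value.  Raises
    :class:`DegenerateDataError` when fewer than 3 matched pairs exist or
    either side has zero variance.
    """
    on = on or [k for k in ("participant_id", "eye", "location_id") if k in x_cells.columns]
    merged = pd.merge(
        x_cells[on + ["value"]],
        y_cells[on + ["value"]],
        on=on,
        suffixes=("_x", "_y"),
    )
    x = merged["value_x"].to_numpy(float)
    y = merged["value_y"].to_numpy(float)
    if len(x) < 3:
        raise DegenerateDataError(f"only {len(x)} matched pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the paired vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))


def _eccentricity_map():
    grid = build_stimulus_grid()
    return dict(zip(grid["location_id"], grid["eccentricity_deg"]))


def group_summary(
    cells: pd.DataFrame, grouping: str, visibility: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean +/- between-participant SE of cell values per group level.

    ``grouping`` is ``"visibility"`` (requires labels from
    :func:`classify_visibility`), ``"eccentricity"`` (derived from
    location_id) or ``"condition"``.  Values are first averaged within each
    participant, then summarised across participants, so the SE reflects
    between-participant variability.
    """
    df = _frame(cells).copy()
    if grouping == "eccentricity":
        df["level"] = df["location_id"].map(_eccentricity_map())
    elif grouping == "condition":
        df["level"] = df["condition"]
    elif grouping == "visibility":
        if visibility is None:
            raise ValueError("visibility labels required for grouping='visibility'")
        df = pd.merge(df, visibility, on=["participant_id", "eye", "location_id"])
        df["level"] = df["label"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    per_participant = (
        df.groupby(["level", "participant_id"])["value"].mean().reset_index()
    )
    out = (
        per_participant.groupby("level")["value"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    out["se"] = (out["sd"] / np.sqrt(out["n"])).fillna(0.0)
    return out[["level", "mean", "se", "n"]]
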