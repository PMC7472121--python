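"""Intensity classification, per-day summaries, and wear-validity rules.

Cut-points (30/100/400 mg) partition waking wear epochs into inactivity,
light, moderate and vigorous; each named threshold belongs to the higher
class ("at or above"). A day is valid when it carries at least 16 h of wear,
and a subject enters analysis with at least 5 valid days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CutPoints

CLASSES = ("inactivity", "light", "moderate", "vigorous")


def classify_epoch(enmo_mg, cuts: CutPoints = CutPoints()):
    """Intensity class for scalar or array ENMO; thresholds go to the higher class."""
    arr = np.asarray(enmo_mg, dtype=float)
    if (arr < 0).any():
        raise ValueError("ENMO must be non-negative")
    bins = [cuts.light, cuts.moderate, cuts.vigorous]
    idx = np.digitize(arr, bins, right=False)
    out = np.take(CLASSES, idx)
    return out.item() if np.isscalar(enmo_mg) or arr.ndim == 0 else out


@dataclass(frozen=True)
class DaySummary:
    date: object
    wear_hours: float
    acc_mean_mg: float
    inactive_min: float
    light_min: float
    moderate_min: float
    vigorous_min: float
    sleep_min: float
    valid: bool


def summarize_day(
    epochs: pd.DataFrame,
    cuts: CutPoints = CutPoints(),
    min_wear_hours: float = 16.0,
) -> DaySummary:
    """Summary of one calendar date of epoch data.

    Intensity minutes and the daily acceleration mean (ACC) are taken over
    waking wear non-sleep epochs; sleep minutes come from the sleep flag;
    wear hours from the wear flag across the whole date.
    """
    if len(epochs) == 0:
        raise ValueError("no epochs for this date")
    epoch_min = (epochs.index[1] - epochs.index[0]).total_seconds() / 60 if len(epochs) > 1 else 5 / 60
    date = epochs.index[0].date()
    wear = epochs["wear"].to_numpy()
    wear_hours = float(wear.sum() * epoch_min / 60)
    active = wear & epochs["waking"].to_numpy() & ~epochs["sleep"].to_numpy()
    counts = dict.fromkeys(CLASSES, 0.0)
    acc = float("nan")
    if active.any():
        labels = classify_epoch(epochs.loc[active, "enmo_mg"].to_numpy(), cuts)
        for cls in CLASSES:
            counts[cls] = float((labels == cls).sum() * epoch_min)
        acc = float(epochs.loc[active, "enmo_mg"].mean())
    sleep_min = float(epochs["sleep"].sum() * epoch_min)
    return DaySummary(
        date=date,
        wear_hours=wear_hours,
        acc_mean_mg=acc,
        inactive_min=counts["inactivity"],
        light_min=counts["light"],
        moderate_min=counts["moderate"],
        vigorous_min=counts["vigorous"],
        sleep_min=sleep_min,
        valid=wear_hours >= min_wear_hours,
    )


def summarize_days(epochs: pd.DataFrame, cuts: CutPoints = CutPoints(), min_wear_hours: float = 16.0) -> pd.DataFrame:
    """One DaySummary row per calendar date."""
    rows = [
        summarize_day(day, cuts, min_wear_hours)
        for _, day in epochs.groupby(epochs.index.date, sort=True)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def validate_subject(days: pd.DataFrame, min_valid_days: int = 5) -> tuple[bool, str]:
    """Inclusion decision: at least ``min_valid_days`` days with >=16 h wear."""
    if len(days) == 0:
        raise ValueError("no day summaries")
    n_valid = int(days["valid"].sum())
    if n_valid >= min_valid_days:
        return True, f"included ({n_valid} valid days)"
    return False, f"excluded: {n_valid} valid days < {min_valid_days}"


def write_day_csv(days: pd.DataFrame, path) -> None:
    out = days.rename(
        columns={
            "wear_hours": "wear_h",
            "acc_mean_mg": "acc_mg",
        }
    )
    out.round(4).to_csv(path, index=False)
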