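"""MVPA bout detection, weekly bout minutes, MET-bouts, WHO classification.

A bout is an episode of at least 10 min during which at least 80% of the
5 s epochs reach the 100 mg MVPA threshold. Weekly estimates divide the
summed bout minutes by the number of assessment days and multiply by 7.
The WHO recommendation is met at 150 weekly moderate bout minutes, 75
vigorous minutes, or 450 MET-bouts; the 450 figure derives from 3 and 6 MET
thresholds (150*3 = 75*6 = 450) while the MET-bout score itself weights
moderate and vigorous minutes by 4 and 8 — both conventions are kept as
stated, not reconciled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Bout, WeeklyPA

MVPA_THRESHOLD_MG = 100.0
VIGOROUS_MG = 400.0
BOUT_MIN_DURATION_MIN = 10.0
BOUT_FRACTION = 0.8

WHO_MODERATE_MIN = 150.0
WHO_VIGOROUS_MIN = 75.0
WHO_MET_THRESHOLD = 450.0
MET_WEIGHTS = (4.0, 8.0)
MET_THRESHOLDS = (3.0, 6.0)  # define the 450 criterion: 150*3 = 75*6


def _scan_bouts(enmo: np.ndarray, epoch_min: float) -> list[tuple[int, int]]:
    """Greedy left-to-right scan over one contiguous eligible block.

    A candidate starts at an epoch at/above threshold and extends while the
    running fraction of threshold epochs stays >= 0.8; trailing sub-threshold
    epochs are trimmed; the episode is emitted if it lasts >= 10 min. No
    re-entry: scanning resumes after the emitted (or abandoned) window.
    """
    above = enmo >= MVPA_THRESHOLD_MG
    min_epochs = int(round(BOUT_MIN_DURATION_MIN / epoch_min))
    out = []
    i = 0
    n = len(enmo)
    while i < n:
        if not above[i]:
            i += 1
            continue
        hits = 0
        last_hit = i
        j = i
        while j < n:
            hits += above[j]
            if hits < BOUT_FRACTION * (j - i + 1):
                break
            if above[j]:
                last_hit = j
            j += 1
        end = last_hit + 1  # trim trailing sub-threshold epochs
        if end - i >= min_epochs:
            out.append((i, end))
            i = end
        else:
            i += 1
    return out


def detect_bouts(epochs: pd.DataFrame) -> list[Bout]:
    """Bouts over waking wear non-sleep epochs; gaps in eligibility break bouts."""
    epoch_min = (epochs.index[1] - epochs.index[0]).total_seconds() / 60 if len(epochs) > 1 else 5 / 60
    eligible = (epochs["wear"] & epochs["waking"] & ~epochs["sleep"]).to_numpy()
    enmo = epochs["enmo_mg"].to_numpy()
    bouts: list[Bout] = []
    # contiguous eligible blocks
    idx = np.flatnonzero(eligible)
    if len(idx) == 0:
        return bouts
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    for bs, be in zip(starts, ends):
        block = idx[bs : be + 1]
        for s, e in _scan_bouts(enmo[block], epoch_min):
            seg = enmo[block[s] : block[s] + (e - s)]
            mean_enmo = float(seg.mean())
            bouts.append(
                Bout(
                    start=epochs.index[block[s]],
                    duration_min=(e - s) * epoch_min,
                    mean_enmo_mg=mean_enmo,
                    intensity="vigorous" if mean_enmo >= VIGOROUS_MG else "moderate",
                )
            )
    return bouts


def weekly_minutes(bouts: list[Bout], n_assessment_days: int) -> tuple[float, float]:
    """Class-wise bout minutes, scaled to an average week."""
    if n_assessment_days < 5:
        raise ValueError("need at least 5 assessment days")
    mod = sum(b.duration_min for b in bouts if b.intensity == "moderate")
    vig = sum(b.duration_min for b in bouts if b.intensity == "vigorous")
    scale = 7.0 / n_assessment_days
    return mod * scale, vig * scale


def met_bouts_per_week(moderate_min: float, vigorous_min: float) -> float:
    """MET-weighted weekly bout minutes (4x moderate + 8x vigorous)."""
    return MET_WEIGHTS[0] * moderate_min + MET_WEIGHTS[1] * vigorous_min


def classify_who(moderate_min: float, vigorous_min: float) -> WeeklyPA:
    """WHO-recommendation status from weekly bout minutes."""
    met = met_bouts_per_week(moderate_min, vigorous_min)
    meets = (
        moderate_min >= WHO_MODERATE_MIN
        or vigorous_min >= WHO_VIGOROUS_MIN
        or met >= WHO_MET_THRESHOLD
    )
    return WeeklyPA(
        moderate_bout_min=float(moderate_min),
        vigorous_bout_min=float(vigorous_min),
        met_bouts=float(met),
        meets_who=bool(meets),
    )


def subject_weekly_pa(epochs: pd.DataFrame, n_assessment_days: int) -> WeeklyPA:
    bouts = detect_bouts(epochs)
    mod, vig = weekly_minutes(bouts, n_assessment_days)
    return classify_who(mod, vig)
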