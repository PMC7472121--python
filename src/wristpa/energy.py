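"""Energy expenditure: activity (AEE), resting (REE) and total (TEE).

AEE comes from a pluggable linear model on epoch ENMO accumulated over
waking wear epochs of valid days; REE from sex- and age-band-specific
linear equations in weight and height (Henry/Oxford form, shipped as a
config table); TEE = (AEE + REE) / 0.9, the 0.9 compensating diet-induced
thermogenesis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import AEEModel, EnergyResult, SubjectProfile

#: Default REE coefficient table (MJ day^-1): per sex and age band,
#: ree = weight_coef * weight_kg + height_coef * height_m + const.
#: Henry/Oxford-form weight+height equations; the 60+ rows are the ones an
#: older cohort exercises.
DEFAULT_REE_TABLE = [
    {"sex": "male", "age_min": 30, "age_max": 60, "weight_coef": 0.048, "height_coef": 0.011, "const": 3.670},
    {"sex": "male", "age_min": 60, "age_max": 200, "weight_coef": 0.038, "height_coef": 4.068, "const": -3.491},
    {"sex": "female", "age_min": 30, "age_max": 60, "weight_coef": 0.034, "height_coef": 0.006, "const": 3.530},
    {"sex": "female", "age_min": 60, "age_max": 200, "weight_coef": 0.033, "height_coef": 1.917, "const": 0.074},
]

DIT_FACTOR = 0.9  # diet-induced thermogenesis divisor


def predict_aee(
    epochs: pd.DataFrame,
    model: AEEModel = AEEModel(),
    min_wear_hours: float = 16.0,
) -> float:
    """Daily activity energy expenditure in kJ day^-1 kg^-1.

    The per-epoch rate (J min^-1 kg^-1, clamped at zero) is integrated over
    waking wear epochs within each calendar date, and daily totals are
    averaged over valid days (>= ``min_wear_hours`` of wear).
    """
    epoch_min = (epochs.index[1] - epochs.index[0]).total_seconds() / 60 if len(epochs) > 1 else 5 / 60
    daily = []
    for _, day in epochs.groupby(epochs.index.date, sort=True):
        wear_hours = day["wear"].sum() * epoch_min / 60
        if wear_hours < min_wear_hours:
            continue
        mask = (day["wear"] & day["waking"]).to_numpy()
        rates = model.rate(day.loc[mask, "enmo_mg"].to_numpy())
        daily.append(rates.sum() * epoch_min / 1000.0)  # J -> kJ per kg
    if not daily:
        raise ValueError("no valid days (>= %.0f h wear) to average over" % min_wear_hours)
    return float(np.mean(daily))


def predict_ree(profile: SubjectProfile, table: list[dict] | None = None) -> float:
    """Resting energy expenditure (MJ day^-1) from age, sex, height, weight."""
    for field in ("age", "sex", "height_m", "weight_kg"):
        if getattr(profile, field) is None:
            raise ValueError(f"REE prediction requires {field}")
    table = table or DEFAULT_REE_TABLE
    for row in table:
        if row["sex"] == profile.sex and row["age_min"] <= profile.age < row["age_max"]:
            ree = (
                row["weight_coef"] * profile.weight_kg
                + row["height_coef"] * profile.height_m
                + row["const"]
            )
            return float(max(0.0, ree))
    raise ValueError(f"no REE coefficients for sex={profile.sex}, age={profile.age}")


def compute_tee(aee_kj_day_kg: float, weight_kg: float, ree_mj_day: float) -> EnergyResult:
    """Total energy expenditure: tee = (aee_abs + ree) / 0.9, all in MJ day^-1."""
    if aee_kj_day_kg < 0 or weight_kg < 0 or ree_mj_day < 0:
        raise ValueError("energy inputs must be non-negative")
    aee_mj = aee_kj_day_kg * weight_kg / 1000.0
    tee = (aee_mj + ree_mj_day) / DIT_FACTOR
    return EnergyResult(
        aee_kj_day_kg=float(aee_kj_day_kg),
        aee_mj_day=float(aee_mj),
        ree_mj_day=float(ree_mj_day),
        tee_mj_day=float(tee),
    )


def subject_energy(
    epochs: pd.DataFrame,
    profile: SubjectProfile,
    model: AEEModel = AEEModel(),
    ree_table: list[dict] | None = None,
) -> EnergyResult:
    aee = predict_aee(epochs, model)
    ree = predict_ree(profile, ree_table)
    return compute_tee(aee, profile.weight_kg, ree)
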