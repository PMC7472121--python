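"""Core domain containers shared across the pipeline.

Raw recordings are regularly sampled tri-axial acceleration in g units;
epoch-level data live in a pandas DataFrame (see :mod:`wristpa.signal`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Intensity states a schedule segment (and an epoch) can take.
STATES = ("sleep", "nonwear", "inactive", "light", "moderate", "vigorous")

#: ENMO bands (mg) implied by the cut-points, used to validate schedule targets.
STATE_BANDS = {
    "inactive": (0.0, 30.0),
    "light": (30.0, 100.0),
    "moderate": (100.0, 400.0),
    "vigorous": (400.0, np.inf),
}


@dataclass
class RawRecording:
    """Regularly sampled tri-axial acceleration.

    Parameters
    ----------
    subject_id : str
        Identifier carried through to outputs.
    sampling_rate : float
        Samples per second (Hz).
    start : pd.Timestamp
        Timestamp of the first sample; subsequent samples are implied by
        ``sampling_rate``.
    xyz : ndarray of shape (n, 3)
        Acceleration in g. Values beyond +/-8 g are physically impossible
        for the emulated device and are flagged by consumers.
    """

    subject_id: str
    sampling_rate: float
    start: pd.Timestamp
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.start = pd.Timestamp(self.start)

    @property
    def n_samples(self) -> int:
        return self.xyz.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def timestamps(self) -> pd.DatetimeIndex:
        """Per-sample timestamps (materialized lazily; large for long files)."""
        step = pd.to_timedelta(1.0 / self.sampling_rate, unit="s")
        return pd.DatetimeIndex(self.start + step * np.arange(self.n_samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.xyz[:, 0], "y": self.xyz[:, 1], "z": self.xyz[:, 2]},
            index=self.timestamps().rename("timestamp"),
        )


@dataclass
class CalibrationParams:
    """Per-axis gain/offset mapping measured acceleration onto the unit sphere.

    ``calibrated = gain * measured + offset`` (offset in g).
    """

    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    residual_error_mg: float = float("nan")
    n_static_windows: int = 0
    converged: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float).reshape(3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)

    @classmethod
    def identity(cls, note: str = "", n_static_windows: int = 0) -> "CalibrationParams":
        return cls(note=note, n_static_windows=n_static_windows, converged=False)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz * self.gain + self.offset


@dataclass(frozen=True)
class CutPoints:
    """ENMO intensity cut-points in mg; each threshold belongs to the higher class."""

    light: float = 30.0
    moderate: float = 100.0
    vigorous: float = 400.0

    def __post_init__(self) -> None:
        if not (0 < self.light < self.moderate < self.vigorous):
            raise ValueError("cut-points must satisfy 0 < light < moderate < vigorous")


@dataclass(frozen=True)
class AEEModel:
    """Linear activity-energy model: rate (J min^-1 kg^-1) = intercept + slope * ENMO(mg)."""

    intercept: float = 0.0
    slope: float = 1.4
    name: str = "wristpa-default-linear"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("AEE slope must be positive")

    def rate(self, enmo_mg: np.ndarray) -> np.ndarray:
        """Per-epoch energy rate, clamped at zero."""
        return np.maximum(0.0, self.intercept + self.slope * np.asarray(enmo_mg))


@dataclass
class SubjectProfile:
    """Anthropometrics and questionnaire scores for one participant."""

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    height_m: float
    weight_kg: float
    bmi: float | None = None
    mmse: float | None = None
    gds: float | None = None
    inchianti: int | None = None
    pase: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.bmi is None:
            self.bmi = self.weight_kg / self.height_m**2
        elif abs(self.bmi - self.weight_kg / self.height_m**2) > 0.1:
            raise ValueError("bmi inconsistent with weight/height beyond 0.1")
        if self.inchianti is not None and self.inchianti not in range(6):
            raise ValueError(f"InCHIANTI level must be 0..5, got {self.inchianti}")


@dataclass(frozen=True)
class EnergyResult:
    """Daily energy expenditure summary for one subject."""

    aee_kj_day_kg: float
    aee_mj_day: float
    ree_mj_day: float
    tee_mj_day: float


@dataclass(frozen=True)
class Bout:
    """A sustained MVPA episode."""

    start: pd.Timestamp
    duration_min: float
    mean_enmo_mg: float
    intensity: str  # "moderate" | "vigorous"


@dataclass(frozen=True)
class WeeklyPA:
    """Weekly bouted physical activity and WHO-recommendation status."""

    moderate_bout_min: float
    vigorous_bout_min: float
    met_bouts: float
    meets_who: bool


@dataclass(frozen=True)
class ActivitySegment:
    """One homogeneous block of a day's schedule."""

    start_min: float  # minutes from the day's midnight
    duration_min: float
    state: str
    target_enmo_mg: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("segment duration must be positive")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state in STATE_BANDS:
            lo, hi = STATE_BANDS[self.state]
            if not (lo <= self.target_enmo_mg < hi):
                raise ValueError(
                    f"target_enmo {self.target_enmo_mg} mg outside {self.state} band [{lo}, {hi})"
                )


@dataclass
class ActivitySchedule:
    """Full multi-day schedule for one subject: per day, segments tiling 24 h."""

    subject_id: str
    n_days: int
    days: list  # list of list[ActivitySegment], one inner list per day

    def __post_init__(self) -> None:
        if self.n_days < 5:
            raise ValueError("n_days must be >= 5 (validity floor)")
        if len(self.days) != self.n_days:
            raise ValueError("days list length must equal n_days")
        for segs in self.days:
            t = 0.0
            for seg in segs:
                if abs(seg.start_min - t) > 1e-9:
                    raise ValueError("segments must tile the day without gaps")
                t += seg.duration_min
            if abs(t - 1440.0) > 1e-6:
                raise ValueError("segments must cover exactly 24 h")

    def state_minutes(self, day: int | None = None) -> dict:
        """Ground-truth minutes per state, for one day or totalled."""
        days = self.days if day is None else [self.days[day]]
        out = {s: 0.0 for s in STATES}
        for segs in days:
            for seg in segs:
                out[seg.state] += seg.duration_min
        return out


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-signal generator.

    noise_sd is per-axis white sensor noise in mg; gain/offset inject a
    miscalibration that the processing chain must detect and undo.
    """

    sampling_rate: float = 100.0
    noise_sd_mg: float = 0.0
    gain: tuple = (1.0, 1.0, 1.0)
    offset_mg: tuple = (0.0, 0.0, 0.0)
    seed: int = 0
    epoch_s: float = 5.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd_mg < 0:
            raise ValueError("noise_sd_mg must be >= 0")
        if any(not 0.9 <= g <= 1.1 for g in self.gain):
            raise ValueError("gain must be near 1 (0.9-1.1)")
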