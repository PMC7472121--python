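"""Raw signal -> calibrated 5 s epoch series with wear/sleep/waking flags.

The chain follows the standard raw-accelerometry order: find static periods,
fit an autocalibration (per-axis gain/offset onto the unit sphere), compute
ENMO and the z-angle on calibrated data, then flag non-wear (60-min SD/range
rule), sleep (z-angle stillness -> nightly sleep-period window) and the
waking clock filter.

Epoch frames carry per-axis sufficient statistics (sum, sum of squares,
min, max) so 60-min raw-signal SD and range can be recombined exactly from
epochs without keeping the raw samples around.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import CalibrationParams, RawRecording

EPOCH_COLUMNS = ["enmo_mg", "z_angle_deg", "wear", "sleep", "waking"]


# ---------------------------------------------------------------- static periods

def detect_static_periods(
    raw: RawRecording,
    window_s: float = 10.0,
    sd_threshold_mg: float = 13.0,
) -> pd.DataFrame:
    """Non-overlapping windows in which every axis SD falls below threshold.

    Returns one row per static window: ``start`` (sample index), ``end``
    (exclusive), per-axis means ``x_mean,y_mean,z_mean``. Consecutive
    windows can be merged with :func:`merge_static_intervals`.
    """
    w = int(round(window_s * raw.sampling_rate))
    n = raw.n_samples // w
    if n == 0:
        raise ValueError("recording shorter than one static window")
    blocks = raw.xyz[: n * w].reshape(n, w, 3)
    sd = blocks.std(axis=1)
    static = (sd < sd_threshold_mg / 1000.0).all(axis=1)
    idx = np.flatnonzero(static)
    means = blocks[idx].mean(axis=1)
    return pd.DataFrame(
        {
            "start": idx * w,
            "end": (idx + 1) * w,
            "x_mean": means[:, 0] if len(idx) else [],
            "y_mean": means[:, 1] if len(idx) else [],
            "z_mean": means[:, 2] if len(idx) else [],
        }
    )


def merge_static_intervals(windows: pd.DataFrame) -> list[tuple[int, int]]:
    """Merge adjacent static windows into maximal [start, end) sample runs."""
    out: list[tuple[int, int]] = []
    for s, e in zip(windows["start"], windows["end"]):
        if out and out[-1][1] == s:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return [tuple(x) for x in out]


def _octants(means: np.ndarray) -> int:
    signs = (means > 0).astype(int)
    return len({tuple(row) for row in signs})


def estimate_calibration(
    window_means: np.ndarray,
    min_windows: int = 10,
    min_octants: int = 2,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CalibrationParams:
    """Iterative closest-point-on-unit-sphere fit of per-axis gain/offset.

    Each iteration projects the calibrated static means onto the unit sphere
    and regresses, per axis, the projection on the current calibrated value;
    gain and offset are composed across iterations. Ill-conditioned inputs
    (too few windows or poor orientation coverage) yield identity parameters
    with a diagnostic note rather than an exception.
    """
    m = np.asarray(window_means, dtype=float).reshape(-1, 3)
    if len(m) < min_windows:
        warnings.warn(f"only {len(m)} static windows; returning identity calibration")
        return CalibrationParams.identity(
            note=f"too few static windows ({len(m)} < {min_windows})",
            n_static_windows=len(m),
        )
    if _octants(m) < min_octants:
        warnings.warn("static windows cover too few orientation octants; identity calibration")
        return CalibrationParams.identity(
            note="insufficient orientation coverage", n_static_windows=len(m)
        )

    gain = np.ones(3)
    offset = np.zeros(3)
    prev = np.inf
    for _ in range(max_iter):
        cal = m * gain + offset
        norms = np.linalg.norm(cal, axis=1)
        resid = float(np.sqrt(np.mean((norms - 1.0) ** 2)))
        if abs(prev - resid) < tol:
            break
        prev = resid
        target = cal / norms[:, None]
        for ax in range(3):
            a, b = np.polyfit(cal[:, ax], target[:, ax], 1)
            gain[ax] *= a
            offset[ax] = a * offset[ax] + b
    cal = m * gain + offset
    resid = float(np.sqrt(np.mean((np.linalg.norm(cal, axis=1) - 1.0) ** 2)))
    return CalibrationParams(
        gain=gain,
        offset=offset,
        residual_error_mg=resid * 1000.0,
        n_static_windows=len(m),
        converged=True,
    )


def calibrate_recording(raw: RawRecording, **kwargs) -> CalibrationParams:
    """Convenience: static-period detection followed by the sphere fit."""
    windows = detect_static_periods(raw)
    return estimate_calibration(windows[["x_mean", "y_mean", "z_mean"]].to_numpy(), **kwargs)


# ---------------------------------------------------------------- epoch series

def compute_epochs(
    raw: RawRecording,
    params: CalibrationParams | None = None,
    epoch_s: float = 5.0,
) -> pd.DataFrame:
    """Calibrated epoch series: ENMO (mg), z-angle (deg), axis statistics.

    ENMO is per-sample ``max(0, ||v|| - 1)`` averaged within the epoch; the
    z-angle is computed from epoch-mean calibrated axes. A trailing partial
    epoch is dropped. Flags are initialized (wear True, sleep False) and
    filled by the detectors below.
    """
    params = params or CalibrationParams()
    spe = int(round(epoch_s * raw.sampling_rate))
    n = raw.n_samples // spe
    if n == 0:
        raise ValueError("recording shorter than one epoch")
    cal = params.apply(raw.xyz[: n * spe]).reshape(n, spe, 3)
    norms = np.linalg.norm(cal, axis=2)
    enmo = np.maximum(0.0, norms - 1.0).mean(axis=1) * 1000.0
    means = cal.mean(axis=1)
    horiz = np.hypot(means[:, 0], means[:, 1])
    mag = np.hypot(horiz, means[:, 2])
    with np.errstate(invalid="ignore"):
        z_angle = np.degrees(np.arctan2(means[:, 2], horiz))
    degenerate = mag < 1e-9
    z_angle = np.where(degenerate, 0.0, z_angle)

    step = pd.to_timedelta(epoch_s, unit="s")
    idx = pd.DatetimeIndex(raw.start + step * np.arange(n), name="epoch_start")
    df = pd.DataFrame(index=idx)
    df["enmo_mg"] = enmo
    df["z_angle_deg"] = z_angle
    df["z_angle_degenerate"] = degenerate
    for ax, name in enumerate("xyz"):
        vals = cal[:, :, ax]
        df[f"{name}_sum"] = vals.sum(axis=1)
        df[f"{name}_sumsq"] = (vals**2).sum(axis=1)
        df[f"{name}_min"] = vals.min(axis=1)
        df[f"{name}_max"] = vals.max(axis=1)
    df["n_samples"] = spe
    df["wear"] = True
    df["sleep"] = False
    df["waking"] = True
    return df


# ---------------------------------------------------------------- non-wear

def detect_nonwear(
    epochs: pd.DataFrame,
    window_min: float = 60.0,
    step_min: float = 15.0,
    sd_threshold_mg: float = 13.0,
    range_threshold_mg: float = 50.0,
    min_axes: int = 2,
) -> pd.DataFrame:
    """Flag non-wear: sliding 60-min windows, 15-min step.

    A window is off-wrist when at least ``min_axes`` of the three axes have
    raw-signal SD below 13 mg *and* value range below 50 mg; every epoch
    covered by any such window gets ``wear=False``. Flagged blocks are then
    expanded outward over adjacent near-constant epochs (epoch-level SD and
    range below the same thresholds on >= ``min_axes`` axes), so an off-wrist
    block whose edges fall between window starts is still covered end to end.
    Axis SD/range are exact raw-sample statistics reassembled from per-epoch
    sums.
    """
    df = epochs.copy()
    epoch_s = (df.index[1] - df.index[0]).total_seconds() if len(df) > 1 else 5.0
    wpe = int(round(window_min * 60 / epoch_s))
    step = max(1, int(round(step_min * 60 / epoch_s)))
    n = len(df)
    if n < wpe:
        warnings.warn("series shorter than one non-wear window; everything kept as wear")
        return df

    nonwear = np.zeros(n, dtype=bool)
    cums, mins, maxs = {}, {}, {}
    for name in "xyz":
        cums[name] = (
            np.concatenate([[0.0], np.cumsum(df[f"{name}_sum"].to_numpy())]),
            np.concatenate([[0.0], np.cumsum(df[f"{name}_sumsq"].to_numpy())]),
        )
        mins[name] = df[f"{name}_min"].to_numpy()
        maxs[name] = df[f"{name}_max"].to_numpy()
    spe = int(df["n_samples"].iloc[0])
    for start in range(0, n - wpe + 1, step):
        end = start + wpe
        cnt = wpe * spe
        hits = 0
        for name in "xyz":
            cs, cs2 = cums[name]
            s = cs[end] - cs[start]
            s2 = cs2[end] - cs2[start]
            var = max(0.0, s2 / cnt - (s / cnt) ** 2)
            sd_mg = np.sqrt(var) * 1000.0
            rng_mg = (maxs[name][start:end].max() - mins[name][start:end].min()) * 1000.0
            if sd_mg < sd_threshold_mg and rng_mg < range_threshold_mg:
                hits += 1
        if hits >= min_axes:
            nonwear[start:end] = True

    if nonwear.any():
        # block expansion: per-epoch stillness on >= min_axes axes
        still = np.zeros((n, 3), dtype=bool)
        for ax, name in enumerate("xyz"):
            cs, cs2 = cums[name]
            s = np.diff(cs)
            s2 = np.diff(cs2)
            var = np.maximum(0.0, s2 / spe - (s / spe) ** 2)
            sd_mg = np.sqrt(var) * 1000.0
            rng_mg = (maxs[name] - mins[name]) * 1000.0
            still[:, ax] = (sd_mg < sd_threshold_mg) & (rng_mg < range_threshold_mg)
        epoch_still = still.sum(axis=1) >= min_axes
        for s0, e0 in _runs(nonwear):
            i = s0 - 1
            while i >= 0 and epoch_still[i] and not nonwear[i]:
                nonwear[i] = True
                i -= 1
            i = e0
            while i < n and epoch_still[i] and not nonwear[i]:
                nonwear[i] = True
                i += 1
    df["wear"] = ~nonwear
    return df


# ---------------------------------------------------------------- sleep

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_sleep_windows(
    epochs: pd.DataFrame,
    angle_threshold_deg: float = 5.0,
    min_duration_min: float = 5.0,
    min_total_sib_min: float = 30.0,
) -> pd.DataFrame:
    """Sleep flags from sustained-inactivity bouts (SIB) and a nightly window.

    SIB: maximal epoch runs in which every rolling 5-min window of z-angle
    has range <= 5 degrees, lasting >= 5 min. Per noon-to-noon night, if the
    total SIB time reaches 30 min, the sleep-period-time window spans the
    first SIB start to the last SIB end and those epochs get ``sleep=True``.
    Non-wear takes precedence: a removed device is static too, so sleep is
    only flagged on worn epochs.
    """
    df = epochs.copy()
    epoch_s = (df.index[1] - df.index[0]).total_seconds() if len(df) > 1 else 5.0
    w = max(1, int(round(min_duration_min * 60 / epoch_s)))
    z = df["z_angle_deg"].to_numpy()
    n = len(z)
    sleep = np.zeros(n, dtype=bool)
    if n >= w:
        roll = pd.Series(z).rolling(w)
        rng = (roll.max() - roll.min()).to_numpy()  # trailing windows
        still = np.zeros(n, dtype=bool)
        ok = np.flatnonzero(rng[w - 1 :] <= angle_threshold_deg) + (w - 1)
        for j in ok:  # epochs covered by any qualifying 5-min window
            still[j - w + 1 : j + 1] = True
        # non-wear precedence: an off-wrist device is static too, so its
        # epochs must not seed sustained-inactivity bouts
        still &= df["wear"].to_numpy()
        sib = np.zeros(n, dtype=bool)
        for s, e in _runs(still):
            if (e - s) * epoch_s >= min_duration_min * 60:
                sib[s:e] = True
        # nightly noon-to-noon search windows
        nights = ((df.index - pd.Timedelta(hours=12)).normalize()).to_numpy()
        for night in pd.unique(nights):
            in_night = nights == night
            night_sib = sib & in_night
            if night_sib.sum() * epoch_s >= min_total_sib_min * 60:
                idx = np.flatnonzero(night_sib)
                sleep[idx[0] : idx[-1] + 1] = True
    df["sleep"] = sleep & df["wear"].to_numpy()
    return df


# ---------------------------------------------------------------- waking filter

def apply_waking_filter(
    epochs: pd.DataFrame,
    start: str = "05:00",
    end: str = "23:00",
) -> pd.DataFrame:
    """waking=True iff local clock time in [start, end) (half-open)."""
    df = epochs.copy()
    t = df.index.hour * 60 + df.index.minute + df.index.second / 60.0
    h0, m0 = map(int, start.split(":"))
    h1, m1 = map(int, end.split(":"))
    df["waking"] = (t >= h0 * 60 + m0) & (t < h1 * 60 + m1)
    return df


# ---------------------------------------------------------------- full chain

def process_recording(
    raw: RawRecording,
    epoch_s: float = 5.0,
    calibrate: bool = True,
    **flag_kwargs,
) -> tuple[pd.DataFrame, CalibrationParams]:
    """Calibration + ENMO/z-angle + all three flag passes, in pipeline order."""
    params = calibrate_recording(raw) if calibrate else CalibrationParams()
    epochs = compute_epochs(raw, params, epoch_s=epoch_s)
    epochs = detect_nonwear(epochs, **flag_kwargs.get("nonwear", {}))
    epochs = detect_sleep_windows(epochs, **flag_kwargs.get("sleep", {}))
    epochs = apply_waking_filter(epochs, **flag_kwargs.get("waking", {}))
    return epochs, params


def write_epoch_csv(epochs: pd.DataFrame, path) -> None:
    out = epochs[EPOCH_COLUMNS].copy()
    out["enmo_mg"] = out["enmo_mg"].round(4)
    out["z_angle_deg"] = out["z_angle_deg"].round(3)
    out.to_csv(path, index_label="epoch_start", date_format="%Y-%m-%dT%H:%M:%S")


def read_epoch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["epoch_start"], index_col="epoch_start")
    for col in ("wear", "sleep", "waking"):
        df[col] = df[col].astype(bool)
    return df
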