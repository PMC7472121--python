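"""Shared fixtures: synthetic recordings with ground truth, epoch factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wristpa import signal as sig
from wristpa import simulate as sim
from wristpa.types import RawRecording, SimulationConfig, SubjectProfile


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile("S0", 75.0, "male", 1.70, 75.0, inchianti=2, mmse=27.0, gds=2.0, pase=80.0)


@pytest.fixture(scope="session")
def noiseless_run(profile):
    """5-day level-2 subject, noiseless, identity calibration, 75 min/day off-wrist.

    Returns (schedule, recording, truth, processed_epochs, params); shared by
    the signal/intensity/bout tests to avoid re-synthesizing.
    """
    cfg = SimulationConfig(sampling_rate=10.0, noise_sd_mg=0.0, seed=11)
    sched = sim.generate_schedule(profile, cfg, n_days=5, nonwear_min_per_day=75)
    rec, truth = sim.synthesize_raw(sched, cfg)
    epochs, params = sig.process_recording(rec)
    return sched, rec, truth, epochs, params


def make_epoch_frame(
    enmo,
    start="2019-06-03 00:00:00",
    epoch_s=5.0,
    wear=True,
    sleep=False,
    waking=True,
):
    """Minimal epoch DataFrame for modules that consume flags + ENMO only."""
    enmo = np.asarray(enmo, dtype=float)
    n = len(enmo)
    idx = pd.date_range(start, periods=n, freq=pd.Timedelta(seconds=epoch_s), name="epoch_start")
    df = pd.DataFrame(index=idx)
    df["enmo_mg"] = enmo
    df["z_angle_deg"] = 0.0
    df["wear"] = np.broadcast_to(wear, n).copy()
    df["sleep"] = np.broadcast_to(sleep, n).copy()
    df["waking"] = np.broadcast_to(waking, n).copy()
    return df


def make_recording(xyz, fs=10.0, start="2019-06-03 00:00:00", subject="T"):
    return RawRecording(subject, fs, pd.Timestamp(start), np.asarray(xyz, dtype=float))


# ------------------------------------------------------------------ oracles

def nonwear_oracle(
    rec: RawRecording,
    epoch_s=5.0,
    window_min=60.0,
    step_min=15.0,
    sd_threshold_mg=13.0,
    range_threshold_mg=50.0,
    min_axes=2,
) -> np.ndarray:
    """Brute-force evaluation of the 60-min SD/range rule + block expansion,
    computed directly on raw samples (independent of the epoch-stat path)."""
    spe = int(round(epoch_s * rec.sampling_rate))
    n_epochs = rec.n_samples // spe
    wpe = int(round(window_min * 60 / epoch_s))
    step = int(round(step_min * 60 / epoch_s))
    flags = np.zeros(n_epochs, dtype=bool)
    xyz = rec.xyz[: n_epochs * spe]
    for s in range(0, n_epochs - wpe + 1, step):
        seg = xyz[s * spe : (s + wpe) * spe]
        hits = 0
        for ax in range(3):
            v = seg[:, ax]
            if v.std() * 1000 < sd_threshold_mg and (v.max() - v.min()) * 1000 < range_threshold_mg:
                hits += 1
        if hits >= min_axes:
            flags[s : s + wpe] = True

    def epoch_still(i):
        seg = xyz[i * spe : (i + 1) * spe]
        hits = 0
        for ax in range(3):
            v = seg[:, ax]
            if v.std() * 1000 < sd_threshold_mg and (v.max() - v.min()) * 1000 < range_threshold_mg:
                hits += 1
        return hits >= min_axes

    grew = True
    while grew:
        grew = False
        for i in range(n_epochs):
            if flags[i]:
                continue
            left = i > 0 and flags[i - 1]
            right = i < n_epochs - 1 and flags[i + 1]
            if (left or right) and epoch_still(i):
                flags[i] = True
                grew = True
    return flags


def bout_oracle(enmo: np.ndarray, epoch_min: float, threshold=100.0, frac=0.8, min_min=10.0):
    """Exhaustive window search for qualifying bouts: from each eligible start,
    the longest end such that every prefix window keeps the threshold fraction,
    trailing sub-threshold epochs trimmed; non-overlapping, earliest start first."""
    above = enmo >= threshold
    n = len(enmo)
    min_epochs = int(round(min_min / epoch_min))
    out = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        e = i - 1
        for k in range(i, n):
            if above[i : k + 1].mean() < frac:
                break
            e = k
        while e >= i and not above[e]:
            e -= 1
        if e - i + 1 >= min_epochs:
            out.append((i, e + 1))
            i = e + 1
        else:
            i += 1
    return out


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """Normal-equations least squares with classical standard errors."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


def fisher_oracle_2x3(table: np.ndarray) -> float:
    """Freeman-Halton p for a 2x3 table by direct double-loop enumeration
    with factorial arithmetic."""
    from math import factorial

    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()

    def prob(tab):
        num = 1.0
        for r in rows:
            num *= factorial(r)
        for c in cols:
            num *= factorial(c)
        den = float(factorial(n))
        for v in np.ravel(tab):
            den *= factorial(v)
        return num / den

    p_obs = prob(table)
    total = 0.0
    for a in range(min(rows[0], cols[0]) + 1):
        for b in range(min(rows[0] - a, cols[1]) + 1):
            c = rows[0] - a - b
            if c < 0 or c > cols[2]:
                continue
            tab = np.array([[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]])
            if (tab < 0).any():
                continue
            p = prob(tab)
            if p <= p_obs * (1 + 1e-10):
                total += p
    return min(1.0, total)
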