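"""Synthetic wrist-accelerometry generator with known ground truth.

Emulates multi-day 24 h wear in an older cohort: nightly sleep with
occasional posture shifts, optional off-wrist (non-wear) blocks with a
near-constant signal, and graded daytime activity whose true epoch ENMO
equals a prescribed target. Per-axis gain/offset miscalibration and white
sensor noise are injected on top, so the processing chain has something
real to detect and undo.

The generator trades biomechanical realism for exactness: activity is a
gravity-oriented unit vector whose magnitude is modulated so that each
5 s epoch's mean ENMO equals the segment target exactly (noise-free), and
whose orientation drifts as a slow random walk so activity is never
mistaken for a static period. Sleep and non-wear are the only truly static
states, which is what the autocalibration step relies on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    ActivitySchedule,
    ActivitySegment,
    RawRecording,
    SimulationConfig,
    SubjectProfile,
)

#: Mean daily activity volume (mean ENMO over waking wear, mg) and
#: between-subject SD per self-reported InCHIANTI level. Levels 1-3 follow
#: the medians observed in older community cohorts (~23/37/44 mg); the
#: extremes are extrapolated monotonically.
COHORT_EFFECTS = {
    0: (15.0, 3.0),
    1: (23.0, 4.0),
    2: (37.0, 6.0),
    3: (44.0, 6.0),
    4: (50.0, 6.0),
    5: (58.0, 7.0),
}

#: Default regression structure of the cohort generator: activity energy
#: expenditure (kJ day^-1 kg^-1) on InCHIANTI dummies (reference level 1),
#: sex, age and BMI. Magnitudes follow a published older-cohort fit.
DEFAULT_TRUE_BETAS = {
    "intercept": 51.55,
    "inchianti2": 19.96,
    "inchianti3": 27.29,
    "female": 6.42,
    "age": -0.13,
    "bmi": -0.26,
}

_EPOCHS_PER_MIN = 12  # 5 s epochs


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    """Independent per-subject stream derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _activity_minutes(volume_mg: float) -> dict:
    """Translate a daily activity volume into per-class waking minutes.

    The 930 active waking minutes (06:30-22:00 minus nothing) are split so
    that the waking-wear mean ENMO approximately equals ``volume_mg`` given
    the class target levels used below (inactive 8, light 50, moderate 150,
    vigorous 450 mg).
    """
    total = 930.0
    light = float(np.clip(8.7 * volume_mg, 60.0, 360.0))
    vig = float(max(0.0, volume_mg - 35.0))
    mod = (total * volume_mg - total * 8.0 - light * 42.0 - vig * 442.0) / 142.0
    mod = float(np.clip(mod, 0.0, total - light - vig))
    inactive = total - light - vig - mod
    return {"inactive": inactive, "light": light, "moderate": mod, "vigorous": vig}


def generate_schedule(
    profile: SubjectProfile,
    config: SimulationConfig,
    n_days: int = 7,
    cohort_effects: dict | None = None,
    nonwear_min_per_day: float = 0.0,
    subject_index: int = 0,
) -> ActivitySchedule:
    """Build a full-tiling multi-day schedule for one subject.

    Daily template: sleep 00:00-06:30 and 22:00-24:00 (with nightly posture
    shifts realized at synthesis time), a morning/evening inactive buffer,
    and a shuffled sequence of activity blocks between 07:00 and 21:30 whose
    composition scales with the subject's InCHIANTI level. Moderate activity
    is laid down in 15-45 min contiguous blocks so that bout detection has
    genuine episodes to find.
    """
    effects = COHORT_EFFECTS if cohort_effects is None else cohort_effects
    if profile.inchianti is None or profile.inchianti not in effects:
        raise ValueError(f"unknown InCHIANTI level: {profile.inchianti!r}")
    if n_days < 5:
        raise ValueError("n_days must be >= 5 (validity floor)")
    rng = _subject_rng(config.seed, subject_index)
    mean_vol, sd_vol = effects[profile.inchianti]
    volume = float(np.clip(rng.normal(mean_vol, sd_vol), 8.0, 120.0))

    days = []
    for _ in range(n_days):
        minutes = _activity_minutes(volume * float(rng.uniform(0.9, 1.1)))
        nonwear = min(nonwear_min_per_day, minutes["inactive"] - 60.0)
        nonwear = max(0.0, 5 * round(nonwear / 5))
        blocks = []  # (state, duration, target)
        if nonwear > 0:
            blocks.append(("nonwear", nonwear, 0.0))
        for state, lo, hi, tgt in (
            ("vigorous", 400.0, 550.0, minutes["vigorous"]),
            ("moderate", 110.0, 220.0, minutes["moderate"]),
            ("light", 35.0, 90.0, minutes["light"]),
        ):
            remaining = 5 * round(tgt / 5)
            while remaining >= 10:
                dur = min(remaining, 5 * int(rng.integers(3, 10)))
                if remaining - dur < 10:
                    dur = remaining
                blocks.append((state, float(dur), float(rng.uniform(lo, hi))))
                remaining -= dur
        inact_total = 870.0 - sum(d for _, d, _ in blocks)
        # interleave inactive filler between activity blocks, quantized to
        # whole 5 s epochs so segments always align with epoch boundaries
        n_fill = len(blocks) + 1
        cuts = np.sort(rng.uniform(0, 1, n_fill - 1))
        fill = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * inact_total
        fill = np.round(fill * _EPOCHS_PER_MIN) / _EPOCHS_PER_MIN
        order = rng.permutation(len(blocks))
        segs = [ActivitySegment(0.0, 390.0, "sleep")]
        t = 390.0

        def _push(state, dur, tgt, t):
            if dur <= 1e-9:
                return t
            segs.append(ActivitySegment(t, dur, state, tgt))
            return t + dur

        t = _push("inactive", 30.0 + fill[0], 8.0, t)
        for k, idx in enumerate(order):
            state, dur, tgt = blocks[idx]
            t = _push(state, dur, tgt, t)
            t = _push("inactive", fill[k + 1], 8.0, t)
        # close the day: inactive buffer to 22:00, then sleep
        t = _push("inactive", 1320.0 - t, 8.0, t)
        segs.append(ActivitySegment(1320.0, 120.0, "sleep"))
        days.append(segs)

    return ActivitySchedule(profile.subject_id, n_days, days)


def _epoch_targets(schedule: ActivitySchedule, epoch_s: float) -> pd.DataFrame:
    """Expand a schedule to one row per epoch: state and true ENMO."""
    per_min = int(round(60.0 / epoch_s))
    rows_state, rows_enmo = [], []
    for segs in schedule.days:
        for seg in segs:
            n = int(round(seg.duration_min * per_min))
            rows_state.extend([seg.state] * n)
            rows_enmo.extend([seg.target_enmo_mg if seg.state not in ("sleep", "nonwear") else 0.0] * n)
    return pd.DataFrame({"state": rows_state, "true_enmo_mg": rows_enmo})


def _magnitude_pattern(n_epochs: int, spe: int, targets_g: np.ndarray) -> np.ndarray:
    """Per-sample magnitude excess a(t) >= 0 whose mean over each epoch is exact.

    First half of the epoch runs at 1.5x target, second half at 0.5x; an odd
    middle sample sits at the target itself, so the epoch mean is the target
    to machine precision.
    """
    pat = np.empty(spe)
    half = spe // 2
    pat[:half] = 1.5
    pat[spe - half:] = 0.5
    if spe % 2:
        pat[half] = 1.0
    return targets_g[:, None] * pat[None, :]


def _orientation_walk(rng, n_epochs: int, start: np.ndarray, step_deg: float) -> np.ndarray:
    """Slow random walk on the unit sphere, one orientation per epoch."""
    out = np.empty((n_epochs, 3))
    v = start.copy()
    step = np.deg2rad(step_deg)
    for i in range(n_epochs):
        out[i] = v
        axis = _random_unit(rng)
        perp = np.cross(axis, v)
        v = v * np.cos(step) + perp * np.sin(step)
        v /= np.linalg.norm(v)
    return out


def synthesize_raw(
    schedule: ActivitySchedule,
    config: SimulationConfig,
    subject_index: int = 0,
    start: str | pd.Timestamp = "2019-06-03 00:00:00",
    orientation_step_deg: float = 3.0,
    wobble_deg: float = 4.0,
) -> tuple[RawRecording, pd.DataFrame]:
    """Render a schedule into a raw recording plus epoch-level ground truth.

    Returns the distorted (gain/offset + noise) recording and a DataFrame
    with columns ``epoch_start, state, true_enmo_mg``.
    """
    fs = config.sampling_rate
    epoch_s = config.epoch_s
    spe = int(round(epoch_s * fs))
    if abs(spe - epoch_s * fs) > 1e-9 or int(round(60 / epoch_s)) * epoch_s != 60:
        raise ValueError("epoch_s must divide 60 s and contain a whole number of samples")
    rng = _subject_rng(config.seed, subject_index)
    truth = _epoch_targets(schedule, epoch_s)
    n_epochs = len(truth)
    xyz = np.empty((n_epochs * spe, 3))

    states = truth["state"].to_numpy()
    targets_g = truth["true_enmo_mg"].to_numpy() / 1000.0

    # group consecutive epochs of the same state into runs
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    bounds = np.concatenate([[0], change, [n_epochs]])
    wobble = np.deg2rad(wobble_deg)
    t_in_epoch = np.arange(spe) / fs

    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        state = states[s0]
        ne = s1 - s0
        sl = slice(s0 * spe, s1 * spe)
        if state in ("sleep", "nonwear"):
            # piecewise-constant orientation; sleep gets posture shifts every
            # 20-40 min so a worn, sleeping wrist is never mistaken for an
            # off-wrist device by the 60-min range rule
            block = np.empty((ne * spe, 3))
            pos = 0
            epm = int(round(60 / epoch_s))
            while pos < ne:
                if state == "sleep":
                    span = min(ne - pos, int(rng.integers(20 * epm, 40 * epm)))
                else:
                    span = ne - pos
                block[pos * spe:(pos + span) * spe] = _random_unit(rng)
                pos += span
            xyz[sl] = block
        else:
            orient = _orientation_walk(rng, ne, _random_unit(rng), orientation_step_deg)
            # two orthogonal wobble directions per epoch (norm-preserving sway)
            ref = np.where(np.abs(orient[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
            w1 = np.cross(orient, ref)
            w1 /= np.linalg.norm(w1, axis=1, keepdims=True)
            w2 = np.cross(orient, w1)
            ph1, ph2 = rng.uniform(0, 2 * np.pi, size=(2, ne, 1))
            s1a = wobble * np.sin(2 * np.pi * 1.0 * t_in_epoch[None, :] + ph1)
            s2a = wobble * np.sin(2 * np.pi * 0.7 * t_in_epoch[None, :] + ph2)
            v = (
                orient[:, None, :]
                + s1a[:, :, None] * w1[:, None, :]
                + s2a[:, :, None] * w2[:, None, :]
            )
            v /= np.linalg.norm(v, axis=2, keepdims=True)
            amp = 1.0 + _magnitude_pattern(ne, spe, targets_g[s0:s1])
            xyz[sl] = (v * amp[:, :, None]).reshape(-1, 3)

    if config.noise_sd_mg > 0:
        noise = rng.normal(0.0, config.noise_sd_mg / 1000.0, size=xyz.shape)
        nonwear_epoch = states == "nonwear"
        if nonwear_epoch.any():
            # off-wrist signal stays near-constant: jitter capped at 3 mg
            cap = min(config.noise_sd_mg, 3.0) / max(config.noise_sd_mg, 1e-12)
            noise[np.repeat(nonwear_epoch, spe)] *= cap
        xyz = xyz + noise

    xyz = xyz * np.asarray(config.gain) + np.asarray(config.offset_mg) / 1000.0

    start = pd.Timestamp(start)
    truth.insert(0, "epoch_start", start + pd.to_timedelta(np.arange(n_epochs) * epoch_s, unit="s"))
    rec = RawRecording(schedule.subject_id, fs, start, xyz)
    return rec, truth


def generate_cohort(
    n: int,
    true_betas: dict | None = None,
    config: SimulationConfig | None = None,
    noise_sd: float = 10.0,
    level_probs: dict | None = None,
    missing_frac: float = 0.0,
) -> pd.DataFrame:
    """Generate a subject table whose AEE follows a known linear model.

    AEE (kJ day^-1 kg^-1) = intercept + b2*[level 2] + b3*[level 3]
    + b_female*[female] + b_age*age + b_bmi*BMI + N(0, noise_sd).
    Daily mean acceleration (ACC) is derived from the same latent activity
    so that rank correlations between ACC and AEE are strongly positive, as
    observed on real wrists.
    """
    if n < 10:
        raise ValueError("n must be >= 10 (degenerate fit below that)")
    betas = dict(DEFAULT_TRUE_BETAS)
    if true_betas:
        betas.update(true_betas)
    for key in ("inchianti2", "inchianti3", "female"):
        if key not in betas:
            raise ValueError(f"true_betas must include {key!r}")
    cfg = config or SimulationConfig()
    probs = level_probs or {1: 0.26, 2: 0.52, 3: 0.22}
    levels = np.array(sorted(probs))
    pvec = np.array([probs[l] for l in levels], dtype=float)
    pvec /= pvec.sum()

    rows = []
    for i in range(n):
        rng = _subject_rng(cfg.seed, i)
        age = float(rng.uniform(66, 90))
        female = bool(rng.random() < 0.46)
        height = float(rng.normal(1.58 if female else 1.68, 0.07))
        bmi = float(np.clip(rng.normal(28.0, 3.5), 22.0, 41.0))
        weight = bmi * height**2
        level = int(rng.choice(levels, p=pvec))
        mmse = float(np.clip(rng.normal(27.4, 2.0), 21.0, 30.0))
        gds = float(np.clip(rng.exponential(3.0), 0.0, 24.0))
        pase = float(max(0.0, rng.normal(40 + 25 * level, 25.0)))
        aee = (
            betas["intercept"]
            + betas["inchianti2"] * (level == 2)
            + betas["inchianti3"] * (level == 3)
            + betas["female"] * female
            + betas.get("age", 0.0) * age
            + betas.get("bmi", 0.0) * bmi
            + rng.normal(0.0, noise_sd)
        )
        acc = aee / 1.45 + rng.normal(0.0, 1.5)
        if missing_frac > 0 and rng.random() < missing_frac:
            mmse, gds = np.nan, np.nan
        rows.append(
            dict(
                subject=f"S{i:04d}",
                age=age,
                sex="female" if female else "male",
                height_m=height,
                weight_kg=weight,
                bmi=bmi,
                mmse=mmse,
                gds=gds,
                inchianti=level,
                pase=pase,
                aee_kj_day_kg=aee,
                acc_mg=acc,
            )
        )
    return pd.DataFrame(rows)


def write_raw_csv(rec: RawRecording, path) -> None:
    """Raw CSV with header ``timestamp,x,y,z`` and ISO-8601 timestamps."""
    step_ms = 1000.0 / rec.sampling_rate
    times = rec.start.to_datetime64() + (
        np.arange(rec.n_samples) * step_ms
    ).astype("timedelta64[ms]")
    stamps = np.datetime_as_string(times, unit="ms")
    df = pd.DataFrame(
        {"timestamp": stamps, "x": rec.xyz[:, 0], "y": rec.xyz[:, 1], "z": rec.xyz[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_raw_csv(path, subject_id: str | None = None) -> RawRecording:
    """Read a regularly sampled raw CSV; rate inferred from the first two rows."""
    head = pd.read_csv(path, nrows=2, parse_dates=["timestamp"])
    if len(head) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = (head["timestamp"].iloc[1] - head["timestamp"].iloc[0]).total_seconds()
    if dt <= 0:
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    xyz = pd.read_csv(path, usecols=["x", "y", "z"], dtype=float).to_numpy()
    sid = subject_id or str(getattr(path, "stem", path))
    return RawRecording(sid, 1.0 / dt, head["timestamp"].iloc[0], xyz)


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
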