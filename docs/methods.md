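# Methods note

`wristpa` implements a wrist-accelerometry processing chain for older-adult
cohorts — raw tri-axial acceleration to epoch metrics, energy expenditure,
bouted physical activity and questionnaire calibration — together with a
synthetic-signal generator that provides ground truth for every stage. This
note records the model, its assumptions, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## 1. Signal model and processing chain

**Raw signal.** Regularly sampled tri-axial acceleration in g units
(`RawRecording`). All downstream quantities derive from 5-s epochs.

**Autocalibration** (`signal.estimate_calibration`). Static 10-s windows
(every axis SD < 13 mg) should lie on the unit sphere. Per-axis gain and
offset are estimated by iterating a closest-point-on-sphere least-squares
fit (each window's target is its current calibrated vector rescaled to unit
norm), up to 100 iterations or a 1e-9 change tolerance. Preconditions: at
least 10 static windows covering at least 2 octants of the sphere;
otherwise identity parameters are returned with a warning rather than a
badly conditioned fit. On synthetic data with gains in [0.95, 1.05] and
offsets within ±20 mg, recovery is far inside the 0.5 % / 2 mg acceptance
tolerances (observed ~1e-7 % and ~1e-5 mg on noiseless static windows;
≈0.3 mg residual on full noisy recordings).

**ENMO** (`signal.compute_epochs`). Per sample, max(0, ‖v‖ − 1) in mg,
averaged within each 5-s epoch; a trailing partial epoch is dropped. The
truncation at zero happens per sample, before epoch averaging. Epochs also
carry per-axis sufficient statistics (sum, sum of squares, min, max) so that
window SD/range rules can be evaluated exactly without re-reading raw data.

**Non-wear** (`signal.detect_nonwear`). Sliding 60-min windows on a 15-min
grid; a window is non-wear when at least 2 of 3 axes have SD < 13 mg and
range < 50 mg. Flagged windows are then expanded over adjacent epochs that
satisfy the same thresholds at epoch scale, so off-wrist blocks that are
only partially covered by the 60-min grid are still captured end-to-end.
Consequence of the rule as stated: off-wrist blocks shorter than 60 min
contain no qualifying window and are undetectable.

**Sleep** (`signal.detect_sleep_windows`). The z-angle is
atan2(z̄, √(x̄² + ȳ²)) in degrees from epoch-mean calibrated axes. Sustained
inactivity bouts (SIBs) are maximal runs, at least 5 min long, in which
every rolling 5-min window of z-angle has range ≤ 5°. Per noon-to-noon
night, if total SIB time is ≥ 30 min, the sleep-period-time window spans the
first to the last SIB. Non-wear takes precedence: epochs flagged non-wear
are removed from stillness *before* SIBs are formed, otherwise an afternoon
off-wrist block would bridge into an absurd SPT. Boundary behaviour: the
rolling window cannot flag epochs within 5 min of a posture/state
transition, so detected sleep is systematically ~2–3 min short per
transition; tests bound disagreement by this mechanism.

**Waking hours.** The half-open clock window [05:00, 23:00).

**Intensity and validity** (`intensity`). Cut-points 30/100/400 mg partition
waking wear non-sleep epochs into inactivity/light/moderate/vigorous; each
named threshold belongs to the *higher* class. A day is valid at ≥ 16 h
wear; a subject is analysable at ≥ 5 valid days.

**Energy** (`energy`). AEE integrates a linear per-epoch rate
(J min⁻¹ kg⁻¹ = intercept + slope·ENMO, clamped at zero; default 0 + 1.4·ENMO)
over waking wear epochs of valid days, averaged across days, in
kJ day⁻¹ kg⁻¹. REE uses sex- and age-band weight+height equations
(Henry/Oxford form) in MJ day⁻¹. TEE = (AEE + REE) / 0.9, the 0.9 absorbing
diet-induced thermogenesis; this identity holds to machine precision by
construction and is asserted as such.

**Bouts and the WHO rule** (`bouts`). A bout is ≥ 10 min in which ≥ 80 % of
epochs reach 100 mg, found by a greedy left-to-right scan (extend while the
prefix fraction stays ≥ 0.8, trim trailing sub-threshold epochs, no
re-entry); bout class comes from mean ENMO (≥ 400 mg → vigorous). Weekly
minutes scale summed bout minutes by 7/n_days. The WHO recommendation is met
at ≥ 150 weekly moderate bout minutes, ≥ 75 vigorous, or ≥ 450 MET-bouts.
Two MET conventions are deliberately kept side by side: the 450 threshold
derives from 3/6 MET weights (150×3 = 75×6 = 450), while the MET-bout score
weights minutes by 4/8. With 4/8 weights the MET criterion dominates the
other two (4×112.5 = 450 < 4×150); this tension is preserved as stated, not
reconciled, and the configuration validator checks the 3/6 identity.

**Questionnaires** (`questionnaires`). InCHIANTI levels are integers 0–5
with fixed labels. PASE bands: ≤ 40 sedentary, (40, 90] light, > 90
moderate-to-intense (the published bands leave (40, 41) unassigned; closing
the gap at 40 keeps the mapping total and monotone).

## 2. Synthetic data generator

**Raw signal** (`simulate.synthesize_raw`). Activity epochs render a
magnitude-modulated gravity vector: within each 5-s epoch the magnitude is
1 + 1.5·t for the first half and 1 + 0.5·t for the second (t the epoch's
target ENMO in g), so the *epoch-mean* ENMO equals the target exactly in
the noiseless case while individual samples vary. Orientation follows a
random walk (3°/epoch) plus norm-preserving 4° wobble sinusoids, making
activity unmistakable for stillness. Sleep is a constant orientation with
posture shifts every 20–40 min (SIB-detectable but failing the 60-min
non-wear range rule); non-wear is strictly constant with sensor noise capped
at 3 mg. Gain/offset distortion (measured = gain⊙v + offset) is applied
last. All per-subject randomness derives from
`np.random.SeedSequence([seed, subject_index])`.

**Schedules** (`simulate.generate_schedule`). Days tile 24 h: sleep
00:00–06:30 and 22:00–24:00, activity between. Class minutes rise with the
reported InCHIANTI level through a latent daily activity volume; blocks of
15–45 min are shuffled through the day, inactivity fills the gaps (durations
quantized to the 5-s epoch grid), and an optional daily off-wrist block is
inserted. Generator defaults are study conditions, not tuning knobs.

**Cohort tables** (`simulate.generate_cohort`). AEE follows a known linear
model in level dummies, sex, age and BMI with N(0, 10) noise; measured
acceleration derives from the same latent so ACC–AEE rank correlations are
strongly positive. These coefficients are the recovery targets of the
parameter-recovery experiments.

## 3. Statistics

Group descriptives use medians/ranges with Kruskal–Wallis for continuous
variables (constant variables yield NaN rather than a 0/0 warning) and an
exact Freeman–Halton Fisher test for 2×C categoricals. The Fisher p-value is
computed by full enumeration with log-gamma arithmetic; SciPy's R×C
`fisher_exact` is Monte-Carlo based and non-deterministic, so it is not used.
Spearman correlations are tie-corrected and pairwise-complete.

The calibration regression puts AEE on dummy-coded InCHIANTI level
(reference = lowest observed level), age, sex and BMI; the full variant adds
MMSE and GDS with complete-case deletion. Confidence intervals use a normal
quantile (default 1.96). Aliased designs raise an error naming the offending
term. Two contrast conventions are exposed: the "reported" style (male
contrast to a level = that level's dummy coefficient; female adds the female
coefficient) and the textbook additive difference of dummy coefficients.
Both are printed by stage 4; neither is silently preferred.

## 4. What the synthetic experiments show — and don't

They **show**: the processing chain inverts the generator (calibration,
non-wear, sleep, class minutes recovered essentially exactly in the
noiseless case); the estimators match independent brute-force oracles; the
regression machinery recovers known coefficients with correct CI coverage;
the rank tests hold their nominal level (KW is mildly conservative at
n=15/group — true level ≈ 0.047 by a 40,000-rep experiment — which is a
property of the chi-square approximation, not of this implementation).

They **don't show**: validity of the 30/100/400 mg cut-points, the AEE
slope, or the sleep heuristic against human criterion measures (calorimetry,
polysomnography); realistic inter-subject behavioural variance; device
artefacts (temperature drift, clipping, missing samples). Published cohort
tables are not reproducible from raw data here because the cohort's raw data
are not deposited; cohort-level numbers produced by this package are
properties of the generator, not of any real population.

## 5. Numerical choices

- Epoch statistics carry exact per-axis sums/sums-of-squares so window SD is
  exact, not an approximation from epoch means.
- Non-wear/sleep window arithmetic is integer epochs throughout; schedule
  fills are quantized to the 5-s grid so days tile exactly.
- Fisher enumeration compares log-probabilities with a 1+1e-10 relative
  slack to make "no more probable than observed" robust to rounding.
- Raw CSV I/O uses vectorized timestamp formatting and reads timestamps from
  only the first two rows (the grid is implied by the sampling rate), which
  keeps multi-day 10 Hz files tractable.
- All derived seeds are reduced modulo 2³¹ before use.

## 6. Limitations

Single-placement wrist emulation; no axis-specific behaviour beyond
gain/offset; sleep generator encodes the same structural assumptions the
detector tests (circularity is intentional — the point is inversion, not
discovery); REE equations are linear approximations valid for the emulated
age range only; the 40-min-and-shorter non-wear blindspot is inherited from
the 60-min rule by design.
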