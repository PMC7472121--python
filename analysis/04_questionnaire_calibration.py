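#!/usr/bin/env python
"""Stage 4: calibrate the InCHIANTI questionnaire against measured AEE.

Fits the partial (age+sex+BMI) and full (+MMSE+GDS) regressions on the
stage-3 cohort table, prints coefficients with 1.96-quantile confidence
intervals, and the sex-specific level contrasts in both conventions. Writes
results/calibration/regression.csv and contrasts.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from wristpa import analysis

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort" / "cohort.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "calibration")
    args = ap.parse_args()

    cohort = pd.read_csv(args.cohort)
    args.out.mkdir(parents=True, exist_ok=True)

    tables = []
    results = {}
    for tag in ("partial", "full"):
        res = analysis.fit_aee_model(cohort, tag)
        results[tag] = res
        t = res.terms.copy()
        t.insert(0, "model", tag)
        t.insert(1, "term", t.index)
        tables.append(t.reset_index(drop=True))
        print(f"\n{tag} model (n={res.n_obs}, reference level {res.reference_level}):")
        print(t.round(3).to_string(index=False))
    pd.concat(tables, ignore_index=True).round(6).to_csv(args.out / "regression.csv", index=False)

    rows = []
    for frm, to in ((1, 2), (2, 3)):
        for sex in ("male", "female"):
            rows.append(
                dict(
                    contrast=f"{frm}->{to}", sex=sex,
                    reported_style=analysis.reported_style_contrast(results["full"], frm, to, sex),
                    additive=analysis.standard_contrast(results["full"], frm, to),
                )
            )
    contrasts = pd.DataFrame(rows)
    contrasts.round(6).to_csv(args.out / "contrasts.csv", index=False)
    print("\nAEE contrasts between adjacent activity levels (kJ/day/kg):")
    print(contrasts.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
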