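#!/usr/bin/env python
"""Stage 1: synthesize a miniature wrist-accelerometer cohort.

Writes per-subject raw CSV recordings (with ground-truth epoch states) and a
metadata table to results/raw/. The defaults keep the raw files small enough
for a laptop; the science-scale knobs are --subjects/--days/--sampling-rate.
"""

import argparse
from pathlib import Path

from wristpa import pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--subjects", type=int, default=6)
    ap.add_argument("--days", type=int, default=5)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sampling-rate", type=float, default=5.0, help="Hz")
    ap.add_argument("--noise-sd", type=float, default=2.0, help="mg")
    ap.add_argument("--nonwear-min", type=float, default=75.0, help="min/day off-wrist")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "raw")
    args = ap.parse_args()

    cohort = pipeline.simulate_cohort_to_dir(
        args.out,
        n_subjects=args.subjects,
        n_days=args.days,
        seed=args.seed,
        sampling_rate=args.sampling_rate,
        noise_sd_mg=args.noise_sd,
        gain=(1.02, 0.98, 1.01),        # injected miscalibration, recovered in stage 2
        offset_mg=(8.0, -6.0, 4.0),
        nonwear_min_per_day=args.nonwear_min,
    )
    print(f"wrote {len(cohort)} subjects ({args.days} days @ {args.sampling_rate} Hz) to {args.out}")


if __name__ == "__main__":
    main()
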