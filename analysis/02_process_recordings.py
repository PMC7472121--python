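#!/usr/bin/env python
"""Stage 2: raw recordings -> epochs, day summaries, subject metrics.

Runs autocalibration, ENMO epochs, non-wear/sleep/waking flags, validity
filtering, energy models and bout/WHO metrics over results/raw/, writing
everything to results/derived/ (subject_metrics.csv is the stage product).
"""

import argparse
from pathlib import Path

from wristpa import pipeline
from wristpa.config import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--raw-dir", type=Path, default=ROOT / "results" / "raw")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "derived")
    ap.add_argument("--config", type=Path, default=None)
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    out = pipeline.run_pipeline(args.raw_dir, args.raw_dir / "metadata.csv", args.out, cfg)
    print(f"included {len(out['metrics'])} subjects; excluded {len(out['excluded'])}")
    for line in out["log"]:
        print(" ", line)


if __name__ == "__main__":
    main()
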