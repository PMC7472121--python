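"""Pipeline configuration: every analysis threshold as data, not literals.

The calibration exercise is threshold-sensitive, so all constants of the
processing chain live in one flat, namespaced mapping that round-trips
through YAML and rejects unknown keys. ``validate()`` asserts the canonical
values, including the WHO MET identity (150 x 3 = 75 x 6 = 450).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

DEFAULTS = {
    "epoch_s": 5.0,
    "calibration.static_window_s": 10.0,
    "calibration.sd_mg": 13.0,
    "calibration.min_windows": 10,
    "calibration.min_octants": 2,
    "nonwear.window_min": 60.0,
    "nonwear.step_min": 15.0,
    "nonwear.sd_mg": 13.0,
    "nonwear.range_mg": 50.0,
    "nonwear.min_axes": 2,
    "sleep.angle_deg": 5.0,
    "sleep.min_dur_min": 5.0,
    "sleep.min_total_sib_min": 30.0,
    "waking.start": "05:00",
    "waking.end": "23:00",
    "cuts.light_mg": 30.0,
    "cuts.moderate_mg": 100.0,
    "cuts.vigorous_mg": 400.0,
    "validity.min_wear_hours": 16.0,
    "validity.min_valid_days": 5,
    "bouts.min_duration_min": 10.0,
    "bouts.fraction": 0.8,
    "who.moderate_min": 150.0,
    "who.vigorous_min": 75.0,
    "who.met_threshold": 450.0,
    "who.met_weights": [4.0, 8.0],
    "who.met_thresholds": [3.0, 6.0],
    "energy.aee.intercept": 0.0,
    "energy.aee.slope": 1.4,
    "energy.dit_factor": 0.9,
    "stats.alpha": 0.05,
    "stats.ci_quantile": 1.96,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    values: dict = field(default_factory=lambda: dict(DEFAULTS))

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values = dict(DEFAULTS)
        values.update(raw)
        cfg = cls(values)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)

    def validate(self) -> None:
        """Structural sanity plus the WHO MET-threshold identity."""
        v = self.values
        if not (0 < v["cuts.light_mg"] < v["cuts.moderate_mg"] < v["cuts.vigorous_mg"]):
            raise ValueError("cut-points must be strictly increasing and positive")
        if not 0 < v["bouts.fraction"] <= 1:
            raise ValueError("bout fraction must be in (0, 1]")
        mt = v["who.met_thresholds"]
        ident = v["who.moderate_min"] * mt[0]
        if not (
            abs(ident - v["who.vigorous_min"] * mt[1]) < 1e-9
            and abs(ident - v["who.met_threshold"]) < 1e-9
        ):
            raise ValueError(
                "WHO MET identity violated: moderate_min*MET_mod must equal "
                "vigorous_min*MET_vig and the MET threshold"
            )
        if v["energy.dit_factor"] <= 0 or v["energy.dit_factor"] > 1:
            raise ValueError("diet-induced thermogenesis factor must be in (0, 1]")
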