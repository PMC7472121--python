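"""Self-report instruments: InCHIANTI activity level and PASE score bands."""

from __future__ import annotations

from dataclasses import dataclass

INCHIANTI_LABELS = {
    0: "no physical activity (or bedridden)",
    1: "minimal physical activity",
    2: "light physical activity (2-4 h/week, no sweating)",
    3: "moderate physical activity (1-2 h/week with sweating, or >4 h/week light)",
    4: "moderate physical activity >3 h/week with sweating",
    5: "regular physical exercise requiring maximal strength/endurance",
}

PASE_CATEGORIES = ("sedentary", "light", "moderate_to_intense")


@dataclass(frozen=True)
class InchiantiLevel:
    level: int

    @property
    def label(self) -> str:
        return INCHIANTI_LABELS[self.level]


def validate_inchianti(raw) -> InchiantiLevel:
    """Accept integers 0-5; everything else is rejected with a message."""
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise ValueError(f"InCHIANTI level must be an integer 0-5, got {raw!r}") from None
    if value != float(raw) or value not in INCHIANTI_LABELS:
        raise ValueError(f"InCHIANTI level must be an integer 0-5, got {raw!r}")
    return InchiantiLevel(value)


def categorize_pase(score: float) -> str:
    """PASE band: <=40 sedentary, (40, 90] light, >90 moderate-to-intense.

    The published bands ("below 40", "41 to 90", "over 90") leave (40, 41)
    unassigned; closing the gap at 40 keeps the mapping total and monotone.
    """
    if score < 0:
        raise ValueError("PASE score must be non-negative")
    if score <= 40:
        return "sedentary"
    if score <= 90:
        return "light"
    return "moderate_to_intense"
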