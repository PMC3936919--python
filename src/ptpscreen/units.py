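"""Unit-dose scale for formulation concentrations.

Formulation doses are expressed on a prescribed-daily-dose scale rather than
in molar units (a formulation is a mixture with no single molecular weight):
1 U is one prescribed daily dose dissolved per mL of assay volume,
1 mU = 1e-3 U and 1 uU (micro-unit) = 1e-6 U.  Crude-drug extracts instead use
mass concentration (ug/mL); the two scales never interconvert.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from .exceptions import InvalidParameterError

#: factor converting one unit of each scale to U
SCALE_TO_U = {"U": 1.0, "mU": 1e-3, "uU": 1e-6}

#: decimal exponent of each scale relative to U
_SCALE_EXP = {"U": 0, "mU": -3, "uU": -6}

_ALIASES = {
    "u": "U",
    "mu": "mU",
    "uu": "uU",
    "μu": "uU",  # Greek mu
    "µu": "uU",  # micro sign
}


def normalize_scale(scale: str) -> str:
    """Return the canonical scale name, accepting micro-sign spellings."""
    key = scale.strip().replace("/mL", "").replace("/ml", "")
    canon = _ALIASES.get(key.lower())
    if canon is None:
        raise InvalidParameterError(f"unknown dose scale: {scale!r}")
    return canon


@dataclass(frozen=True)
class UnitDose:
    """A dose on the prescribed-daily-dose (Unit) scale, per mL."""

    value: float
    scale: str = "uU"

    def __post_init__(self):
        object.__setattr__(self, "scale", normalize_scale(self.scale))

    def to(self, target_scale: str) -> "UnitDose":
        """Convert to another scale by an exact power-of-ten decimal shift.

        The shift is done in decimal (not by a float multiply, whose
        rounding would break round-trips), so 0.1 mU/mL is exactly
        100 uU/mL and conversions there and back are the identity.
        """
        target_scale = normalize_scale(target_scale)
        diff = _SCALE_EXP[self.scale] - _SCALE_EXP[target_scale]
        return UnitDose(float(Decimal(repr(self.value)).scaleb(diff)), target_scale)

    @property
    def in_uU(self) -> float:
        return self.to("uU").value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:g} {self.scale}/mL"


def convert_dose(value: float, scale: str, target_scale: str) -> UnitDose:
    """Convert ``value`` on ``scale`` to ``target_scale`` (exact)."""
    return UnitDose(value, scale).to(target_scale)
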