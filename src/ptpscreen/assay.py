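"""Percent-inhibition computation from chromogenic phosphatase assays.

A phosphatase assay read is an absorbance increase at 405 nm over 30 min
(hydrolysis of p-nitrophenyl phosphate to p-nitrophenol).  The inhibition
rate of a sample is

    rate% = (1 - (dA_sample - dA_blank) / dA_control) * 100

where ``dA_blank`` measures non-enzymatic substrate hydrolysis (no enzyme)
and ``dA_control`` is the uninhibited enzymatic signal, already
blank-corrected.  A rate of 90% or higher counts as complete inhibition; the
threshold is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .exceptions import DegenerateControlError, InvalidParameterError, MixedDoseError
from .units import UnitDose

COMPLETE_INHIBITION_THRESHOLD = 90.0


@dataclass(frozen=True)
class AbsorbanceTriple:
    """One assay observation: sample, blank and control dA405 at a dose.

    ``dA_control`` is the blank-corrected uninhibited signal.  Plate exports
    that report a raw (uncorrected) control can set
    ``control_is_blank_corrected=False`` and the blank is subtracted
    internally.
    """

    dA_sample: float
    dA_blank: float
    dA_control: float
    dose: Optional[UnitDose] = None
    control_is_blank_corrected: bool = True

    def __post_init__(self):
        if self.dA_sample < 0 or self.dA_blank < 0:
            raise InvalidParameterError(
                "absorbance changes must be non-negative "
                f"(dA_sample={self.dA_sample}, dA_blank={self.dA_blank})"
            )

    @property
    def corrected_control(self) -> float:
        if self.control_is_blank_corrected:
            return self.dA_control
        return self.dA_control - self.dA_blank


@dataclass(frozen=True)
class InhibitionResult:
    """Percent inhibition with the complete-inhibition flag."""

    rate_pct: float
    complete: bool
    dose: Optional[UnitDose] = None

    @property
    def out_of_range(self) -> bool:
        """True when the measured rate falls outside [0, 100]."""
        return self.rate_pct < 0.0 or self.rate_pct > 100.0


def classify_complete(
    rate_pct: float, threshold: float = COMPLETE_INHIBITION_THRESHOLD
) -> bool:
    """True iff ``rate_pct`` meets the complete-inhibition threshold (inclusive)."""
    if not math.isfinite(rate_pct):
        raise InvalidParameterError(f"non-finite inhibition rate: {rate_pct}")
    return rate_pct >= threshold


def inhibition_rate(
    triple: AbsorbanceTriple,
    threshold: float = COMPLETE_INHIBITION_THRESHOLD,
    clip: bool = False,
) -> InhibitionResult:
    """Compute percent inhibition from an absorbance triple.

    Rates below 0% or above 100% are preserved (and flagged via
    ``InhibitionResult.out_of_range``) unless ``clip`` is set — downstream
    regression should see the measured values.
    """
    control = triple.corrected_control
    if control <= 0:
        raise DegenerateControlError(
            f"control dA405 must be positive, got {control}"
        )
    rate = (1.0 - (triple.dA_sample - triple.dA_blank) / control) * 100.0
    if clip:
        rate = min(max(rate, 0.0), 100.0)
    return InhibitionResult(rate, classify_complete(rate, threshold), triple.dose)


def triple_from_rate(
    rate_pct: float,
    dose: Optional[UnitDose] = None,
    dA_control: float = 0.4,
    dA_blank: float = 0.05,
) -> AbsorbanceTriple:
    """Invert the inhibition-rate formula: build a triple yielding ``rate_pct``.

    Synthetic fixture constructor; the returned triple satisfies
    ``inhibition_rate(t).rate_pct == rate_pct`` up to rounding.
    """
    dA_sample = dA_blank + dA_control * (1.0 - rate_pct / 100.0)
    if dA_sample < 0:
        # very strong signal amplification requested; shift the blank instead
        dA_blank = dA_blank - dA_sample
        dA_sample = 0.0
    return AbsorbanceTriple(dA_sample, dA_blank, dA_control, dose)


@dataclass(frozen=True)
class ScreenResult:
    """A panel screen: per-sample rates sorted by potency, plus the hit count."""

    table: pd.DataFrame  # columns: sample_id, rate_pct, complete
    n_complete: int
    threshold: float
    dose: Optional[UnitDose] = None


def screen_panel(
    triples: Mapping[str, AbsorbanceTriple],
    threshold: float = COMPLETE_INHIBITION_THRESHOLD,
    allow_mixed_doses: bool = False,
) -> ScreenResult:
    """Screen a panel of samples at a common dose.

    Returns a table of (sample_id, rate_pct, complete) sorted descending by
    rate, and the count of complete-inhibition hits.  Panels mixing doses
    raise unless ``allow_mixed_doses`` is set.
    """
    doses = {
        (t.dose.value, t.dose.scale) if t.dose is not None else None
        for t in triples.values()
    }
    if len(doses) > 1 and not allow_mixed_doses:
        raise MixedDoseError(
            f"panel contains {len(doses)} distinct doses; "
            "pass allow_mixed_doses=True to screen anyway"
        )
    rows = []
    for sample_id, t in triples.items():
        res = inhibition_rate(t, threshold)
        rows.append((sample_id, res.rate_pct, res.complete))
    table = pd.DataFrame(rows, columns=["sample_id", "rate_pct", "complete"])
    if rows:
        table = table.sort_values(
            "rate_pct", ascending=False, kind="stable"
        ).reset_index(drop=True)
    dose = None
    if len(doses) == 1 and triples:
        dose = next(iter(triples.values())).dose
    return ScreenResult(table, int(table["complete"].sum()), threshold, dose)


def read_plate_csv(path) -> dict:
    """Read a plate export CSV into a sample_id -> AbsorbanceTriple mapping.

    Expected columns: sample_id, dA_sample, dA_blank, dA_control and
    optionally dose_value, dose_scale.  Replicate rows per sample are
    averaged (mean of each dA column) before the triple is formed.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "dA_sample", "dA_blank", "dA_control"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"plate CSV missing columns: {sorted(missing)}")
    triples = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        dose = None
        if "dose_value" in grp.columns and "dose_scale" in grp.columns:
            dose = UnitDose(float(grp["dose_value"].iloc[0]), str(grp["dose_scale"].iloc[0]))
        triples[sample_id] = AbsorbanceTriple(
            float(grp["dA_sample"].mean()),
            float(grp["dA_blank"].mean()),
            float(grp["dA_control"].mean()),
            dose,
        )
    return triples


def replicate_rates(
    triples: Iterable[AbsorbanceTriple],
    threshold: float = COMPLETE_INHIBITION_THRESHOLD,
) -> tuple[float, float]:
    """Mean and SD of inhibition rates over replicate wells of one sample."""
    rates = [inhibition_rate(t, threshold).rate_pct for t in triples]
    s = pd.Series(rates, dtype=float)
    return float(s.mean()), float(s.std(ddof=1)) if len(rates) > 1 else 0.0
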