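"""Selectivity profiling across a phosphatase panel at one matched dose.

Members of the protein tyrosine phosphatase family share a highly similar
catalytic centre, so an inhibitor of the primary target (PTP1B by default)
is profiled against homologues (TCPTP, VHR, SHP-1, SHP-2) at the same dose.
Selectivity is summarised as a rate difference at matched dose,
``rate(reference) - rate(enzyme)`` — IC50 ratios would need full panel
dose-response curves, which a single-dose screen does not measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .assay import COMPLETE_INHIBITION_THRESHOLD
from .exceptions import InvalidParameterError
from .units import UnitDose

DEFAULT_REFERENCE = "PTP1B"


@dataclass(frozen=True)
class PanelResult:
    """Percent inhibition of one sample across an enzyme panel at one dose."""

    sample_id: str
    rates: Mapping[str, float]  # enzyme -> percent inhibition
    dose: Optional[UnitDose] = None
    reference_enzyme: str = DEFAULT_REFERENCE

    def __post_init__(self):
        if self.reference_enzyme not in self.rates:
            raise InvalidParameterError(
                f"reference enzyme {self.reference_enzyme!r} missing from panel "
                f"{sorted(self.rates)}"
            )


@dataclass(frozen=True)
class SelectivityProfile:
    """Ranked selectivity table for one sample."""

    table: pd.DataFrame  # enzyme, inhibition_pct, selectivity_index
    reference_enzyme: str
    reference_rate: float
    reference_complete: bool
    sample_id: str = ""

    def summary(self) -> str:
        rows = [
            f"Selectivity profile{' for ' + self.sample_id if self.sample_id else ''}",
            f"  reference {self.reference_enzyme}: {self.reference_rate:.1f}% "
            f"({'complete' if self.reference_complete else 'partial'} inhibition)",
        ]
        for _, r in self.table.iterrows():
            rows.append(
                f"  {r['enzyme']:<8} {r['inhibition_pct']:6.1f}%   "
                f"index {r['selectivity_index']:+.1f}"
            )
        return "\n".join(rows)


def selectivity_profile(
    result: PanelResult,
    complete_threshold: float = COMPLETE_INHIBITION_THRESHOLD,
) -> SelectivityProfile:
    """Rank panel enzymes by inhibition and compute selectivity indices.

    The comparison set excludes the reference enzyme; enzymes are sorted by
    descending inhibition.  ``selectivity_index = rate(reference) - rate(enzyme)``
    (positive means the sample prefers the reference target).
    """
    ref = result.reference_enzyme
    ref_rate = float(result.rates[ref])
    rows = [
        (enzyme, float(rate), ref_rate - float(rate))
        for enzyme, rate in result.rates.items()
        if enzyme != ref
    ]
    table = pd.DataFrame(rows, columns=["enzyme", "inhibition_pct", "selectivity_index"])
    if rows:
        table = table.sort_values(
            "inhibition_pct", ascending=False, kind="stable"
        ).reset_index(drop=True)
    return SelectivityProfile(
        table=table,
        reference_enzyme=ref,
        reference_rate=ref_rate,
        reference_complete=ref_rate >= complete_threshold,
        sample_id=result.sample_id,
    )


def read_panel_csv(path) -> list[PanelResult]:
    """Read a long CSV (sample_id, enzyme, dose_value, dose_scale, inhibition_pct)."""
    df = pd.read_csv(path)
    panels = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        dose = None
        if "dose_value" in grp.columns and "dose_scale" in grp.columns:
            dose = UnitDose(float(grp["dose_value"].iloc[0]), str(grp["dose_scale"].iloc[0]))
        rates = dict(zip(grp["enzyme"], grp["inhibition_pct"].astype(float)))
        if len(rates) != len(grp):
            raise InvalidParameterError(
                f"duplicate enzymes in panel for sample {sample_id!r}"
            )
        panels.append(PanelResult(str(sample_id), rates, dose))
    return panels
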