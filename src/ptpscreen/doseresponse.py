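"""IC50 estimation by linear regression on the semi-log dose-response plot.

The estimator follows classical screening practice: percent inhibition is
regressed on log10(concentration) by ordinary least squares over the points
whose rates fall inside a working band (default the open interval 5-95%,
where the dose-response of a one-site inhibitor is closest to log-linear),
and the IC50 is read off as the concentration where the fitted line crosses
50%:

    IC50 = 10 ** ((50 - intercept) / slope)

This is deliberately not a four-parameter logistic fit; the semi-log line is
the estimator under test, and its robustness to the underlying Hill-shaped
truth is quantified in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidParameterError, NoFitError

DEFAULT_BAND = (5.0, 95.0)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Paired concentrations and percent inhibitions for one sample."""

    concs: np.ndarray
    rates: np.ndarray
    sample_id: str = ""
    dose_scale: str = "uU"  # or a mass-concentration label such as "ug/mL"

    def __post_init__(self):
        concs = np.asarray(self.concs, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "concs", concs)
        object.__setattr__(self, "rates", rates)
        if concs.shape != rates.shape or concs.ndim != 1:
            raise InvalidParameterError("concs and rates must be 1-D and equal length")
        if len(concs) < 3:
            raise InvalidParameterError("a dose-response curve needs at least 3 points")
        if np.any(concs <= 0):
            raise InvalidParameterError("concentrations must be positive")
        if np.any(np.diff(concs) < 0):
            # accept any ordering but keep a sorted canonical form
            order = np.argsort(concs, kind="stable")
            object.__setattr__(self, "concs", concs[order])
            object.__setattr__(self, "rates", rates[order])
        if np.any(np.diff(self.concs) == 0):
            raise InvalidParameterError("concentrations must be distinct")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "conc": self.concs, "inhibition_pct": self.rates}
        )


@dataclass(frozen=True)
class IC50Results:
    """Fitted IC50 with regression diagnostics.

    ``bracketed`` is True when the observed rates span 50%; an unbracketed
    estimate is an extrapolation of the semi-log line and is returned with a
    warning, never silently.
    """

    ic50: float
    slope: float
    intercept: float
    n_points_used: int
    bracketed: bool
    rsquared: float
    ci_halfwidth: Optional[float] = None
    sample_id: str = ""
    dose_scale: str = "uU"
    band: tuple = DEFAULT_BAND

    def summary(self) -> str:
        lines = [
            f"IC50 estimate{' for ' + self.sample_id if self.sample_id else ''}",
            f"  IC50           : {self.ic50:.4g} {self.dose_scale}/mL",
            f"  semi-log slope : {self.slope:.4g} %/log10",
            f"  intercept      : {self.intercept:.4g} %",
            f"  R^2            : {self.rsquared:.4f}",
            f"  points used    : {self.n_points_used} (band {self.band[0]:g}-{self.band[1]:g}%)",
            f"  50% bracketed  : {self.bracketed}",
        ]
        if self.ci_halfwidth is not None:
            lines.append(f"  ~95% CI (+/-)  : {self.ci_halfwidth:.4g}")
        return "\n".join(lines)


class IC50Model:
    """Semi-log linear dose-response model for one sample.

    Parameters
    ----------
    curve : DoseResponseCurve
        Concentration series with percent inhibition.
    band : (low, high)
        Open working band on the rate scale; points with
        ``low < rate < high`` enter the regression.
    log_base : float
        Base of the concentration logarithm (10 matches standard semi-log
        plotting; the IC50 estimate itself is base-invariant).
    """

    def __init__(
        self,
        curve: DoseResponseCurve,
        band: tuple = DEFAULT_BAND,
        log_base: float = 10.0,
    ):
        if band[0] >= band[1]:
            raise InvalidParameterError(f"invalid working band {band}")
        self.curve = curve
        self.band = (float(band[0]), float(band[1]))
        self.log_base = float(log_base)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str = "", **kwargs) -> "IC50Model":
        """Build from a long CSV frame with columns conc, inhibition_pct."""
        sub = df if not sample_id else df[df["sample_id"] == sample_id]
        curve = DoseResponseCurve(
            sub["conc"].to_numpy(float),
            sub["inhibition_pct"].to_numpy(float),
            sample_id=sample_id,
            dose_scale=str(sub["conc_scale"].iloc[0]) if "conc_scale" in sub else "uU",
        )
        return cls(curve, **kwargs)

    def fit(self) -> IC50Results:
        rates = self.curve.rates
        concs = self.curve.concs
        in_band = (rates > self.band[0]) & (rates < self.band[1])
        if int(in_band.sum()) < 2:
            raise InsufficientDataError(
                f"only {int(in_band.sum())} point(s) inside the "
                f"{self.band[0]:g}-{self.band[1]:g}% working band; need >= 2"
            )
        x = np.log(concs[in_band]) / np.log(self.log_base)
        y = rates[in_band]
        fit = stats.linregress(x, y)
        if fit.slope <= 0:
            raise NoFitError(
                f"semi-log slope is {fit.slope:.4g} (must be positive): "
                "data are flat or non-monotone"
            )
        log_ic50 = (50.0 - fit.intercept) / fit.slope
        ic50 = float(self.log_base**log_ic50)
        bracketed = bool(rates.min() <= 50.0 <= rates.max())
        if not bracketed:
            warnings.warn(
                f"50% inhibition not bracketed by observed rates "
                f"[{rates.min():.1f}, {rates.max():.1f}]%; IC50 for "
                f"{self.curve.sample_id or 'sample'} is an extrapolation",
                UserWarning,
                stacklevel=2,
            )
        ci = None
        n = len(x)
        if n >= 3 and fit.stderr and fit.stderr > 0:
            # delta-method ~95% CI on log-IC50, propagated to the dose scale
            tcrit = stats.t.ppf(0.975, n - 2)
            var_log = (fit.intercept_stderr / fit.slope) ** 2 + (
                log_ic50 / fit.slope
            ) ** 2 * fit.stderr**2
            half_log = tcrit * np.sqrt(var_log)
            ci = float(
                ic50 * (self.log_base**half_log - self.log_base**-half_log) / 2.0
            )
        return IC50Results(
            ic50=ic50,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            n_points_used=n,
            bracketed=bracketed,
            rsquared=float(fit.rvalue**2),
            ci_halfwidth=ci,
            sample_id=self.curve.sample_id,
            dose_scale=self.curve.dose_scale,
            band=self.band,
        )

    def plot(self, ax=None, results: Optional[IC50Results] = None):
        """Semi-log dose-response plot with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.curve.concs, self.curve.rates, "o", label="observed")
        if results is None:
            results = self.fit()
        grid = np.geomspace(self.curve.concs.min(), self.curve.concs.max(), 100)
        line = results.intercept + results.slope * np.log10(grid)
        ax.semilogx(grid, line, "-", label="semi-log fit")
        ax.axhline(50.0, color="grey", lw=0.8, ls="--")
        ax.axvline(results.ic50, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(f"concentration ({self.curve.dose_scale}/mL)")
        ax.set_ylabel("inhibition (%)")
        ax.legend()
        return ax


def fit_ic50(
    curve: DoseResponseCurve, band: tuple = DEFAULT_BAND, log_base: float = 10.0
) -> IC50Results:
    """Convenience wrapper: fit the semi-log IC50 model for one curve."""
    return IC50Model(curve, band=band, log_base=log_base).fit()


def fit_ic50_table(
    df: pd.DataFrame, band: tuple = DEFAULT_BAND
) -> pd.DataFrame:
    """Fit every sample in a long dose-response frame; sorted ascending IC50.

    Expects columns sample_id, conc, inhibition_pct (optionally conc_scale).
    """
    rows = []
    for sample_id in df["sample_id"].unique():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = IC50Model.from_dataframe(df, sample_id=str(sample_id), band=band).fit()
            rows.append(
                (sample_id, res.ic50, res.dose_scale, res.n_points_used, res.bracketed)
            )
        except (InsufficientDataError, NoFitError):
            rows.append((sample_id, np.nan, "", 0, False))
    out = pd.DataFrame(
        rows, columns=["sample_id", "ic50", "scale", "n_points_used", "bracketed"]
    )
    return out.sort_values("ic50", kind="stable").reset_index(drop=True)
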