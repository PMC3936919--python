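"""Lineweaver-Burk analysis and inhibition-mode classification.

Initial velocities over a substrate x inhibitor-dose factorial are assumed to
follow the general linear-inhibition rate law

    v = Vmax * S / ( Km * (1 + I/Ki) + S * (1 + I/Ki') )

where Ki is the inhibitor's dissociation constant from free enzyme and Ki'
from the enzyme-substrate complex.  In double-reciprocal coordinates each
inhibitor level gives a line

    1/v = (Km/Vmax) * (1 + I/Ki) * (1/S)  +  (1 + I/Ki') / Vmax

so the primary-plot slope is linear in I with x-intercept -Ki on the
secondary slope replot, and the primary intercept is linear in I with
x-intercept -Ki' on the secondary intercept replot.  The mode call follows
from which constants are finite and from alpha = Ki'/Ki:

    competitive      Ki finite,  Ki' infinite
    uncompetitive    Ki infinite, Ki' finite
    noncompetitive   alpha within the unity band [1/band, band] (default 1.5)
    mixed            both finite, alpha outside the band; tendency
                     competitive-like (alpha > band) or uncompetitive-like

Two estimators of the replot lines are provided.  ``method="joint"`` (the
default) notes that the whole double-reciprocal surface is linear in the
four replot parameters,

    1/v = c_s * (1/S) + s_s * (I/S) + c_i + s_i * I,

and fits them in a single weighted least-squares regression over every grid
cell, with weights w = v**2 (the delta-method variance of 1/v under
multiplicative velocity noise), so the flatness tests run at the full
residual degrees of freedom.  ``method="two-stage"`` is the classical
textbook procedure — unweighted per-level double-reciprocal lines followed
by two 1-D replots — kept for comparability; with few inhibitor levels its
replot t-tests have very few degrees of freedom and the mode call is
noticeably noisier.

A replot slope counts as flat — an infinite constant — unless it is
significantly *positive* (one-sided t-test; a negative trend is impossible
under the rate law, so a significant negative fit is noise on a flat
replot) and the implied constant would modulate the line by at least
``min_modulation`` over the dosed range (default 0.3, i.e. a 30% change at
I_max; smaller implied effects are not distinguishable from plate noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InconsistentKineticsError,
    InsufficientDataError,
    InvalidParameterError,
)

DEFAULT_ALPHA_BAND = 1.5
DEFAULT_MIN_MODULATION = 0.3
DEFAULT_FLAT_PVALUE = 0.05

MODE_COMPETITIVE = "competitive"
MODE_UNCOMPETITIVE = "uncompetitive"
MODE_NONCOMPETITIVE = "noncompetitive"
MODE_MIXED = "mixed"
NO_INHIBITION = "no_inhibition"  # sentinel, not a mode


@dataclass(frozen=True)
class KineticsGrid:
    """Initial velocities on a substrate x inhibitor factorial.

    ``v`` is indexed (inhibitor level, substrate level).
    """

    S_levels: np.ndarray  # substrate, mM
    I_levels: np.ndarray  # inhibitor dose (unit-dose scale)
    v: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.S_levels, dtype=float)
        I = np.asarray(self.I_levels, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "S_levels", S)
        object.__setattr__(self, "I_levels", I)
        object.__setattr__(self, "v", v)
        if v.shape != (len(I), len(S)):
            raise InvalidParameterError(
                f"velocity matrix shape {v.shape} != (n_I={len(I)}, n_S={len(S)})"
            )
        if len(np.unique(S)) < 3:
            raise InsufficientDataError("need >= 3 distinct substrate levels")
        if np.any(S <= 0):
            raise InvalidParameterError("substrate concentrations must be positive")
        if np.any(I < 0):
            raise InvalidParameterError("inhibitor doses must be non-negative")
        if 0.0 not in I:
            raise InvalidParameterError("inhibitor levels must include 0 (no inhibitor)")
        if np.any(v <= 0):
            raise InvalidParameterError("all velocities must be positive")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "KineticsGrid":
        """Build from a long frame with columns substrate_mM, inhibitor_dose, velocity."""
        pivot = df.pivot_table(
            index="inhibitor_dose", columns="substrate_mM", values="velocity"
        )
        return cls(
            pivot.columns.to_numpy(float),
            pivot.index.to_numpy(float),
            pivot.to_numpy(float),
        )

    def to_long(self) -> pd.DataFrame:
        rows = [
            (S, I, self.v[i, j])
            for i, I in enumerate(self.I_levels)
            for j, S in enumerate(self.S_levels)
        ]
        return pd.DataFrame(rows, columns=["substrate_mM", "inhibitor_dose", "velocity"])


@dataclass(frozen=True)
class LBLine:
    """One double-reciprocal line: 1/v = slope * (1/S) + intercept."""

    I: float
    slope: float  # Km_app / Vmax_app
    intercept: float  # 1 / Vmax_app
    r2: float

    @property
    def Vmax_app(self) -> float:
        return 1.0 / self.intercept

    @property
    def Km_app(self) -> float:
        return self.slope / self.intercept


@dataclass(frozen=True)
class ModeCall:
    """Inhibition-mode classification with the underlying constants."""

    mode: str
    tendency: str  # 'competitive-like' | 'uncompetitive-like' | 'none'
    Ki: float  # may be math.inf
    Ki_prime: float  # may be math.inf
    alpha: Optional[float]  # Ki'/Ki when both finite, else None


@dataclass(frozen=True)
class ReplotDiagnostics:
    """Replot-line regression diagnostics for one inhibition constant."""

    slope: float
    intercept: float
    slope_se: float
    tstat: float
    tcrit: float
    flat: bool
    constant: float  # the implied Ki or Ki'; inf when flat


def fit_lb_lines(grid: KineticsGrid) -> list[LBLine]:
    """Unweighted OLS of 1/v on 1/S, one line per inhibitor level, ordered by I."""
    order = np.argsort(grid.I_levels, kind="stable")
    x = 1.0 / grid.S_levels
    lines = []
    for i in order:
        y = 1.0 / grid.v[i]
        fit = stats.linregress(x, y)
        lines.append(
            LBLine(
                I=float(grid.I_levels[i]),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r2=float(fit.rvalue**2),
            )
        )
    return lines


def _judge_replot(
    slope: float,
    intercept: float,
    slope_se: float,
    df: int,
    I_max: float,
    min_modulation: float,
    flat_pvalue: float,
    what: str,
) -> ReplotDiagnostics:
    """Decide flat vs finite for one replot line and derive its constant."""
    tcrit = float(stats.t.ppf(1.0 - flat_pvalue, df)) if df > 0 else math.inf
    if slope_se > 0:
        tstat = slope / slope_se
    else:  # exact data: any positive slope is significant
        tstat = math.inf if slope > 0 else (-math.inf if slope < 0 else 0.0)
    constant = math.inf
    flat = True
    if tstat >= tcrit:  # one-sided: only a positive trend is physical
        if intercept <= 0:
            raise InconsistentKineticsError(
                f"{what} replot has non-positive intercept {intercept:.4g} "
                "with a significant slope; not valid enzymology"
            )
        cand = intercept / slope  # x-intercept of the replot is -constant
        # require a practically detectable modulation over the dosed range
        if I_max / cand >= min_modulation:
            constant = float(cand)
            flat = False
    return ReplotDiagnostics(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        tstat=float(tstat),
        tcrit=tcrit,
        flat=flat,
        constant=constant,
    )


def replot_estimates(
    lines: Sequence[LBLine],
    min_modulation: float = DEFAULT_MIN_MODULATION,
    flat_pvalue: float = DEFAULT_FLAT_PVALUE,
) -> tuple[float, float, dict]:
    """Two-stage secondary replots: (Ki, Ki', diagnostics) from fitted lines.

    Regresses the primary-line slopes and intercepts on I; either constant
    is ``math.inf`` when its replot is flat (see module docstring for the
    flatness rule).
    """
    if len(lines) < 3:
        raise InsufficientDataError("secondary replots need >= 3 inhibitor levels")
    I = np.array([ln.I for ln in lines])
    if 0.0 not in I:
        raise InvalidParameterError("replot needs the uninhibited (I=0) line")
    diag = {}
    out = []
    for what, y in (
        ("slope", np.array([ln.slope for ln in lines])),
        ("intercept", np.array([ln.intercept for ln in lines])),
    ):
        fit = stats.linregress(I, y)
        se = float(fit.stderr) if fit.stderr else 0.0
        d = _judge_replot(
            float(fit.slope),
            float(fit.intercept),
            se,
            len(I) - 2,
            float(I.max()),
            min_modulation,
            flat_pvalue,
            what,
        )
        diag[f"{what}_replot"] = d
        out.append(d.constant)
    return out[0], out[1], diag


def joint_replot_estimates(
    grid: KineticsGrid,
    min_modulation: float = DEFAULT_MIN_MODULATION,
    flat_pvalue: float = DEFAULT_FLAT_PVALUE,
) -> tuple[float, float, dict]:
    """(Ki, Ki', diagnostics) from one weighted fit of the reciprocal surface.

    Fits 1/v = c_s/S + s_s*(I/S) + c_i + s_i*I over all grid cells by
    weighted least squares (w = v**2), then applies the same flatness rule
    as :func:`replot_estimates` to (c_s, s_s) and (c_i, s_i) at the full
    residual degrees of freedom.
    """
    if len(grid.I_levels) < 3:
        raise InsufficientDataError("replot analysis needs >= 3 inhibitor levels")
    Sg, Ig = np.meshgrid(grid.S_levels, grid.I_levels)
    v = grid.v.ravel()
    s, i = Sg.ravel(), Ig.ravel()
    y = 1.0 / v
    X = np.column_stack([1.0 / s, i / s, np.ones_like(s), i])
    w = v**2
    A = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ beta
    df = len(y) - 4
    sigma2 = float(resid @ (w * resid)) / df if df > 0 else 0.0
    cov = np.linalg.inv(A) * sigma2
    diag = {}
    out = []
    for what, (c_idx, s_idx) in (("slope", (0, 1)), ("intercept", (2, 3))):
        d = _judge_replot(
            float(beta[s_idx]),
            float(beta[c_idx]),
            math.sqrt(max(float(cov[s_idx, s_idx]), 0.0)),
            df,
            float(grid.I_levels.max()),
            min_modulation,
            flat_pvalue,
            what,
        )
        diag[f"{what}_replot"] = d
        out.append(d.constant)
    return out[0], out[1], diag


def classify_mode(
    Ki: float,
    Ki_prime: float,
    alpha_band: float = DEFAULT_ALPHA_BAND,
) -> ModeCall:
    """Classify the inhibition mode from the two constants.

    ``alpha_band`` b defines 'noncompetitive' as alpha = Ki'/Ki in [1/b, b].
    Both constants infinite is not a mode: the sentinel ``NO_INHIBITION``
    is returned.
    """
    if alpha_band <= 1.0:
        raise InvalidParameterError("alpha_band must exceed 1")
    ki_fin = math.isfinite(Ki)
    kip_fin = math.isfinite(Ki_prime)
    if not ki_fin and not kip_fin:
        return ModeCall(NO_INHIBITION, "none", Ki, Ki_prime, None)
    if ki_fin and not kip_fin:
        return ModeCall(MODE_COMPETITIVE, "none", Ki, Ki_prime, None)
    if kip_fin and not ki_fin:
        return ModeCall(MODE_UNCOMPETITIVE, "none", Ki, Ki_prime, None)
    if Ki <= 0 or Ki_prime <= 0:
        raise InvalidParameterError("inhibition constants must be positive")
    alpha = Ki_prime / Ki
    if 1.0 / alpha_band <= alpha <= alpha_band:
        return ModeCall(MODE_NONCOMPETITIVE, "none", Ki, Ki_prime, alpha)
    tendency = "competitive-like" if alpha > alpha_band else "uncompetitive-like"
    return ModeCall(MODE_MIXED, tendency, Ki, Ki_prime, alpha)


@dataclass(frozen=True)
class KineticsResults:
    """Full Lineweaver-Burk analysis of one sample's grid."""

    lines: list
    mode_call: ModeCall
    diagnostics: dict
    sample_id: str = ""

    @property
    def Ki(self) -> float:
        return self.mode_call.Ki

    @property
    def Ki_prime(self) -> float:
        return self.mode_call.Ki_prime

    @property
    def alpha(self) -> Optional[float]:
        return self.mode_call.alpha

    @property
    def mode(self) -> str:
        return self.mode_call.mode

    def summary(self) -> str:
        fmt = lambda k: "inf" if math.isinf(k) else f"{k:.4g}"
        rows = [
            f"Lineweaver-Burk analysis{' for ' + self.sample_id if self.sample_id else ''}",
            "  I dose    slope    intercept   R^2",
        ]
        for ln in self.lines:
            rows.append(
                f"  {ln.I:7.3g}  {ln.slope:8.4g}  {ln.intercept:8.4g}  {ln.r2:7.5f}"
            )
        rows += [
            f"  Ki       : {fmt(self.Ki)}",
            f"  Ki'      : {fmt(self.Ki_prime)}",
            f"  alpha    : {self.alpha:.4g}" if self.alpha is not None else "  alpha    : n/a",
            f"  mode     : {self.mode}"
            + (f" ({self.mode_call.tendency})" if self.mode_call.tendency != "none" else ""),
        ]
        return "\n".join(rows)

    def to_dict(self) -> dict:
        clean = lambda k: None if math.isinf(k) else k
        return {
            "sample_id": self.sample_id,
            "lines": [
                {"I": ln.I, "slope": ln.slope, "intercept": ln.intercept, "r2": ln.r2}
                for ln in self.lines
            ],
            "Ki": clean(self.Ki),
            "Ki_prime": clean(self.Ki_prime),
            "alpha": self.alpha,
            "mode": self.mode,
            "tendency": self.mode_call.tendency,
        }


class LineweaverBurk:
    """Model object: double-reciprocal analysis of a kinetics grid.

    ``fit()`` runs the primary per-inhibitor-level regressions, estimates
    (Ki, Ki') from the replot lines and classifies the mode, returning a
    :class:`KineticsResults`.

    Parameters
    ----------
    method : {"joint", "two-stage"}
        Replot estimator; "joint" (default) fits both replot lines in one
        weighted regression over the whole grid, "two-stage" is the
        classical unweighted per-level procedure.
    alpha_band : float
        Half-width (on the ratio scale) of the 'noncompetitive' band.
    min_modulation, flat_pvalue : float
        Flatness rule for the replots (see module docstring).
    """

    def __init__(
        self,
        grid: KineticsGrid,
        sample_id: str = "",
        method: str = "joint",
        alpha_band: float = DEFAULT_ALPHA_BAND,
        min_modulation: float = DEFAULT_MIN_MODULATION,
        flat_pvalue: float = DEFAULT_FLAT_PVALUE,
    ):
        if method not in ("joint", "two-stage"):
            raise InvalidParameterError(f"unknown method {method!r}")
        self.grid = grid
        self.sample_id = sample_id
        self.method = method
        self.alpha_band = alpha_band
        self.min_modulation = min_modulation
        self.flat_pvalue = flat_pvalue

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "LineweaverBurk":
        return cls(KineticsGrid.from_long(df), **kwargs)

    def fit(self) -> KineticsResults:
        lines = fit_lb_lines(self.grid)
        if self.method == "joint":
            Ki, Ki_prime, diag = joint_replot_estimates(
                self.grid,
                min_modulation=self.min_modulation,
                flat_pvalue=self.flat_pvalue,
            )
        else:
            Ki, Ki_prime, diag = replot_estimates(
                lines,
                min_modulation=self.min_modulation,
                flat_pvalue=self.flat_pvalue,
            )
        call = classify_mode(Ki, Ki_prime, alpha_band=self.alpha_band)
        return KineticsResults(lines, call, diag, sample_id=self.sample_id)

    def plot(self, ax=None):
        """Double-reciprocal plot, one line per inhibitor level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = 1.0 / self.grid.S_levels
        lines = fit_lb_lines(self.grid)
        order = np.argsort(self.grid.I_levels, kind="stable")
        for ln, i in zip(lines, order):
            ax.plot(x, 1.0 / self.grid.v[i], "o", ms=4)
            xx = np.linspace(0, x.max() * 1.05, 50)
            ax.plot(xx, ln.intercept + ln.slope * xx, "-", label=f"I = {ln.I:g}")
        ax.set_xlabel("1/[S] (1/mM)")
        ax.set_ylabel("1/v")
        ax.legend()
        return ax
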