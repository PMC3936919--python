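"""PLS1 regression (NIPALS) with leave-one-out PRESS component selection.

Implements univariate-response partial least squares for attributing the
activity of multi-ingredient formulations to their constituent crude drugs.
The composition matrix X (formulations x crude drugs, dose weights) is wide
and collinear — ingredients co-occur in fixed recipes — which rules out
plain least squares; PLS projects X onto A latent components that maximise
covariance with the response and regresses on those.

Model, with column-mean-centred Xc and yc:

    y = ybar + sum_k t_k q_k + e         X = Xbar + sum_k t_k p_k^T + E

Per NIPALS component (no y-deflation, which is equivalent for a univariate
response): weight w_k ∝ Xc^T yc (unit norm), score t_k = Xc w_k, loading
p_k = Xc^T t_k / (t_k^T t_k), response coefficient q_k = t_k^T yc /
(t_k^T t_k), then deflate Xc <- Xc - t_k p_k^T.  Original-space coefficients
are recovered as

    b = W (P^T W)^{-1} q,    b0 = ybar - Xbar . b

so predictions can be written y_hat = b0 + X b.  The component count A is
chosen by leave-one-out cross-validation: for each candidate A the model is
refit n times with one sample held out, and PRESS(A) = sum_i (y_i -
y_hat_(-i))^2 is minimised, ties broken toward the smaller (more
parsimonious) A.

Preprocessing is mean-centring only; unit-variance scaling is available via
``scale=True`` but is off by default because the dose weights share a common
unit.  Zero-variance columns are dropped with a warning and reported as not
estimable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import (
    ColumnMismatchError,
    ComponentCollapseError,
    InsufficientDataError,
    InvalidParameterError,
)

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class PRESSProfile:
    """Leave-one-out PRESS per candidate component count."""

    press: np.ndarray  # PRESS(A) for A = 1..A_max
    a_selected: int
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ncomp": np.arange(1, len(self.press) + 1), "press": self.press}
        )


def evaluate_fit(y, y_hat) -> tuple[float, np.ndarray]:
    """Coefficient of determination and residuals of a prediction.

    residuals = y - y_hat elementwise; R^2 = 1 - SS_res / SS_tot with SS_tot
    about the mean of y.  Constant y makes R^2 undefined and raises (the
    residuals are available on the exception as ``.residuals``).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise InvalidParameterError("y and y_hat must be 1-D and equal length")
    if len(y) < 2:
        raise InsufficientDataError("need at least 2 observations")
    residuals = y - y_hat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        err = InvalidParameterError("R^2 undefined for constant y")
        err.residuals = residuals
        raise err
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot
    return r2, residuals


def _nipals(Xc: np.ndarray, yc: np.ndarray, ncomp: int):
    """Core NIPALS-PLS1 loop on centred data.

    Returns (T, P, W, q).  Raises ComponentCollapseError when the weight or
    score norm vanishes before ``ncomp`` components are extracted.
    """
    n, m = Xc.shape
    T = np.zeros((n, ncomp))
    P = np.zeros((m, ncomp))
    W = np.zeros((m, ncomp))
    q = np.zeros(ncomp)
    Xk = Xc.copy()
    x_scale = np.linalg.norm(Xc) * np.linalg.norm(yc)
    tol = max(x_scale, 1.0) * 1e-12
    for k in range(ncomp):
        w = Xk.T @ yc
        nw = np.linalg.norm(w)
        if nw <= tol:
            raise ComponentCollapseError(
                f"weight norm vanished at component {k + 1}; "
                f"achieved rank {k}",
                achieved_rank=k,
            )
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt <= tol**2 or tt <= _EPS * max(1.0, float(np.sum(Xc**2))):
            raise ComponentCollapseError(
                f"score norm vanished at component {k + 1}; achieved rank {k}",
                achieved_rank=k,
            )
        p = Xk.T @ t / tt
        q[k] = float(t @ yc) / tt
        Xk -= np.outer(t, p)
        T[:, k] = t
        P[:, k] = p
        W[:, k] = w
    return T, P, W, q


class PLS1:
    """Univariate-response PLS model of a formulation composition matrix.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response per formulation (e.g. its IC50).
    exog : DataFrame or array, shape (n, m)
        Composition matrix; columns are crude drugs, entries are dose
        weights per daily Unit.
    scale : bool
        Autoscale columns to unit variance after centring (off by default:
        the model equations centre only).
    drop_constant : bool
        Drop zero-variance columns with a warning; their coefficients are
        reported as NaN ("not estimable").
    """

    def __init__(
        self,
        endog,
        exog,
        scale: bool = False,
        drop_constant: bool = True,
    ):
        if isinstance(exog, pd.DataFrame):
            self.exog_names = [str(c) for c in exog.columns]
            self.row_ids = [str(i) for i in exog.index]
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim != 2:
                raise InvalidParameterError("exog must be 2-D")
            self.exog_names = [f"x{j}" for j in range(X.shape[1])]
            self.row_ids = [str(i) for i in range(X.shape[0])]
        y = np.asarray(endog, dtype=float).ravel()
        if np.isnan(X).any() or np.isnan(y).any():
            raise InvalidParameterError("missing entries are not allowed")
        if X.shape[0] != len(y):
            raise InvalidParameterError(
                f"exog has {X.shape[0]} rows but endog has {len(y)}"
            )
        if X.shape[0] < 3:
            raise InsufficientDataError("need at least 3 formulations")
        self._X_full = X
        self.endog = y
        self.scale = bool(scale)

        col_var = X.var(axis=0)
        self.constant_cols = [
            self.exog_names[j] for j in np.nonzero(col_var == 0.0)[0]
        ]
        if self.constant_cols and drop_constant:
            warnings.warn(
                f"dropping zero-variance column(s) {self.constant_cols}: "
                "coefficient not estimable",
                UserWarning,
                stacklevel=2,
            )
            keep = col_var > 0.0
        else:
            keep = np.ones(X.shape[1], dtype=bool)
        self._keep = keep
        self.exog = X[:, keep]
        self.active_names = [n for n, k in zip(self.exog_names, keep) if k]
        if self.exog.shape[1] == 0 or np.all(self.exog.var(axis=0) == 0.0):
            raise InvalidParameterError("all regressor columns are constant")

    @classmethod
    def from_dataframes(
        cls, composition: pd.DataFrame, response: Union[pd.Series, Sequence[float]], **kwargs
    ) -> "PLS1":
        """Build from a wide composition frame and an aligned response.

        When ``response`` is a Series it is aligned on the composition index.
        """
        if isinstance(response, pd.Series):
            response = response.reindex(composition.index)
            if response.isna().any():
                missing = list(response[response.isna()].index)
                raise InvalidParameterError(f"response missing for {missing}")
        return cls(np.asarray(response, dtype=float), composition, **kwargs)

    @property
    def max_ncomp(self) -> int:
        return min(self.exog.shape[0] - 1, self.exog.shape[1])

    def _centred(self, X: np.ndarray, y: np.ndarray):
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
        Xc = X - x_mean
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1.0
        else:
            sd = np.ones(X.shape[1])
        return Xc / sd, y - y_mean, x_mean, y_mean, sd

    def fit(self, ncomp: int, press_profile: Optional[PRESSProfile] = None) -> "PLS1Results":
        """Fit with a fixed number of latent components."""
        if ncomp < 1:
            raise InvalidParameterError("ncomp must be >= 1")
        if ncomp > self.max_ncomp:
            raise InvalidParameterError(
                f"ncomp={ncomp} exceeds min(n-1, m) = {self.max_ncomp}"
            )
        Xc, yc, x_mean, y_mean, sd = self._centred(self.exog, self.endog)
        if float(yc @ yc) == 0.0:
            # exactly constant response: the trivial model predicts ybar
            n, m = Xc.shape
            T = np.zeros((n, ncomp))
            P = np.zeros((m, ncomp))
            W = np.zeros((m, ncomp))
            q = np.zeros(ncomp)
            b_active = np.zeros(m)
        else:
            T, P, W, q = _nipals(Xc, yc, ncomp)
            b_active = W @ np.linalg.solve(P.T @ W, q)
        b_active = b_active / sd
        b0 = y_mean - float(x_mean @ b_active)
        coef = np.full(len(self.exog_names), np.nan)
        coef[self._keep] = b_active
        return PLS1Results(
            model=self,
            ncomp=ncomp,
            x_mean=x_mean,
            y_mean=y_mean,
            x_sd=sd,
            scores=T,
            x_loadings=P,
            weights=W,
            y_loadings=q,
            coef=coef,
            intercept=b0,
            press_profile=press_profile,
        )

    def loo_press(self, a_max: Optional[int] = None) -> PRESSProfile:
        """Leave-one-out PRESS over component counts 1..a_max.

        Each fold fits one NIPALS decomposition at ``a_max`` components on
        the n-1 retained rows; held-out predictions for every smaller A fall
        out of the same decomposition (the first A components of a NIPALS
        fit equal the A-component fit), so the profile costs n fits rather
        than n * a_max.
        """
        n, m = self.exog.shape
        cap = min(n - 2, m)
        if a_max is None:
            a_max = cap
        if a_max < 1 or a_max > cap:
            raise InvalidParameterError(
                f"a_max={a_max} infeasible: leave-one-out with n={n} rows "
                f"and m={m} columns supports 1..{cap}"
            )
        press = np.zeros(a_max)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            X_train, y_train = self.exog[mask], self.endog[mask]
            Xc, yc, x_mean, y_mean, sd = self._centred(X_train, y_train)
            x_new = (self.exog[i] - x_mean) / sd
            if float(yc @ yc) == 0.0:
                press += (self.endog[i] - y_mean) ** 2
                continue
            try:
                T, P, W, q = _nipals(Xc, yc, a_max)
                achieved = a_max
            except ComponentCollapseError as err:
                achieved = err.achieved_rank
                if achieved == 0:
                    press += (self.endog[i] - y_mean) ** 2
                    continue
                T, P, W, q = _nipals(Xc, yc, achieved)
            for a in range(1, a_max + 1):
                aa = min(a, achieved)
                b = W[:, :aa] @ np.linalg.solve(P[:, :aa].T @ W[:, :aa], q[:aa])
                y_hat = y_mean + float(x_new @ b)
                press[a - 1] += (self.endog[i] - y_hat) ** 2
        a_selected = int(np.argmin(press)) + 1  # argmin takes the first = smallest A
        return PRESSProfile(press=press, a_selected=a_selected, n_folds=n)

    def fit_press(self, a_max: Optional[int] = None) -> "PLS1Results":
        """Select the component count by leave-one-out PRESS, then fit."""
        profile = self.loo_press(a_max=a_max)
        return self.fit(profile.a_selected, press_profile=profile)


@dataclass
class PLS1Results:
    """Fitted PLS1 model: latent structure, coefficients and diagnostics."""

    model: PLS1
    ncomp: int
    x_mean: np.ndarray
    y_mean: float
    x_sd: np.ndarray
    scores: np.ndarray  # T, n x A
    x_loadings: np.ndarray  # P, m x A
    weights: np.ndarray  # W, m x A
    y_loadings: np.ndarray  # q, A
    coef: np.ndarray  # original-space b over all input columns (NaN = dropped)
    intercept: float  # b0
    press_profile: Optional[PRESSProfile] = None

    @property
    def params(self) -> pd.Series:
        """Original-space coefficients indexed by crude-drug name."""
        return pd.Series(self.coef, index=self.model.exog_names, name="coef")

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model._X_full)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rsquared(self) -> float:
        r2, _ = evaluate_fit(self.model.endog, self.fittedvalues)
        return r2

    def predict(self, X_new) -> np.ndarray:
        """Predict responses for new composition rows: y_hat = b0 + X b."""
        if isinstance(X_new, pd.DataFrame):
            missing = [c for c in self.model.exog_names if c not in X_new.columns]
            extra = [c for c in X_new.columns if c not in self.model.exog_names]
            if missing or extra:
                raise ColumnMismatchError(
                    f"composition columns do not match the model: "
                    f"missing {missing}, unexpected {extra}"
                )
            X_new = X_new[self.model.exog_names].to_numpy(dtype=float)
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != len(self.model.exog_names):
            raise ColumnMismatchError(
                f"expected {len(self.model.exog_names)} columns, got {X_new.shape[1]}"
            )
        b = np.where(np.isnan(self.coef), 0.0, self.coef)
        return self.intercept + X_new @ b

    def predict_from_scores(self) -> np.ndarray:
        """Training predictions via the latent route ybar + T q (diagnostic)."""
        return self.y_mean + self.scores @ self.y_loadings

    def ranking(self, response_is_ic50: bool = True) -> pd.DataFrame:
        """Rank crude drugs by their contribution to activity.

        With an IC50 response lower means more potent, so the most negative
        coefficient contributes most; for a potency-like response the
        largest positive coefficient ranks first.  Dropped (constant)
        columns sort last with NaN coefficients; exact ties keep input
        order and are flagged.
        """
        s = self.params
        order = s.sort_values(
            ascending=response_is_ic50, kind="stable", na_position="last"
        )
        tied = s.duplicated(keep=False) & s.notna()
        out = pd.DataFrame(
            {
                "crude_drug": order.index,
                "coef": order.to_numpy(),
                "rank": np.arange(1, len(order) + 1),
                "tied": tied.reindex(order.index).to_numpy(),
            }
        ).reset_index(drop=True)
        return out

    def summary(self) -> str:
        prof = self.press_profile
        rows = [
            "PLS1 regression results",
            f"  n formulations : {len(self.model.endog)}",
            f"  m crude drugs  : {len(self.model.exog_names)}"
            + (f" ({len(self.model.constant_cols)} constant, dropped)"
               if self.model.constant_cols else ""),
            f"  components (A) : {self.ncomp}"
            + (" [PRESS-selected]" if prof and prof.a_selected == self.ncomp else ""),
            f"  R^2            : {self.rsquared:.4f}",
            f"  intercept (b0) : {self.intercept:.4g}",
        ]
        if prof is not None:
            press_str = ", ".join(f"{v:.4g}" for v in prof.press)
            rows.append(f"  PRESS(1..{len(prof.press)}) : {press_str}")
        rows.append("  coefficients:")
        for name, c in self.params.items():
            rows.append(
                f"    {name:<28} {'not estimable' if np.isnan(c) else f'{c:+.4g}'}"
            )
        return "\n".join(rows)

    def to_dict(self) -> dict:
        d = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "ncomp": self.ncomp,
            "scores": self.scores.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "weights": self.weights.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": {n: (None if np.isnan(c) else c) for n, c in self.params.items()},
            "intercept": self.intercept,
            "rsquared": self.rsquared,
        }
        if self.press_profile is not None:
            d["press"] = self.press_profile.press.tolist()
            d["a_selected"] = self.press_profile.a_selected
        return d


def coefficient_ranking(
    coef: Union[pd.Series, PLS1Results], response_is_ic50: bool = True
) -> pd.DataFrame:
    """Rank crude drugs by contribution, from a results object or raw coefficients."""
    if isinstance(coef, PLS1Results):
        return coef.ranking(response_is_ic50=response_is_ic50)
    s = pd.Series(coef, dtype=float)
    order = s.sort_values(ascending=response_is_ic50, kind="stable", na_position="last")
    tied = s.duplicated(keep=False) & s.notna()
    return pd.DataFrame(
        {
            "crude_drug": order.index,
            "coef": order.to_numpy(),
            "rank": np.arange(1, len(order) + 1),
            "tied": tied.reindex(order.index).to_numpy(),
        }
    ).reset_index(drop=True)
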