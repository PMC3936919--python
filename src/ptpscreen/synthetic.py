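"""Synthetic assay and formulation-panel generators with known ground truth.

Every downstream stage (screening, IC50 regression, Lineweaver-Burk mode
calls, PLS attribution) is exercised against data simulated here, so
parameter recovery can be checked exactly.  The generators emulate:

* Michaelis-Menten initial velocities under the general linear-inhibition
  rate law (competitive / uncompetitive / noncompetitive / mixed),
* log-linear-ish dose-response curves via a Hill form (default slope 1) —
  deliberately not the straight line the IC50 estimator assumes, so the
  estimator's robustness to curvature is part of what tests measure,
* formulation panels in which a composition matrix (formulations x crude
  drugs, dose weights per daily Unit) and a sparse potency vector generate
  response IC50s through the reciprocal law
  IC50_j = ic50_scale / sum_m composition[j, m] * potency[m].

Noise is multiplicative Gaussian (a coefficient of variation on the relative
scale), because plate-assay error grows with signal; replicated draws under
one seed are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseCurve
from .exceptions import InvalidParameterError
from .kinetics import (
    MODE_COMPETITIVE,
    MODE_MIXED,
    MODE_NONCOMPETITIVE,
    MODE_UNCOMPETITIVE,
    KineticsGrid,
)

#: substrate levels (mM) and inhibitor doses used in the reference study design
DEFAULT_S_LEVELS = (2.0, 4.0, 8.0, 16.0)
DEFAULT_I_LEVELS = (0.0, 2.0, 5.0, 7.0)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise: x -> x * (1 + cv * N(0,1))."""

    cv: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.cv < 0:
            raise InvalidParameterError("cv must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: Optional[np.random.Generator] = None):
        values = np.asarray(values, dtype=float)
        if self.cv == 0.0:
            return values.copy()
        if rng is None:
            rng = self.rng()
        return values * (1.0 + self.cv * rng.standard_normal(values.shape))


NOISELESS = NoiseModel(0.0)


@dataclass(frozen=True)
class KineticParameters:
    """Rate-law constants for one enzyme/inhibitor pair.

    ``Ki`` binds the inhibitor to free enzyme, ``Ki_prime`` to the
    enzyme-substrate complex; an infinite constant switches that pathway
    off.  ``mode_label`` is derived from the constants and validated if
    supplied.
    """

    Vmax: float
    Km: float
    Ki: float = math.inf
    Ki_prime: float = math.inf
    mode_label: Optional[str] = None

    def __post_init__(self):
        if self.Vmax <= 0 or self.Km <= 0:
            raise InvalidParameterError("Vmax and Km must be positive")
        if self.Ki <= 0 or self.Ki_prime <= 0:
            raise InvalidParameterError("Ki and Ki_prime must be positive (or inf)")
        derived = self._derive_mode()
        if self.mode_label is None:
            object.__setattr__(self, "mode_label", derived)
        elif self.mode_label != derived:
            raise InvalidParameterError(
                f"mode_label {self.mode_label!r} inconsistent with constants "
                f"(Ki={self.Ki}, Ki_prime={self.Ki_prime} imply {derived!r})"
            )

    def _derive_mode(self) -> str:
        ki_fin = math.isfinite(self.Ki)
        kip_fin = math.isfinite(self.Ki_prime)
        if ki_fin and not kip_fin:
            return MODE_COMPETITIVE
        if kip_fin and not ki_fin:
            return MODE_UNCOMPETITIVE
        if not ki_fin and not kip_fin:
            return "none"
        return MODE_NONCOMPETITIVE if self.Ki == self.Ki_prime else MODE_MIXED

    @classmethod
    def competitive(cls, Vmax: float, Km: float, Ki: float) -> "KineticParameters":
        return cls(Vmax, Km, Ki=Ki)

    @classmethod
    def uncompetitive(cls, Vmax: float, Km: float, Ki_prime: float) -> "KineticParameters":
        return cls(Vmax, Km, Ki_prime=Ki_prime)

    @classmethod
    def noncompetitive(cls, Vmax: float, Km: float, Ki: float) -> "KineticParameters":
        return cls(Vmax, Km, Ki=Ki, Ki_prime=Ki)

    @classmethod
    def mixed(cls, Vmax: float, Km: float, Ki: float, Ki_prime: float) -> "KineticParameters":
        if Ki == Ki_prime:
            raise InvalidParameterError("mixed requires Ki != Ki_prime")
        return cls(Vmax, Km, Ki=Ki, Ki_prime=Ki_prime)


def simulate_velocity(params: KineticParameters, S, I=0.0) -> np.ndarray:
    """Noiseless initial velocity under the general linear-inhibition rate law.

    v = Vmax * S / (Km * (1 + I/Ki) + S * (1 + I/Ki_prime)); vectorised over
    S and I (broadcast).
    """
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S <= 0):
        raise InvalidParameterError("substrate concentration must be positive")
    if np.any(I < 0):
        raise InvalidParameterError("inhibitor dose must be non-negative")
    ki_term = I * 0.0 if math.isinf(params.Ki) else I / params.Ki
    kip_term = I * 0.0 if math.isinf(params.Ki_prime) else I / params.Ki_prime
    v = params.Vmax * S / (params.Km * (1.0 + ki_term) + S * (1.0 + kip_term))
    return v if v.ndim else float(v)


def simulate_kinetics_grid(
    params: KineticParameters,
    S_levels: Sequence[float] = DEFAULT_S_LEVELS,
    I_levels: Sequence[float] = DEFAULT_I_LEVELS,
    noise: NoiseModel = NOISELESS,
    rng: Optional[np.random.Generator] = None,
) -> KineticsGrid:
    """Factorial grid of velocities with multiplicative noise.

    At cv=0 the grid equals :func:`simulate_velocity` pointwise.
    """
    S = np.asarray(S_levels, dtype=float)
    I = np.asarray(I_levels, dtype=float)
    if S.size == 0 or I.size == 0:
        raise InvalidParameterError("substrate and inhibitor level lists must be non-empty")
    if len(S) < 3 or len(I) < 2:
        raise InvalidParameterError("need >= 3 substrate levels and >= 2 inhibitor levels")
    v = simulate_velocity(params, S[np.newaxis, :], I[:, np.newaxis])
    v = noise.apply(v, rng=rng)
    return KineticsGrid(S, I, v)


def simulate_dose_response(
    ic50: float,
    conc_levels: Sequence[float],
    hill_slope: float = 1.0,
    noise: NoiseModel = NOISELESS,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "",
    dose_scale: str = "uU",
) -> DoseResponseCurve:
    """Hill-form dose-response: inhibition(c) = 100 c^h / (c^h + ic50^h).

    Noise is applied multiplicatively to the inhibition rates, which are
    then truncated to [0, 100].
    """
    if ic50 <= 0:
        raise InvalidParameterError("ic50 must be positive")
    if hill_slope <= 0:
        raise InvalidParameterError("hill_slope must be positive")
    c = np.sort(np.asarray(conc_levels, dtype=float))
    if c.size == 0 or np.any(c <= 0):
        raise InvalidParameterError("concentrations must be positive and non-empty")
    ch = c**hill_slope
    rates = 100.0 * ch / (ch + ic50**hill_slope)
    rates = np.clip(noise.apply(rates, rng=rng), 0.0, 100.0)
    return DoseResponseCurve(c, rates, sample_id=sample_id, dose_scale=dose_scale)


def half_log_dilutions(center: float, n: int = 8) -> np.ndarray:
    """``n`` half-log10-spaced concentrations centred (geometrically) on ``center``."""
    exponents = (np.arange(n) - (n - 1) / 2.0) * 0.5
    return center * 10.0**exponents


@dataclass(frozen=True)
class FormulationGroundTruth:
    """Ground truth behind a synthetic formulation panel.

    ``composition`` holds dose weights per daily Unit (n formulations x m
    crude drugs); ``potency`` the true per-unit-weight inhibitory potency of
    each drug; ``ic50_scale`` links summed potency to the response through
    IC50_j = ic50_scale / (x_j . potency).
    """

    composition: np.ndarray
    potency: np.ndarray
    ic50_scale: float = 10.0
    formulation_ids: Optional[tuple] = None
    drug_names: Optional[tuple] = None

    def __post_init__(self):
        X = np.asarray(self.composition, dtype=float)
        p = np.asarray(self.potency, dtype=float)
        object.__setattr__(self, "composition", X)
        object.__setattr__(self, "potency", p)
        if X.ndim != 2 or p.ndim != 1 or X.shape[1] != len(p):
            raise InvalidParameterError("composition must be n x m with potency length m")
        if np.any(X < 0) or np.any(p < 0):
            raise InvalidParameterError("weights and potencies must be non-negative")
        if self.ic50_scale <= 0:
            raise InvalidParameterError("ic50_scale must be positive")
        if np.any(X.sum(axis=1) == 0.0):
            raise InvalidParameterError("every formulation needs a nonzero ingredient")
        if self.formulation_ids is None:
            object.__setattr__(
                self,
                "formulation_ids",
                tuple(f"formulation_{i + 1:03d}" for i in range(X.shape[0])),
            )
        if self.drug_names is None:
            object.__setattr__(
                self,
                "drug_names",
                tuple(f"drug_{j + 1:02d}" for j in range(X.shape[1])),
            )

    @property
    def noiseless_ic50(self) -> np.ndarray:
        total = self.composition @ self.potency
        if np.any(total <= 0.0):
            raise InvalidParameterError(
                "a formulation has zero total potency; its IC50 is undefined"
            )
        return self.ic50_scale / total

    def composition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.composition,
            index=list(self.formulation_ids),
            columns=list(self.drug_names),
        )


def simulate_formulation_panel(
    truth: FormulationGroundTruth,
    noise: NoiseModel = NOISELESS,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Composition matrix and (noisy) response IC50s for a formulation panel."""
    y = noise.apply(truth.noiseless_ic50, rng=rng)
    X = truth.composition_frame()
    return X, pd.Series(y, index=X.index, name="ic50")


def random_formulation_truth(
    n_formulations: int = 40,
    n_drugs: int = 11,
    dominant_drug: int = 0,
    dominant_potency: float = 1.0,
    background_potency: float = 0.05,
    ingredients_per_formulation: tuple = (3, 6),
    weight_range: tuple = (0.5, 3.0),
    ic50_scale: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> FormulationGroundTruth:
    """Random sparse panel with one dominant-potency crude drug.

    Each formulation draws 3-6 of the m crude drugs (uniformly, always at
    least one) with dose weights uniform on ``weight_range`` grams per daily
    Unit; the dominant drug appears in roughly half the formulations so the
    panel contains both active and weak recipes, mimicking a screening
    collection where a single ingredient carries most of the activity.
    """
    if rng is None:
        rng = np.random.default_rng()
    potency = np.full(n_drugs, background_potency, dtype=float)
    potency[dominant_drug] = dominant_potency
    lo, hi = ingredients_per_formulation
    X = np.zeros((n_formulations, n_drugs))
    for i in range(n_formulations):
        k = int(rng.integers(lo, hi + 1))
        drugs = rng.choice(n_drugs, size=min(k, n_drugs), replace=False)
        X[i, drugs] = rng.uniform(*weight_range, size=len(drugs))
    # guarantee the dominant drug is present in about half the panel
    present = X[:, dominant_drug] > 0
    target = n_formulations // 2
    idx = np.arange(n_formulations)
    if present.sum() < target:
        add = rng.choice(idx[~present], size=target - int(present.sum()), replace=False)
        X[add, dominant_drug] = rng.uniform(*weight_range, size=len(add))
    elif present.sum() > target:
        drop = rng.choice(idx[present], size=int(present.sum()) - target, replace=False)
        X[drop, dominant_drug] = 0.0
        empty = X.sum(axis=1) == 0.0
        for i in idx[empty]:
            j = int(rng.integers(0, n_drugs))
            X[i, j] = rng.uniform(*weight_range)
    return FormulationGroundTruth(X, potency, ic50_scale=ic50_scale)


def screen_rates(
    n_samples: int = 147,
    n_hits: int = 22,
    hit_range: tuple = (90.0, 100.0),
    miss_range: tuple = (-5.0, 85.0),
    rng: Optional[np.random.Generator] = None,
) -> pd.Series:
    """True inhibition rates for a synthetic screening panel.

    ``n_hits`` samples draw rates from ``hit_range`` (complete inhibition),
    the rest from ``miss_range``; order is shuffled.  Rates feed
    :func:`ptpscreen.assay.triple_from_rate` to build absorbance fixtures.
    """
    if n_hits > n_samples:
        raise InvalidParameterError("n_hits cannot exceed n_samples")
    if rng is None:
        rng = np.random.default_rng()
    rates = np.concatenate(
        [
            rng.uniform(*hit_range, size=n_hits),
            rng.uniform(*miss_range, size=n_samples - n_hits),
        ]
    )
    rng.shuffle(rates)
    return pd.Series(rates, index=[f"sample_{i + 1:03d}" for i in range(n_samples)])
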