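import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptpscreen.exceptions import InvalidParameterError
from ptpscreen.synthetic import (
    FormulationGroundTruth,
    KineticParameters,
    NoiseModel,
    half_log_dilutions,
    random_formulation_truth,
    screen_rates,
    simulate_dose_response,
    simulate_formulation_panel,
    simulate_kinetics_grid,
    simulate_velocity,
)

pos = st.floats(min_value=0.1, max_value=50.0)


class TestRateLaw:
    def test_half_saturation_gives_half_vmax(self):
        assert simulate_velocity(KineticParameters(1.0, 4.0), S=4.0) == pytest.approx(0.5)

    def test_hand_evaluated_competitive_point(self):
        # v = 1*4 / (4*(1+2/2) + 4) = 4/12
        v = simulate_velocity(KineticParameters.competitive(1, 4, Ki=2), S=4.0, I=2.0)
        assert v == pytest.approx(1.0 / 3.0)

    def test_velocity_vanishes_at_saturating_inhibitor(self):
        p = KineticParameters.competitive(1, 4, Ki=2)
        assert simulate_velocity(p, S=4.0, I=1e12) < 1e-9

    @given(S=pos, I=pos, Km=pos, Ki=pos)
    def test_reduces_to_michaelis_menten_at_zero_inhibitor(self, S, I, Km, Ki):
        for p in (
            KineticParameters.competitive(1.0, Km, Ki=Ki),
            KineticParameters.uncompetitive(1.0, Km, Ki_prime=Ki),
            KineticParameters.noncompetitive(1.0, Km, Ki=Ki),
        ):
            assert simulate_velocity(p, S, 0.0) == pytest.approx(S / (Km + S))

    @given(S=pos, Km=pos, Ki=pos, I1=pos, I2=pos)
    def test_strictly_decreasing_in_inhibitor(self, S, Km, Ki, I1, I2):
        p = KineticParameters.noncompetitive(1.0, Km, Ki=Ki)
        lo, hi = sorted([I1, I2])
        if hi > lo:
            assert simulate_velocity(p, S, hi) < simulate_velocity(p, S, lo)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            KineticParameters(-1.0, 4.0)
        with pytest.raises(InvalidParameterError):
            KineticParameters(1.0, 4.0, Ki=-2.0)
        with pytest.raises(InvalidParameterError):
            simulate_velocity(KineticParameters(1, 4), S=0.0)

    def test_mode_label_derived_and_validated(self):
        assert KineticParameters(1, 4, Ki=2).mode_label == "competitive"
        assert KineticParameters(1, 4, Ki=2, Ki_prime=2).mode_label == "noncompetitive"
        assert KineticParameters(1, 4, Ki=2, Ki_prime=3).mode_label == "mixed"
        with pytest.raises(InvalidParameterError):
            KineticParameters(1, 4, Ki=2, Ki_prime=3, mode_label="competitive")


class TestKineticsGridGenerator:
    def test_noiseless_grid_equals_rate_law_pointwise(self):
        p = KineticParameters.mixed(1.0, 4.0, Ki=2.0, Ki_prime=6.0)
        grid = simulate_kinetics_grid(p)
        assert grid.v.shape == (4, 4)
        for i, I in enumerate(grid.I_levels):
            for j, S in enumerate(grid.S_levels):
                assert grid.v[i, j] == pytest.approx(simulate_velocity(p, S, I))

    def test_same_seed_reproduces_bitwise(self):
        p = KineticParameters.competitive(1, 4, Ki=2)
        g1 = simulate_kinetics_grid(p, noise=NoiseModel(cv=0.05, seed=7))
        g2 = simulate_kinetics_grid(p, noise=NoiseModel(cv=0.05, seed=7))
        assert np.array_equal(g1.v, g2.v)

    def test_noise_cv_calibrated(self, rng):
        """Per-cell sample CV of 1000 replicate grids matches the nominal cv."""
        p = KineticParameters(1.0, 4.0)
        noise = NoiseModel(cv=0.03)
        reps = np.stack(
            [simulate_kinetics_grid(p, noise=noise, rng=rng).v for _ in range(1000)]
        )
        cvs = reps.std(axis=0, ddof=1) / reps.mean(axis=0)
        assert np.all(np.abs(cvs - 0.03) < 0.005)

    def test_empty_levels_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_kinetics_grid(KineticParameters(1, 4), S_levels=(), I_levels=(0, 2))

    def test_competitive_apparent_vmax_constant(self):
        grid = simulate_kinetics_grid(KineticParameters.competitive(1.0, 4.0, Ki=2.0))
        # apparent Vmax from each noiseless row via the reciprocal intercept
        from ptpscreen.kinetics import fit_lb_lines

        vmaxes = [ln.Vmax_app for ln in fit_lb_lines(grid)]
        assert np.ptp(vmaxes) < 1e-9

    def test_uncompetitive_km_over_vmax_constant(self):
        grid = simulate_kinetics_grid(
            KineticParameters.uncompetitive(1.0, 4.0, Ki_prime=2.0)
        )
        from ptpscreen.kinetics import fit_lb_lines

        ratios = [ln.Km_app / ln.Vmax_app for ln in fit_lb_lines(grid)]
        assert np.ptp(ratios) < 1e-9


class TestDoseResponseGenerator:
    def test_midpoint_is_50pct(self):
        curve = simulate_dose_response(4.3, [1.0, 4.3, 20.0])
        assert curve.rates[list(curve.concs).index(4.3)] == pytest.approx(50.0)

    def test_hand_evaluated_hill_point(self):
        # h=1, c = 9*ic50 -> 100*9/(9+1) = 90%
        curve = simulate_dose_response(1.0, [0.5, 1.0, 9.0])
        assert curve.rates[-1] == pytest.approx(90.0)

    def test_low_doses_near_zero_and_monotone(self):
        curve = simulate_dose_response(100.0, [0.001, 0.01, 0.1])
        assert np.all(curve.rates < 0.2)
        assert np.all(np.diff(curve.rates) >= 0)

    def test_noise_truncated_to_0_100(self, rng):
        curve = simulate_dose_response(
            1.0,
            half_log_dilutions(1.0, 8),
            noise=NoiseModel(cv=0.5),
            rng=rng,
        )
        assert np.all(curve.rates >= 0.0) and np.all(curve.rates <= 100.0)

    def test_invalid_ic50_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_dose_response(0.0, [1, 2, 3])

    def test_half_log_dilutions_spacing(self):
        d = half_log_dilutions(4.3, 8)
        assert len(d) == 8
        np.testing.assert_allclose(np.diff(np.log10(d)), 0.5, atol=1e-12)
        assert np.isclose(np.sqrt(d[3] * d[4]), 4.3)


class TestFormulationPanel:
    def test_single_drug_identity(self):
        truth = FormulationGroundTruth(
            np.array([[1.0], [1.0], [1.0]]), np.array([1.0]), ic50_scale=4.1
        )
        _, y = simulate_formulation_panel(truth)
        np.testing.assert_allclose(y, 4.1)

    def test_doubling_active_weight_halves_ic50(self):
        truth = FormulationGroundTruth(
            np.array([[1.0, 0.5], [2.0, 0.5], [1.0, 1.0]]),
            np.array([1.0, 0.0]),
            ic50_scale=4.0,
        )
        y = truth.noiseless_ic50
        assert y[1] == pytest.approx(y[0] / 2.0)

    def test_reciprocal_identity_exact(self, rng):
        truth = random_formulation_truth(rng=rng)
        y = truth.noiseless_ic50
        total = truth.composition @ truth.potency
        np.testing.assert_allclose(y * total, truth.ic50_scale, rtol=1e-12)

    def test_strongest_formulation_has_smallest_ic50(self, rng):
        truth = random_formulation_truth(rng=rng)
        _, y = simulate_formulation_panel(truth)
        total = truth.composition @ truth.potency
        assert np.argmax(total) == np.argmin(y.to_numpy())

    def test_dominant_drug_column_anticorrelated_with_ic50(self, rng):
        truth = random_formulation_truth(rng=rng)
        X, y = simulate_formulation_panel(truth, noise=NoiseModel(cv=0.05), rng=rng)
        r = np.corrcoef(X.iloc[:, 0], y)[0, 1]
        assert r < 0

    def test_zero_total_potency_rejected(self):
        truth = FormulationGroundTruth(
            np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]), np.array([1.0, 0.0])
        )
        with pytest.raises(InvalidParameterError):
            simulate_formulation_panel(truth)

    def test_empty_formulation_rejected(self):
        with pytest.raises(InvalidParameterError):
            FormulationGroundTruth(np.array([[1.0], [0.0], [1.0]]), np.array([1.0]))

    def test_panel_reproducible_under_seed(self):
        t1 = random_formulation_truth(rng=np.random.default_rng(5))
        t2 = random_formulation_truth(rng=np.random.default_rng(5))
        assert np.array_equal(t1.composition, t2.composition)


def test_screen_rates_hit_partition(rng):
    rates = screen_rates(147, 22, rng=rng)
    assert len(rates) == 147
    assert int((rates >= 90.0).sum()) == 22
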