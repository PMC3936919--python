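import numpy as np
import pandas as pd
import pytest

from ptpscreen.exceptions import (
    ColumnMismatchError,
    InsufficientDataError,
    InvalidParameterError,
)
from ptpscreen.pls import PLS1, coefficient_ranking, evaluate_fit
from ptpscreen.synthetic import (
    NoiseModel,
    random_formulation_truth,
    simulate_formulation_panel,
)

# the five-formulation worked example: measured and model-predicted IC50s
EXPERIMENTAL = np.array([4.1, 4.3, 4.9, 6.3, 6.6])
PREDICTED = np.array([4.4, 3.9, 5.1, 6.3, 6.4])


def random_problem(rng, n=30, m=5, noise=0.1):
    X = rng.normal(size=(n, m))
    beta = rng.normal(size=m)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


def ols_oracle(X, y):
    """Normal-equations least squares with intercept, independent of NIPALS."""
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


class TestNipalsFit:
    def test_single_regressor_equals_simple_regression(self, rng):
        x = rng.uniform(0, 10, size=12)
        y = 3.0 - 0.7 * x + rng.normal(size=12)
        res = PLS1(y, x[:, None]).fit(1)
        b0, b1 = ols_oracle(x[:, None], y)
        assert res.coef[0] == pytest.approx(b1, abs=1e-12)
        assert res.intercept == pytest.approx(b0, abs=1e-12)

    def test_full_rank_fit_matches_ols(self, rng):
        """At A = rank(X) the PLS solution coincides with least squares."""
        X, y = random_problem(rng)
        res = PLS1(y, X).fit(5)
        expected = ols_oracle(X, y)
        assert res.intercept == pytest.approx(expected[0], abs=1e-8)
        np.testing.assert_allclose(res.coef, expected[1:], atol=1e-8)

    def test_constant_response_gives_zero_model(self):
        X = np.arange(12.0).reshape(4, 3)
        y = np.full(4, 7.7)
        res = PLS1(y, X).fit(2)
        assert np.allclose(res.y_loadings, 0.0)
        assert np.allclose(res.coef, 0.0)
        assert res.intercept == pytest.approx(7.7)
        np.testing.assert_allclose(res.predict(X), 7.7)

    def test_score_orthogonality(self, rng):
        """T columns mutually orthogonal on random problems."""
        for _ in range(100):
            n = int(rng.integers(6, 25))
            m = int(rng.integers(2, 10))
            X = rng.normal(size=(n, m))
            y = rng.normal(size=n)
            A = min(n - 1, m)
            T = PLS1(y, X).fit(A).scores
            G = T.T @ T
            off = G - np.diag(np.diag(G))
            scale = max(np.abs(np.diag(G)).max(), 1.0)
            assert np.abs(off).max() < 1e-8 * scale

    def test_deflation_residual_norm_non_increasing(self, rng):
        X, y = random_problem(rng, n=20, m=6)
        model = PLS1(y, X)
        norms = []
        for A in range(1, 7):
            res = model.fit(A)
            Xc = X - X.mean(axis=0)
            E = Xc - res.scores @ res.x_loadings.T
            norms.append(np.linalg.norm(E))
        assert all(b <= a + 1e-10 for a, b in zip(norms, norms[1:]))

    def test_two_prediction_routes_agree_on_training_data(self, rng):
        X, y = random_problem(rng, n=15, m=4)
        res = PLS1(y, X).fit(3)
        np.testing.assert_allclose(
            res.fittedvalues, res.predict_from_scores(), atol=1e-10
        )

    def test_prediction_equivariance_under_response_shift_and_scale(self, rng):
        X, y = random_problem(rng, n=15, m=4)
        base = PLS1(y, X).fit(2)
        shifted = PLS1(y + 11.0, X).fit(2)
        np.testing.assert_allclose(shifted.coef, base.coef, atol=1e-10)
        assert shifted.intercept == pytest.approx(base.intercept + 11.0, abs=1e-10)
        scaled = PLS1(3.0 * y, X).fit(2)
        np.testing.assert_allclose(scaled.coef, 3.0 * base.coef, atol=1e-10)
        assert scaled.intercept == pytest.approx(3.0 * base.intercept, abs=1e-10)

    def test_noiseless_linear_truth_interpolated_exactly(self, rng):
        X, y = random_problem(rng, n=25, m=4, noise=0.0)
        res = PLS1(y, X).fit(4)
        np.testing.assert_allclose(res.predict(X), y, atol=1e-8)

    def test_mean_row_predicts_mean_response(self, rng):
        X, y = random_problem(rng, n=15, m=4)
        res = PLS1(y, X).fit(2)
        assert res.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-10
        )

    def test_ncomp_bounds_enforced(self, rng):
        X, y = random_problem(rng, n=6, m=8)
        model = PLS1(y, X)
        with pytest.raises(InvalidParameterError):
            model.fit(6)  # > n-1
        with pytest.raises(InvalidParameterError):
            model.fit(0)

    def test_all_constant_exog_rejected(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            with pytest.raises(InvalidParameterError):
                PLS1([1.0, 2.0, 3.0], np.ones((3, 2)))

    def test_constant_columns_dropped_with_warning(self, rng):
        X, y = random_problem(rng, n=10, m=3)
        Xdf = pd.DataFrame(X, columns=["a", "b", "c"])
        Xdf["const"] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = PLS1.from_dataframes(Xdf, pd.Series(y, index=Xdf.index))
        res = model.fit(3)
        assert np.isnan(res.params["const"])
        assert model.constant_cols == ["const"]
        # dropped column sorts last in the ranking and keeps its NaN coefficient
        assert res.ranking()["crude_drug"].iloc[-1] == "const"

    def test_column_mismatch_named_in_error(self, rng):
        X, y = random_problem(rng, n=10, m=3)
        Xdf = pd.DataFrame(X, columns=["a", "b", "c"])
        res = PLS1.from_dataframes(Xdf, pd.Series(y, index=Xdf.index)).fit(2)
        with pytest.raises(ColumnMismatchError, match="missing"):
            res.predict(Xdf.rename(columns={"c": "zzz"}))


class TestAgainstEstablishedImplementation:
    def test_predictions_match_sklearn(self, rng):
        """Independent cross-check: sklearn's PLSRegression on random problems."""
        from sklearn.cross_decomposition import PLSRegression

        for _ in range(10):
            n = int(rng.integers(8, 30))
            m = int(rng.integers(2, 8))
            A = int(rng.integers(1, min(n - 1, m) + 1))
            X = rng.normal(size=(n, m))
            y = rng.normal(size=n)
            ours = PLS1(y, X).fit(A)
            ref = PLSRegression(n_components=A, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.predict(X), ref.predict(X).ravel(), atol=1e-6
            )


class TestLooPress:
    @staticmethod
    def brute_force_press(X, y, a_max):
        """Literal oracle: refit one model per (A, held-out sample)."""
        n = len(y)
        press = np.zeros(a_max)
        for a in range(1, a_max + 1):
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                res = PLS1(y[mask], X[mask]).fit(a)
                press[a - 1] += (y[i] - res.predict(X[i][None, :])[0]) ** 2
        return press

    def test_matches_brute_force_refits(self, rng):
        X, y = random_problem(rng, n=10, m=4)
        profile = PLS1(y, X).loo_press(a_max=4)
        expected = self.brute_force_press(X, y, 4)
        np.testing.assert_allclose(profile.press, expected, atol=1e-10)

    def test_minimal_problem_bookkeeping(self, rng):
        X, y = random_problem(rng, n=3, m=2)
        profile = PLS1(y, X).loo_press(a_max=1)
        assert profile.n_folds == 3
        assert profile.press.shape == (1,)
        assert profile.press[0] >= 0.0

    def test_exact_linear_single_driver_selects_one_component(self, rng):
        """y exactly linear in the sole varying regressor: PRESS(1) ~ 0.

        With additional varying-but-inactive columns a one-component fit is
        not exact (leave-one-out re-centring mixes the columns into the
        first weight vector), so the single-active-column construction is
        the one where the zero-PRESS property genuinely holds.
        """
        x = rng.uniform(0, 1, size=12)
        y = 2.0 + 5.0 * x
        profile = PLS1(y, x[:, None]).loo_press(a_max=1)
        assert profile.a_selected == 1
        assert profile.press[0] == pytest.approx(0.0, abs=1e-16)

    def test_selected_a_attains_the_minimum_preferring_smaller(self, rng):
        X, y = random_problem(rng, n=12, m=5)
        profile = PLS1(y, X).loo_press(a_max=4)
        mins = np.flatnonzero(profile.press == profile.press.min())
        assert profile.a_selected == mins[0] + 1

    def test_a_max_validation(self, rng):
        X, y = random_problem(rng, n=5, m=6)
        with pytest.raises(InvalidParameterError):
            PLS1(y, X).loo_press(a_max=4)  # > n-2


class TestEvaluateFit:
    def test_worked_example_residuals(self):
        r2, resid = evaluate_fit(EXPERIMENTAL, PREDICTED)
        np.testing.assert_allclose(resid, [-0.3, 0.4, -0.2, 0.0, 0.2], atol=1e-12)

    def test_worked_example_r_squared(self):
        r2, _ = evaluate_fit(EXPERIMENTAL, PREDICTED)
        assert r2 == pytest.approx(1.0 - 0.33 / 5.272, abs=1e-12)
        assert r2 == pytest.approx(0.937, abs=5e-4)

    def test_perfect_fit(self):
        r2, resid = evaluate_fit(EXPERIMENTAL, EXPERIMENTAL)
        assert r2 == 1.0
        assert np.all(resid == 0.0)

    def test_constant_y_undefined_but_residuals_returned(self):
        with pytest.raises(InvalidParameterError) as exc_info:
            evaluate_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(exc_info.value.residuals, [1.0, 0.0, -1.0])


class TestCoefficientRanking:
    # regression coefficients of the 11 crude drugs in the worked example
    TABLE3 = pd.Series(
        {
            "Rhei Rhizoma": -0.017,
            "Cannabisi Fructus": -0.010,
            "Armeniacae Semen": -0.005,
            "Paeoniae Radix": -0.005,
            "Cinnamomi Cortex": -0.004,
            "Aurantii Fructus Immaturus": -0.004,
            "Magnoliae Cortex": -0.004,
            "Persicae Semen": -0.003,
            "Zingiberis Rhizoma": -0.001,
            "Zizyphi Fructus": -0.001,
            "Ephedrae Herba": -0.001,
        }
    )

    def test_published_coefficients_rank_rhei_rhizoma_first(self):
        ranked = coefficient_ranking(self.TABLE3, response_is_ic50=True)
        assert ranked["crude_drug"].iloc[0] == "Rhei Rhizoma"
        assert ranked["crude_drug"].iloc[1] == "Cannabisi Fructus"
        assert ranked["coef"].iloc[0] == -0.017

    def test_potency_response_ranks_largest_positive_first(self):
        s = pd.Series({"a": 0.5, "b": 2.0, "c": -1.0})
        ranked = coefficient_ranking(s, response_is_ic50=False)
        assert ranked["crude_drug"].tolist() == ["b", "a", "c"]

    def test_all_equal_coefficients_keep_input_order_and_flag_ties(self):
        s = pd.Series({"x": -0.2, "y": -0.2, "z": -0.2})
        ranked = coefficient_ranking(s)
        assert ranked["crude_drug"].tolist() == ["x", "y", "z"]
        assert ranked["tied"].all()

    def test_dominant_driver_recovered_in_noisy_panels(self, rng):
        """The truly potent crude drug tops the ranking in most replicates."""
        noise = NoiseModel(cv=0.05)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            truth = random_formulation_truth(rng=rng)
            X, y = simulate_formulation_panel(truth, noise=noise, rng=rng)
            res = PLS1.from_dataframes(X, y).fit_press(a_max=5)
            ranked = res.ranking(response_is_ic50=True)
            hits += ranked["crude_drug"].iloc[0] == truth.drug_names[0]
        assert hits >= 18


def test_summary_mentions_selected_components(rng):
    X = rng.normal(size=(12, 4))
    y = X @ np.array([1.0, 0.0, 0.0, 0.0]) + 0.05 * rng.normal(size=12)
    res = PLS1(y, X).fit_press(a_max=3)
    text = res.summary()
    assert "PRESS" in text
    assert f"components (A) : {res.ncomp}" in text
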