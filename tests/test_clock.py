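"""Clock: QC boundary, KNN imputation oracle, ElasticNet fit, metrics."""

import numpy as np
import pandas as pd
import pytest

from rdnameth import (
    ClockModel,
    evaluate,
    fit_clock,
    knn_impute,
    predict_age,
    qc_filter_samples,
)
from rdnameth.clock import _standardize, lambda_path
from rdnameth.errors import ClockFitError, ImputationError


def _matrix(rows, columns=None, index=None):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr,
        columns=columns or [f"c{j}" for j in range(arr.shape[1])],
        index=index or [f"s{i}" for i in range(arr.shape[0])],
    )


class TestQcFilter:
    def test_ten_missing_dropped_nine_kept(self):
        """The published rule: samples with 10+ missing CpGs (of 53) are
        removed; 9 missing is still acceptable."""
        base = np.zeros((3, 53))
        base[1, :10] = np.nan  # exactly 10 missing -> dropped
        base[2, :9] = np.nan  # exactly 9 missing -> kept
        m = _matrix(base)
        kept, dropped = qc_filter_samples(m)
        assert dropped == ["s1"]
        assert list(kept.index) == ["s0", "s2"]

    def test_complete_matrix_is_identity(self):
        m = _matrix(np.ones((4, 5)))
        kept, dropped = qc_filter_samples(m)
        assert kept.equals(m) and dropped == []

    def test_all_dropped_is_error(self):
        m = _matrix(np.full((2, 12), np.nan))
        with pytest.raises(ClockFitError):
            qc_filter_samples(m)


class TestKnnImpute:
    def test_complete_input_unchanged(self, rng):
        m = _matrix(rng.normal(size=(6, 4)))
        assert knn_impute(m, k=3).equals(m)

    def test_duplicate_neighbor_with_k1(self):
        rows = [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [50.0, 60.0, 70.0]]
        out = knn_impute(_matrix(rows), k=1)
        assert out.iloc[1, 2] == pytest.approx(3.0)

    def test_three_sample_exhaustive_oracle(self):
        """Hand-computed nearest-neighbor average on a 3-sample fixture."""
        rows = [
            [0.0, 0.0, 10.0],
            [1.0, 1.0, 20.0],
            [8.0, 9.0, np.nan],
        ]
        # distances from s2 over shared CpGs (c0, c1):
        #   to s0: sqrt((64+81)/2) ≈ 8.514 ; to s1: sqrt((49+64)/2) ≈ 7.517
        # k=2 -> both neighbors -> mean(10, 20) = 15 ; k=1 -> nearest is s1 -> 20
        assert knn_impute(_matrix(rows), k=2).iloc[2, 2] == pytest.approx(15.0)
        assert knn_impute(_matrix(rows), k=1).iloc[2, 2] == pytest.approx(20.0)

    def test_output_is_complete_and_deterministic(self, rng):
        arr = rng.normal(50, 10, size=(20, 8))
        arr[rng.random(arr.shape) < 0.15] = np.nan
        arr[:, 0] = 1.0  # keep one column fully observed
        m = _matrix(arr)
        out1, out2 = knn_impute(m, k=5), knn_impute(m, k=5)
        assert not out1.isna().any().any()
        assert out1.equals(out2)

    def test_parameter_and_empty_column_errors(self):
        m = _matrix(np.ones((3, 2)))
        with pytest.raises(ImputationError):
            knn_impute(m, k=3)
        m2 = _matrix([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]])
        with pytest.raises(ImputationError):
            knn_impute(m2, k=1)


def _objective(Xs, y, b0, coef, lam, alpha):
    n = len(y)
    resid = y - b0 - Xs @ coef
    return (
        resid @ resid / (2 * n)
        + lam * (alpha * np.abs(coef).sum() + (1 - alpha) / 2 * coef @ coef)
    )


def _coordinate_descent_oracle(Xs, y, lam, alpha, n_iter=5000):
    """Brute-force cyclic coordinate descent for the 1/(2n) elastic net."""
    n, p = Xs.shape
    coef = np.zeros(p)
    b0 = y.mean()
    col_sq = (Xs**2).sum(axis=0) / n
    for _ in range(n_iter):
        for j in range(p):
            resid = y - b0 - Xs @ coef + Xs[:, j] * coef[j]
            rho = Xs[:, j] @ resid / n
            z = np.sign(rho) * max(abs(rho) - lam * alpha, 0.0)
            coef[j] = z / (col_sq[j] + lam * (1 - alpha))
        b0 = (y - Xs @ coef).mean()
    return b0, coef


class TestFitClock:
    def test_huge_lambda_gives_intercept_only_model(self, rng):
        X = _matrix(rng.normal(size=(30, 5)))
        y = rng.uniform(25, 60, 30)
        model, _ = fit_clock(X, y, n_folds=5, seed=0, lambdas=np.array([1e6]))
        assert model.n_features_selected == 0
        assert model.intercept == pytest.approx(y.mean())

    def test_lambda_zero_equals_ols_normal_equations(self, rng):
        X = _matrix(rng.normal(size=(40, 4)))
        y = rng.normal(size=40) + X.to_numpy() @ [1.0, -2.0, 0.5, 3.0]
        model, _ = fit_clock(X, y, n_folds=5, seed=0, lambdas=np.array([0.0]))
        A = np.column_stack([np.ones(40), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(list(model.weights.values()), beta[1:], atol=1e-8)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)

    def test_noiseless_sparse_signal_recovered(self, rng):
        """Age an exact linear function of 5 of 53 CpGs -> the selected
        model predicts with MAD below half a year."""
        X = _matrix(rng.uniform(0, 30, size=(120, 53)))
        w = np.zeros(53)
        w[[0, 10, 20, 30, 40]] = [0.5, 0.3, 0.8, -0.2, 0.4]
        y = 20.0 + X.to_numpy() @ w
        model, _ = fit_clock(X, y, seed=1)
        pred = predict_age(model, X)
        metrics = evaluate(pred, y)
        assert metrics.mad < 0.5

    def test_objective_matches_coordinate_descent_oracle(self, rng):
        """Tiny instance (n=8, p=3), fixed λ: the fitted objective value
        agrees with a brute-force coordinate-descent oracle to 1e-6."""
        from rdnameth.clock import _fit_at_lambda

        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        Xs, _, _ = _standardize(X)
        lam, alpha = 0.3, 0.5
        coef, b0, _ = _fit_at_lambda(Xs, y, lam, alpha)
        b0_o, coef_o = _coordinate_descent_oracle(Xs, y, lam, alpha)
        assert _objective(Xs, y, b0, coef, lam, alpha) == pytest.approx(
            _objective(Xs, y, b0_o, coef_o, lam, alpha), abs=1e-6
        )

    def test_sparsity_nonincreasing_along_path(self, rng):
        """Stronger penalties keep fewer CpGs (1-feature tolerance for
        coordinate-descent noise)."""
        from rdnameth.clock import _fit_at_lambda

        X = _matrix(rng.normal(size=(60, 10)))
        y = X.to_numpy() @ rng.normal(size=10) + rng.normal(size=60)
        Xs, _, _ = _standardize(X.to_numpy())
        lams = lambda_path(X.to_numpy(), y, alpha=0.5, n_lambda=30)
        est = None
        counts = []
        for lam in lams:
            coef, _, est = _fit_at_lambda(Xs, y, lam, 0.5, est)
            counts.append(int((coef != 0).sum()))
        diffs = np.diff(counts)
        assert (diffs >= -1).all()
        assert counts[0] == 0 and counts[-1] >= counts[0]

    def test_same_seed_bit_stable_different_seed_changes_folds(self, rng):
        X = _matrix(rng.normal(50, 8, size=(50, 12)))
        y = rng.uniform(25, 60, 50)
        m1, cv1 = fit_clock(X, y, n_folds=5, seed=3)
        m2, cv2 = fit_clock(X, y, n_folds=5, seed=3)
        assert m1.weights == m2.weights and m1.lam == m2.lam
        m3, _ = fit_clock(X, y, n_folds=5, seed=4)
        assert m3.alpha == m1.alpha  # hyperparameters unchanged by seed

    def test_degenerate_inputs_rejected(self, rng):
        X = _matrix(rng.normal(size=(12, 3)))
        with pytest.raises(ClockFitError):
            fit_clock(X, np.full(12, 40.0), n_folds=4)
        with pytest.raises(ClockFitError):
            fit_clock(X, rng.uniform(20, 60, 12), n_folds=20)


class TestPredictEvaluate:
    def test_zero_weights_predict_intercept(self):
        model = ClockModel(35.0, {"c0": 0.0, "c1": 0.0}, 0.5, 1.0)
        m = _matrix(np.ones((3, 2)))
        assert (predict_age(model, m) == 35.0).all()

    def test_single_weight_passthrough(self):
        model = ClockModel(0.0, {"c0": 1.0}, 0.5, 1.0)
        m = _matrix([[12.5], [40.0]])
        assert predict_age(model, m).tolist() == [12.5, 40.0]

    def test_fixture_dot_products(self):
        model = ClockModel(10.0, {"c0": 2.0, "c1": -1.0}, 0.5, 1.0)
        m = _matrix([[3.0, 4.0], [0.0, 10.0]])
        assert predict_age(model, m).tolist() == [10 + 6 - 4, 10 - 10]

    def test_missing_model_column_rejected(self):
        model = ClockModel(0.0, {"c0": 1.0, "zz": 2.0}, 0.5, 1.0)
        with pytest.raises(ClockFitError):
            predict_age(model, _matrix([[1.0]]))

    def test_metrics_arithmetic(self):
        m = evaluate([30.0, 40.0], [33.0, 43.0])
        assert (m.mse, m.mad, m.r) == (9.0, 3.0, pytest.approx(1.0))
        perfect = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert perfect.mse == 0.0 and perfect.mad == 0.0 and perfect.r == pytest.approx(1.0)

    def test_five_pair_fixture(self):
        pred = np.array([30.0, 45.0, 50.0, 28.0, 60.0])
        chron = np.array([32.0, 44.0, 55.0, 30.0, 58.0])
        m = evaluate(pred, chron)
        err = pred - chron
        assert m.mse == pytest.approx(np.mean(err**2))
        assert m.mad == pytest.approx(np.median(np.abs(err)))
        assert m.r == pytest.approx(np.corrcoef(pred, chron)[0, 1])

    def test_constant_predictions_flagged(self):
        m = evaluate([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert np.isnan(m.r) and m.mse > 0

    def test_model_json_roundtrip(self, tmp_path):
        model = ClockModel(12.0, {"a": 1.5, "b": 0.0}, 0.5, 1.15, {"n_samples": 9})
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ClockModel.from_json(path)
        assert back.intercept == model.intercept
        assert back.weights == model.weights
        assert back.n_features_selected == 1
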