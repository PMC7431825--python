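"""The sperm rDNA methylation clock.

A penalized linear model predicting chronological age (years) from the β
values (%) of the 53 rDNA CpGs: samples with 10 or more missing CpG
measurements are dropped, remaining gaps are KNN-imputed, and an ElasticNet
(α = 0.5 mix of lasso and ridge) is fitted with the penalty λ chosen by
tenfold cross-validation under the 1-SE rule — the largest λ whose CV mean
squared error is within one standard error of the minimum.

The objective minimized (predictors standardized internally, coefficients
reported on the original scale, response unstandardized)::

    (1/(2n)) Σ_i (y_i − b0 − Σ_j x_ij b_j)²
        + λ [ α Σ_j |b_j| + ((1−α)/2) Σ_j b_j² ]

The 1/(2n) convention keeps λ comparable across cohort sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

from .errors import ClockFitError, ImputationError

__all__ = [
    "ClockModel",
    "ClockMetrics",
    "qc_filter_samples",
    "knn_impute",
    "lambda_path",
    "fit_clock",
    "predict_age",
    "evaluate",
]


@dataclass
class ClockModel:
    """Fitted age predictor: intercept (years) + CpG weights (years per %)."""

    intercept: float
    weights: dict[str, float]  # CpG id -> coefficient (zeros included)
    alpha: float
    lam: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_features_selected(self) -> int:
        return sum(1 for w in self.weights.values() if w != 0.0)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "intercept": self.intercept,
                "weights": self.weights,
                "alpha": self.alpha,
                "lambda": self.lam,
                "metadata": self.metadata,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @staticmethod
    def from_json(source: str | Path) -> "ClockModel":
        text = str(source)
        if "{" not in text:  # a path, not inline JSON
            text = Path(source).read_text()
        d = json.loads(text)
        return ClockModel(
            intercept=d["intercept"],
            weights=d["weights"],
            alpha=d["alpha"],
            lam=d["lambda"],
            metadata=d.get("metadata", {}),
        )


@dataclass
class ClockMetrics:
    mse: float  # years²
    mad: float  # years, median absolute prediction error
    r: float  # Pearson r of predicted vs chronological age (NaN if undefined)


def qc_filter_samples(
    matrix: pd.DataFrame, max_missing: int = 9
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples with more than ``max_missing`` missing CpG values.

    The default keeps samples with up to 9 gaps and removes those with 10 or
    more, the published QC rule.
    """
    if matrix.empty:
        raise ClockFitError("empty matrix")
    n_missing = matrix.isna().sum(axis=1)
    dropped = matrix.index[n_missing > max_missing].tolist()
    kept = matrix.loc[n_missing <= max_missing]
    if kept.empty:
        raise ClockFitError("QC removed every sample")
    return kept, dropped


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing β values from the k nearest samples.

    Distance between samples is the RMS difference over mutually observed
    CpGs; candidate neighbors must themselves have the target CpG observed.
    If no eligible neighbor exists the CpG's overall mean is used as a
    fallback.  Deterministic: ties broken by stable sample order.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if k >= n:
        raise ImputationError(f"k={k} must be smaller than n_samples={n}")
    col_obs = ~np.isnan(X)
    if not col_obs.any(axis=0).all():
        bad = matrix.columns[~col_obs.any(axis=0)].tolist()
        raise ImputationError(f"CpGs with no observed values: {bad}")
    if col_obs.all():
        return matrix.copy()

    col_means = np.nanmean(X, axis=0)
    out = X.copy()
    for i in range(n):
        miss = np.flatnonzero(~col_obs[i])
        if miss.size == 0:
            continue
        shared = col_obs[i][None, :] & col_obs  # (n, p)
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, X[i][None, :] - np.nan_to_num(X), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.nansum(diff**2, axis=1) / np.maximum(n_shared, 1))
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for j in miss:
            d = dist.copy()
            d[~col_obs[:, j]] = np.inf
            order = np.argsort(d, kind="stable")[:k]
            eligible = order[np.isfinite(d[order])]
            out[i, j] = X[eligible, j].mean() if eligible.size else col_means[j]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# ElasticNet fitting
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def lambda_path(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 100,
    min_ratio: float = 1e-4
) -> np.ndarray:
    """Geometric λ path from λ_max (all coefficients zero) down four orders
    of magnitude; λ_max = max_j |⟨x_j, y − ȳ⟩| / (n·α) on standardized x."""
    Xs, _, _ = _standardize(X)
    n = len(y)
    lam_max = float(np.abs(Xs.T @ (y - y.mean())).max() / (n * max(alpha, 1e-3)))
    if lam_max <= 0:
        raise ClockFitError("degenerate response: lambda_max is zero")
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_at_lambda(
    Xs: np.ndarray, y: np.ndarray, lam: float, alpha: float,
    est: ElasticNet | None = None,
) -> tuple[np.ndarray, float, ElasticNet | None]:
    """Fit on standardized predictors at one λ; λ=0 falls back to exact OLS."""
    if lam == 0.0:
        A = np.column_stack([np.ones(len(y)), Xs])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        return beta[1:], float(beta[0]), None
    if est is None:
        est = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True,
            max_iter=20_000, tol=1e-6, warm_start=True,
        )
    else:
        est.set_params(alpha=lam)
    est.fit(Xs, y)
    return est.coef_.copy(), float(est.intercept_), est


def fit_clock(
    matrix: pd.DataFrame,
    ages,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
) -> tuple[ClockModel, pd.DataFrame]:
    """Fit the clock with cross-validated 1-SE λ selection.

    Returns (model, cv_curve) where the CV curve has one row per λ with the
    mean CV MSE and its standard error across folds.  Folds are assigned by
    a seeded permutation, as equal in size as possible; predictors are
    re-standardized inside each training fold.
    """
    X = matrix.to_numpy(dtype=float)
    y = np.asarray(ages, dtype=float)
    n, p = X.shape
    if np.isnan(X).any():
        raise ClockFitError("matrix contains missing values; impute first")
    if not np.isfinite(y).all():
        raise ClockFitError("ages must be finite")
    if np.ptp(y) == 0:
        raise ClockFitError("constant response")
    if n < n_folds:
        raise ClockFitError(f"n={n} smaller than n_folds={n_folds}")

    if lambdas is None:
        lambdas = lambda_path(X, y, alpha)
    lambdas = np.asarray(lambdas, dtype=float)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    fold_mse = np.empty((n_folds, len(lambdas)))
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
        Xt, mu, sd = _standardize(X[train_idx])
        yt = y[train_idx]
        Xv = (X[val_idx] - mu) / sd
        est = None
        for li, lam in enumerate(lambdas):  # warm start down the path
            coef, b0, est = _fit_at_lambda(Xt, yt, lam, alpha, est)
            pred = Xv @ coef + b0
            fold_mse[f, li] = np.mean((y[val_idx] - pred) ** 2)

    cv_mse = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mse))
    threshold = cv_mse[i_min] + cv_se[i_min]
    # path is decreasing in λ, so the first index within threshold is the
    # largest qualifying λ
    i_1se = int(np.flatnonzero(cv_mse <= threshold)[0])
    lam_1se = float(lambdas[i_1se])

    Xs, mu, sd = _standardize(X)
    coef_std, b0_std, _ = _fit_at_lambda(Xs, y, lam_1se, alpha, None)
    coef = coef_std / sd
    intercept = float(b0_std - np.dot(coef_std, mu / sd))

    model = ClockModel(
        intercept=intercept,
        weights={c: float(w) for c, w in zip(matrix.columns, coef)},
        alpha=alpha,
        lam=lam_1se,
        metadata={
            "n_samples": n,
            "n_features": p,
            "n_folds": n_folds,
            "seed": seed,
            "lambda_min_cv": float(lambdas[i_min]),
            "cv_mse_min": float(cv_mse[i_min]),
        },
    )
    cv_curve = pd.DataFrame({"lambda": lambdas, "cv_mse": cv_mse, "cv_se": cv_se})
    return model, cv_curve


def predict_age(model: ClockModel, matrix: pd.DataFrame) -> pd.Series:
    """b0 + Σ_j x_ij·b_j per sample; requires every model CpG present."""
    missing = [c for c in model.weights if c not in matrix.columns]
    if missing:
        raise ClockFitError(f"matrix lacks model CpGs: {missing[:5]}")
    cols = list(model.weights)
    X = matrix[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ClockFitError("matrix contains missing values; impute first")
    w = np.array([model.weights[c] for c in cols])
    return pd.Series(X @ w + model.intercept, index=matrix.index, name="predicted_age")


def evaluate(predicted, chronological) -> ClockMetrics:
    """MSE, median absolute difference, and Pearson r of predicted vs
    chronological age.  r is NaN when predictions are constant."""
    pred = np.asarray(predicted, dtype=float)
    chron = np.asarray(chronological, dtype=float)
    if len(pred) != len(chron) or len(pred) < 2:
        raise ClockFitError("need equal-length vectors with n >= 2")
    err = pred - chron
    mse = float(np.mean(err**2))
    mad = float(np.median(np.abs(err)))
    if np.ptp(pred) == 0 or np.ptp(chron) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred, chron)[0])
    return ClockMetrics(mse=mse, mad=mad, r=r)
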