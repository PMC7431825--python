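"""Cohort-level statistics for methylation aging studies.

Regional means over sample × CpG β matrices, Pearson/Spearman correlations,
Pearson partial correlations adjusting for confounders (BMI, sperm
concentration), Welch-t / Mann–Whitney group comparisons, epimutation-rate
fold changes, and cross-species life-span normalization of age.

Missing β values are handled pairwise-complete; each result reports the n
actually used.  No multiple-testing correction is applied — p-values are
reported raw, one per amplicon, as is conventional for targeted assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allele import AlleleSummary
from .errors import DegenerateCovariateError, UndefinedStatisticError

__all__ = [
    "CorrelationResult",
    "regional_mean",
    "pearson_corr",
    "spearman_corr",
    "partial_corr",
    "partial_corr_precision",
    "group_compare",
    "relative_age",
    "er_ratio",
    "LIFE_SPANS",
]

#: Species maximum life spans used for cross-species normalization.  Mouse
#: ages are given in months, all other species in years.
LIFE_SPANS: Mapping[str, tuple[float, str]] = {
    "mouse": (28.0, "months"),
    "bovine": (20.0, "years"),
    "marmoset": (12.0, "years"),
    "human": (80.0, "years"),
}


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    df: int
    covariates: tuple[str, ...] = field(default_factory=tuple)
    method: str = "pearson"


def regional_mean(matrix: pd.DataFrame, region: Sequence[str]) -> pd.Series:
    """Per-sample mean β (%) over a region's CpG columns, skipping missing
    cells; a sample with the whole region missing stays missing (NaN)."""
    region = list(region)
    if not region:
        raise UndefinedStatisticError("empty region")
    unknown = [c for c in region if c not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown CpG ids: {unknown}")
    return matrix[region].mean(axis=1, skipna=True)


def _pairwise_complete(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    stacked = np.column_stack(arrays)
    keep = ~np.isnan(stacked).any(axis=1)
    return tuple(stacked[keep, i] for i in range(stacked.shape[1]))


def _corr(x, y, method: str) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError(f"need n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n, df=n - 2, method=method)


def pearson_corr(x, y) -> CorrelationResult:
    """Product-moment correlation; p from the t transform with df = n − 2."""
    return _corr(x, y, "pearson")


def spearman_corr(x, y) -> CorrelationResult:
    """Rank correlation for non-normal data."""
    return _corr(x, y, "spearman")


def partial_corr(x, y, covariates=None, covariate_names: tuple[str, ...] = ()) -> CorrelationResult:
    """Pearson partial correlation of x and y given covariates.

    Computed by correlating the OLS residuals of x-on-covariates and
    y-on-covariates (with intercept); p from the t transform with
    df = n − 2 − k.  With no (or constant) covariates this reduces to the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        return pearson_corr(x, y)
    Z = np.column_stack([np.asarray(c, dtype=float) for c in _as_columns(covariates)])
    cols = _pairwise_complete(x, y, *Z.T)
    x, y, Z = cols[0], cols[1], np.column_stack(cols[2:])

    # drop constant covariates (they adjust for nothing)
    keep = np.ptp(Z, axis=0) > 0
    Z = Z[:, keep]
    k = Z.shape[1]
    n = len(x)
    if n < 3 + k:
        raise UndefinedStatisticError(f"need n >= {3 + k} for {k} covariates, got {n}")
    if k == 0:
        return pearson_corr(x, y)

    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateCovariateError("covariate matrix is rank-deficient")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateCovariateError("a variable is explained exactly by the covariates")

    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    if df < 1:
        raise UndefinedStatisticError("no degrees of freedom left")
    r = float(np.clip(r, -1.0, 1.0))
    t = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df))
    names = covariate_names or tuple(f"z{i}" for i in range(k))
    return CorrelationResult(r=r, p=p, n=n, df=df, covariates=names, method="pearson-partial")


def partial_corr_precision(x, y, covariates) -> float:
    """Partial correlation via the inverse correlation (precision) matrix.

    Algebraically equivalent to the residual-regression form; kept as an
    independent route for cross-checking.
    """
    Z = np.column_stack([np.asarray(c, dtype=float) for c in _as_columns(covariates)])
    cols = _pairwise_complete(np.asarray(x, float), np.asarray(y, float), *Z.T)
    M = np.column_stack(cols)
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def _as_columns(covariates) -> list[np.ndarray]:
    if isinstance(covariates, pd.DataFrame):
        return [covariates[c].to_numpy(float) for c in covariates.columns]
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        return [arr]
    return [arr[:, j] for j in range(arr.shape[1])]


def group_compare(a, b, test: str = "t") -> tuple[float, float]:
    """Two-sided group comparison: Welch t test or Mann–Whitney U.

    Returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise UndefinedStatisticError("each group needs n >= 2")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def relative_age(age: float, species: str) -> float:
    """Age as a fraction of the species' life span (mouse ages in months,
    all other species in years); may exceed 1 for very old donors."""
    if species not in LIFE_SPANS:
        raise UndefinedStatisticError(
            f"unknown species {species!r}; known: {sorted(LIFE_SPANS)}"
        )
    if age <= 0:
        raise UndefinedStatisticError("age must be positive")
    span, _unit = LIFE_SPANS[species]
    return age / span


def _mean_er(summaries: Iterable) -> float:
    vals = [
        s.epimutation_rate if isinstance(s, AlleleSummary) else float(s)
        for s in summaries
    ]
    if not vals:
        raise UndefinedStatisticError("empty summary set")
    return float(np.mean(vals))


def er_ratio(numerator, denominator) -> float:
    """Ratio of cohort-mean epimutation rates (e.g. old/young, or A/G)."""
    num, den = _mean_er(numerator), _mean_er(denominator)
    if den <= 0:
        raise UndefinedStatisticError("denominator cohort has zero mean ER")
    return num / den
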