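"""Standardization and multicollinearity diagnostics.

The modelling pipeline standardizes every variable (subtract mean, divide
by SD; the sample SD with an n-1 denominator is used consistently) and
screens predictors with the variance inflation factor, VIF_j =
1/(1 - R^2_j) with R^2_j from the least-squares regression (intercept
included) of predictor j on all other predictors.  VIF > 10 flags severe
multicollinearity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort

#: conventional multicollinearity criterion
VIF_THRESHOLD = 10.0


class DegenerateColumnError(ValueError):
    """A column has zero sample SD and cannot be standardized."""


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, Cohort):
        df = X.predictors
        return df.to_numpy(dtype=float), list(df.columns)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


class CohortStandardizer(BaseEstimator, TransformerMixin):
    """Column-wise (x - mean) / sd transformer with sample (n-1) SD.

    Differs from :class:`sklearn.preprocessing.StandardScaler` only in the
    SD denominator (n-1 rather than n), chosen to match the mean +/- SD
    convention used for cohort descriptive statistics.

    Attributes
    ----------
    mean_ : ndarray of shape (p,)
    scale_ : ndarray of shape (p,)
        Sample standard deviations (ddof=1).
    columns_ : list of str
    """

    def fit(self, X, y=None) -> "CohortStandardizer":
        arr, cols = _as_matrix(X)
        if arr.shape[0] < 2:
            raise ValueError("standardizer requires at least 2 records")
        mean = arr.mean(axis=0)
        scale = arr.std(axis=0, ddof=1)
        for j, s in enumerate(scale):
            if s == 0.0 or not np.isfinite(s):
                raise DegenerateColumnError(
                    f"column {cols[j]!r} has zero or non-finite sample SD"
                )
        self.mean_ = mean
        self.scale_ = scale
        self.columns_ = cols
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        arr, _ = _as_matrix(X)
        return (arr - self.mean_) / self.scale_

    def inverse_transform(self, Z) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        return Z * self.scale_ + self.mean_


def fit_standardizer(cohort: Cohort | pd.DataFrame) -> CohortStandardizer:
    """Fit a :class:`CohortStandardizer` on a cohort's predictor table."""
    return CohortStandardizer().fit(cohort)


#: relative tolerance below which 1 - R^2 is treated as exact collinearity
_EXACT_COLLINEARITY_EPS = 1e-12


def compute_vif(X, threshold: float = VIF_THRESHOLD) -> pd.DataFrame:
    """Variance inflation factor for each predictor.

    Parameters
    ----------
    X : Cohort, DataFrame or array of shape (n, p)
    threshold : float
        Flagging criterion (default 10).

    Returns
    -------
    DataFrame indexed by predictor with columns ``vif`` and ``flagged``.
    Exact collinearity (R^2 = 1 within 1e-12) is reported as ``inf`` and
    flagged — the screen's purpose is to *detect* collinearity, so this is
    a result, not an error.
    """
    arr, cols = _as_matrix(X)
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 records for VIF (n={n}, p={p})")
    vifs = np.empty(p)
    for j in range(p):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0.0:
            raise DegenerateColumnError(f"column {cols[j]!r} is constant")
        one_minus_r2 = np.sum(resid**2) / ss_tot
        vifs[j] = np.inf if one_minus_r2 < _EXACT_COLLINEARITY_EPS else 1.0 / one_minus_r2
    return pd.DataFrame({"vif": vifs, "flagged": vifs > threshold}, index=cols)
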