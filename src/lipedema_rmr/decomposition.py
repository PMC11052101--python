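"""Classical PCA on standardized predictors.

The decomposition is the eigendecomposition of the sample correlation
matrix of the 12 predictors (no kernel, no rotation), computed through
the SVD of the standardized data matrix for numerical stability.
Retention follows either Kaiser's rule (eigenvalue > 1) or a cumulative
explained-variance threshold; variable representation quality is
summarized by squared cosines (cos2).

Two projection conventions for "standardized PC scores" are supported:

* ``standard`` — scores are the loadings applied to *standardized*
  variables, then divided by the component SD (sqrt of the eigenvalue).
  This is the textbook convention.
* ``raw`` — scores are the loadings applied to *raw* variable values,
  then affinely standardized by the training-cohort raw-score mean and
  SD.  This reproduces the published equation system's arithmetic, whose
  component means (~109) and SDs (~34.5) only arise when unit-norm
  loadings multiply raw measurement values.

The two conventions are *not* equivalent up to an affine map per
component (their gradients with respect to a subject differ by the
per-variable SDs); both are first-class and the choice is explicit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import Cohort
from .preprocessing import CohortStandardizer, _as_matrix


class NotFittedError(RuntimeError):
    pass


class CorrelationPCA(BaseEstimator, TransformerMixin):
    """PCA of the sample correlation matrix via SVD of standardized data.

    Attributes (after :meth:`fit`)
    ------------------------------
    loadings_ : ndarray (p, p)
        Unit eigenvectors as columns, eigenvalue-descending, sign-fixed so
        each column's largest-magnitude entry is positive.
    eigenvalues_ : ndarray (p,)
        Eigenvalues of the correlation matrix (sum to p).
    explained_variance_ratio_, cumulative_variance_ratio_ : ndarray (p,)
    standardizer_ : CohortStandardizer
    raw_score_mean_, raw_score_sd_ : ndarray (p,)
        Training-cohort mean and sample SD of raw-convention scores.
    retained_k_ : int
        Number of retained components (set by ``n_components`` or by
        :meth:`select_components`; defaults to all).
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None) -> "CorrelationPCA":
        arr, cols = _as_matrix(X if not isinstance(X, Cohort) else X.predictors)
        n, p = arr.shape
        self.standardizer_ = CohortStandardizer().fit(arr)
        if n < p + 1:
            warnings.warn(
                f"only {n} records for {p} predictors: correlation matrix is "
                "rank-deficient; decomposition returned anyway",
                UserWarning,
                stacklevel=2,
            )
        Z = self.standardizer_.transform(arr)
        # SVD of standardized data: corr = V diag(s^2/(n-1)) V^T
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        eigenvalues = s**2 / (n - 1)
        loadings = vt.T
        # sign convention: largest-|entry| of each component positive
        idx = np.argmax(np.abs(loadings), axis=0)
        signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
        signs[signs == 0] = 1.0
        loadings = loadings * signs
        if loadings.shape[1] < p:  # rank deficient: pad with zeros
            pad = p - loadings.shape[1]
            loadings = np.hstack([loadings, np.zeros((p, pad))])
            eigenvalues = np.concatenate([eigenvalues, np.zeros(pad)])
        self.loadings_ = loadings
        self.eigenvalues_ = eigenvalues
        total = eigenvalues.sum()
        self.explained_variance_ratio_ = eigenvalues / total
        self.cumulative_variance_ratio_ = np.cumsum(self.explained_variance_ratio_)
        self.feature_names_in_ = cols
        self.n_samples_ = n
        self.n_features_in_ = p
        raw_scores = arr @ loadings
        self.raw_score_mean_ = raw_scores.mean(axis=0)
        self.raw_score_sd_ = raw_scores.std(axis=0, ddof=1)
        self.retained_k_ = self.n_components if self.n_components is not None else p
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "loadings_"):
            raise NotFittedError("CorrelationPCA is not fitted")

    # -- retention ----------------------------------------------------------
    def select_components(
        self, rule: str = "kaiser", threshold: float | None = None
    ) -> int:
        """Choose how many components to retain and record it.

        ``rule='kaiser'`` counts eigenvalues > 1.0; ``rule='cumulative'``
        takes the smallest k whose cumulative explained-variance ratio
        reaches ``threshold`` (a fraction in (0, 1]).
        """
        self._check_fitted()
        if rule == "kaiser":
            k = int(np.sum(self.eigenvalues_ > 1.0))
        elif rule == "cumulative":
            if threshold is None or not 0.0 < threshold <= 1.0:
                raise ValueError("cumulative rule needs a threshold in (0, 1]")
            k = int(np.searchsorted(self.cumulative_variance_ratio_, threshold) + 1)
            k = min(k, len(self.eigenvalues_))
        else:
            raise ValueError(f"unknown retention rule {rule!r}")
        k = max(k, 1)
        self.retained_k_ = k
        return k

    # -- diagnostics ---------------------------------------------------------
    def cos2(self) -> pd.DataFrame:
        """Squared cosines: cos2[v, c] = (loading_vc * sqrt(eigenvalue_c))^2.

        Rows are variables, columns components; each row sums to 1 over all
        p components (the variable's unit variance fully decomposed).
        """
        self._check_fitted()
        tbl = (self.loadings_ * np.sqrt(self.eigenvalues_)) ** 2
        return pd.DataFrame(
            tbl,
            index=self.feature_names_in_,
            columns=[f"PC{i + 1}" for i in range(tbl.shape[1])],
        )

    # -- projection ----------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Retained-component scores, standard convention (not rescaled)."""
        self._check_fitted()
        arr, _ = _as_matrix(X if not isinstance(X, Cohort) else X.predictors)
        Z = self.standardizer_.transform(arr)
        return Z @ self.loadings_[:, : self.retained_k_]

    def project(self, X, convention: str = "standard") -> np.ndarray:
        """Standardized PC scores for new subjects (retained components).

        ``standard``: loadings on standardized variables, divided by the
        component SD sqrt(eigenvalue).  ``raw``: loadings on raw values,
        affinely standardized by the training raw-score mean/SD.
        """
        self._check_fitted()
        k = self.retained_k_
        arr, _ = _as_matrix(X if not isinstance(X, Cohort) else X.predictors)
        if convention == "standard":
            scores = self.transform(arr)
            sd = np.sqrt(self.eigenvalues_[:k])
            sd = np.where(sd > 0, sd, 1.0)
            return scores / sd
        if convention == "raw":
            raw = arr @ self.loadings_[:, :k]
            return (raw - self.raw_score_mean_[:k]) / self.raw_score_sd_[:k]
        raise ValueError(f"unknown projection convention {convention!r}")


def fit_pca(cohort, n_components: int | None = None) -> CorrelationPCA:
    """Fit :class:`CorrelationPCA` on a cohort's 12 predictors."""
    return CorrelationPCA(n_components=n_components).fit(cohort)


def select_components(model: CorrelationPCA, rule: str = "kaiser",
                      threshold: float | None = None) -> int:
    return model.select_components(rule=rule, threshold=threshold)


def cos2(model: CorrelationPCA) -> pd.DataFrame:
    return model.cos2()


def project(model: CorrelationPCA, X, convention: str = "standard") -> np.ndarray:
    return model.project(X, convention=convention)
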