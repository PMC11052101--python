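"""Model zoo and derivation pipeline.

Five learners map retained standardized PC scores to standardized RMR:
epsilon-SVR with a degree-1 polynomial kernel, random forest, k-nearest
neighbours, ridge, and the segmented model — two degree-1 poly-kernel
SVRs fitted separately below/above the median of standardized RMR, each
reduced to closed linear form, with the lower branch's linear form
serving as the gate.  Hyperparameter presets follow the published fits.

Model selection uses a single random 90/10 train/test split and 5-fold
grid-search cross-validation scored by fold-out MAPE on the kcal/day
scale (predictions are back-transformed before scoring, since the model
is meant to predict RMR for real subjects).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, ParameterGrid, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .cohort import Cohort
from .decomposition import CorrelationPCA
from .equations import EquationDocument, SegmentedEquation, extract_linear_equation

#: published hyperparameters per learner (epsilon/gamma/coef0 were not
#: reported for the SVRs; the defaults below are the package's documented
#: choices and are overridable)
LEARNER_PRESETS: dict[str, dict] = {
    "svr": {"C": 1.0, "kernel": "poly", "degree": 1, "gamma": "scale",
            "coef0": 0.0, "epsilon": 0.1},
    "rfr": {"n_estimators": 200, "bootstrap": True, "max_depth": 10,
            "max_features": "sqrt", "min_samples_leaf": 4,
            "min_samples_split": 2},
    "knn": {"n_neighbors": 6, "weights": "uniform", "algorithm": "auto"},
    "ridge": {"alpha": 1e-4, "solver": "auto", "tol": 1e-3},
    "segmented": {"C_lower": 1.5, "C_upper": 1.0, "epsilon": 0.1,
                  "gamma": "scale", "coef0": 0.0},
}


def make_learner(kind: str, random_state: int | None = None, **overrides):
    """Instantiate one of the five learners with its published presets."""
    if kind not in LEARNER_PRESETS:
        raise ValueError(f"unknown learner kind {kind!r}; "
                         f"choose from {sorted(LEARNER_PRESETS)}")
    params = {**LEARNER_PRESETS[kind], **overrides}
    if kind == "svr":
        return SVR(**params)
    if kind == "rfr":
        return RandomForestRegressor(random_state=random_state, **params)
    if kind == "knn":
        return KNeighborsRegressor(**params)
    if kind == "ridge":
        return Ridge(**params)
    return SegmentedSVR(**params)


def _split_indices(n: int, test_fraction: float, seed: int):
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(n)
    train, test = train_test_split(
        idx, test_size=test_fraction, random_state=seed, shuffle=True
    )
    if len(train) == 0 or len(test) == 0:
        raise ValueError(f"degenerate split for n={n}, test_fraction={test_fraction}")
    return np.sort(train), np.sort(test)


def split_cohort(cohort: Cohort, test_fraction: float = 0.1, seed: int = 0):
    """Random one-shot train/test partition; test size = ceil(fraction * n)."""
    train_idx, test_idx = _split_indices(len(cohort), test_fraction, seed)
    frame = cohort.frame
    return (
        Cohort(frame.iloc[train_idx], provenance=f"{cohort.provenance} [train]"),
        Cohort(frame.iloc[test_idx], provenance=f"{cohort.provenance} [test]"),
    )


@dataclass
class GridSearchResult:
    best_params: dict
    best_score: float           # mean fold-out MAPE, percent
    table: pd.DataFrame         # one row per candidate, grid order


def grid_search_cv(
    estimator,
    param_grid: dict | list,
    X,
    y,
    cv_folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive grid search scored by mean fold-out MAPE (percent).

    Folds are contiguous blocks after a seeded shuffle
    (:class:`~sklearn.model_selection.KFold` with ``shuffle=True``); every
    record is held out exactly once.  Ties are broken by grid order.
    ``estimator`` must predict on the same (raw) scale as ``y``.
    """
    from .evaluation import mape

    candidates = list(ParameterGrid(param_grid))
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y_arr = np.asarray(y, dtype=float)
    if len(y_arr) < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} records")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X_arr))
    rows = []
    best_i, best_score = 0, np.inf
    for i, params in enumerate(candidates):
        fold_scores = []
        for tr, va in folds:
            est = clone(estimator).set_params(**params)
            est.fit(X_arr[tr], y_arr[tr])
            fold_scores.append(mape(y_arr[va], est.predict(X_arr[va])))
        score = float(np.mean(fold_scores))
        rows.append({**params, "mean_cv_mape": score})
        if score < best_score:
            best_i, best_score = i, score
    return GridSearchResult(
        best_params=dict(candidates[best_i]),
        best_score=best_score,
        table=pd.DataFrame(rows),
    )


class SegmentedSVR(BaseEstimator, RegressorMixin):
    """Median-split segmented regression built from two linear SVRs.

    ``fit(X, y)`` expects standardized targets.  The split threshold is
    the (linearly interpolated) median of ``y`` unless ``threshold`` is
    given — the derivation pipeline passes the median of the *full*
    modelling dataset so the split rule is predetermined before the
    train/test division.  Records with ``y <= threshold`` train the lower
    branch, the rest the upper branch; each branch is a degree-1
    polynomial-kernel SVR reduced to closed linear form, and the lower
    branch's linear form gates new subjects (ties at the threshold go to
    branch 1).

    Attributes
    ----------
    threshold_ : float
    equation_ : SegmentedEquation
    svr_lower_, svr_upper_ : fitted sklearn SVR objects
    """

    def __init__(self, C_lower: float = 1.5, C_upper: float = 1.0,
                 epsilon: float = 0.1, gamma="scale", coef0: float = 0.0,
                 threshold: float | None = None,
                 back_transform: tuple[float, float] = (1.0, 0.0)):
        self.C_lower = C_lower
        self.C_upper = C_upper
        self.epsilon = epsilon
        self.gamma = gamma
        self.coef0 = coef0
        self.threshold = threshold
        self.back_transform = back_transform

    def fit(self, X, y) -> "SegmentedSVR":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        thr = float(np.median(y)) if self.threshold is None else float(self.threshold)
        lower = y <= thr
        if np.ptp(y) == 0.0:
            # degenerate: constant target; both branches fit the constant
            lower = np.ones_like(lower)
            upper = lower
        elif lower.sum() < 2 or (~lower).sum() < 2:
            raise ValueError(
                f"each side of the threshold needs >= 2 records "
                f"(got {int(lower.sum())}/{int((~lower).sum())})"
            )
        else:
            upper = ~lower
        common = dict(kernel="poly", degree=1, gamma=self.gamma,
                      coef0=self.coef0, epsilon=self.epsilon)
        self.svr_lower_ = SVR(C=self.C_lower, **common).fit(X[lower], y[lower])
        self.svr_upper_ = SVR(C=self.C_upper, **common).fit(X[upper], y[upper])
        w1, b1 = extract_linear_equation(self.svr_lower_)
        w2, b2 = extract_linear_equation(self.svr_upper_)
        sd, mean = self.back_transform
        self.threshold_ = thr
        self.equation_ = SegmentedEquation(
            gate_weights=tuple(w1), gate_intercept=b1, gate_threshold=thr,
            branch1_weights=tuple(w1), branch1_intercept=b1,
            branch2_weights=tuple(w2), branch2_intercept=b2,
            rmr_sd=float(sd), rmr_mean=float(mean),
        )
        return self

    def predict(self, X) -> np.ndarray:
        return self.equation_.predict_standardized(np.asarray(X, dtype=float))


def fit_segmented(X, y_standardized, threshold: float | None = None,
                  **params) -> SegmentedSVR:
    """Fit a :class:`SegmentedSVR` with the published presets."""
    kw = {**LEARNER_PRESETS["segmented"], **params}
    return SegmentedSVR(threshold=threshold, **kw).fit(X, y_standardized)


class PCRegressionRMR(BaseEstimator, RegressorMixin):
    """Full PC-regression RMR predictor: standardize, PCA, retain k
    components, fit a learner on standardized targets, predict kcal/day.

    Parameters
    ----------
    learner : str
        'svr', 'rfr', 'knn', 'ridge' or 'segmented'.
    n_components : int
        Retained components (the published analysis keeps 3).
    convention : str
        PC-score convention, 'standard' or 'raw' (see decomposition docs).
    learner_params : dict or None
        Overrides on the learner presets.
    threshold : float or None
        Predetermined median threshold (standardized RMR) for the
        segmented learner; default recomputes it on the fitted data.
    """

    def __init__(self, learner: str = "segmented", n_components: int = 3,
                 convention: str = "standard", learner_params: dict | None = None,
                 threshold: float | None = None, random_state: int | None = None):
        self.learner = learner
        self.n_components = n_components
        self.convention = convention
        self.learner_params = learner_params
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y) -> "PCRegressionRMR":
        y = np.asarray(y, dtype=float)
        self.pca_ = CorrelationPCA(n_components=self.n_components).fit(X)
        scores = self.pca_.project(X, convention=self.convention)
        self.rmr_mean_ = float(y.mean())
        self.rmr_sd_ = float(y.std(ddof=1))
        if self.rmr_sd_ == 0.0:
            raise ValueError("target has zero variance")
        y_st = (y - self.rmr_mean_) / self.rmr_sd_
        overrides = dict(self.learner_params or {})
        if self.learner == "segmented":
            overrides.setdefault("threshold", self.threshold)
            overrides.setdefault("back_transform", (self.rmr_sd_, self.rmr_mean_))
        self.learner_ = make_learner(self.learner, random_state=self.random_state,
                                     **overrides)
        self.learner_.fit(scores, y_st)
        if self.learner == "segmented":
            self.equation_ = self.learner_.equation_
        elif self.learner in ("svr",):
            w, b = extract_linear_equation(self.learner_)
            self.linear_equation_ = (w, b)
        elif self.learner == "ridge":
            self.linear_equation_ = (np.asarray(self.learner_.coef_, float),
                                     float(self.learner_.intercept_))
        return self

    def predict(self, X) -> np.ndarray:
        scores = self.pca_.project(X, convention=self.convention)
        y_st = self.learner_.predict(scores)
        return y_st * self.rmr_sd_ + self.rmr_mean_

    def to_document(self, metadata: dict | None = None) -> EquationDocument:
        """Export the fitted segmented model as a self-contained document."""
        if not hasattr(self, "equation_"):
            raise ValueError("only the segmented learner exports a document")
        pca = self.pca_
        k = pca.retained_k_
        if self.convention == "standard":
            score_mean = tuple(0.0 for _ in range(k))
            score_sd = tuple(np.sqrt(pca.eigenvalues_[:k]))
            var_mean = tuple(pca.standardizer_.mean_)
            var_sd = tuple(pca.standardizer_.scale_)
        else:
            score_mean = tuple(pca.raw_score_mean_[:k])
            score_sd = tuple(pca.raw_score_sd_[:k])
            var_mean = var_sd = None
        return EquationDocument(
            convention=self.convention,
            variable_names=tuple(pca.feature_names_in_),
            loadings=tuple(tuple(row) for row in pca.loadings_[:, :k]),
            score_mean=score_mean,
            score_sd=score_sd,
            equation=self.equation_,
            variable_mean=var_mean,
            variable_sd=var_sd,
            metadata=dict(metadata or {}),
        )


@dataclass
class EquationFitResult:
    """Outcome of the full derivation pipeline."""

    equation: SegmentedEquation
    document: EquationDocument
    train_mape: float
    test_mape: float
    predictions: pd.DataFrame   # columns: split, measured, predicted, branch
    n: int
    seed: int


def derive_published_style_equation(
    cohort: Cohort,
    seed: int = 0,
    test_fraction: float = 0.1,
    n_components: int = 3,
    learner_params: dict | None = None,
) -> EquationFitResult:
    """Run the full published-style derivation on a cohort with measured RMR.

    Standardization, PCA, the component-score affine and the median split
    threshold are fitted on the *full* modelling dataset (the split rule
    is predetermined); the two branch SVRs are fitted on the 90% training
    partition only, and MAPE is reported on the raw kcal/day scale for
    both partitions.
    """
    from .evaluation import mape

    if not cohort.has_rmr:
        raise ValueError("derivation requires a cohort with measured rmr")
    X = cohort.predictors
    y = cohort.rmr
    n = len(cohort)

    pca = CorrelationPCA(n_components=n_components).fit(X)
    scores = pca.project(X, convention="standard")
    rmr_mean = float(y.mean())
    rmr_sd = float(y.std(ddof=1))
    y_st = (y - rmr_mean) / rmr_sd
    threshold = float(np.median(y_st))

    train_idx, test_idx = _split_indices(n, test_fraction, seed)
    seg = fit_segmented(
        scores[train_idx], y_st[train_idx], threshold=threshold,
        **(learner_params or {}),
    )
    equation = dataclasses.replace(seg.equation_, rmr_sd=rmr_sd, rmr_mean=rmr_mean)

    model = PCRegressionRMR(learner="segmented", n_components=n_components)
    model.pca_ = pca
    model.rmr_mean_, model.rmr_sd_ = rmr_mean, rmr_sd
    model.learner_ = seg
    model.equation_ = equation
    document = model.to_document(metadata={"seed": seed, "n": n,
                                           "test_fraction": test_fraction})

    pred = equation.predict_kcal(scores)
    branch = equation.branches(scores)
    split = np.full(n, "train", dtype=object)
    split[test_idx] = "test"
    predictions = pd.DataFrame({
        "split": split, "measured": y, "predicted": pred, "branch": branch,
    })
    return EquationFitResult(
        equation=equation,
        document=document,
        train_mape=mape(y[train_idx], pred[train_idx]),
        test_mape=mape(y[test_idx], pred[test_idx]),
        predictions=predictions,
        n=n,
        seed=seed,
    )
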