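"""Closed-form equation objects: segmented linear equations over PC scores,
extraction of linear weights from degree-1 polynomial-kernel SVRs, and a
self-contained serializable equation document.

A degree-1 polynomial kernel is affine — K(u, v) = gamma * <u, v> + c0 —
so the decision function of an epsilon-SVR fitted with it,

    f(x) = sum_i alpha_i * (gamma * <x_i, x> + c0) + b,

is exactly linear in x with weights ``gamma * sum_i alpha_i x_i`` and
intercept ``b + c0 * sum_i alpha_i``.  This is what lets the segmented
model be written down as a closed-form system of equations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR


class ExtractionError(ValueError):
    """The fitted model is not a degree-1 polynomial-kernel SVR."""


def extract_linear_equation(svr: SVR) -> tuple[np.ndarray, float]:
    """Reduce a fitted degree-1 poly-kernel SVR to ``(weights, intercept)``.

    The returned affine form reproduces ``svr.predict`` exactly (up to
    floating-point roundoff).
    """
    if not hasattr(svr, "support_vectors_"):
        raise ExtractionError("SVR is not fitted")
    if svr.kernel != "poly" or int(svr.degree) != 1:
        raise ExtractionError(
            f"extraction requires kernel='poly', degree=1; got "
            f"kernel={svr.kernel!r}, degree={svr.degree}"
        )
    gamma = float(svr._gamma)  # resolved value of 'scale'/'auto'/numeric
    dual = svr.dual_coef_.ravel()
    weights = gamma * (dual @ svr.support_vectors_)
    intercept = float(svr.intercept_[0] + svr.coef0 * dual.sum())
    return np.asarray(weights, dtype=float), intercept


@dataclass(frozen=True)
class SegmentedEquation:
    """Two-branch linear equation over standardized PC scores with a linear
    gate, predicting standardized RMR, plus the affine back-transform to
    kcal/day.

    The gate value ``g = gate_weights . s + gate_intercept`` is compared to
    ``gate_threshold``; ``g <= threshold`` routes to branch 1 (ties
    inclusive), otherwise branch 2.  The branch output is
    ``weights . s + intercept`` in standardized-RMR units; kcal/day
    predictions are ``value * rmr_sd + rmr_mean``.
    """

    gate_weights: tuple[float, ...]
    gate_intercept: float
    gate_threshold: float
    branch1_weights: tuple[float, ...]
    branch1_intercept: float
    branch2_weights: tuple[float, ...]
    branch2_intercept: float
    rmr_sd: float = 1.0
    rmr_mean: float = 0.0
    caveats: tuple[str, ...] = ()

    @property
    def n_scores(self) -> int:
        return len(self.gate_weights)

    def _scores(self, scores) -> np.ndarray:
        s = np.atleast_2d(np.asarray(scores, dtype=float))
        if s.shape[1] != self.n_scores:
            raise ValueError(
                f"expected {self.n_scores} scores per subject, got {s.shape[1]}"
            )
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        return s

    def gate_values(self, scores) -> np.ndarray:
        s = self._scores(scores)
        return s @ np.asarray(self.gate_weights) + self.gate_intercept

    def branches(self, scores) -> np.ndarray:
        """Branch indicator per subject: 1 or 2 (ties at the threshold -> 1)."""
        return np.where(self.gate_values(scores) <= self.gate_threshold, 1, 2)

    def predict_standardized(self, scores) -> np.ndarray:
        s = self._scores(scores)
        b1 = s @ np.asarray(self.branch1_weights) + self.branch1_intercept
        b2 = s @ np.asarray(self.branch2_weights) + self.branch2_intercept
        return np.where(self.branches(s) == 1, b1, b2)

    def predict_kcal(self, scores) -> np.ndarray:
        return self.predict_standardized(scores) * self.rmr_sd + self.rmr_mean

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "gate_weights": list(self.gate_weights),
            "gate_intercept": self.gate_intercept,
            "gate_threshold": self.gate_threshold,
            "branch1_weights": list(self.branch1_weights),
            "branch1_intercept": self.branch1_intercept,
            "branch2_weights": list(self.branch2_weights),
            "branch2_intercept": self.branch2_intercept,
            "rmr_sd": self.rmr_sd,
            "rmr_mean": self.rmr_mean,
            "caveats": list(self.caveats),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentedEquation":
        return cls(
            gate_weights=tuple(d["gate_weights"]),
            gate_intercept=float(d["gate_intercept"]),
            gate_threshold=float(d["gate_threshold"]),
            branch1_weights=tuple(d["branch1_weights"]),
            branch1_intercept=float(d["branch1_intercept"]),
            branch2_weights=tuple(d["branch2_weights"]),
            branch2_intercept=float(d["branch2_intercept"]),
            rmr_sd=float(d.get("rmr_sd", 1.0)),
            rmr_mean=float(d.get("rmr_mean", 0.0)),
            caveats=tuple(d.get("caveats", ())),
        )


@dataclass(frozen=True)
class EquationDocument:
    """Self-contained, serializable RMR equation.

    Carries everything needed to score a new subject from raw predictor
    values: the projection convention, per-variable standardization (for
    the ``standard`` convention; absent for ``raw``), the 12 x k loadings,
    the per-component score affine (mean, SD), and the segmented equation
    with its kcal/day back-transform.
    """

    convention: str                       # "standard" | "raw"
    variable_names: tuple[str, ...]
    loadings: tuple[tuple[float, ...], ...]   # p rows, k columns
    score_mean: tuple[float, ...]
    score_sd: tuple[float, ...]
    equation: SegmentedEquation
    variable_mean: tuple[float, ...] | None = None
    variable_sd: tuple[float, ...] | None = None
    metadata: dict = field(default_factory=dict)

    SCHEMA_VERSION = 1

    def scores(self, X) -> np.ndarray:
        """Standardized PC scores for a table of raw predictor values."""
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            X = X.loc[:, list(self.variable_names)].to_numpy(dtype=float)
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        L = np.asarray(self.loadings)
        if self.convention == "standard":
            if self.variable_mean is None or self.variable_sd is None:
                raise ValueError("standard convention requires variable mean/sd")
            arr = (arr - np.asarray(self.variable_mean)) / np.asarray(self.variable_sd)
        raw = arr @ L
        return (raw - np.asarray(self.score_mean)) / np.asarray(self.score_sd)

    def predict(self, X) -> np.ndarray:
        """Predicted RMR in kcal/day for raw predictor values."""
        return self.equation.predict_kcal(self.scores(X))

    def predict_detailed(self, X):
        """DataFrame with scores, gate value, branch, and prediction."""
        import pandas as pd

        s = self.scores(X)
        out = {f"pc{i + 1}_st": s[:, i] for i in range(s.shape[1])}
        out["gate_value"] = self.equation.gate_values(s)
        out["branch"] = self.equation.branches(s)
        out["rmr_pred_kcal_day"] = self.equation.predict_kcal(s)
        return pd.DataFrame(out)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "convention": self.convention,
            "variable_names": list(self.variable_names),
            "variable_mean": None if self.variable_mean is None else list(self.variable_mean),
            "variable_sd": None if self.variable_sd is None else list(self.variable_sd),
            "loadings": [list(row) for row in self.loadings],
            "score_mean": list(self.score_mean),
            "score_sd": list(self.score_sd),
            "equation": self.equation.to_dict(),
            "metadata": dict(self.metadata),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "EquationDocument":
        return cls(
            convention=d["convention"],
            variable_names=tuple(d["variable_names"]),
            loadings=tuple(tuple(row) for row in d["loadings"]),
            score_mean=tuple(d["score_mean"]),
            score_sd=tuple(d["score_sd"]),
            equation=SegmentedEquation.from_dict(d["equation"]),
            variable_mean=None if d.get("variable_mean") is None else tuple(d["variable_mean"]),
            variable_sd=None if d.get("variable_sd") is None else tuple(d["variable_sd"]),
            metadata=dict(d.get("metadata", {})),
        )

    @classmethod
    def from_json(cls, text: str) -> "EquationDocument":
        return cls.from_dict(json.loads(text))
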