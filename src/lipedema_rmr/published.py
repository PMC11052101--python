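"""The published RMR equation system for women with lipedema, verbatim.

Implements the final printed equation with every printed constant: three
principal-component scores computed from the 12 raw predictor values via
the printed loadings, affinely standardized by the printed component
means/SDs, then a two-branch linear equation gated at -0.0567 on a linear
combination of the scores, back-transformed with the printed RMR
mean/SD.  Also provides the Weir indirect-calorimetry formula.

Two printed quirks are preserved exactly and surfaced as machine-readable
caveats rather than "fixed":

* the gate weight on PC1st (0.0482) differs from branch 1's prediction
  weight (0.0472), which makes the function discontinuous at the gate;
* the back-transform RMR mean (1693.5234 kcal/day) differs from the
  cohort-table RMR mean (1685.8 kcal/day).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import PREDICTORS, SubjectRecord
from .equations import EquationDocument, SegmentedEquation

#: loadings of the first three principal components on the 12 predictors,
#: canonical variable order (age ... whr)
PUBLISHED_LOADINGS = np.array([
    #   PC1      PC2      PC3
    [0.2328,  0.4479,  0.3150],   # age
    [-0.2903, 0.4934, -0.1447],   # height
    [0.2936, -0.2250, -0.0650],   # weight
    [0.3674, -0.0695, -0.0215],   # bmi
    [0.2726, -0.2927, -0.1423],   # lbm
    [0.3374,  0.0497,  0.1300],   # pbf
    [0.3294, -0.1349, -0.0030],   # mbf
    [0.2066, -0.3635, -0.2148],   # tbw
    [0.3174,  0.0776,  0.3330],   # vfl
    [0.2962,  0.0535, -0.3125],   # waist
    [0.2795, -0.3113,  0.2579],   # hips
    [0.1853,  0.3951, -0.7189],   # whr
])

PC_MEANS = np.array([109.5763, 109.9039, 108.9802])
PC_SDS = np.array([34.5448, 34.5661, 34.5062])

RMR_MEAN = 1693.5234   # kcal/day (back-transform constant)
RMR_SD = 310.5558      # kcal/day

GATE_WEIGHTS = (0.0482, 0.0452, 0.0509)
GATE_INTERCEPT = -0.600
GATE_THRESHOLD = -0.0567
BRANCH1_WEIGHTS = (0.0472, 0.0452, 0.0509)
BRANCH1_INTERCEPT = -0.600
BRANCH2_WEIGHTS = (0.2160, 0.2184, 0.2116)
BRANCH2_INTERCEPT = 0.4945

CAVEATS = (
    "gate weight on PC1st (0.0482) differs from branch-1 prediction weight "
    "(0.0472) as printed; the prediction is discontinuous at the gate",
    "back-transform RMR mean (1693.5234) differs from the cohort-table RMR "
    "mean (1685.8); the printed back-transform constant is used",
)

PUBLISHED_EQUATION = SegmentedEquation(
    gate_weights=GATE_WEIGHTS,
    gate_intercept=GATE_INTERCEPT,
    gate_threshold=GATE_THRESHOLD,
    branch1_weights=BRANCH1_WEIGHTS,
    branch1_intercept=BRANCH1_INTERCEPT,
    branch2_weights=BRANCH2_WEIGHTS,
    branch2_intercept=BRANCH2_INTERCEPT,
    rmr_sd=RMR_SD,
    rmr_mean=RMR_MEAN,
    caveats=CAVEATS,
)


def published_document() -> EquationDocument:
    """The published equation as a self-contained equation document.

    Uses the ``raw`` projection convention: the printed loadings are
    applied to raw predictor values, then standardized by the printed
    component means/SDs — exactly as the published score formulas read.
    """
    return EquationDocument(
        convention="raw",
        variable_names=PREDICTORS,
        loadings=tuple(tuple(row) for row in PUBLISHED_LOADINGS),
        score_mean=tuple(PC_MEANS),
        score_sd=tuple(PC_SDS),
        equation=PUBLISHED_EQUATION,
        metadata={"source": "published constants"},
    )


def _record_values(record) -> np.ndarray:
    if isinstance(record, SubjectRecord):
        return record.as_array()[None, :]
    if isinstance(record, pd.DataFrame):
        missing = [c for c in PREDICTORS if c not in record.columns]
        if missing:
            raise ValueError(f"missing predictors: {missing}")
        return record.loc[:, list(PREDICTORS)].to_numpy(dtype=float)
    arr = np.atleast_2d(np.asarray(record, dtype=float))
    if arr.shape[1] != len(PREDICTORS):
        raise ValueError(f"expected {len(PREDICTORS)} predictor values")
    return arr


def published_pc_scores(record) -> np.ndarray:
    """(PC1st, PC2st, PC3st) per the printed scalar formulas.

    Each score is the weighted sum of the 12 *raw* predictor values with
    the printed loadings, minus the printed component mean, divided by
    the printed component SD.  Accepts a SubjectRecord, a DataFrame with
    the canonical columns, or an array of 12 values; returns shape (3,)
    for a single subject, (n, 3) otherwise.
    """
    arr = _record_values(record)
    if not np.all(np.isfinite(arr)):
        raise ValueError("all 12 predictors must be present and finite")
    scores = (arr @ PUBLISHED_LOADINGS - PC_MEANS) / PC_SDS
    return scores[0] if scores.shape[0] == 1 and not isinstance(record, pd.DataFrame) else scores


def predict_rmr(record=None, scores=None):
    """Published-equation RMR prediction in kcal/day, plus branch indicator.

    Provide either ``record`` (raw predictor values; scores computed via
    :func:`published_pc_scores`) or ``scores`` (the three standardized
    component scores directly).  Returns ``(rmr, branch)`` scalars for a
    single subject, arrays otherwise.
    """
    if (record is None) == (scores is None):
        raise ValueError("provide exactly one of record= or scores=")
    if scores is None:
        s = np.atleast_2d(published_pc_scores(_record_values(record)))
    else:
        s = np.atleast_2d(np.asarray(scores, dtype=float))
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    rmr = PUBLISHED_EQUATION.predict_kcal(s)
    branch = PUBLISHED_EQUATION.branches(s)
    if rmr.shape[0] == 1 and np.ndim(scores if scores is not None else 0) <= 1 \
            and not isinstance(record, pd.DataFrame):
        return float(rmr[0]), int(branch[0])
    return rmr, branch


class PublishedRMRPredictor(BaseEstimator):
    """Predict-only estimator wrapping the published equation system.

    ``fit`` is a no-op (all constants are printed); ``predict`` maps a
    table of the 12 raw predictors to kcal/day.
    """

    def fit(self, X=None, y=None) -> "PublishedRMRPredictor":
        self.document_ = published_document()
        return self

    def predict(self, X) -> np.ndarray:
        doc = getattr(self, "document_", None) or published_document()
        return doc.predict(_record_values(X))

    def predict_detailed(self, X) -> pd.DataFrame:
        doc = getattr(self, "document_", None) or published_document()
        return doc.predict_detailed(_record_values(X))


#: Weir equation constants: kcal per liter O2 and CO2, minutes per day
WEIR_O2 = 3.941
WEIR_CO2 = 1.11
_MIN_PER_DAY = 1440.0


def weir_ree(vo2: float, vco2: float) -> float:
    """Resting energy expenditure (kcal/day) from indirect calorimetry.

    ``vo2``/``vco2`` are oxygen consumption and carbon dioxide production
    in liters per minute: REE = (VO2 * 3.941 + VCO2 * 1.11) * 1440.
    """
    vo2 = float(vo2)
    vco2 = float(vco2)
    if not (math.isfinite(vo2) and math.isfinite(vco2)):
        raise ValueError("vo2 and vco2 must be finite")
    if vo2 < 0 or vco2 < 0:
        raise ValueError("vo2 and vco2 must be non-negative")
    return (vo2 * WEIR_O2 + vco2 * WEIR_CO2) * _MIN_PER_DAY
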