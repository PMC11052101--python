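"""Prediction-agreement statistics: MAPE and Bland-Altman analysis.

MAPE is computed on the raw kcal/day scale (the model is meant for real
subjects, so percentage error against measured values is the headline
metric).  Bland-Altman differences are oriented predicted - measured, so
a positive mean difference means the equation overestimates; limits of
agreement are mean +/- 1.96 * sample SD of the differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

#: normal-theory multiplier for the 95% limits of agreement
LOA_MULTIPLIER = 1.96


def _pair(measured, predicted) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if m.shape != p.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {p.shape}")
    if m.size == 0:
        raise ValueError("need at least one pair")
    return m, p


def mape(measured, predicted) -> float:
    """Mean absolute percentage error, in percent:
    ``100 * mean(|measured - predicted| / |measured|)``.
    """
    m, p = _pair(measured, predicted)
    if np.any(m == 0):
        raise ValueError("MAPE undefined: a measured value is zero")
    return float(100.0 * np.mean(np.abs(m - p) / np.abs(m)))


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    sd_difference: float
    lower_loa: float
    upper_loa: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "lower_loa": self.lower_loa,
            "upper_loa": self.upper_loa,
            "n": self.n,
        }


def bland_altman(measured, predicted) -> BlandAltman:
    """Agreement summary for differences d = predicted - measured.

    Sample (n-1) SD; limits of agreement are mean +/- 1.96 SD.
    """
    m, p = _pair(measured, predicted)
    if m.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = p - m
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return BlandAltman(
        mean_difference=mean_d,
        sd_difference=sd_d,
        lower_loa=mean_d - LOA_MULTIPLIER * sd_d,
        upper_loa=mean_d + LOA_MULTIPLIER * sd_d,
        n=int(m.size),
    )


@dataclass
class EvaluationReport:
    """MAPE plus Bland-Altman summary with the per-subject table."""

    mape: float
    n: int
    bland_altman: BlandAltman
    table: pd.DataFrame   # measured, predicted, difference, mean_of_pair

    def to_dict(self) -> dict:
        return {
            "mape": self.mape,
            "n": self.n,
            "bland_altman": self.bland_altman.to_dict(),
            "table": {c: self.table[c].tolist() for c in self.table.columns},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        ba = BlandAltman(**d["bland_altman"])
        cols = ["measured", "predicted", "difference", "mean_of_pair"]
        table = pd.DataFrame(d["table"])
        table = table[[c for c in cols if c in table.columns]]
        return cls(mape=float(d["mape"]), n=int(d["n"]), bland_altman=ba,
                   table=table)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(text))


def evaluate_predictions(measured, predicted) -> EvaluationReport:
    m, p = _pair(measured, predicted)
    table = pd.DataFrame({
        "measured": m,
        "predicted": p,
        "difference": p - m,
        "mean_of_pair": (m + p) / 2.0,
    })
    return EvaluationReport(
        mape=mape(m, p), n=int(m.size), bland_altman=bland_altman(m, p), table=table
    )


def evaluate_model(test: Cohort, predictor) -> EvaluationReport:
    """Apply a predictor to a cohort with measured RMR and summarize.

    ``predictor`` is anything with a ``predict(X)`` method taking the
    12-predictor table, or a callable doing the same.
    """
    if not test.has_rmr:
        raise ValueError("evaluation requires a cohort with measured rmr")
    X = test.predictors
    predicted = predictor.predict(X) if hasattr(predictor, "predict") else predictor(X)
    return evaluate_predictions(test.rmr, predicted)


def bland_altman_plot(report: EvaluationReport, path) -> None:
    """Write a Bland-Altman scatter (mean of pair vs difference) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = report.bland_altman
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(report.table["mean_of_pair"], report.table["difference"],
               s=18, alpha=0.7)
    for yv, style, label in (
        (ba.mean_difference, "-", f"mean {ba.mean_difference:.1f}"),
        (ba.lower_loa, "--", f"-1.96 SD {ba.lower_loa:.1f}"),
        (ba.upper_loa, "--", f"+1.96 SD {ba.upper_loa:.1f}"),
    ):
        ax.axhline(yv, linestyle=style, color="gray")
        ax.annotate(label, xy=(1.01, yv), xycoords=("axes fraction", "data"),
                    fontsize=8, va="center")
    ax.set_xlabel("mean of measured and predicted RMR (kcal/day)")
    ax.set_ylabel("predicted - measured (kcal/day)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
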