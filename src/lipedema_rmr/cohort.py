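"""Cohort container, subject-level validation, and delimited-text I/O.

A cohort is a table of women, one row per subject, with the twelve
anthropometric / body-composition predictors used throughout the package
and an optional column of resting metabolic rate (RMR) measured by
indirect calorimetry.  Column order is canonical and fixed:

    age height weight bmi lbm pbf mbf tbw vfl waist hips whr [rmr]

Units: years, cm, kg, kg/m^2, kg, %, kg, kg, level (dimensionless ordinal),
cm, cm, dimensionless, kcal/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

PREDICTORS: tuple[str, ...] = (
    "age", "height", "weight", "bmi", "lbm", "pbf",
    "mbf", "tbw", "vfl", "waist", "hips", "whr",
)
RMR_COLUMN = "rmr"
ALL_COLUMNS: tuple[str, ...] = PREDICTORS + (RMR_COLUMN,)

# strict-consistency tolerances: absorb instrument/display rounding
BMI_TOL = 0.1     # kg/m^2
WHR_TOL = 0.01
MASS_TOL = 0.5    # kg, for MBF and LBM identities


class CohortError(ValueError):
    """Base class for cohort I/O and validation failures."""


class SchemaError(CohortError):
    """Header is missing required columns or has unknown ones."""


class ParseError(CohortError):
    """A cell could not be read as a finite number."""


class ValidationError(CohortError):
    """A row violates a subject-level invariant."""


@dataclass
class SubjectRecord:
    """One subject's predictors and optional measured RMR.

    ``vfl`` is the Tanita visceral-fat level, an ordinal score; it is kept
    as a float for uniformity but generated/validated as a small positive
    integer-valued quantity.
    """

    age: float
    height: float
    weight: float
    bmi: float
    lbm: float
    pbf: float
    mbf: float
    tbw: float
    vfl: float
    waist: float
    hips: float
    whr: float
    rmr: Optional[float] = None

    def as_array(self) -> np.ndarray:
        """The 12 predictors in canonical order."""
        return np.array([getattr(self, c) for c in PREDICTORS], dtype=float)

    def validate(self, strict: bool = False, where: str = "record") -> None:
        """Check invariants; raise :class:`ValidationError` naming the field.

        Parameters
        ----------
        strict : bool
            Additionally enforce the deterministic anthropometric
            identities (BMI from weight/height, WHR from waist/hips,
            MBF from PBF and weight, LBM = weight - MBF) up to rounding
            tolerances.
        where : str
            Label (e.g. ``"row 3"``) used in error messages.
        """
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                if f.name == RMR_COLUMN:
                    continue
                raise ValidationError(f"{where}: field {f.name!r} is missing")
            if not math.isfinite(v):
                raise ValidationError(f"{where}: field {f.name!r} is not finite ({v!r})")
        for f in ("height", "weight", "waist", "hips"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"{where}: field {f!r} must be strictly positive")
        if not 0 < self.pbf < 100:
            raise ValidationError(
                f"{where}: field 'pbf' must lie in (0, 100), got {self.pbf}"
            )
        if strict:
            bmi = self.weight / (self.height / 100.0) ** 2
            if abs(self.bmi - bmi) > BMI_TOL:
                raise ValidationError(
                    f"{where}: bmi={self.bmi} inconsistent with weight/height^2={bmi:.3f}"
                )
            whr = self.waist / self.hips
            if abs(self.whr - whr) > WHR_TOL:
                raise ValidationError(
                    f"{where}: whr={self.whr} inconsistent with waist/hips={whr:.4f}"
                )
            mbf = self.pbf / 100.0 * self.weight
            if abs(self.mbf - mbf) > MASS_TOL:
                raise ValidationError(
                    f"{where}: mbf={self.mbf} inconsistent with pbf/100*weight={mbf:.3f}"
                )
            lbm = self.weight - self.mbf
            if abs(self.lbm - lbm) > MASS_TOL:
                raise ValidationError(
                    f"{where}: lbm={self.lbm} inconsistent with weight-mbf={lbm:.3f}"
                )


class Cohort:
    """An ordered, validated collection of :class:`SubjectRecord`.

    Backed by a :class:`pandas.DataFrame` in canonical column order.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "") -> None:
        if len(frame) == 0:
            raise ValidationError("cohort must be non-empty")
        missing = [c for c in PREDICTORS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        cols = list(PREDICTORS) + ([RMR_COLUMN] if RMR_COLUMN in frame.columns else [])
        self._frame = frame.loc[:, cols].reset_index(drop=True).astype(float)
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self._frame.equals(other._frame)

    # -- views --------------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The full table (copy), canonical column order."""
        return self._frame.copy()

    @property
    def predictors(self) -> pd.DataFrame:
        """The 12 predictor columns (copy)."""
        return self._frame.loc[:, list(PREDICTORS)].copy()

    @property
    def has_rmr(self) -> bool:
        return RMR_COLUMN in self._frame.columns

    @property
    def rmr(self) -> np.ndarray:
        if not self.has_rmr:
            raise ValidationError("cohort has no measured rmr column")
        return self._frame[RMR_COLUMN].to_numpy()

    @property
    def records(self) -> list[SubjectRecord]:
        out = []
        for row in self._frame.itertuples(index=False):
            d = row._asdict()
            out.append(SubjectRecord(**d))
        return out

    @classmethod
    def from_records(
        cls, records: Sequence[SubjectRecord], provenance: str = ""
    ) -> "Cohort":
        if not records:
            raise ValidationError("cohort must be non-empty")
        has_rmr = all(r.rmr is not None for r in records)
        cols = list(PREDICTORS) + ([RMR_COLUMN] if has_rmr else [])
        data = {c: [getattr(r, c) for r in records] for c in cols}
        return cls(pd.DataFrame(data), provenance=provenance)

    def validate(self, strict: bool = False) -> None:
        for i, rec in enumerate(self.records):
            rec.validate(strict=strict, where=f"row {i}")


def read_cohort(path, strict: bool = False) -> "Cohort":
    """Read a cohort from a canonical CSV file.

    The file must be comma-separated, dot-decimal UTF-8 with a header row
    containing the 12 predictor names (``rmr`` optional).  Lines starting
    with ``#`` are metadata comments and are skipped.  Every row is
    validated; ``strict=True`` additionally enforces the anthropometric
    identities.
    """
    raw = pd.read_csv(path, dtype=str, comment="#", skipinitialspace=True)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in PREDICTORS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    unknown = [c for c in raw.columns if c not in ALL_COLUMNS]
    if unknown:
        raise SchemaError(f"{path}: unknown columns: {unknown}")
    if len(raw) == 0:
        raise ValidationError(f"{path}: cohort must be non-empty")

    numeric = {}
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            cell = raw[col].iloc[i]
            raise ParseError(
                f"{path}: row {i}, column {col!r}: cannot parse {cell!r} as a number"
            )
        numeric[col] = vals.astype(float)
    frame = pd.DataFrame(numeric)
    cohort = Cohort(frame, provenance=str(path))
    cohort.validate(strict=strict)
    return cohort


def write_cohort(cohort: Cohort, path, metadata: str | None = None) -> None:
    """Write a cohort as canonical CSV.

    ``metadata``, when given, is written as a leading ``#`` comment line
    (skipped by :func:`read_cohort`).  Values are printed with 10
    significant digits, so a read/write round trip preserves every field
    well beyond 6 significant digits.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if metadata:
            fh.write(f"# {metadata}\n")
        cohort._frame.to_csv(fh, index=False, float_format="%.10g")


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-column mean and sample SD (n-1 denominator), as ``mean``/``sd``.

    With a single record the SD is undefined and reported as NaN.
    """
    frame = cohort._frame
    out = pd.DataFrame({"mean": frame.mean(axis=0), "sd": frame.std(axis=0, ddof=1)})
    return out
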