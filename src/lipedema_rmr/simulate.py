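"""Synthetic lipedema-cohort generator.

Emulates the statistical structure the modelling pipeline assumes: the
study cohort's marginal means and SDs, the deterministic anthropometric
identities (BMI, WHR, MBF, LBM), the resulting severe multicollinearity
among body-size predictors, and a resting metabolic rate driven linearly
by body composition plus measurement noise.

Structure
---------
* ``age`` and ``height`` are independent truncated Gaussians.
* A single standard-Gaussian *adiposity latent* A drives ``weight``,
  ``pbf``, ``waist``, ``hips`` and ``vfl``: each equals its mean plus
  ``loading * A`` plus an independent Gaussian residual, truncated to its
  bounds.  The shared latent is the minimal structure producing both the
  realistic weight-waist-PBF-VFL cross-correlations and the low effective
  rank that makes a handful of principal components dominant.
* ``bmi``, ``whr``, ``mbf``, ``lbm`` are computed exactly from their
  identities; ``tbw`` is the standard hydration fraction of lean mass
  (0.73) plus a small residual.
* ``rmr`` is Cunningham-like: intercept + 21 kcal/day/kg LBM
  + 4 kcal/day/kg MBF - 2 kcal/day/year age + Gaussian noise (SD
  110 kcal/day), with the intercept chosen in closed form so the
  population mean lands on the cohort target of 1685.8 kcal/day.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import Cohort

#: Cohort calibration targets (mean, SD) for the marginals the generator
#: draws directly; derived variables (bmi, whr, mbf, lbm, tbw) follow from
#: the identities and are not forced.
COHORT_TARGETS: dict[str, tuple[float, float]] = {
    "age": (43.4, 13.4),
    "height": (165.5, 6.8),
    "weight": (87.5, 21.8),
    "pbf": (37.7, 7.3),
    "vfl": (12.7, 5.1),
    "waist": (96.5, 17.5),
    "hips": (115.6, 13.6),
    "rmr": (1685.8, 310.4),
}


class GeneratorConfigError(ValueError):
    """Invalid or infeasible generator configuration."""


@dataclass(frozen=True)
class Marginal:
    """Marginal distribution of one directly-drawn variable.

    ``loading`` is the coefficient on the shared adiposity latent; the
    independent residual SD is ``sqrt(sd**2 - loading**2)`` so the
    marginal SD equals ``sd``.
    """

    mean: float
    sd: float
    lower: float
    upper: float
    loading: float = 0.0

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise GeneratorConfigError(f"{name}: sd must be >= 0")
        if not self.lower <= self.upper:
            raise GeneratorConfigError(f"{name}: truncation bounds out of order")
        if abs(self.loading) > self.sd:
            raise GeneratorConfigError(f"{name}: |loading| may not exceed sd")
        # infeasible truncation: the bounds exclude mean +/- 6 SD entirely
        if self.lower > self.mean + 6 * self.sd or self.upper < self.mean - 6 * self.sd:
            raise GeneratorConfigError(
                f"{name}: truncation bounds [{self.lower}, {self.upper}] exclude "
                f"mean +/- 6 SD"
            )

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(max(self.sd**2 - self.loading**2, 0.0)))


@dataclass(frozen=True)
class RMRModel:
    """Linear generative model for measured RMR (kcal/day)."""

    intercept: float
    slope_lbm: float = 21.0   # kcal/day per kg lean mass
    slope_mbf: float = 4.0    # kcal/day per kg fat mass
    slope_age: float = -2.0   # kcal/day per year
    noise_sd: float = 110.0   # kcal/day

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise GeneratorConfigError("rmr_model: noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 119
    seed: int = 0
    age: Marginal = field(default_factory=lambda: Marginal(43.4, 13.4, 0.0, 97.0))
    height: Marginal = field(
        default_factory=lambda: Marginal(165.5, 6.8, 138.3, 192.7)
    )
    weight: Marginal = field(
        default_factory=lambda: Marginal(87.5, 21.8, 30.0, 174.7, loading=19.62)
    )
    pbf: Marginal = field(
        default_factory=lambda: Marginal(37.7, 7.3, 8.5, 66.9, loading=6.205)
    )
    waist: Marginal = field(
        default_factory=lambda: Marginal(96.5, 17.5, 50.0, 166.5, loading=15.75)
    )
    hips: Marginal = field(
        default_factory=lambda: Marginal(115.6, 13.6, 61.2, 170.0, loading=12.24)
    )
    vfl: Marginal = field(
        default_factory=lambda: Marginal(12.7, 5.1, 1.0, 33.1, loading=4.59)
    )
    tbw_water_fraction: float = 0.73
    tbw_residual_sd: float = 1.5
    rmr_model: RMRModel = field(default_factory=lambda: RMRModel(intercept=516.6))

    def validate(self) -> None:
        if self.n < 2:
            raise GeneratorConfigError("n must be >= 2")
        for name in ("age", "height", "weight", "pbf", "waist", "hips", "vfl"):
            getattr(self, name).validate(name)
        if self.tbw_residual_sd < 0:
            raise GeneratorConfigError("tbw_residual_sd must be >= 0")
        self.rmr_model.validate()

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kw = dict(d)
        for name in ("age", "height", "weight", "pbf", "waist", "hips", "vfl"):
            if name in kw and isinstance(kw[name], dict):
                kw[name] = Marginal(**kw[name])
        if "rmr_model" in kw and isinstance(kw["rmr_model"], dict):
            kw["rmr_model"] = RMRModel(**kw["rmr_model"])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def expected_population_moments(config: GeneratorConfig) -> dict[str, float]:
    """Closed-form (untruncated) population means of the derived variables.

    cov(pbf, weight) = loading_pbf * loading_weight, so

        E[mbf] = (mean_pbf * mean_weight + loading_pbf * loading_weight) / 100
        E[lbm] = mean_weight - E[mbf]
    """
    e_mbf = (
        config.pbf.mean * config.weight.mean + config.pbf.loading * config.weight.loading
    ) / 100.0
    e_lbm = config.weight.mean - e_mbf
    m = config.rmr_model
    e_rmr = (
        m.intercept
        + m.slope_lbm * e_lbm
        + m.slope_mbf * e_mbf
        + m.slope_age * config.age.mean
    )
    return {"mbf": e_mbf, "lbm": e_lbm, "rmr": e_rmr}


def default_config(n: int = 119, seed: int = 0) -> GeneratorConfig:
    """The default generator configuration, calibrated to the study cohort.

    Marginal means/SDs equal the cohort targets for age, height, weight,
    PBF, VFL, waist and hips; the RMR intercept is solved in closed form
    so the untruncated population mean of RMR equals the 1685.8 kcal/day
    target given the default slopes.
    """
    cfg = GeneratorConfig(n=n, seed=seed)
    m = cfg.rmr_model
    mom = expected_population_moments(cfg)
    intercept = COHORT_TARGETS["rmr"][0] - (
        m.slope_lbm * mom["lbm"] + m.slope_mbf * mom["mbf"] + m.slope_age * cfg.age.mean
    )
    cfg = dataclasses.replace(cfg, rmr_model=dataclasses.replace(m, intercept=intercept))
    cfg.validate()
    return cfg


def _truncated_normal(
    rng: np.random.Generator, n: int, marg: Marginal, shift: np.ndarray | float = 0.0
) -> np.ndarray:
    """Truncated-normal draw around ``mean + shift`` via the inverse CDF.

    ``shift`` carries the latent contribution; truncation therefore acts on
    the conditional distribution given the latent (exact even when the
    conditional mean sits far outside the bounds).  With a degenerate
    residual (sd 0) values are clipped to the bounds instead.
    """
    from scipy.stats import truncnorm

    base = marg.mean + np.asarray(shift, dtype=float)
    sd = marg.residual_sd
    if sd == 0.0:
        return np.clip(np.broadcast_to(base, (n,)).astype(float), marg.lower, marg.upper)
    a = (marg.lower - base) / sd
    b = (marg.upper - base) / sd
    return truncnorm.rvs(a, b, loc=base, scale=sd, size=n, random_state=rng)


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw a synthetic cohort; identical seed implies bit-identical output."""
    if config is None:
        config = default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    age = _truncated_normal(rng, n, config.age)
    height = _truncated_normal(rng, n, config.height)
    latent = rng.standard_normal(n)

    weight = _truncated_normal(rng, n, config.weight, config.weight.loading * latent)
    pbf = _truncated_normal(rng, n, config.pbf, config.pbf.loading * latent)
    waist = _truncated_normal(rng, n, config.waist, config.waist.loading * latent)
    hips = _truncated_normal(rng, n, config.hips, config.hips.loading * latent)
    vfl_raw = _truncated_normal(rng, n, config.vfl, config.vfl.loading * latent)
    vfl = np.clip(np.rint(vfl_raw), 1.0, 59.0)

    bmi = weight / (height / 100.0) ** 2
    whr = waist / hips
    mbf = pbf / 100.0 * weight
    lbm = weight - mbf
    tbw = config.tbw_water_fraction * lbm + (
        rng.normal(0.0, config.tbw_residual_sd, size=n)
        if config.tbw_residual_sd > 0
        else 0.0
    )
    m = config.rmr_model
    rmr = (
        m.intercept
        + m.slope_lbm * lbm
        + m.slope_mbf * mbf
        + m.slope_age * age
        + (rng.normal(0.0, m.noise_sd, size=n) if m.noise_sd > 0 else 0.0)
    )

    frame = {
        "age": age, "height": height, "weight": weight, "bmi": bmi,
        "lbm": lbm, "pbf": pbf, "mbf": mbf, "tbw": tbw, "vfl": vfl,
        "waist": waist, "hips": hips, "whr": whr, "rmr": rmr,
    }
    import pandas as pd

    return Cohort(
        pd.DataFrame(frame),
        provenance=f"synthetic seed={config.seed} n={config.n}",
    )
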