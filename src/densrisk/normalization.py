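"""Standardization of continuous percent mammographic density.

Raw percent density (area-based or volumetric) depends strongly on age and
BMI.  To use it as a fixed covariate in an age-indexed hazard model, the
pipeline (i) regresses percent density linearly on age at entry and,
when available, BMI (no interaction); (ii) applies a two-parameter Box-Cox
transform to the residuals to make them Gaussian; (iii) standardizes the
transformed values to mean 0 and SD 1.  The fitted block of parameters is
what a deployed model ships, so new women need only their raw density (and
age / BMI) to be scored.

Two covariate sets are supported — ``age_only`` and ``age_bmi`` — fitted
separately per density tool (STRATUS percent area, Volpara percent
volume), mirroring the BMI-present / BMI-absent duality of the risk model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "NormalizationParams",
    "DensityNormalizer",
    "fit_residual_regression",
    "fit_boxcox",
    "standardize_density",
]

#: profile-likelihood grid for the Box-Cox exponent
BOXCOX_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 10)


@dataclass(frozen=True)
class NormalizationParams:
    """Fitted residualization + Box-Cox + standardization block.

    ``coeffs`` maps covariate name ('intercept', 'age', optionally 'bmi')
    to the linear-regression coefficient on the percent scale.
    ``boxcox_shift`` is the additive constant c making every shifted
    training residual strictly positive (min residual + c =
    ``shift_offset``); ``mean``/``sd`` standardize the transformed scale.
    """

    tool: str
    covariate_set: str
    coeffs: dict[str, float]
    boxcox_lambda: float
    boxcox_shift: float
    mean: float
    sd: float
    shift_offset: float = 1.0
    clamp_policy: str = "clamp"

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("standardization SD must be positive")
        if self.covariate_set not in ("age_only", "age_bmi"):
            raise ValueError("covariate_set must be 'age_only' or 'age_bmi'")
        if self.clamp_policy not in ("clamp", "raise"):
            raise ValueError("clamp_policy must be 'clamp' or 'raise'")

    def to_dict(self) -> dict:
        return {
            "tool": self.tool,
            "covariate_set": self.covariate_set,
            "coeffs": dict(self.coeffs),
            "boxcox_lambda": float(self.boxcox_lambda),
            "boxcox_shift": float(self.boxcox_shift),
            "mean": float(self.mean),
            "sd": float(self.sd),
            "shift_offset": float(self.shift_offset),
            "clamp_policy": self.clamp_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(**d)


def fit_residual_regression(density, age, bmi=None):
    """Ordinary least squares of percent density on age (and optionally BMI).

    Returns ``(coeffs, residuals)``; rows with any missing value among the
    used columns are dropped before fitting, and residuals are returned for
    the complete rows in their original order.
    """
    density = np.asarray(density, dtype=float)
    age = np.asarray(age, dtype=float)
    cols = [np.ones_like(age), age]
    names = ["intercept", "age"]
    if bmi is not None:
        bmi = np.asarray(bmi, dtype=float)
        cols.append(bmi)
        names.append("bmi")
    X = np.column_stack(cols)
    mask = np.isfinite(density) & np.all(np.isfinite(X), axis=1)
    if not mask.any():
        raise ValueError("density is entirely missing")
    Xc, yc = X[mask], density[mask]
    if len(yc) < 3:
        raise ValueError("need at least 3 complete rows")
    for j, name in enumerate(names[1:], start=1):
        if np.std(Xc[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    residuals = yc - Xc @ beta
    return dict(zip(names, (float(b) for b in beta))), residuals


def fit_boxcox(residuals, shift_offset: float = 1.0, grid=BOXCOX_GRID):
    """Two-parameter Box-Cox fit of the density residuals.

    The shift c is set so that the smallest shifted residual equals
    ``shift_offset`` (strictly positive); the exponent maximizes the
    Gaussian profile log-likelihood of ((r+c)^lam - 1)/lam over ``grid``.
    Returns ``(lambda, shift, mean, sd)`` with mean/SD of the transformed
    sample, so standardizing reproduces an exactly mean-0 / SD-1 training
    sample.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    if len(r) < 10:
        raise ValueError("need at least 10 residuals")
    if np.ptp(r) == 0:
        raise ValueError("residuals are degenerate (all equal)")
    shift = -float(np.min(r)) + float(shift_offset)
    y = r + shift
    llf = np.array([stats.boxcox_llf(lam, y) for lam in np.asarray(grid)])
    lam = float(np.asarray(grid)[int(np.argmax(llf))])
    t = special.boxcox(y, lam)
    return lam, shift, float(np.mean(t)), float(np.std(t, ddof=1))


def standardize_density(x, age, bmi, params: NormalizationParams):
    """Score raw percent density into SD units using a fitted parameter block.

    ``z = (boxcox(x - predicted(age[, bmi]) + shift) - mean) / sd``.  Values
    whose shifted residual is not strictly positive lie below the
    transformable range; per ``params.clamp_policy`` they are clamped to
    the smallest training shifted residual (with a warning) or rejected.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    age = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any((x < 0) | (x > 100)):
        raise ValueError("percent density must lie in [0, 100]")
    pred = params.coeffs["intercept"] + params.coeffs["age"] * age
    if params.covariate_set == "age_bmi":
        if bmi is None:
            raise ValueError("params expect BMI but none was given")
        bmi = np.atleast_1d(np.asarray(bmi, dtype=float))
        if np.any(~np.isfinite(bmi)):
            raise ValueError("params expect BMI but it is missing")
        pred = pred + params.coeffs["bmi"] * bmi
    shifted = x - pred + params.boxcox_shift
    below = shifted <= 0
    if below.any():
        if params.clamp_policy == "raise":
            raise ValueError("density below transformable range")
        warnings.warn(
            f"{int(below.sum())} value(s) below transformable range; "
            "clamped to the training minimum",
            stacklevel=2,
        )
        shifted = np.where(below, params.shift_offset, shifted)
    z = (special.boxcox(shifted, params.boxcox_lambda) - params.mean) / params.sd
    return float(z[0]) if scalar else z


class DensityNormalizer:
    """Model-style wrapper: fit the full standardization block from a cohort.

    Parameters
    ----------
    tool : 'stratus' or 'volpara' — which density column to standardize
        ('pmd' and 'pvd' respectively).
    covariate_set : 'age_only' or 'age_bmi'.
    """

    _COLUMN = {"stratus": "pmd", "volpara": "pvd"}

    def __init__(self, tool="stratus", covariate_set="age_bmi", shift_offset=1.0,
                 grid=BOXCOX_GRID, clamp_policy="clamp"):
        if tool not in self._COLUMN:
            raise ValueError("tool must be 'stratus' or 'volpara'")
        self.tool = tool
        self.covariate_set = covariate_set
        self.shift_offset = shift_offset
        self.grid = grid
        self.clamp_policy = clamp_policy
        self.params_: NormalizationParams | None = None

    def fit(self, cohort) -> NormalizationParams:
        density = cohort[self._COLUMN[self.tool]].to_numpy(dtype=float)
        age = cohort["age_entry"].to_numpy(dtype=float)
        bmi = (
            cohort["bmi"].to_numpy(dtype=float)
            if self.covariate_set == "age_bmi"
            else None
        )
        coeffs, residuals = fit_residual_regression(density, age, bmi)
        lam, shift, mean, sd = fit_boxcox(residuals, self.shift_offset, self.grid)
        self.params_ = NormalizationParams(
            tool=self.tool,
            covariate_set=self.covariate_set,
            coeffs=coeffs,
            boxcox_lambda=lam,
            boxcox_shift=shift,
            mean=mean,
            sd=sd,
            shift_offset=self.shift_offset,
            clamp_policy=self.clamp_policy,
        )
        return self.params_

    def transform(self, x, age, bmi=None):
        if self.params_ is None:
            raise RuntimeError("call fit() first")
        return standardize_density(x, age, bmi, self.params_)

    def fit_transform(self, cohort):
        self.fit(cohort)
        density = cohort[self._COLUMN[self.tool]].to_numpy(dtype=float)
        age = cohort["age_entry"].to_numpy(dtype=float)
        bmi = cohort["bmi"].to_numpy(dtype=float) if self.covariate_set == "age_bmi" else None
        return self.transform(density, age, bmi)
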