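"""Hazard-ratio estimation for standardized residual density.

Cox proportional-hazards fits on the age scale (left truncation at the age
at entry, Efron tie handling), reporting the hazard ratio per SD of the
standardized residual density.  A binary menopausal-status interaction
yields separate pre- and postmenopausal slopes; the unknown-status HR is a
separate no-interaction fit on all women.  Inverse-probability-of-inclusion
weights support the genotyped (PGS) subcohort design, and a least-squares
attenuation line maps PGS-unadjusted to PGS-adjusted log-HRs.

The partial-likelihood maximization is delegated to
``lifelines.CoxPHFitter``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "HazardEstimates",
    "DensityCoxModel",
    "to_survival_records",
    "fit_density_hazards",
    "inclusion_weights",
    "AttenuationLine",
    "pgs_attenuation_line",
]

DEFAULT_QRF_COLS = ("height", "alcohol", "hormone_use")


@dataclass
class HazardEstimates:
    """Results container for a density Cox fit.

    Hazard ratios are per SD of the standardized residual density; a pre /
    post pair comes from an interaction fit, the unknown-status value from
    a no-interaction fit.  Confidence intervals are Wald intervals from the
    observed information.
    """

    hr_pre: float | None = None
    hr_post: float | None = None
    hr_unknown: float | None = None
    ci_pre: tuple[float, float] | None = None
    ci_post: tuple[float, float] | None = None
    ci_unknown: tuple[float, float] | None = None
    adjusted_for_pgs: bool = False
    adjustment_covariates: tuple[str, ...] = ()
    log_likelihood: float = math.nan
    n: int = 0
    n_events: int = 0
    coefficients: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        for hr, ci in ((self.hr_pre, self.ci_pre), (self.hr_post, self.ci_post),
                       (self.hr_unknown, self.ci_unknown)):
            if hr is not None:
                if hr <= 0:
                    raise ValueError("hazard ratios must be positive")
                if ci is not None and not ci[0] < hr < ci[1]:
                    raise ValueError("CI must bracket the point estimate")

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, hr, ci in (
            ("premenopausal", self.hr_pre, self.ci_pre),
            ("postmenopausal", self.hr_post, self.ci_post),
            ("unknown status", self.hr_unknown, self.ci_unknown),
        ):
            if hr is not None:
                rows.append(
                    {"stratum": label, "hr_per_sd": hr,
                     "ci_low": ci[0] if ci else math.nan,
                     "ci_high": ci[1] if ci else math.nan}
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "hr_pre": self.hr_pre,
            "hr_post": self.hr_post,
            "hr_unknown": self.hr_unknown,
            "ci_pre": list(self.ci_pre) if self.ci_pre else None,
            "ci_post": list(self.ci_post) if self.ci_post else None,
            "ci_unknown": list(self.ci_unknown) if self.ci_unknown else None,
            "adjusted_for_pgs": self.adjusted_for_pgs,
            "adjustment_covariates": list(self.adjustment_covariates),
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "n_events": self.n_events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HazardEstimates":
        d = dict(d)
        for k in ("ci_pre", "ci_post", "ci_unknown"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        d["adjustment_covariates"] = tuple(d.get("adjustment_covariates", ()))
        return cls(**d)


def to_survival_records(
    cohort: pd.DataFrame,
    z: np.ndarray,
    adjustment_cols=DEFAULT_QRF_COLS,
    include_fh: bool = True,
    include_pgs: bool = False,
    split_menopause: bool = True,
    expected_menopause_age: float = 51.0,
) -> pd.DataFrame:
    """Build Cox records on the age scale from a cohort table.

    Each woman contributes (entry_age, exit_age] with event flag 1 for
    invasive breast cancer.  With ``split_menopause`` the follow-up of a
    woman who passes her age at menopause is episode-split at the first
    whole follow-up year starting at or after it, so the binary ``post``
    column tracks current status — consistent with a hazard whose density
    effect switches at menopause.  Family history enters as two dummies
    (1 vs 0 and 2+ vs 0 affected first-degree relatives).
    """
    entry = cohort["age_entry"].to_numpy(dtype=float)
    exit_ = entry + cohort["time"].to_numpy(dtype=float)
    event = (cohort["event"] == "invasive_bc").astype(int).to_numpy()
    menop = cohort["age_menopause"].to_numpy(dtype=float)
    menop = np.where(np.isfinite(menop), menop, expected_menopause_age)
    switch = entry + np.ceil(np.maximum(menop - entry, 0.0))

    base = {"z": np.asarray(z, dtype=float)}
    for c in adjustment_cols:
        base[c] = cohort[c].to_numpy(dtype=float)
    if include_fh:
        fh = cohort["fh_category"].to_numpy()
        base["fh_1"] = (fh == 1).astype(float)
        base["fh_2plus"] = (fh >= 2).astype(float)
    if include_pgs:
        base["pgs"] = cohort["pgs"].to_numpy(dtype=float)

    if not split_menopause:
        post = (cohort["menopause_status"] == "post").astype(float).to_numpy()
        return pd.DataFrame(
            {"entry_age": entry, "exit_age": exit_, "event_flag": event,
             "post": post, "source_row": np.arange(len(entry)), **base}
        )

    needs_split = (switch > entry) & (switch < exit_)
    pre_rows = {
        "entry_age": entry,
        "exit_age": np.where(needs_split, switch, exit_),
        "event_flag": np.where(needs_split, 0, event),
        "post": (switch <= entry).astype(float),
        "source_row": np.arange(len(entry)),
        **base,
    }
    first = pd.DataFrame(pre_rows)
    if needs_split.any():
        idx = np.flatnonzero(needs_split)
        second = pd.DataFrame(
            {"entry_age": switch[idx], "exit_age": exit_[idx],
             "event_flag": event[idx], "post": 1.0, "source_row": idx,
             **{k: np.asarray(v)[idx] for k, v in base.items()}}
        )
        return pd.concat([first, second], ignore_index=True)
    return first


class DensityCoxModel:
    """Cox model of invasive-breast-cancer hazard on the age scale.

    Parameters
    ----------
    records : DataFrame with columns ``entry_age``, ``exit_age``,
        ``event_flag``, the density column, optional interaction column,
        adjustment columns, optional ``weight``.
    density_col : name of the per-SD density covariate.
    interaction_col : binary pre(0)/post(1) column; when given, the fit
        reports stratum-specific pre and post hazard ratios (the status
        main effect is always included alongside the interaction).
    adjustment_cols : additional covariates entered additively on the log
        hazard scale.
    weights_col : positive case weights (inverse inclusion probabilities).
    """

    def __init__(self, records: pd.DataFrame, density_col: str = "z",
                 interaction_col: str | None = None, adjustment_cols=(),
                 weights_col: str | None = None, adjusted_for_pgs: bool = False):
        self.records = records
        self.density_col = density_col
        self.interaction_col = interaction_col
        self.adjustment_cols = tuple(adjustment_cols)
        self.weights_col = weights_col
        self.adjusted_for_pgs = adjusted_for_pgs

    def fit(self, alpha: float = 0.05) -> HazardEstimates:
        df = self.records
        if int(df["event_flag"].sum()) == 0:
            raise ValueError("no events in the data")
        z = df[self.density_col].to_numpy(dtype=float)
        if np.std(z) == 0:
            raise ValueError("density column is constant")
        if not np.all(df["exit_age"].to_numpy() > df["entry_age"].to_numpy()):
            raise ValueError("exit_age must exceed entry_age for every record")

        fit_df = pd.DataFrame(
            {"entry_age": df["entry_age"], "exit_age": df["exit_age"],
             "event_flag": df["event_flag"]}
        )
        if self.interaction_col is not None:
            post = df[self.interaction_col].to_numpy(dtype=float)
            if not set(np.unique(post)) <= {0.0, 1.0}:
                raise ValueError("interaction column must be binary pre(0)/post(1)")
            fit_df["z_pre"] = z * (1.0 - post)
            fit_df["z_post"] = z * post
            fit_df["post"] = post
        else:
            fit_df["z"] = z
        for c in self.adjustment_cols:
            fit_df[c] = df[c].to_numpy(dtype=float)
        kwargs = {}
        if self.weights_col is not None:
            w = df[self.weights_col].to_numpy(dtype=float)
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            fit_df["weight"] = w
            kwargs = {"weights_col": "weight", "robust": True}

        cph = CoxPHFitter()
        try:
            cph.fit(
                fit_df,
                duration_col="exit_age",
                event_col="event_flag",
                entry_col="entry_age",
                fit_options={"precision": 1e-9, "max_steps": 500},
                **kwargs,
            )
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox fit did not converge: {exc}") from exc

        summ = cph.summary
        ci_cols = [c for c in summ.columns if c.endswith("lower 95%")][0], [
            c for c in summ.columns if c.endswith("upper 95%")
        ][0]

        def _hr(name):
            row = summ.loc[name]
            return (
                float(np.exp(row["coef"])),
                (float(np.exp(row[ci_cols[0]])), float(np.exp(row[ci_cols[1]]))),
            )

        est = HazardEstimates(
            adjusted_for_pgs=self.adjusted_for_pgs,
            adjustment_covariates=self.adjustment_cols,
            log_likelihood=float(cph.log_likelihood_),
            n=len(df),
            n_events=int(df["event_flag"].sum()),
            coefficients=summ,
        )
        if self.interaction_col is not None:
            est.hr_pre, est.ci_pre = _hr("z_pre")
            est.hr_post, est.ci_post = _hr("z_post")
        else:
            est.hr_unknown, est.ci_unknown = _hr("z")
        return est


def fit_density_hazards(
    cohort: pd.DataFrame,
    z: np.ndarray,
    adjustment_cols=DEFAULT_QRF_COLS,
    include_pgs: bool = False,
    weights: np.ndarray | None = None,
    split_menopause: bool = True,
) -> HazardEstimates:
    """Convenience front end: interaction fit plus the unknown-status fit.

    Returns one :class:`HazardEstimates` carrying the pre/post pair from
    the menopause-interaction model and the unknown-status HR from a
    separate no-interaction model on all women.
    """
    records = to_survival_records(
        cohort, z, adjustment_cols=adjustment_cols, include_pgs=include_pgs,
        split_menopause=split_menopause,
    )
    adj = list(adjustment_cols) + ["fh_1", "fh_2plus"] + (["pgs"] if include_pgs else [])
    if weights is not None:
        # weights are per woman; episode splitting repeats them per record
        wcol = np.asarray(weights, dtype=float)[records["source_row"].to_numpy()]
        records = records.assign(weight=wcol)
    inter = DensityCoxModel(
        records, "z", interaction_col="post", adjustment_cols=adj,
        weights_col="weight" if weights is not None else None,
        adjusted_for_pgs=include_pgs,
    ).fit()
    no_inter = DensityCoxModel(
        records, "z", interaction_col=None, adjustment_cols=adj,
        weights_col="weight" if weights is not None else None,
        adjusted_for_pgs=include_pgs,
    ).fit()
    inter.hr_unknown, inter.ci_unknown = no_inter.hr_unknown, no_inter.ci_unknown
    return inter


def inclusion_weights(
    cohort: pd.DataFrame,
    case_fraction: float,
    control_fraction: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a genotyped-style subcohort and attach inverse-probability weights.

    Cases (invasive breast cancer) are sampled with probability
    ``case_fraction`` and all other women with ``control_fraction``;
    sampled rows get weight 1/probability and unsampled rows are dropped.
    """
    for f in (case_fraction, control_fraction):
        if not 0 < f <= 1:
            raise ValueError("sampling fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    is_case = (cohort["event"] == "invasive_bc").to_numpy()
    p = np.where(is_case, case_fraction, control_fraction)
    keep = rng.random(len(cohort)) < p
    sub = cohort.loc[keep].copy()
    sub["weight"] = 1.0 / p[keep]
    return sub


@dataclass(frozen=True)
class AttenuationLine:
    """Least-squares line mapping PGS-unadjusted to PGS-adjusted log-HRs."""

    slope: float
    intercept: float

    def predict(self, log_hr_unadjusted):
        return self.slope * np.asarray(log_hr_unadjusted, dtype=float) + self.intercept


def pgs_attenuation_line(estimate_pairs) -> AttenuationLine:
    """Fit the attenuation line through (log-HR unadjusted, adjusted) pairs.

    Used to project the PGS-adjusted effect size onto the full cohort where
    only a subcohort carries genotype data.  Requires at least two pairs
    with distinct x values.
    """
    pairs = np.asarray(estimate_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need at least two (unadjusted, adjusted) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("x values are identical; line is underdetermined")
    slope, intercept = np.polyfit(x, y, 1)
    return AttenuationLine(float(slope), float(intercept))
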