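"""Model performance battery: calibration, discrimination, reclassification.

Implements the standard validation toolkit for 5-year absolute-risk
predictions: the calibration slope (logistic regression of outcome on the
log-odds of predicted risk), quantile calibration with exact Poisson
intervals on observed counts, the ROC AUC with a DeLong confidence
interval, risk categorization at guideline thresholds, the
reclassification matrix between two models and the absolute net
reclassification improvement (NRI, range [-2, 2]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FOUR_CATEGORY_THRESHOLDS",
    "FIVE_CATEGORY_THRESHOLDS",
    "calibration_slope",
    "quantile_calibration",
    "auc",
    "classify_risk",
    "reclassification_matrix",
    "nri",
    "ValidationReport",
    "ModelValidation",
]

#: guideline 5-year risk category boundaries: <1%, [1%, 1.67%), [1.67%, 3%), >=3%
FOUR_CATEGORY_THRESHOLDS = (0.01, 0.0167, 0.03)
#: the lowest category further split at 0.35% (about half the 5-year
#: population risk of a 40-year-old) to resolve low-risk subpopulations
FIVE_CATEGORY_THRESHOLDS = (0.0035, 0.01, 0.0167, 0.03)


def _check_binary(outcome):
    outcome = np.asarray(outcome, dtype=float)
    if not set(np.unique(outcome)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if outcome.sum() == 0 or outcome.sum() == len(outcome):
        raise ValueError("need at least one case and one non-case")
    return outcome.astype(int)


def calibration_slope(predicted, outcome, alpha: float = 0.05):
    """Slope of a logistic regression of outcome on logit(predicted risk).

    A slope of 1 means the spread of predicted risks matches the outcome
    odds; below 1 indicates overdispersed (too extreme) predictions.
    Returns ``(slope, (lower, upper))`` with a Wald interval.
    """
    p = np.asarray(predicted, dtype=float)
    y = _check_binary(outcome)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted risks must lie strictly in (0, 1)")
    x = np.log(p / (1 - p))
    if np.ptp(x) == 0:
        raise ValueError("predictions are constant; slope undefined")
    res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    slope = float(res.params[1])
    se = float(res.bse[1])
    zq = stats.norm.ppf(1 - alpha / 2)
    return slope, (slope - zq * se, slope + zq * se)


def quantile_calibration(predicted, outcome, n_bins: int = 5) -> pd.DataFrame:
    """Observed vs mean predicted risk in equal-count bins of predicted risk.

    Ties are broken by stable input order.  The 95% interval on the
    observed proportion is the exact Poisson interval on the case count,
    scaled by the bin size; zero observed cases give a lower bound of 0.
    """
    p = np.asarray(predicted, dtype=float)
    y = _check_binary(outcome)
    n = len(p)
    if n < n_bins:
        raise ValueError("need at least as many observations as bins")
    distinct = len(np.unique(p))
    if distinct < n_bins:
        warnings.warn(
            f"only {distinct} distinct predictions; merged to {distinct} bins",
            stacklevel=2,
        )
        n_bins = distinct
    order = np.argsort(p, kind="stable")
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    rows = []
    pos = 0
    for b in range(n_bins):
        idx = order[pos : pos + sizes[b]]
        pos += sizes[b]
        k = int(y[idx].sum())
        m = len(idx)
        lo = 0.0 if k == 0 else stats.chi2.ppf(0.025, 2 * k) / 2.0 / m
        hi = stats.chi2.ppf(0.975, 2 * k + 2) / 2.0 / m
        rows.append(
            {
                "bin": b + 1,
                "n": m,
                "mean_predicted": float(p[idx].mean()),
                "observed": k / m,
                "observed_low": lo,
                "observed_high": hi,
            }
        )
    return pd.DataFrame(rows)


def auc(predicted, outcome, alpha: float = 0.05):
    """ROC AUC (Mann-Whitney estimator, ties counted 1/2) with DeLong CI.

    Returns ``(auc, (lower, upper))``; the interval is clipped to [0, 1]
    and degenerates to the point for perfectly separated data.
    """
    p = np.asarray(predicted, dtype=float)
    y = _check_binary(outcome)
    pos = p[y == 1]
    neg = p[y == 0]
    m, n = len(pos), len(neg)

    # midranks over the pooled sample give the placement values
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    r_pos, r_neg = all_r[:m], all_r[m:]
    a = (r_pos.sum() - m * (m + 1) / 2) / (m * n)

    # DeLong structural components
    v10 = (r_pos - stats.rankdata(pos)) / n
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    zq = stats.norm.ppf(1 - alpha / 2)
    half = zq * np.sqrt(var)
    return float(a), (float(max(a - half, 0.0)), float(min(a + half, 1.0)))


def classify_risk(predicted, thresholds=FOUR_CATEGORY_THRESHOLDS):
    """Assign ordered risk categories with half-open [lo, hi) intervals.

    Category 0 is below the first threshold; the top category is closed
    above at 1.  Thresholds must be strictly increasing within (0, 1).
    """
    th = np.asarray(thresholds, dtype=float)
    if np.any((th <= 0) | (th >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    if np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    p = np.asarray(predicted, dtype=float)
    return np.searchsorted(th, p, side="right")


def reclassification_matrix(old_categories, new_categories, n_categories: int | None = None):
    """Counts of women moving between old (rows) and new (columns) categories."""
    old = np.asarray(old_categories, dtype=int)
    new = np.asarray(new_categories, dtype=int)
    if old.shape != new.shape:
        raise ValueError("category vectors must have the same length")
    k = n_categories or int(max(old.max(), new.max())) + 1
    mat = np.zeros((k, k), dtype=int)
    np.add.at(mat, (old, new), 1)
    return mat


def nri(old_categories, new_categories, outcome) -> float:
    """Absolute net reclassification improvement across ordered categories.

    ``[P(up|case) - P(down|case)] + [P(down|non-case) - P(up|non-case)]``,
    bounded in [-2, 2]; positive when the new model moves cases up and
    non-cases down.
    """
    old = np.asarray(old_categories, dtype=int)
    new = np.asarray(new_categories, dtype=int)
    y = _check_binary(outcome)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("inputs must have the same length")
    up = new > old
    down = new < old
    case = y == 1
    nri_cases = up[case].mean() - down[case].mean()
    nri_ctrls = down[~case].mean() - up[~case].mean()
    return float(nri_cases + nri_ctrls)


@dataclass
class ValidationReport:
    """Collected performance metrics for one model (optionally vs a baseline)."""

    n: int
    n_cases: int
    calibration_slope: float
    calibration_slope_ci: tuple
    auc: float
    auc_ci: tuple
    quantile_table: pd.DataFrame
    category_proportions: np.ndarray
    thresholds: tuple
    reclassification: np.ndarray | None = None
    nri: float | None = None

    def __post_init__(self):
        if abs(self.category_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("category proportions must sum to 1")

    def summary(self) -> str:
        lines = [
            f"n = {self.n} ({self.n_cases} cases)",
            "calibration slope = {:.3f} (95% CI {:.3f} to {:.3f})".format(
                self.calibration_slope, *self.calibration_slope_ci
            ),
            "AUC = {:.3f} (95% CI {:.3f} to {:.3f})".format(self.auc, *self.auc_ci),
            "category proportions: "
            + ", ".join(f"{p:.3f}" for p in self.category_proportions),
        ]
        if self.nri is not None:
            lines.append(f"NRI vs baseline = {self.nri:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "n_cases": self.n_cases,
            "calibration_slope": self.calibration_slope,
            "calibration_slope_ci": list(self.calibration_slope_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "quantile_table": self.quantile_table.to_dict(orient="records"),
            "category_proportions": self.category_proportions.tolist(),
            "thresholds": list(self.thresholds),
        }
        if self.reclassification is not None:
            d["reclassification"] = self.reclassification.tolist()
            d["nri"] = self.nri
        return d


class ModelValidation:
    """Run the full battery for a risk model on a cohort with follow-up.

    Observed 5-year status: a woman is a case if she developed invasive
    breast cancer within the prediction window (the horizon starting one
    landmark year after entry) and unaffected if she developed it later;
    women censored before the window closes keep their observed status
    (``censor_rule='observed'``) or are dropped (``'drop'``).
    """

    def __init__(self, model, cohort, baseline_model=None, horizon: float = 5.0,
                 thresholds=FOUR_CATEGORY_THRESHOLDS, landmark: float = 1.0,
                 censor_rule: str = "observed"):
        if censor_rule not in ("observed", "drop"):
            raise ValueError("censor_rule must be 'observed' or 'drop'")
        self.model = model
        self.cohort = cohort
        self.baseline_model = baseline_model
        self.horizon = horizon
        self.thresholds = tuple(thresholds)
        self.landmark = landmark
        self.censor_rule = censor_rule

    def observed_outcome(self):
        t = self.cohort["time"].to_numpy(dtype=float)
        ev = self.cohort["event"].to_numpy()
        window_end = self.landmark + self.horizon
        keep = t > self.landmark
        if self.censor_rule == "drop":
            complete = (t >= window_end) | ((ev == "invasive_bc") & (t <= window_end))
            keep &= complete
        y = ((ev == "invasive_bc") & (t <= window_end)).astype(int)
        return keep, y

    def run(self) -> ValidationReport:
        keep, y = self.observed_outcome()
        cohort = self.cohort.loc[keep]
        y = y[keep]
        pred = self.model.predict(cohort, horizon=self.horizon, start_offset=self.landmark)
        p = pred.frame["risk"].to_numpy()
        valid = np.isfinite(p)
        p, y = p[valid], y[valid]

        slope, slope_ci = calibration_slope(p, y)
        a, a_ci = auc(p, y)
        qt = quantile_calibration(p, y)
        cats = classify_risk(p, self.thresholds)
        k = len(self.thresholds) + 1
        props = np.bincount(cats, minlength=k) / len(cats)

        reclass = nri_val = None
        if self.baseline_model is not None:
            bpred = self.baseline_model.predict(
                cohort, horizon=self.horizon, start_offset=self.landmark
            )
            bp = bpred.frame["risk"].to_numpy()[valid]
            old = classify_risk(bp, self.thresholds)
            reclass = reclassification_matrix(old, cats, k)
            nri_val = nri(old, cats, y)

        return ValidationReport(
            n=len(y),
            n_cases=int(y.sum()),
            calibration_slope=slope,
            calibration_slope_ci=slope_ci,
            auc=a,
            auc_ci=a_ci,
            quantile_table=qt,
            category_proportions=props,
            thresholds=self.thresholds,
            reclassification=reclass,
            nri=nri_val,
        )
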