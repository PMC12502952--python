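"""Multifactorial absolute breast-cancer risk engine.

The model is multiplicative on the hazard scale: each woman's annual
invasive-cancer hazard is a population baseline times
``exp(linear predictor)``, where the linear predictor adds per-factor log
relative risks — continuous mammographic density (per SD of the
standardized residual, with separate pre- and postmenopausal effects) or a
four-category BIRADS term, questionnaire risk factors, family history and
an optional polygenic score.  The baseline is *constrained* to population
incidence: for every age and calendar period it is the registry rate
divided by the population-mean relative risk, so that the model averaged
over the risk-factor distributions reproduces the observed incidence
exactly.  Absolute risks come from a discrete annual recursion with
competing all-cause mortality.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import NormalizationParams, standardize_density
from .rates import RateTable, synthetic_bc_incidence, synthetic_mortality

__all__ = [
    "RiskFactorDistributions",
    "AbsoluteRiskModel",
    "RiskPredictions",
    "DEFAULT_DENSITY_HR",
    "DEFAULT_BIRADS_LOG_RR",
]

#: reference per-SD hazard ratios for the standardized residual density,
#: by tool and menopausal stratum; the "adjusted" set is used when a
#: polygenic score is part of the input combination (its correlation with
#: density slightly attenuates the density effect).
DEFAULT_DENSITY_HR = {
    "unadjusted": {
        "stratus": {"pre": 1.48, "post": 1.41, "unknown": 1.44},
        "volpara": {"pre": 1.27, "post": 1.38, "unknown": 1.32},
    },
    "adjusted": {
        "stratus": {"pre": 1.45, "post": 1.38, "unknown": 1.41},
        "volpara": {"pre": 1.26, "post": 1.37, "unknown": 1.31},
    },
}

#: default log relative risks for BIRADS categories 1-4 (relative to the
#: population-typical category 2)
DEFAULT_BIRADS_LOG_RR = tuple(math.log(r) for r in (0.55, 1.00, 1.45, 2.05))

_DEFAULT_QRF_LOG_RR = {
    "height": math.log(1.10),
    "alcohol": math.log(1.08),
    "hormone_use": (0.0, math.log(1.3)),
}
_DEFAULT_FH_LOG_RR = (0.0, math.log(1.8), math.log(2.9))


@dataclass(frozen=True)
class RiskFactorDistributions:
    """Population distributions used for the baseline constraint.

    BIRADS probabilities are age-band specific (below / at-or-above 50
    years of attained age); continuous factors (standardized density,
    z-scored QRFs, PGS) are standard normal; the age-at-menopause
    distribution mixes the pre/post density effects during projection.
    """

    birads_probs: dict = field(
        default_factory=lambda: {
            "lt50": (0.08, 0.37, 0.43, 0.12),
            "ge50": (0.13, 0.45, 0.34, 0.08),
        }
    )
    qrf: dict = field(
        default_factory=lambda: {
            "height": "normal",
            "alcohol": "normal",
            "hormone_use": (0.8, 0.2),
        }
    )
    fh_probs: tuple = (0.88, 0.105, 0.015)
    menopause_age_mean: float = 51.0
    menopause_age_sd: float = 4.0
    menopause_age_bounds: tuple = (40.0, 60.0)

    def __post_init__(self):
        for band, p in self.birads_probs.items():
            if abs(sum(p) - 1.0) > 1e-12:
                raise ValueError(f"BIRADS probabilities for {band} must sum to 1")
        if abs(sum(self.fh_probs) - 1.0) > 1e-12:
            raise ValueError("fh_probs must sum to 1")

    def p_post(self, age):
        """Probability of being postmenopausal at an attained age."""
        a, b = self.menopause_age_bounds
        lo = (a - self.menopause_age_mean) / self.menopause_age_sd
        hi = (b - self.menopause_age_mean) / self.menopause_age_sd
        return stats.truncnorm.cdf(
            np.asarray(age, dtype=float), lo, hi,
            loc=self.menopause_age_mean, scale=self.menopause_age_sd,
        )

    def birads_band(self, age):
        return np.where(np.asarray(age) < 50.0, 0, 1)

    def to_dict(self):
        return {
            "birads_probs": {k: list(v) for k, v in self.birads_probs.items()},
            "qrf": {k: (v if isinstance(v, str) else list(v)) for k, v in self.qrf.items()},
            "fh_probs": list(self.fh_probs),
            "menopause_age_mean": self.menopause_age_mean,
            "menopause_age_sd": self.menopause_age_sd,
            "menopause_age_bounds": list(self.menopause_age_bounds),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            birads_probs={k: tuple(v) for k, v in d["birads_probs"].items()},
            qrf={k: (v if isinstance(v, str) else tuple(v)) for k, v in d["qrf"].items()},
            fh_probs=tuple(d["fh_probs"]),
            menopause_age_mean=d["menopause_age_mean"],
            menopause_age_sd=d["menopause_age_sd"],
            menopause_age_bounds=tuple(d["menopause_age_bounds"]),
        )


@dataclass
class RiskPredictions:
    """Per-woman absolute risk output.

    ``frame`` has columns ``id`` and ``risk`` (NaN where the row failed
    validation; the failure message is in ``errors`` keyed by id).
    """

    frame: pd.DataFrame
    horizon: float
    errors: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        r = self.frame["risk"]
        return pd.DataFrame(
            {
                "horizon_years": [self.horizon],
                "n": [len(r)],
                "n_failed": [int(r.isna().sum())],
                "mean_risk": [float(r.mean())],
                "p1": [float(r.quantile(0.01))],
                "p99": [float(r.quantile(0.99))],
            }
        )


class AbsoluteRiskModel:
    """Absolute-risk model built from hazard ratios, distributions and rates.

    Parameters
    ----------
    incidence, mortality : :class:`~densrisk.rates.RateTable`
        Population invasive-breast-cancer incidence and all-cause
        mortality by single year of age and calendar period.
    input_combination : subset of {'md', 'qrf', 'fh', 'pgs'}
        Which factors the linear predictor uses; the baseline constraint
        integrates over exactly these.
    md_input : 'birads', 'stratus' or 'volpara'
        Exactly one mammographic-density representation is active per
        prediction.
    density_hr : {'unadjusted': {...}, 'adjusted': {...}}
        Per-SD hazard ratios keyed by menopausal stratum; the adjusted set
        is selected automatically when 'pgs' is in the input combination.
    normalization : mapping {(tool, covariate_set): NormalizationParams}
        Standardization blocks used to score raw percent density; rows
        with missing BMI dispatch to the age-only block.
    """

    def __init__(
        self,
        incidence: RateTable | None = None,
        mortality: RateTable | None = None,
        input_combination=("md",),
        md_input: str = "stratus",
        density_hr: dict | None = None,
        normalization: dict | None = None,
        birads_log_rr=DEFAULT_BIRADS_LOG_RR,
        qrf_log_rr=None,
        fh_log_rr=_DEFAULT_FH_LOG_RR,
        pgs_log_rr: float = math.log(1.6),
        distributions: RiskFactorDistributions | None = None,
        menopause_transition_age: float = 51.0,
        entry_year: int = 2012,
    ):
        self.incidence = incidence if incidence is not None else synthetic_bc_incidence()
        self.mortality = mortality if mortality is not None else synthetic_mortality()
        self.input_combination = tuple(input_combination)
        unknown_inputs = set(self.input_combination) - {"md", "qrf", "fh", "pgs"}
        if unknown_inputs:
            raise ValueError(f"unknown inputs: {sorted(unknown_inputs)}")
        if md_input not in ("birads", "stratus", "volpara"):
            raise ValueError("md_input must be 'birads', 'stratus' or 'volpara'")
        self.md_input = md_input
        if density_hr is None:
            if md_input in ("stratus", "volpara"):
                density_hr = {
                    key: dict(DEFAULT_DENSITY_HR[key][md_input])
                    for key in ("unadjusted", "adjusted")
                }
            else:
                density_hr = {}
        self.density_hr = density_hr
        self.normalization = normalization or {}
        self.birads_log_rr = tuple(birads_log_rr)
        self.qrf_log_rr = dict(qrf_log_rr) if qrf_log_rr is not None else dict(_DEFAULT_QRF_LOG_RR)
        self.fh_log_rr = tuple(fh_log_rr)
        self.pgs_log_rr = float(pgs_log_rr)
        self.distributions = distributions or RiskFactorDistributions()
        self.menopause_transition_age = float(menopause_transition_age)
        self.entry_year = int(entry_year)
        self._mean_rr_cache: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    # linear predictor and population-mean relative risk                 #
    # ------------------------------------------------------------------ #

    def _density_log_hrs(self):
        key = "adjusted" if ("pgs" in self.input_combination and
                             self.density_hr.get("adjusted")) else "unadjusted"
        hrs = self.density_hr[key]
        return {k: math.log(v) for k, v in hrs.items()}

    def _density_beta_at(self, age, menopause_status, age_menopause):
        """Vectorized per-SD log-HR at an attained age."""
        b = self._density_log_hrs()
        age = np.asarray(age, dtype=float)
        status = np.asarray(menopause_status, dtype=object)
        m = np.asarray(age_menopause, dtype=float)
        m = np.where(np.isfinite(m), m, self.menopause_transition_age)
        beta = np.where(age < m, b["pre"], b["post"])
        return np.where(status == "unknown", b["unknown"], beta)

    def linear_predictor(self, profile, age: float) -> float:
        """Log relative risk of one woman at an attained age (nats)."""
        lp = 0.0
        if "md" in self.input_combination:
            if self.md_input == "birads":
                for key in ("z", "pmd", "pvd"):
                    v = profile.get(key)
                    if v is not None and np.isfinite(v):
                        raise ValueError(
                            "BIRADS and continuous density both supplied"
                        )
                cat = profile.get("birads")
                if cat is None or not np.isfinite(cat):
                    raise ValueError("missing required factor: birads")
                lp += self.birads_log_rr[int(cat) - 1]
            else:
                z = self._profile_z(profile)
                beta = float(
                    self._density_beta_at(
                        age,
                        profile.get("menopause_status", "unknown"),
                        profile.get("age_menopause", math.nan),
                    )
                )
                lp += beta * z
        if "qrf" in self.input_combination:
            for name, lr in self.qrf_log_rr.items():
                v = profile.get(name)
                if v is None or not np.isfinite(v):
                    raise ValueError(f"missing required factor: {name}")
                lp += lr[int(v)] if isinstance(lr, tuple) else lr * float(v)
        if "fh" in self.input_combination:
            fh = profile.get("fh_category")
            if fh is None or not np.isfinite(fh):
                raise ValueError("missing required factor: fh_category")
            lp += self.fh_log_rr[min(int(fh), 2)]
        if "pgs" in self.input_combination:
            pgs = profile.get("pgs")
            if pgs is None or not np.isfinite(pgs):
                raise ValueError("missing required factor: pgs")
            lp += self.pgs_log_rr * float(pgs)
        return float(lp)

    def _profile_z(self, profile):
        z = profile.get("z")
        if z is not None and np.isfinite(z):
            return float(z)
        col = "pmd" if self.md_input == "stratus" else "pvd"
        x = profile.get(col)
        if x is None or not np.isfinite(x):
            raise ValueError(f"missing required factor: {col} (or z)")
        age = profile.get("age_entry")
        bmi = profile.get("bmi")
        params = self._dispatch_normalization(bmi)
        return float(standardize_density(x, age, bmi, params))

    def _dispatch_normalization(self, bmi) -> NormalizationParams:
        covset = "age_bmi" if bmi is not None and np.isfinite(bmi) else "age_only"
        key = (self.md_input, covset)
        if key not in self.normalization:
            raise ValueError(f"no normalization parameters for {key}")
        return self.normalization[key]

    def population_mean_rr(self, age) -> float:
        """E[exp(linear predictor)] over the joint factor distribution.

        Components are independent; the continuous-density term is a
        menopause mixture of the lognormal mean ``E[e^{beta z}] =
        e^{beta^2/2}``, categorical terms are probability-weighted sums.
        """
        age = float(age)
        rr = 1.0
        d = self.distributions
        if "md" in self.input_combination:
            if self.md_input == "birads":
                band = "lt50" if age < 50.0 else "ge50"
                probs = np.asarray(d.birads_probs[band])
                rr *= float(probs @ np.exp(np.asarray(self.birads_log_rr)))
            else:
                b = self._density_log_hrs()
                p_post = float(d.p_post(age))
                rr *= (1 - p_post) * math.exp(b["pre"] ** 2 / 2) + p_post * math.exp(
                    b["post"] ** 2 / 2
                )
        if "qrf" in self.input_combination:
            for name, lr in self.qrf_log_rr.items():
                dist = d.qrf.get(name)
                if dist is None:
                    raise ValueError(f"no distribution for QRF {name!r}")
                if isinstance(lr, tuple):
                    rr *= float(np.asarray(dist) @ np.exp(np.asarray(lr)))
                else:
                    rr *= math.exp(lr**2 / 2)
        if "fh" in self.input_combination:
            rr *= float(np.asarray(d.fh_probs) @ np.exp(np.asarray(self.fh_log_rr)))
        if "pgs" in self.input_combination:
            rr *= math.exp(self.pgs_log_rr**2 / 2)
        return rr

    def _mean_rr_by_age(self) -> np.ndarray:
        if self._mean_rr_cache is None:
            ages = self.incidence.ages
            self._mean_rr_cache = np.array(
                [self.population_mean_rr(a) for a in ages]
            )
        return self._mean_rr_cache

    def baseline(self, age, period):
        """Constrained baseline hazard: population rate / population-mean RR."""
        mean_rr = self._mean_rr_by_age()
        i = np.clip(
            np.floor(np.asarray(age)).astype(int) - self.incidence.ages[0],
            0,
            len(self.incidence.ages) - 1,
        )
        out = self.incidence.rate(age, period) / mean_rr[i]
        return float(out) if np.ndim(out) == 0 else out

    # ------------------------------------------------------------------ #
    # absolute risk                                                      #
    # ------------------------------------------------------------------ #

    def absolute_risk(
        self,
        profile,
        start_age: float,
        horizon: float,
        competing_mortality: bool = True,
    ) -> float:
        """Probability of invasive breast cancer within the horizon.

        Discrete annual recursion: in each projection year the woman, if
        still alive and cancer-free, develops cancer with probability
        ``baseline * exp(linear predictor)``; all-cause mortality competes.
        Projection is capped at age 80.
        """
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        birth_year = profile.get("birth_year")
        n_years = int(min(math.ceil(horizon), max(0, math.ceil(80.0 - start_age))))
        risk = 0.0
        s_bc = s_m = 1.0
        for t in range(n_years):
            a = start_age + t
            period = (birth_year + a) if birth_year is not None else self.entry_year
            lam = self.baseline(a, period) * math.exp(self.linear_predictor(profile, a))
            lam = min(lam, 1.0)
            m = self.mortality.rate(a, period) if competing_mortality else 0.0
            risk += lam * s_bc * s_m
            s_bc *= 1.0 - lam
            s_m *= 1.0 - m
        return risk

    def risk_curve(self, profile, start_age: float, to_age: float = 80.0,
                   competing_mortality: bool = True) -> pd.DataFrame:
        """Cumulative risk at each whole year from start_age to to_age."""
        horizons = np.arange(1, int(math.ceil(min(to_age, 80.0) - start_age)) + 1)
        risks = [
            self.absolute_risk(profile, start_age, int(h), competing_mortality)
            for h in horizons
        ]
        return pd.DataFrame({"age": start_age + horizons, "cumulative_risk": risks})

    # ------------------------------------------------------------------ #
    # vectorized cohort prediction                                       #
    # ------------------------------------------------------------------ #

    def predict(
        self,
        cohort: pd.DataFrame,
        horizon: float = 5.0,
        start_offset: float = 1.0,
        competing_mortality: bool = True,
    ) -> RiskPredictions:
        """Absolute risks for a cohort, starting ``start_offset`` years
        (default one, a landmark excluding prevalent disease) after the
        age at entry.  Row failures are collected per id, not raised.
        """
        n = len(cohort)
        ids = cohort["id"].to_numpy() if "id" in cohort else np.arange(n)
        errors: dict = {}
        ok = np.ones(n, dtype=bool)

        age_entry = cohort["age_entry"].to_numpy(dtype=float)
        start = age_entry + start_offset
        lp_fixed = np.zeros(n)

        z = np.full(n, np.nan)
        status = np.full(n, "unknown", dtype=object)
        menop = np.full(n, np.nan)
        birads_idx = None
        if "md" in self.input_combination:
            if self.md_input == "birads":
                b = cohort["birads"].to_numpy(dtype=float)
                bad = ~np.isfinite(b) | (b < 1) | (b > len(self.birads_log_rr))
                self._mark(bad, ids, errors, "missing or invalid birads")
                ok &= ~bad
                birads_idx = np.where(bad, 1, b).astype(int) - 1
                lp_fixed += np.asarray(self.birads_log_rr)[birads_idx]
            else:
                z = self._cohort_z(cohort, ids, errors, ok)
                if "menopause_status" in cohort:
                    status = cohort["menopause_status"].astype(object).to_numpy()
                if "age_menopause" in cohort:
                    menop = cohort["age_menopause"].to_numpy(dtype=float)
        if "qrf" in self.input_combination:
            for name, lr in self.qrf_log_rr.items():
                v = cohort[name].to_numpy(dtype=float)
                bad = ~np.isfinite(v)
                self._mark(bad, ids, errors, f"missing {name}")
                ok &= ~bad
                vv = np.where(bad, 0, v)
                lp_fixed += (
                    np.asarray(lr)[vv.astype(int)] if isinstance(lr, tuple) else lr * vv
                )
        if "fh" in self.input_combination:
            fh = cohort["fh_category"].to_numpy(dtype=float)
            bad = ~np.isfinite(fh)
            self._mark(bad, ids, errors, "missing fh_category")
            ok &= ~bad
            lp_fixed += np.asarray(self.fh_log_rr)[
                np.minimum(np.where(bad, 0, fh).astype(int), 2)
            ]
        if "pgs" in self.input_combination:
            pgs = cohort["pgs"].to_numpy(dtype=float)
            bad = ~np.isfinite(pgs)
            self._mark(bad, ids, errors, "missing pgs")
            ok &= ~bad
            lp_fixed += self.pgs_log_rr * np.where(bad, 0, pgs)

        birth_year = (
            cohort["birth_year"].to_numpy(dtype=float)
            if "birth_year" in cohort
            else self.entry_year - age_entry
        )

        continuous_md = "md" in self.input_combination and self.md_input != "birads"
        if continuous_md:
            m_fill = np.where(np.isfinite(menop), menop, self.menopause_transition_age)
            b = self._density_log_hrs()
            unknown = status == "unknown"
            zz = np.where(ok, z, 0.0)

        n_years_vec = np.minimum(
            int(math.ceil(horizon)), np.maximum(0, np.ceil(80.0 - start)).astype(int)
        )
        max_years = int(n_years_vec.max()) if n else 0
        risk = np.zeros(n)
        s_bc = np.ones(n)
        s_m = np.ones(n)
        for t in range(max_years):
            active = t < n_years_vec
            a = start + t
            period = birth_year + a
            lp = lp_fixed.copy()
            if continuous_md:
                beta = np.where(a < m_fill, b["pre"], b["post"])
                beta = np.where(unknown, b["unknown"], beta)
                lp += beta * zz
            lam = np.minimum(self.baseline(a, period) * np.exp(lp), 1.0)
            lam = np.where(active, lam, 0.0)
            m = self.mortality.rate(a, period) if competing_mortality else np.zeros(n)
            m = np.where(active, m, 0.0)
            risk += lam * s_bc * s_m
            s_bc *= 1.0 - lam
            s_m *= 1.0 - m

        risk = np.where(ok, risk, np.nan)
        frame = pd.DataFrame({"id": ids, "risk": risk})
        return RiskPredictions(frame=frame, horizon=horizon, errors=errors)

    def _cohort_z(self, cohort, ids, errors, ok):
        if "z" in cohort.columns:
            z = cohort["z"].to_numpy(dtype=float)
            bad = ~np.isfinite(z)
            self._mark(bad, ids, errors, "missing z")
            ok &= ~bad
            return np.where(bad, 0.0, z)
        col = "pmd" if self.md_input == "stratus" else "pvd"
        x = cohort[col].to_numpy(dtype=float)
        age = cohort["age_entry"].to_numpy(dtype=float)
        bmi = (
            cohort["bmi"].to_numpy(dtype=float)
            if "bmi" in cohort.columns
            else np.full(len(cohort), np.nan)
        )
        bad = ~np.isfinite(x)
        self._mark(bad, ids, errors, f"missing {col}")
        ok &= ~bad
        z = np.zeros(len(cohort))
        has_bmi = np.isfinite(bmi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for covset, mask in (("age_bmi", has_bmi & ~bad), ("age_only", ~has_bmi & ~bad)):
                if not mask.any():
                    continue
                key = (self.md_input, covset)
                if key not in self.normalization:
                    self._mark(mask, ids, errors, f"no normalization parameters for {key}")
                    ok &= ~mask
                    continue
                z[mask] = standardize_density(
                    x[mask], age[mask],
                    bmi[mask] if covset == "age_bmi" else None,
                    self.normalization[key],
                )
        return z

    @staticmethod
    def _mark(bad, ids, errors, message):
        for i in np.flatnonzero(bad):
            errors.setdefault(ids[i], message)

    # ------------------------------------------------------------------ #
    # sampling and serialization                                         #
    # ------------------------------------------------------------------ #

    def sample_population(self, n: int, seed: int = 0, age_range=(40.0, 74.0)) -> pd.DataFrame:
        """Draw a cohort-like table from the model's own factor distributions.

        Entry ages are uniform over ``age_range``; every factor in the
        input combination is sampled from the distribution the baseline
        constraint integrates over, so the mean predicted risk matches
        population incidence by construction.
        """
        rng = np.random.default_rng(seed)
        d = self.distributions
        age = rng.uniform(*age_range, size=n)
        lo = (d.menopause_age_bounds[0] - d.menopause_age_mean) / d.menopause_age_sd
        hi = (d.menopause_age_bounds[1] - d.menopause_age_mean) / d.menopause_age_sd
        menop = stats.truncnorm.rvs(
            lo, hi, loc=d.menopause_age_mean, scale=d.menopause_age_sd,
            size=n, random_state=rng,
        )
        out = pd.DataFrame(
            {
                "id": np.arange(n),
                "age_entry": age,
                "menopause_status": np.where(age >= menop, "post", "pre"),
                "age_menopause": menop,
                "birth_year": self.entry_year - age,
            }
        )
        if "md" in self.input_combination:
            if self.md_input == "birads":
                band = d.birads_band(age)
                b = np.empty(n, dtype=int)
                for bi, key in enumerate(("lt50", "ge50")):
                    mask = band == bi
                    b[mask] = rng.choice(
                        4, size=int(mask.sum()), p=np.asarray(d.birads_probs[key])
                    ) + 1
                out["birads"] = b
            else:
                out["z"] = rng.standard_normal(n)
        if "qrf" in self.input_combination:
            for name, dist in d.qrf.items():
                if dist == "normal":
                    out[name] = rng.standard_normal(n)
                else:
                    out[name] = rng.choice(len(dist), size=n, p=np.asarray(dist))
        if "fh" in self.input_combination:
            out["fh_category"] = rng.choice(3, size=n, p=np.asarray(d.fh_probs))
        if "pgs" in self.input_combination:
            out["pgs"] = rng.standard_normal(n)
        return out

    def to_dict(self) -> dict:
        return {
            "input_combination": list(self.input_combination),
            "md_input": self.md_input,
            "density_hr": self.density_hr,
            "normalization": {
                f"{k[0]}|{k[1]}": v.to_dict() for k, v in self.normalization.items()
            },
            "birads_log_rr": list(self.birads_log_rr),
            "qrf_log_rr": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.qrf_log_rr.items()
            },
            "fh_log_rr": list(self.fh_log_rr),
            "pgs_log_rr": self.pgs_log_rr,
            "distributions": self.distributions.to_dict(),
            "menopause_transition_age": self.menopause_transition_age,
            "entry_year": self.entry_year,
            "incidence": _rate_table_dict(self.incidence),
            "mortality": _rate_table_dict(self.mortality),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AbsoluteRiskModel":
        return cls(
            incidence=_rate_table_from(d["incidence"]),
            mortality=_rate_table_from(d["mortality"]),
            input_combination=tuple(d["input_combination"]),
            md_input=d["md_input"],
            density_hr=d["density_hr"],
            normalization={
                tuple(k.split("|")): NormalizationParams.from_dict(v)
                for k, v in d["normalization"].items()
            },
            birads_log_rr=tuple(d["birads_log_rr"]),
            qrf_log_rr={
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in d["qrf_log_rr"].items()
            },
            fh_log_rr=tuple(d["fh_log_rr"]),
            pgs_log_rr=d["pgs_log_rr"],
            distributions=RiskFactorDistributions.from_dict(d["distributions"]),
            menopause_transition_age=d["menopause_transition_age"],
            entry_year=d["entry_year"],
        )


def _rate_table_dict(t: RateTable) -> dict:
    return {
        "ages": t.ages.tolist(),
        "period_starts": t.period_starts.tolist(),
        "rates": t.rates.tolist(),
    }


def _rate_table_from(d: dict) -> RateTable:
    return RateTable(d["ages"], d["period_starts"], d["rates"])
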