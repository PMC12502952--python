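"""Synthetic mammography-screening cohort generator.

Emulates the statistical structure of a Scandinavian screening cohort
(entry ages 40-74): right-skewed percent mammographic density that declines
with age and BMI, menopause status derived from a truncated-normal
age-at-menopause distribution, questionnaire risk factors (QRFs), a
categorical first-degree family history, an optional polygenic score (PGS)
weakly correlated with density, and invasive breast-cancer event times from
a piecewise-constant proportional-hazards model in which the covariate is
the standardized residual density (computed internally with the same
residualization pipeline used downstream).  Competing events — other
cancer, in-situ breast cancer, prophylactic mastectomy, death, reaching age
80, administrative end of follow-up — censor at the earliest simulated
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import fit_residual_regression, fit_boxcox, standardize_density

__all__ = [
    "QrfSpec",
    "CohortConfig",
    "generate_cohort",
    "generate_outcomes_from_model",
    "table1_recovery_config",
]

EVENT_CODES = (
    "invasive_bc",
    "in_situ_bc",
    "other_cancer",
    "mastectomy",
    "death",
    "age80",
    "admin_censor",
)

# censoring causes with per-year rates in CohortConfig.censoring_rates
_CENSOR_CAUSES = ("other_cancer", "in_situ_bc", "mastectomy", "death")


@dataclass(frozen=True)
class QrfSpec:
    """One questionnaire risk factor: its distribution and log relative risk.

    kind "normal" draws a standard-normal (already z-scored) value with
    ``log_rr`` per SD; kind "categorical" draws category ``k`` with
    probability ``probs[k]`` and log-RR ``log_rr[k]``.
    """

    name: str
    kind: str
    log_rr: float | tuple[float, ...]
    probs: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("normal", "categorical"):
            raise ValueError(f"unknown QRF kind {self.kind!r}")
        if self.kind == "categorical":
            if self.probs is None or len(self.probs) != len(self.log_rr):
                raise ValueError(f"QRF {self.name}: probs/log_rr length mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-12:
                raise ValueError(f"QRF {self.name}: probs must sum to 1")


def _default_qrfs() -> tuple[QrfSpec, ...]:
    return (
        QrfSpec("height", "normal", math.log(1.10)),
        QrfSpec("alcohol", "normal", math.log(1.08)),
        QrfSpec("hormone_use", "categorical", (0.0, math.log(1.3)), (0.8, 0.2)),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults emulate the target screening cohort.

    Density is generated on a latent Gaussian scale, linear in age and BMI,
    then mapped through an inverse shifted-power (Box-Cox inverse)
    transform with shape ``density_skew`` and clipped to [0, 100] percent,
    so the downstream residual + Box-Cox fit has real signal to recover.
    ``bc_base_rate`` is the annual baseline invasive-cancer hazard; the
    default (together with 8 years of follow-up) yields a crude incidence
    of roughly 2.5 per 1,000 woman-years, typical of a screening cohort of
    this age range.
    """

    n_women: int = 10_000
    age_range: tuple[float, float] = (40.0, 74.0)
    # Beta(a, b) shape of the entry-age distribution across age_range;
    # (1.2, 2.0) skews enrolment toward the younger screening ages.
    age_beta: tuple[float, float] = (1.2, 2.0)
    bmi_log_mean: float = math.log(25.0)
    bmi_log_sd: float = 0.15
    menopause_age_mean: float = 51.0
    menopause_age_sd: float = 4.0
    menopause_age_bounds: tuple[float, float] = (40.0, 60.0)
    density_tool: str = "stratus"  # which density column (pmd or pvd) is filled
    density_coeffs: tuple[float, float, float] = (10.6, -0.06, -0.08)
    density_noise_sd: float = 1.6
    density_skew: float = 0.35
    true_log_hr_pre: float = math.log(1.48)
    true_log_hr_post: float = math.log(1.41)
    qrf_spec: tuple[QrfSpec, ...] = field(default_factory=_default_qrfs)
    fh_probs: tuple[float, float, float] = (0.88, 0.105, 0.015)
    fh_log_rrs: tuple[float, float, float] = (0.0, math.log(1.8), math.log(2.9))
    pgs_density_corr: float = 0.1
    pgs_log_rr: float = math.log(1.6)
    followup_years: float = 8.0
    bc_base_rate: float = 0.002
    censoring_rates: dict = field(
        default_factory=lambda: {
            "other_cancer": 0.004,
            "in_situ_bc": 0.0005,
            "mastectomy": 0.0002,
            "death": 0.004,
        }
    )
    birads_quantiles: tuple[float, float, float] = (0.10, 0.51, 0.90)
    unknown_status_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_women <= 0:
            raise ValueError("n_women must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range low must be below high")
        if abs(sum(self.fh_probs) - 1.0) > 1e-12:
            raise ValueError("fh_probs must sum to 1")
        if any(r < 0 for r in self.censoring_rates.values()):
            raise ValueError("censoring rates must be non-negative")
        if self.bc_base_rate < 0 or self.followup_years <= 0:
            raise ValueError("rates must be >= 0 and follow-up positive")
        if not -1.0 <= self.pgs_density_corr <= 1.0:
            raise ValueError("pgs_density_corr must lie in [-1, 1]")
        if self.density_tool not in ("stratus", "volpara"):
            raise ValueError("density_tool must be 'stratus' or 'volpara'")
        if not 0.0 <= self.unknown_status_prob <= 1.0:
            raise ValueError("unknown_status_prob must lie in [0, 1]")


def _inverse_power_transform(latent: np.ndarray, skew: float) -> np.ndarray:
    """Map a latent Gaussian variable to a right-skewed percent in [0, 100]."""
    if skew == 0.0:
        out = np.exp(latent)
    else:
        base = skew * latent + 1.0
        out = np.where(base > 0.0, np.maximum(base, 0.0) ** (1.0 / skew), 0.0)
    return np.clip(out, 0.0, 100.0)


def _truncnorm_rvs(mean, sd, bounds, size, rng):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a cohort table; byte-identical for identical config and seed.

    The invasive-cancer hazard for woman *i* in follow-up year *t* is
    ``bc_base_rate * exp(beta(t) * z_i + qrf + fh + pgs terms)`` where
    ``z_i`` is her standardized residual density and ``beta(t)`` switches
    from the pre- to the postmenopausal log-HR at the first whole follow-up
    year starting at or after her age at menopause.  Event times within a
    year are drawn by inverse-transform sampling of the piecewise-constant
    hazard, so exit times are continuous.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_women

    lo, hi = cfg.age_range
    age = lo + (hi - lo) * rng.beta(*cfg.age_beta, size=n)
    bmi = np.exp(rng.normal(cfg.bmi_log_mean, cfg.bmi_log_sd, size=n))
    menop_age = _truncnorm_rvs(
        cfg.menopause_age_mean, cfg.menopause_age_sd, cfg.menopause_age_bounds, n, rng
    )
    post_at_entry = age >= menop_age
    status = np.where(post_at_entry, "post", "pre").astype(object)
    if cfg.unknown_status_prob > 0:
        unknown = rng.random(n) < cfg.unknown_status_prob
        status[unknown] = "unknown"

    # latent density: linear in age and BMI plus noise, then skewed to percent
    c0, c_age, c_bmi = cfg.density_coeffs
    eps = rng.normal(0.0, cfg.density_noise_sd, size=n)
    latent = c0 + c_age * age + c_bmi * bmi + eps
    density = _inverse_power_transform(latent, cfg.density_skew)

    # PGS shares the density *noise* component so the correlation survives
    # residualization on age and BMI
    rho = cfg.pgs_density_corr
    pgs = rho * (eps / cfg.density_noise_sd) + math.sqrt(1 - rho**2) * rng.standard_normal(n)

    qrf_values: dict[str, np.ndarray] = {}
    lp_fixed = np.zeros(n)
    for q in cfg.qrf_spec:
        if q.kind == "normal":
            v = rng.standard_normal(n)
            lp_fixed += q.log_rr * v
        else:
            v = rng.choice(len(q.probs), size=n, p=np.asarray(q.probs))
            lp_fixed += np.asarray(q.log_rr)[v]
        qrf_values[q.name] = v
    fh = rng.choice(3, size=n, p=np.asarray(cfg.fh_probs))
    lp_fixed += np.asarray(cfg.fh_log_rrs)[fh]
    lp_fixed += cfg.pgs_log_rr * pgs

    # standardized residual density, computed with the pipeline's own
    # residualization so the simulated effect is per SD of the same covariate
    # the downstream Cox fit will use
    coeffs, residuals = fit_residual_regression(density, age, bmi)
    lam, shift, mu, sd = fit_boxcox(residuals)
    from .normalization import NormalizationParams  # local import avoids cycle at module load

    params = NormalizationParams(
        tool=cfg.density_tool,
        covariate_set="age_bmi",
        coeffs=coeffs,
        boxcox_lambda=lam,
        boxcox_shift=shift,
        mean=mu,
        sd=sd,
    )
    z = standardize_density(density, age, bmi, params)

    time, event = _simulate_event_times(
        rng=rng,
        age=age,
        menop_age=menop_age,
        z=z,
        lp_fixed=lp_fixed,
        status=status,
        cfg=cfg,
    )

    cuts = np.quantile(density, cfg.birads_quantiles)
    birads = 1 + np.searchsorted(cuts, density, side="right")

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "age_entry": age,
            "bmi": bmi,
            "menopause_status": status,
            # latent simulated value kept for every woman (not only post) so
            # that time-varying-status analyses and projection transitions can
            # use the individual age; real data would only carry it post
            "age_menopause": menop_age,
            "pmd": density if cfg.density_tool == "stratus" else np.nan,
            "pvd": density if cfg.density_tool == "volpara" else np.nan,
            "birads": birads,
            **qrf_values,
            "fh_category": fh,
            "pgs": pgs,
            "time": time,
            "event": event,
        }
    )
    return table


def _simulate_event_times(rng, age, menop_age, z, lp_fixed, status, cfg):
    """Piecewise-constant-hazard competing-event simulation on an annual grid."""
    n = age.size
    # administrative end of follow-up, capped by age 80
    t_admin = np.minimum(cfg.followup_years, 80.0 - age)
    censors_at_80 = 80.0 - age < cfg.followup_years
    n_years = int(math.ceil(cfg.followup_years))

    cens_rates = np.array([cfg.censoring_rates.get(c, 0.0) for c in _CENSOR_CAUSES])
    lam_cens = cens_rates.sum()

    # year of menopause switch on each woman's personal annual grid
    t_switch = np.ceil(np.maximum(menop_age - age, 0.0))

    unknown = status == "unknown"
    beta_mix = 0.5 * (cfg.true_log_hr_pre + cfg.true_log_hr_post)

    # cumulative total hazard at whole-year boundaries
    hazards = np.empty((n, n_years))
    for t in range(n_years):
        post_now = t >= t_switch
        beta = np.where(post_now, cfg.true_log_hr_post, cfg.true_log_hr_pre)
        beta = np.where(unknown, beta_mix, beta)
        lam_bc = cfg.bc_base_rate * np.exp(lp_fixed + beta * z)
        width = np.clip(t_admin - t, 0.0, 1.0)
        hazards[:, t] = (lam_bc + lam_cens) * width
    cum = np.cumsum(hazards, axis=1)
    total = cum[:, -1]

    u = rng.exponential(1.0, size=n)
    censored = u >= total
    # year index of the event for non-censored women
    year = np.argmax(u[:, None] < cum, axis=1)
    prev = np.where(year > 0, np.take_along_axis(cum, np.maximum(year - 1, 0)[:, None], 1)[:, 0], 0.0)
    rate_in_year = np.take_along_axis(hazards, year[:, None], 1)[:, 0]
    width = np.clip(t_admin - year, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(rate_in_year > 0, (u - prev) / rate_in_year * width, 0.0)
    t_event = year + frac

    # cause of the event: invasive BC vs one of the censoring causes,
    # proportional to the cause-specific hazards in the event year
    post_now = year >= t_switch
    beta = np.where(post_now, cfg.true_log_hr_post, cfg.true_log_hr_pre)
    beta = np.where(unknown, beta_mix, beta)
    lam_bc = cfg.bc_base_rate * np.exp(lp_fixed + beta * z)
    cause_haz = np.concatenate([lam_bc[:, None], np.tile(cens_rates, (n, 1))], axis=1)
    cause_tot = cause_haz.sum(axis=1)
    cum_cause = np.cumsum(cause_haz / np.maximum(cause_tot, 1e-300)[:, None], axis=1)
    v = rng.random(n)
    cause_idx = (v[:, None] >= cum_cause).sum(axis=1)
    cause_names = np.array(("invasive_bc",) + _CENSOR_CAUSES)

    time = np.where(censored, t_admin, t_event)
    event = np.where(
        censored,
        np.where(censors_at_80, "age80", "admin_censor"),
        cause_names[np.minimum(cause_idx, len(cause_names) - 1)],
    ).astype(object)
    # guard against zero-length follow-up from age-80 truncation
    time = np.maximum(time, 1e-9)
    return time, event


def generate_outcomes_from_model(
    cohort: pd.DataFrame, model, horizon: float = 5.0, seed: int = 0
) -> pd.DataFrame:
    """Draw binary horizon outcomes as independent Bernoulli(predicted risk).

    Used for self-calibration experiments: when outcomes come from the
    model's own risks, a calibration slope of 1 is the truth.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    preds = model.predict(cohort, horizon=horizon)
    risk = preds.frame["risk"].to_numpy()
    if np.isnan(risk).any():
        raise ValueError("model returned missing risks; cannot draw outcomes")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    out["predicted_risk"] = risk
    out["outcome"] = rng.binomial(1, risk)
    return out


def table1_recovery_config(tool: str, n_women: int = 40_000, seed: int = 0) -> CohortConfig:
    """Study conditions for the hazard-ratio recovery experiments.

    The configured pre/post log-HRs are the reference per-SD density
    effects for the given tool; they are interpreted as the *total*
    (PGS-unadjusted) density effect, so the PGS is kept out of the
    simulated hazard here to avoid double counting its correlated share.
    """
    hr = {"stratus": (1.48, 1.41), "volpara": (1.27, 1.38)}
    if tool not in hr:
        raise ValueError("tool must be 'stratus' or 'volpara'")
    pre, post = hr[tool]
    coeffs = (10.6, -0.06, -0.08) if tool == "stratus" else (7.2, -0.045, -0.06)
    return CohortConfig(
        n_women=n_women,
        density_tool=tool,
        density_coeffs=coeffs,
        true_log_hr_pre=math.log(pre),
        true_log_hr_post=math.log(post),
        pgs_log_rr=0.0,
        seed=seed,
    )
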