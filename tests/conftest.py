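import numpy as np
import pandas as pd
import pytest

from densrisk import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 6,000-woman synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_women=6000, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


# ---------------------------------------------------------------------- #
# independent oracles                                                    #
# ---------------------------------------------------------------------- #

def efron_partial_loglik(beta, entry, exit_, event, x):
    """Brute-force Cox partial log-likelihood (Efron ties, left truncation).

    Written independently of the fitting code: explicit loops over event
    times and risk sets.
    """
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(exit_[event == 1]):
        dead = (exit_ == t) & (event == 1)
        risk = (entry < t) & (exit_ >= t)
        d = int(dead.sum())
        eta = np.exp(beta * x)
        s_risk = eta[risk].sum()
        s_dead = eta[dead].sum()
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(s_risk - (ell / d) * s_dead)
    return ll


def grid_maximize_loglik(entry, exit_, event, x, lo=-3.0, hi=3.0):
    """Two-stage exhaustive grid search of the Efron partial likelihood."""
    grid = np.arange(lo, hi + 1e-12, 1e-3)
    lls = [efron_partial_loglik(b, entry, exit_, event, x) for b in grid]
    best = grid[int(np.argmax(lls))]
    fine = np.arange(best - 2e-3, best + 2e-3, 1e-6)
    lls = [efron_partial_loglik(b, entry, exit_, event, x) for b in fine]
    return float(fine[int(np.argmax(lls))])


def mc_absolute_risk(model, profile, start_age, horizon, n, seed,
                     competing_mortality=True):
    """Monte-Carlo event simulation oracle for the annual risk recursion.

    Each replicate steps through the years: develops cancer with the
    woman's annual hazard while alive and cancer-free, else may die.
    Returns (estimate, standard error).
    """
    rng = np.random.default_rng(seed)
    birth_year = profile.get("birth_year")
    alive = np.ones(n, dtype=bool)
    cancer = np.zeros(n, dtype=bool)
    n_years = int(min(np.ceil(horizon), max(0, np.ceil(80.0 - start_age))))
    for t in range(n_years):
        a = start_age + t
        period = (birth_year + a) if birth_year is not None else model.entry_year
        lam = min(model.baseline(a, period)
                  * np.exp(model.linear_predictor(profile, a)), 1.0)
        m = model.mortality.rate(a, period) if competing_mortality else 0.0
        at_risk = alive & ~cancer
        new_cancer = at_risk & (rng.random(n) < lam)
        cancer |= new_cancer
        dies = alive & ~cancer & (rng.random(n) < m)
        alive &= ~dies
    p = cancer.mean()
    return p, np.sqrt(p * (1 - p) / n)


def records_frame(entry, exit_, event, x, name="z"):
    return pd.DataFrame(
        {"entry_age": entry, "exit_age": exit_, "event_flag": event, name: x}
    )
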