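"""Age- and calendar-period-specific population rate tables.

Holds annual event probabilities (breast-cancer incidence, all-cause
mortality) on a single-year-of-age grid with calendar-period columns.
Synthetic builders provide smooth Nordic-like tables for simulation work
when registry tables are not supplied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["RateTable", "synthetic_bc_incidence", "synthetic_mortality"]


class RateTable:
    """Annual rates by single year of age and calendar period.

    ``rates[i, j]`` is the annual probability at age ``ages[i]`` in the
    period starting at ``period_starts[j]``.  Lookups clamp to the table
    edges (nearest age row, nearest period column).
    """

    def __init__(self, ages, period_starts, rates):
        ages = np.asarray(ages, dtype=int)
        period_starts = np.asarray(period_starts, dtype=int)
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (len(ages), len(period_starts)):
            raise ValueError("rates must be (n_ages, n_periods)")
        if np.any((rates < 0) | (rates > 1)):
            raise ValueError("rates must lie in [0, 1]")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be contiguous single years")
        if len(period_starts) > 1 and np.any(np.diff(period_starts) <= 0):
            raise ValueError("period starts must be increasing")
        self.ages = ages
        self.period_starts = period_starts
        self.rates = rates

    def rate(self, age, period):
        """Vectorized lookup; ages/periods outside the table clamp to edges."""
        age = np.asarray(age)
        period = np.asarray(period)
        i = np.clip(np.floor(age).astype(int) - self.ages[0], 0, len(self.ages) - 1)
        j = np.clip(
            np.searchsorted(self.period_starts, period, side="right") - 1,
            0,
            len(self.period_starts) - 1,
        )
        out = self.rates[i, j]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age": int(a), "period_start": int(p), "rate": float(self.rates[i, j])}
            for i, a in enumerate(self.ages)
            for j, p in enumerate(self.period_starts)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateTable":
        piv = df.pivot(index="age", columns="period_start", values="rate").sort_index()
        return cls(piv.index.to_numpy(), piv.columns.to_numpy(), piv.to_numpy())


def synthetic_bc_incidence(period_starts=(1990, 2000, 2010, 2020)) -> RateTable:
    """Smooth synthetic female breast-cancer incidence, ages 0-80.

    Logistic-in-age shape rising from near zero before 30 to about 3.5 per
    1,000 per year in the seventies, with a mild upward calendar trend —
    the broad shape of Nordic registry incidence.
    """
    ages = np.arange(0, 81)
    base = 0.004 / (1.0 + np.exp(-(ages - 52.0) / 9.0))
    base[ages < 20] = 0.0
    trend = 1.0 + 0.03 * np.arange(len(period_starts))
    return RateTable(ages, period_starts, np.outer(base, trend))


def synthetic_mortality(period_starts=(1990, 2000, 2010, 2020)) -> RateTable:
    """Smooth synthetic all-cause female mortality, ages 0-80 (Gompertz-like)."""
    ages = np.arange(0, 81)
    base = np.minimum(0.0004 * np.exp(0.10 * (ages - 40.0)), 1.0)
    base[ages < 30] = 0.0003
    trend = 1.0 - 0.02 * np.arange(len(period_starts))
    return RateTable(ages, period_starts, np.outer(base, trend))
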