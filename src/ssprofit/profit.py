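"""Feedlot profitability phenotypes.

Two novel traits are computed from daily feedlot weight/intake series and
economic parameters:

* **APF** — accumulated feedlot profit over the finishing period:
  the sum over days of (daily revenue − daily cost), where daily revenue is
  the arroba price times the day's carcass-arroba gain and daily cost is
  dry-matter intake times the diet price plus a fixed daily overhead.
* **PFT** — profit per arroba (15 kg carcass unit) gained over the period:
  total profit divided by the period's arroba gain. A per-kg view is
  ``PFT / 15`` (``PFT_per_kg`` output column).

Carcass arrobas on day d are ``0.96 × weight × dressing% / 100 / 15``: the
shrunk body weight (96% of live weight) converted to carcass weight with a
sex-specific dressing percentage, in 15-kg units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import EconomicParams
from .errors import DataError, SsprofitError


class DomainError(SsprofitError):
    """Argument outside the physical domain (negative weight/intake)."""


def accumulated_arroba(body_weight_kg, dressing_pct: float, econ: EconomicParams | None = None):
    """Carcass arrobas in a live animal of the given weight.

    shrunk weight (96% of live) x dressing/100, in 15-kg units.
    """
    econ = econ or EconomicParams()
    w = np.asarray(body_weight_kg, dtype=float)
    if np.any(w <= 0):
        raise DomainError("body weight must be positive")
    out = econ.shrink_factor * w * (dressing_pct / 100.0) / econ.arroba_kg
    return float(out) if out.ndim == 0 else out


def arroba_gain(arroba_by_day: np.ndarray, d: int) -> float:
    """Arroba gain from day 1 to day ``d`` (1-based, day 1 = first feedlot day)."""
    a = np.asarray(arroba_by_day, dtype=float)
    if d < 1 or d > len(a):
        raise DataError(f"day {d} outside series of length {len(a)}")
    return float(a[d - 1] - a[0])


def daily_cost(dmi_kg, econ: EconomicParams):
    """Feed cost (DMI x diet price) plus the fixed daily overhead."""
    dmi = np.asarray(dmi_kg, dtype=float)
    if np.any(dmi < 0):
        raise DomainError("dry-matter intake must be non-negative")
    out = dmi * econ.diet_price_kg + econ.feedlot_daily_overhead
    return float(out) if out.ndim == 0 else out


def daily_revenue(arroba_gain_day, econ: EconomicParams):
    """Arroba price times the day's arroba gain (negative if weight drops)."""
    out = econ.arroba_price * np.asarray(arroba_gain_day, dtype=float)
    return float(out) if out.ndim == 0 else out


def profit_series(series: pd.DataFrame, econ: EconomicParams) -> pd.DataFrame:
    """Profit phenotypes per animal from a long-format feedlot table.

    ``series`` columns: animal, day, weight_kg, dmi_kg, sex (day contiguous
    from 1 over the period). Returns one row per animal with APF, PFT,
    arroba_gain, total_cost, total_revenue; the accounting identity
    ``APF = total_revenue − total_cost`` holds to machine precision. When
    the period's arroba gain is ≤ 0, PFT is NaN and ``zero_gain_flag`` is
    set (the record is retained).
    """
    req = {"animal", "day", "weight_kg", "dmi_kg", "sex"}
    missing = req - set(series.columns)
    if missing:
        raise DataError(f"feedlot series missing columns {sorted(missing)}")
    rows = []
    for animal, grp in series.groupby("animal", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        d = min(econ.period_days, int(days.max()))
        if days[0] != 1 or not np.array_equal(days[:d], np.arange(1, d + 1)):
            raise DataError(f"animal {animal}: day index not contiguous from 1")
        grp = grp.iloc[:d]
        sex = grp["sex"].iloc[0]
        arr = accumulated_arroba(grp["weight_kg"].to_numpy(), econ.dressing_for(sex), econ)
        gain_by_day = np.diff(arr, prepend=arr[0])  # day 1 gain is 0 by definition
        revenue = daily_revenue(gain_by_day, econ)
        cost = daily_cost(grp["dmi_kg"].to_numpy(), econ)
        total_rev = float(np.sum(revenue))
        total_cost = float(np.sum(cost))
        apf = total_rev - total_cost  # exact accounting identity by construction
        gain = arroba_gain(arr, d)
        pft = apf / gain if gain > 0 else np.nan
        rows.append({
            "animal": animal, "APF": apf, "PFT": pft,
            "PFT_per_kg": pft / econ.arroba_kg if gain > 0 else np.nan,
            "arroba_gain": gain, "total_cost": total_cost,
            "total_revenue": total_rev, "zero_gain_flag": gain <= 0,
        })
    return pd.DataFrame(rows)


def standardize_prices(series: pd.DataFrame, econ: EconomicParams) -> pd.DataFrame:
    """Attach one common set of prices to every batch.

    Mirrors the study design: diet prices, the non-feed overhead and the
    arroba price are set identical across batches so that revenue per
    arroba is equal for all animals; performance fields are untouched.
    Idempotent.
    """
    out = series.copy()
    out["diet_price_kg"] = econ.diet_price_kg
    out["feedlot_daily_overhead"] = econ.feedlot_daily_overhead
    out["arroba_price"] = econ.arroba_price
    return out
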