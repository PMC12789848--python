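"""Annual carbon budgets, gap-based uncertainty, and uptake-season statistics.

Half-hourly fluxes are integrated to annual carbon sums per full calendar
year (gC m⁻² yr⁻¹), the annual uncertainty is the |cumulative flux| times the
fraction of gap-filled records in that year, and the CO2 uptake season is
bracketed by the first day the 10-day moving average of daily NEE drops below
zero and the day it turns positive again.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DAYS_PER_YEAR, STEPS_PER_YEAR, doy_365

SECONDS_PER_STEP = 1800.0
#: µmol CO2 m⁻² s⁻¹ → gC per half-hour
UMOL_CO2_TO_GC = SECONDS_PER_STEP * 12.0 * 1e-6
#: nmol CH4 m⁻² s⁻¹ → gC per half-hour
NMOL_CH4_TO_GC = SECONDS_PER_STEP * 12.0 * 1e-9
_UNIT_FACTORS = {"co2": UMOL_CO2_TO_GC, "ch4": NMOL_CH4_TO_GC}


@dataclass
class AnnualBudget:
    site_id: str
    year: int
    nee_cum: float        # gC m⁻² yr⁻¹
    ch4_cum: float        # gC m⁻² yr⁻¹
    gap_fraction_nee: float
    gap_fraction_ch4: float
    nee_uncertainty: float
    ch4_uncertainty: float
    uptake_start_doy: float | None = None
    uptake_end_doy: float | None = None
    uptake_length_days: float | None = None
    wetland_age: float | None = None


def integrate_annual(series: pd.Series, gas: str) -> float:
    """Integrate one full calendar year of half-hourly flux to gC m⁻² yr⁻¹.

    gas='co2' expects µmol CO2 m⁻² s⁻¹; gas='ch4' expects nmol CH4 m⁻² s⁻¹.
    """
    if gas not in _UNIT_FACTORS:
        raise ValueError(f"unknown gas tag {gas!r}")
    v = series.to_numpy(dtype=float)
    if len(v) != STEPS_PER_YEAR:
        raise ValueError(
            f"expected one full 365-day calendar year ({STEPS_PER_YEAR} half-hours), got {len(v)}"
        )
    if not np.isfinite(v).all():
        raise ValueError("series still contains gaps; gap-fill before integrating")
    return float(v.sum() * _UNIT_FACTORS[gas])


def gc_to_mean_flux(cumulative: float, gas: str) -> float:
    """Inverse of integrate_annual for a constant flux (unit round-trip)."""
    return cumulative / (_UNIT_FACTORS[gas] * STEPS_PER_YEAR)


def gap_uncertainty(cumulative: float, mask: np.ndarray | pd.Series) -> float:
    """Annual uncertainty = |cumulative flux| × fraction of gap-filled records."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        raise ValueError("empty gap mask")
    return abs(cumulative) * float(m.mean())


def daily_means(series: pd.Series, min_coverage: float = 0.8) -> pd.Series:
    """Daily means of a half-hourly series on the 365-day calendar.

    Days with less than ``min_coverage`` of half-hours present are NaN
    (gap-filled series are complete, so this only matters for external data).
    """
    grp = series.groupby([series.index.year, doy_365(series.index).astype(int)])
    means = grp.mean()
    cov = grp.count() / 48.0
    means[cov < min_coverage] = np.nan
    means.index.names = ["year", "doy"]
    return means


def uptake_window(daily_nee: np.ndarray, window: int = 10):
    """Detect the CO2-uptake season in one calendar year of daily NEE means.

    The trailing ``window``-day moving average (labeled by its last day,
    full windows only) is scanned: start = first day the average is below
    zero; end = the day before it first returns positive, or day 365 if it
    never does. Returns (start_doy, end_doy, length) or (None, None, None)
    when the average never drops below zero. A value of exactly zero counts
    as "not below zero". Only the first window is reported; later windows
    are returned in the companion list by :func:`uptake_windows_all`.
    """
    first = uptake_windows_all(daily_nee, window)
    return first[0] if first else (None, None, None)


def uptake_windows_all(daily_nee: np.ndarray, window: int = 10):
    v = np.asarray(daily_nee, dtype=float)
    if len(v) != DAYS_PER_YEAR:
        raise ValueError(f"expected {DAYS_PER_YEAR} daily values, got {len(v)}")
    if not np.isfinite(v).all():
        raise ValueError("daily series contains missing values")
    avg = pd.Series(v).rolling(window).mean().to_numpy()  # NaN before day `window`
    windows = []
    day = window  # 1-based doy of first full window
    while day <= DAYS_PER_YEAR:
        below = avg[day - 1] < 0
        if below:
            start = day
            end = DAYS_PER_YEAR
            for d in range(start + 1, DAYS_PER_YEAR + 1):
                if avg[d - 1] > 0:
                    end = d - 1
                    break
            windows.append((start, end, end - start + 1))
            day = end + 1
        day += 1
    return windows


def compare_uptake_lengths(groups):
    """Kruskal-Wallis rank test on uptake lengths grouped by site.

    ``groups`` is a mapping or sequence of per-site length collections.
    Returns (H, p). Identical-valued groups give H = 0, p = 1.
    """
    if hasattr(groups, "values"):
        groups = list(groups.values())
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 site-years each")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def annual_budgets(filled_nee: pd.Series, filled_ch4: pd.Series,
                   nee_gap_mask, ch4_gap_mask, site_id: str = "SITE",
                   restoration_year: int | None = None) -> list[AnnualBudget]:
    """Per-calendar-year budgets for a (possibly multi-year) filled record."""
    out = []
    years = sorted(set(filled_nee.index.year))
    for i, yr in enumerate(years):
        sel = filled_nee.index.year == yr
        if sel.sum() != STEPS_PER_YEAR:
            continue  # only full calendar years are admitted
        nee_y = filled_nee[sel]
        ch4_y = filled_ch4[sel]
        nee_cum = integrate_annual(nee_y, "co2")
        ch4_cum = integrate_annual(ch4_y, "ch4")
        gf_nee = float(np.asarray(nee_gap_mask)[sel].mean())
        gf_ch4 = float(np.asarray(ch4_gap_mask)[sel].mean())
        start, end, length = uptake_window(daily_means(nee_y).to_numpy())
        out.append(AnnualBudget(
            site_id=site_id, year=int(yr),
            nee_cum=nee_cum, ch4_cum=ch4_cum,
            gap_fraction_nee=gf_nee, gap_fraction_ch4=gf_ch4,
            nee_uncertainty=gap_uncertainty(nee_cum, np.asarray(nee_gap_mask)[sel]),
            ch4_uncertainty=gap_uncertainty(ch4_cum, np.asarray(ch4_gap_mask)[sel]),
            uptake_start_doy=start, uptake_end_doy=end, uptake_length_days=length,
            wetland_age=None if restoration_year is None else float(yr - restoration_year),
        ))
    return out


def budgets_to_frame(budgets) -> pd.DataFrame:
    """Tidy per-site-year table (the input contract for forcing/drivers)."""
    return pd.DataFrame([b.__dict__ for b in budgets])
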