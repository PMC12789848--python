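"""Shared in-memory containers for half-hourly flux/meteorology series."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Half-hours in a fixed 365-day calendar year (no leap days).
STEPS_PER_DAY = 48
DAYS_PER_YEAR = 365
STEPS_PER_YEAR = STEPS_PER_DAY * DAYS_PER_YEAR

#: Canonical meteorology column order (AmeriFlux-style vocabulary).
MET_COLUMNS = ("TA", "TS", "PA", "PAR", "NETRAD", "VPD", "WT", "GCC", "WD", "USTAR")
FLUX_COLUMNS = ("NEE", "FCH4")


@dataclass
class FluxSeries:
    """Half-hourly fluxes plus meteorology for one site.

    ``data`` is indexed by timestamp (interval start, local standard time);
    missing values are NaN. ``units`` records the unit of each column after
    normalization on read.
    """

    data: pd.DataFrame
    site_id: str = "SITE"
    units: dict = field(default_factory=dict)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value mask (True = missing)."""
        return self.data.isna()

    def __len__(self) -> int:
        return len(self.data)


def year_index(years: int, start_year: int = 2010) -> pd.DatetimeIndex:
    """Half-hourly timestamps for ``years`` fixed 365-day calendar years.

    Leap days are dropped so every year contributes exactly 17,520 rows,
    which keeps annual integrals directly comparable across years.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    idx = pd.date_range(
        start=f"{start_year}-01-01 00:00",
        end=f"{start_year + years - 1}-12-31 23:30",
        freq="30min",
    )
    idx = idx[~((idx.month == 2) & (idx.day == 29))]
    assert len(idx) == years * STEPS_PER_YEAR
    return idx


def doy_365(index: pd.DatetimeIndex) -> np.ndarray:
    """Day of year on the fixed 365-day calendar (leap days removed)."""
    doy = index.dayofyear.to_numpy().astype(float)
    leap = index.is_leap_year & (doy > 59)  # after Feb 28 in a leap year
    return np.where(leap, doy - 1, doy)
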