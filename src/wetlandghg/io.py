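"""Reading and writing AmeriFlux-style half-hourly CSV files.

Files carry TIMESTAMP_START/TIMESTAMP_END columns (YYYYMMDDHHMM, local
standard time, interval-start convention), the missing-value sentinel -9999,
and the standard variable vocabulary (FC/NEE, FCH4, TA, TS, PA, PPFD_IN,
NETRAD, VPD, WTD, USTAR, WD). On read the sentinel becomes an explicit
missing mask and units are normalized (VPD in hPa -> kPa); on write the
sentinel is restored, so read -> write round-trips losslessly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FluxSeries

SENTINEL = -9999.0
TS_FORMAT = "%Y%m%d%H%M"

#: external (AmeriFlux) name -> internal name
DEFAULT_COLUMN_MAP = {
    "FC": "NEE",
    "NEE": "NEE",
    "FCH4": "FCH4",
    "TA": "TA",
    "TS": "TS",
    "PA": "PA",
    "PPFD_IN": "PAR",
    "PAR": "PAR",
    "NETRAD": "NETRAD",
    "VPD": "VPD",
    "WTD": "WT",
    "WT": "WT",
    "GCC": "GCC",
    "WD": "WD",
    "USTAR": "USTAR",
}
#: internal name -> preferred external name on write
WRITE_NAMES = {"NEE": "FC", "PAR": "PPFD_IN", "WT": "WTD"}

CANONICAL_UNITS = {
    "NEE": "umolCO2 m-2 s-1", "FCH4": "nmolCH4 m-2 s-1", "TA": "degC",
    "TS": "degC", "PA": "kPa", "PAR": "umol m-2 s-1", "NETRAD": "W m-2",
    "VPD": "kPa", "WT": "m", "GCC": "-", "WD": "deg", "USTAR": "m s-1",
}


@dataclass
class SiteFileDialect:
    sentinel: float = SENTINEL
    vpd_unit: str = "kPa"          # "kPa" or "hPa" as declared by the file
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))


def read_site_csv(path, dialect: SiteFileDialect | None = None,
                  site_id: str | None = None) -> FluxSeries:
    """Read an AmeriFlux-style half-hourly CSV into a FluxSeries."""
    dialect = dialect or SiteFileDialect()
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("TIMESTAMP_START", "TIMESTAMP_END"):
        if col not in df.columns:
            raise ValueError(f"mandatory column {col} missing from {path.name}")
    idx = pd.to_datetime(df["TIMESTAMP_START"].astype(str), format=TS_FORMAT)
    if idx.duplicated().any():
        raise ValueError(f"duplicate timestamps in {path.name}")
    if not idx.is_monotonic_increasing:
        raise ValueError(f"timestamps not monotone in {path.name}")
    data = df.drop(columns=["TIMESTAMP_START", "TIMESTAMP_END"])
    data = data.rename(columns={c: dialect.column_map.get(c, c) for c in data.columns})
    data.index = pd.DatetimeIndex(idx.values)
    data = data.replace(dialect.sentinel, np.nan)
    units = {c: CANONICAL_UNITS.get(c, "?") for c in data.columns}
    provenance = {}
    if "VPD" in data.columns and dialect.vpd_unit.lower() == "hpa":
        data["VPD"] = data["VPD"] * 0.1
        provenance["VPD"] = "converted hPa -> kPa (x0.1)"
    series = FluxSeries(data=data, site_id=site_id or path.stem, units=units)
    series.units["_provenance"] = provenance
    return series


def write_site_csv(series: FluxSeries, path, header_comments: dict | None = None):
    """Write a FluxSeries to AmeriFlux-style CSV (sentinel restored).

    ``header_comments`` become ``# key: value`` provenance lines above the
    column header.
    """
    path = Path(path)
    df = series.data.copy()
    df = df.rename(columns={c: WRITE_NAMES.get(c, c) for c in df.columns})
    out = pd.DataFrame({
        "TIMESTAMP_START": df.index.strftime(TS_FORMAT),
        "TIMESTAMP_END": (df.index + pd.Timedelta(minutes=30)).strftime(TS_FORMAT),
    }, index=df.index)
    out = pd.concat([out, df.fillna(SENTINEL)], axis=1)
    with open(path, "w") as f:
        for k, v in (header_comments or {}).items():
            f.write(f"# {k}: {v}\n")
        out.to_csv(f, index=False, lineterminator="\n")
    return path


def read_raster_tiff(path) -> np.ndarray:
    """Read a single-band reflectance raster from a (Geo)TIFF via tifffile."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)
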