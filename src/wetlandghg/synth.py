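"""Synthetic half-hourly meteorology and CO2/CH4 flux generator.

Emulates the statistical structure of eddy-covariance records from restored
freshwater wetlands: light/greenness/temperature-driven net ecosystem exchange
(net uptake in summer, net respiration in winter), summer-peaking CH4 emission
driven by soil temperature and water table, disturbance years (water-table
drawdown, salinity intrusion, insect outbreaks) that suppress uptake, and
realistic gap patterns. Every downstream stage of the package is testable
against the known "truth" series produced here.

Units follow the flux-network convention: NEE in µmol CO2 m⁻² s⁻¹ (negative =
uptake), FCH4 in nmol CH4 m⁻² s⁻¹. Conversion to gC is done only in budgets.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    DAYS_PER_YEAR,
    STEPS_PER_DAY,
    STEPS_PER_YEAR,
    FluxSeries,
    doy_365,
    year_index,
)

VALID_DISTURBANCES = ("drawdown", "salinity", "insect")


@dataclass
class Disturbance:
    """A site-level disturbance in one year.

    ``severity`` in [0, 1] scales the suppression of gross primary
    productivity (and, for drawdown, of CH4 emission). Drawdown events also
    pull the water table below the soil surface for their duration.
    """

    year: int  # 0-based index into the scenario's years
    kind: str
    severity: float
    start_doy: int = 140
    end_doy: int = 260

    def __post_init__(self):
        if self.kind not in VALID_DISTURBANCES:
            raise ValueError(f"unknown disturbance kind {self.kind!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")


@dataclass
class SiteScenario:
    """Configuration of one synthetic site record."""

    site_id: str = "SYN"
    years: int = 3
    vegetation_trajectory: Sequence[float] = ()
    disturbances: Sequence[Disturbance] = ()
    latitude: float = 38.1
    wt_offset: float = 0.15  # mean water table above soil surface, m
    seed: int = 0
    start_year: int = 2010

    def __post_init__(self):
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if not self.vegetation_trajectory:
            self.vegetation_trajectory = tuple(
                min(1.0, 0.4 + 0.2 * y) for y in range(self.years)
            )
        if len(self.vegetation_trajectory) != self.years:
            raise ValueError("vegetation_trajectory length must equal years")
        if any(not 0.0 <= g <= 1.0 for g in self.vegetation_trajectory):
            raise ValueError("greenness must be within [0, 1]")
        self.disturbances = tuple(
            d if isinstance(d, Disturbance) else Disturbance(*d)
            for d in self.disturbances
        )


@dataclass
class MetSeries:
    """Complete (gap-free) meteorology truth series."""

    data: pd.DataFrame
    scenario: SiteScenario

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FluxParams:
    """Coefficients of the flux-generating process.

    GPP follows a rectangular-hyperbola light response scaled by greenness
    and an air-temperature modifier; ER is exponential (Q10) in soil
    temperature; CH4 is exponential in soil temperature gated by a logistic
    water-table term. Defaults give annual budgets in the range reported for
    mature temperate restored wetlands (NEE of order −400 gC m⁻² yr⁻¹, CH4
    of order 35 gC m⁻² yr⁻¹).
    """

    gpp_amax: float = 28.0       # µmol m⁻² s⁻¹ at saturating light, greenness 1
    gpp_k_par: float = 350.0     # half-saturation PAR, µmol m⁻² s⁻¹
    gpp_t_opt: float = 24.0      # °C, optimum of Gaussian temperature modifier
    gpp_t_width: float = 14.0    # °C
    er_base: float = 1.6         # µmol m⁻² s⁻¹ at TS = 10 °C
    er_q10: float = 2.0
    ch4_base: float = 55.0       # nmol m⁻² s⁻¹ at TS = 10 °C, fully inundated
    ch4_q10: float = 3.2
    ch4_wt_mid: float = -0.05    # m, logistic midpoint of water-table gate
    ch4_wt_scale: float = 0.05   # m
    nee_noise_base: float = 0.3  # additive Gaussian sd, µmol m⁻² s⁻¹
    nee_noise_rel: float = 0.08  # sd fraction of |flux|
    ch4_noise_sigma: float = 0.25  # lognormal sigma (multiplicative)


@dataclass
class FluxTruth:
    """Gap-free flux truth with the generating coefficients attached.

    Invariant: ``NEE = ER - GPP`` exactly at every timestamp (observation
    noise is carried inside ER so the identity is conserved).
    """

    data: pd.DataFrame  # columns NEE, FCH4, ER, GPP
    params: FluxParams
    scenario: SiteScenario


@dataclass
class GapConfig:
    """Gap-pattern configuration: random missingness plus block outages."""

    random_rate: float = 0.0
    blocks_per_year: float = 0.0
    block_mean_length: int = 48  # half-hours; 48 = one day
    seed: int = 0
    variables: Sequence[str] = ("NEE", "FCH4")
    mask_met: bool = False

    def __post_init__(self):
        if not 0.0 <= self.random_rate < 1.0:
            raise ValueError("random_rate must be in [0, 1)")
        if self.blocks_per_year < 0:
            raise ValueError("blocks_per_year must be >= 0")


@dataclass
class GapMask:
    """Boolean missingness mask per flux variable plus its generator record."""

    mask: pd.DataFrame
    config: GapConfig

    def fraction(self, var: str) -> float:
        return float(self.mask[var].mean())


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float = 0.95) -> np.ndarray:
    """Autocorrelated Gaussian noise with stationary standard deviation sd."""
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def _solar_elevation_sin(latitude: float, doy: np.ndarray, hour: np.ndarray) -> np.ndarray:
    decl = np.deg2rad(-23.44) * np.cos(2 * np.pi * (doy + 10) / 365.0)
    lat = np.deg2rad(latitude)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    return np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)


def _season_bump(doy: np.ndarray) -> np.ndarray:
    """Smooth growing-season curve in [0, 1], peaking near day 200."""
    return np.exp(-0.5 * ((doy - 200.0) / 60.0) ** 2)


def greenness_series(scenario: SiteScenario, index: pd.DatetimeIndex) -> np.ndarray:
    """Per-timestamp greenness in [0, 1]: yearly trajectory × seasonal bump."""
    doy = doy_365(index)
    year_idx = index.year.to_numpy() - scenario.start_year
    traj = np.asarray(scenario.vegetation_trajectory, dtype=float)[year_idx]
    return traj * _season_bump(doy)


def _disturbance_window(scenario: SiteScenario, index: pd.DatetimeIndex, kinds=None):
    """(in_window, severity) arrays over the index for matching disturbances."""
    doy = doy_365(index)
    year_idx = index.year.to_numpy() - scenario.start_year
    sev = np.zeros(len(index))
    for d in scenario.disturbances:
        if kinds is not None and d.kind not in kinds:
            continue
        win = (year_idx == d.year) & (doy >= d.start_doy) & (doy <= d.end_doy)
        sev = np.maximum(sev, np.where(win, d.severity, 0.0))
    return sev > 0, sev


def generate_met(scenario: SiteScenario) -> MetSeries:
    """Generate a complete half-hourly meteorology series.

    Deterministic for a fixed scenario seed. Each variable is a seasonal
    harmonic plus a diurnal cycle plus AR(1) noise; the water table follows
    the management scenario and drops below the soil surface during drawdown
    events.
    """
    idx = year_index(scenario.years, scenario.start_year)
    n = len(idx)
    rng = np.random.default_rng(scenario.seed)
    doy = doy_365(idx)
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0

    season = np.cos(2 * np.pi * (doy - 200.0) / 365.0)  # +1 mid-summer
    sin_elev = _solar_elevation_sin(scenario.latitude, doy, hour)
    daylight = np.clip(sin_elev, 0.0, None)

    # Radiation: PAR = 0 at night by construction; cloudiness modulates days.
    cloud = np.clip(1.0 - 0.35 * np.abs(_ar1(rng, n, 1.0, 0.98)), 0.2, 1.0)
    par = 2200.0 * daylight * cloud
    netrad = 0.55 * par - 40.0 + _ar1(rng, n, 15.0, 0.9)

    ta = 14.0 + 9.0 * season + 4.5 * daylight + _ar1(rng, n, 2.0, 0.97)
    # Soil temperature: damped, slightly lagged air temperature.
    ts = 13.0 + 7.0 * np.cos(2 * np.pi * (doy - 215.0) / 365.0) + 1.0 * daylight
    ts = ts + _ar1(rng, n, 0.8, 0.99)

    pa = 101.3 + _ar1(rng, n, 0.4, 0.995)
    es = 0.6108 * np.exp(17.27 * ta / (ta + 237.3))  # kPa, Tetens
    rh = np.clip(0.75 - 0.15 * daylight + _ar1(rng, n, 0.08, 0.97), 0.2, 1.0)
    vpd = np.clip(es * (1.0 - rh), 0.0, None)

    wt = scenario.wt_offset + 0.08 * np.cos(2 * np.pi * (doy - 60.0) / 365.0)
    wt = wt + _ar1(rng, n, 0.03, 0.995)
    in_draw, sev = _disturbance_window(scenario, idx, kinds=("drawdown",))
    # Drawdown pulls the table below the surface, deeper for higher severity.
    wt = np.where(in_draw, -0.05 - 0.45 * sev, wt)

    gcc = 0.30 + 0.12 * greenness_series(scenario, idx) + _ar1(rng, n, 0.005, 0.9)
    wd = (225.0 + 40.0 * _ar1(rng, n, 1.0, 0.9)) % 360.0
    ustar = np.clip(0.28 + 0.1 * daylight + _ar1(rng, n, 0.08, 0.9), 0.02, None)

    data = pd.DataFrame(
        {
            "TA": ta, "TS": ts, "PA": pa, "PAR": par, "NETRAD": netrad,
            "VPD": vpd, "WT": wt, "GCC": gcc, "WD": wd, "USTAR": ustar,
        },
        index=idx,
    )
    assert not data.isna().any().any()
    return MetSeries(data=data, scenario=scenario)


def generate_fluxes(
    met: MetSeries,
    scenario: SiteScenario | None = None,
    params: FluxParams | None = None,
) -> FluxTruth:
    """Generate flux truth (NEE, FCH4, ER, GPP) from meteorology.

    GPP is a rectangular hyperbola in PAR scaled by greenness and a Gaussian
    air-temperature modifier; ER is Q10-exponential in soil temperature; CH4
    is Q10-exponential in soil temperature gated by a logistic water-table
    term with multiplicative lognormal noise. Disturbance years suppress GPP
    (and CH4 for drawdown) by their severity. NEE observation noise is
    additive Gaussian with |flux|-scaled sd and is carried inside ER so that
    NEE = ER − GPP holds exactly.
    """
    scenario = scenario or met.scenario
    params = params or FluxParams()
    d = met.data
    if scenario.years * STEPS_PER_YEAR != len(d):
        raise ValueError("met series length does not match scenario years")
    idx = d.index
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 7]))

    green = greenness_series(scenario, idx)
    _, sev_gpp = _disturbance_window(scenario, idx)
    _, sev_ch4 = _disturbance_window(scenario, idx, kinds=("drawdown",))

    par = d["PAR"].to_numpy()
    light = par / (par + params.gpp_k_par)
    t_mod = np.exp(-0.5 * ((d["TA"].to_numpy() - params.gpp_t_opt) / params.gpp_t_width) ** 2)
    gpp = params.gpp_amax * green * light * t_mod * (1.0 - sev_gpp)

    er = params.er_base * params.er_q10 ** ((d["TS"].to_numpy() - 10.0) / 10.0)
    # Aerobic boost when the water table is below the surface.
    er = er * (1.0 + np.clip(-d["WT"].to_numpy(), 0.0, None) * 1.5)

    nee_clean = er - gpp
    noise = rng.normal(0.0, params.nee_noise_base + params.nee_noise_rel * np.abs(nee_clean))
    noise = np.maximum(noise, -er)  # keep ER_true >= 0
    er_true = er + noise
    nee_true = er_true - gpp

    wt_gate = 1.0 / (1.0 + np.exp(-(d["WT"].to_numpy() - params.ch4_wt_mid) / params.ch4_wt_scale))
    ch4 = params.ch4_base * params.ch4_q10 ** ((d["TS"].to_numpy() - 10.0) / 10.0)
    ch4 = ch4 * wt_gate * (1.0 - sev_ch4)
    ch4 = ch4 * rng.lognormal(mean=-0.5 * params.ch4_noise_sigma**2,
                              sigma=params.ch4_noise_sigma, size=len(idx))

    data = pd.DataFrame(
        {"NEE": nee_true, "FCH4": ch4, "ER": er_true, "GPP": gpp}, index=idx
    )
    return FluxTruth(data=data, params=params, scenario=scenario)


def apply_gaps(truth: FluxTruth, met: MetSeries, config: GapConfig):
    """Apply a gap mask to the truth, returning (observed FluxSeries, GapMask).

    Random (MCAR) missingness at ``random_rate`` plus block outages with
    geometric lengths of mean ``block_mean_length``, both reproducible from
    the config seed. The mask applies to flux variables only unless
    ``mask_met`` is set.
    """
    idx = truth.data.index
    n = len(idx)
    rng = np.random.default_rng(config.seed)
    mask = pd.DataFrame(False, index=idx, columns=list(config.variables))
    for var in config.variables:
        m = rng.random(n) < config.random_rate
        n_blocks = rng.poisson(config.blocks_per_year * (n / STEPS_PER_YEAR))
        if n_blocks > 0:
            starts = rng.integers(0, n, size=n_blocks)
            lengths = rng.geometric(1.0 / config.block_mean_length, size=n_blocks)
            for s, l in zip(starts, lengths):
                m[s : s + l] = True
        mask[var] = m

    observed = pd.concat([truth.data[["NEE", "FCH4"]].copy(), met.data.copy()], axis=1)
    for var in config.variables:
        observed.loc[mask[var].to_numpy(), var] = np.nan
    if config.mask_met:
        any_gap = mask.any(axis=1).to_numpy()
        observed.loc[any_gap, list(met.data.columns)] = np.nan
    series = FluxSeries(
        data=observed,
        site_id=truth.scenario.site_id,
        units={"NEE": "umolCO2 m-2 s-1", "FCH4": "nmolCH4 m-2 s-1"},
    )
    return series, GapMask(mask=mask, config=config)


def generate_site(scenario: SiteScenario, gap_config: GapConfig | None = None,
                  params: FluxParams | None = None):
    """Convenience wrapper: met + fluxes + gaps for one scenario."""
    met = generate_met(scenario)
    truth = generate_fluxes(met, scenario, params)
    if gap_config is None:
        gap_config = GapConfig(random_rate=0.15, blocks_per_year=6, seed=scenario.seed + 1)
    observed, mask = apply_gaps(truth, met, gap_config)
    return met, truth, observed, mask
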