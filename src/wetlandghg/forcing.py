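"""Atmospheric perturbation model: radiative balance and switchover times.

The model tracks the atmospheric inventories of ecosystem-derived CO2 and
CH4 under annual emissions (or uptake) and first-order removal. CH4 follows
simple one-pool decay with its carbon oxidized to CO2; CO2 is buffered
through five non-interacting pools with distinct lifetimes (one effectively
permanent), so a pulse of CO2 decays as the impulse response

    IRF(t) = sum_i a_i * exp(-t / tau_i),   sum_i a_i = 1.

Burdens are converted to kg of gas before radiative efficiencies are
applied, and the radiative balance of a restored wetland is compared with
that of its prior land use (the baseline); the switchover time is the first
year the net (delta) radiative forcing reaches zero and stays at or below
zero. Monte-Carlo resampling of the monitored years propagates interannual
flux variability into a 95% interval on the switchover year.

All model constants are configuration, not code: see
``data/forcing_defaults.yaml`` for the shipped defaults and their provenance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

GC_TO_KG_CO2 = (44.0 / 12.0) * 1e-3   # gC m-2 -> kg CO2 m-2
GC_TO_KG_CH4 = (16.0 / 12.0) * 1e-3   # gC m-2 -> kg CH4 m-2
CH4_TO_CO2_MASS = 44.0 / 16.0         # kg CO2 produced per kg CH4 oxidized


@dataclass
class PerturbationParams:
    """Pool structure, lifetimes and radiative efficiencies of the model."""

    co2_pool_fractions: np.ndarray
    co2_pool_lifetimes: np.ndarray   # years; np.inf allowed
    ch4_lifetime: float              # years
    ch4_oxidation_yield: float       # fraction of decayed CH4-C -> CO2
    re_co2: float                    # W m-2 per kg CO2
    re_ch4: float                    # W m-2 per kg CH4
    ch4_indirect_multiplier: float = 1.65

    def __post_init__(self):
        self.co2_pool_fractions = np.asarray(self.co2_pool_fractions, dtype=float)
        self.co2_pool_lifetimes = np.asarray(self.co2_pool_lifetimes, dtype=float)
        if abs(self.co2_pool_fractions.sum() - 1.0) > 1e-12:
            raise ValueError("CO2 pool fractions must sum to 1")
        if (self.co2_pool_fractions < 0).any():
            raise ValueError("CO2 pool fractions must be >= 0")
        if (self.co2_pool_lifetimes <= 0).any() or self.ch4_lifetime <= 0:
            raise ValueError("lifetimes must be positive")
        if not 0.0 <= self.ch4_oxidation_yield <= 1.0:
            raise ValueError("oxidation yield must be in [0, 1]")
        if self.re_co2 <= 0 or self.re_ch4 <= 0:
            raise ValueError("radiative efficiencies must be positive")
        if self.ch4_indirect_multiplier < 1.0:
            raise ValueError("indirect multiplier must be >= 1")

    @classmethod
    def default(cls) -> "PerturbationParams":
        """Load the shipped default parameterization."""
        with resources.files("wetlandghg.data").joinpath("forcing_defaults.yaml").open() as f:
            cfg = yaml.safe_load(f)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PerturbationParams":
        return cls(
            co2_pool_fractions=cfg["co2_pool_fractions"],
            co2_pool_lifetimes=cfg["co2_pool_lifetimes"],
            ch4_lifetime=float(cfg["ch4_lifetime"]),
            ch4_oxidation_yield=float(cfg["ch4_oxidation_yield"]),
            re_co2=float(cfg["re_co2"]),
            re_ch4=float(cfg["re_ch4"]),
            ch4_indirect_multiplier=float(cfg.get("ch4_indirect_multiplier", 1.65)),
        )

    @property
    def co2_decay(self) -> np.ndarray:
        """Per-year retention factor of each CO2 pool."""
        with np.errstate(divide="ignore"):
            return np.exp(-1.0 / self.co2_pool_lifetimes)

    @property
    def ch4_decay(self) -> float:
        return float(np.exp(-1.0 / self.ch4_lifetime))


def mass_convert(flux_gc: float | np.ndarray, gas: str) -> float | np.ndarray:
    """gC m-2 yr-1 -> kg gas m-2 yr-1 (CO2: x44/12e-3, CH4: x16/12e-3)."""
    if gas.lower() == "co2":
        return np.multiply(flux_gc, GC_TO_KG_CO2)
    if gas.lower() == "ch4":
        return np.multiply(flux_gc, GC_TO_KG_CH4)
    raise ValueError(f"unknown gas tag {gas!r}")


def co2_impulse_response(t, params: PerturbationParams):
    """Fraction of a CO2 pulse remaining airborne after ``t`` years."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    with np.errstate(divide="ignore"):
        rates = 1.0 / params.co2_pool_lifetimes
    out = np.sum(
        params.co2_pool_fractions * np.exp(-t[..., None] * rates), axis=-1
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class BurdenState:
    """Atmospheric inventory: kg CH4 plus kg CO2 in each pool."""

    co2_pools: np.ndarray
    ch4: np.ndarray | float

    @classmethod
    def zero(cls, params: PerturbationParams, shape=()) -> "BurdenState":
        return cls(
            co2_pools=np.zeros(shape + (len(params.co2_pool_fractions),)),
            ch4=np.zeros(shape),
        )

    @property
    def co2(self):
        return self.co2_pools.sum(axis=-1)


def step_burdens(state: BurdenState, co2_input_kg, ch4_input_kg,
                 params: PerturbationParams):
    """Advance the inventory by one year (pulse-at-start convention).

    The standing burdens decay for one year; the carbon of the decayed CH4
    is oxidized to CO2 (mass rescale 44/16 times the yield) and joins the
    year's net CO2 input, which is distributed over the pools by their
    fractions. Returns (next_state, diagnostics); the diagnostics carry the
    decayed/removed masses so a carbon ledger can be closed externally.
    """
    ch4_decayed = state.ch4 * (1.0 - params.ch4_decay)
    ch4_next = state.ch4 * params.ch4_decay + ch4_input_kg
    co2_removed = (state.co2_pools * (1.0 - params.co2_decay)).sum(axis=-1)
    co2_from_ch4 = ch4_decayed * params.ch4_oxidation_yield * CH4_TO_CO2_MASS
    co2_in = np.asarray(co2_input_kg) + co2_from_ch4
    pools_next = state.co2_pools * params.co2_decay + \
        co2_in[..., None] * params.co2_pool_fractions
    info = {
        "ch4_decayed": ch4_decayed,
        "co2_removed": co2_removed,
        "co2_from_ch4": co2_from_ch4,
    }
    return BurdenState(co2_pools=pools_next, ch4=ch4_next), info


def simulate_burdens(co2_inputs_kg: np.ndarray, ch4_inputs_kg: np.ndarray,
                     params: PerturbationParams):
    """Run the recursion over the leading-..., time-last input arrays.

    Inputs have shape (..., T); returns (co2_burden, ch4_burden) of the same
    shape, where entry t is the inventory just after year t's input.
    """
    co2_inputs_kg = np.asarray(co2_inputs_kg, dtype=float)
    ch4_inputs_kg = np.asarray(ch4_inputs_kg, dtype=float)
    if co2_inputs_kg.shape != ch4_inputs_kg.shape:
        raise ValueError("CO2 and CH4 input arrays must share a shape")
    T = co2_inputs_kg.shape[-1]
    state = BurdenState.zero(params, shape=co2_inputs_kg.shape[:-1])
    co2_burden = np.empty_like(co2_inputs_kg)
    ch4_burden = np.empty_like(ch4_inputs_kg)
    for t in range(T):
        state, _ = step_burdens(state, co2_inputs_kg[..., t], ch4_inputs_kg[..., t], params)
        co2_burden[..., t] = state.co2
        ch4_burden[..., t] = state.ch4
    return co2_burden, ch4_burden


@dataclass
class AnnualFluxScenario:
    """Annual flux record of a restored wetland and its baseline land use.

    Fluxes are gC m-2 yr-1 (NEE negative = uptake, CH4 as CH4-C emission).
    Baselines may be scalars (constant prior land use) or per-year arrays.
    Years beyond the monitored record are filled by recycling the record
    cyclically, preserving the observed interannual distribution.
    """

    nee: np.ndarray
    ch4: np.ndarray
    baseline_nee: np.ndarray | float = 0.0
    baseline_ch4: np.ndarray | float = 0.0
    horizon: int = 200
    mode: str = "sustained"   # or "instantaneous"

    def __post_init__(self):
        self.nee = np.atleast_1d(np.asarray(self.nee, dtype=float))
        self.ch4 = np.atleast_1d(np.asarray(self.ch4, dtype=float))
        if self.nee.shape != self.ch4.shape:
            raise ValueError("NEE and CH4 records must have equal length")
        if self.horizon < len(self.nee):
            raise ValueError("horizon shorter than the monitored record")
        if self.mode not in ("sustained", "instantaneous"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def _extend(self, record: np.ndarray) -> np.ndarray:
        reps = int(np.ceil(self.horizon / len(record)))
        return np.tile(record, reps)[: self.horizon]

    def inputs(self):
        """(co2_in, ch4_in, base_co2_in, base_ch4_in) in kg gas m-2 yr-1."""
        base_nee = np.broadcast_to(np.atleast_1d(self.baseline_nee), (len(self.nee),)) \
            if np.ndim(self.baseline_nee) else np.full(len(self.nee), self.baseline_nee)
        base_ch4 = np.broadcast_to(np.atleast_1d(self.baseline_ch4), (len(self.ch4),)) \
            if np.ndim(self.baseline_ch4) else np.full(len(self.ch4), self.baseline_ch4)
        if self.mode == "sustained":
            nee, ch4 = self._extend(self.nee), self._extend(self.ch4)
            bnee, bch4 = self._extend(np.asarray(base_nee)), self._extend(np.asarray(base_ch4))
        else:
            # record-mean annual flux emitted as a single pulse at year 0
            nee = np.zeros(self.horizon); nee[0] = self.nee.mean()
            ch4 = np.zeros(self.horizon); ch4[0] = self.ch4.mean()
            bnee = np.zeros(self.horizon); bnee[0] = np.mean(base_nee)
            bch4 = np.zeros(self.horizon); bch4[0] = np.mean(base_ch4)
        return (mass_convert(nee, "co2"), mass_convert(ch4, "ch4"),
                mass_convert(bnee, "co2"), mass_convert(bch4, "ch4"))


@dataclass
class ForcingTrajectory:
    """Per-year burdens and radiative balance over the horizon.

    ``years`` counts 1..horizon after restoration; ``delta_forcing`` is the
    wetland-minus-baseline net radiative forcing (W m-2 of atmosphere per
    m2 of site).
    """

    years: np.ndarray
    co2_burden: np.ndarray
    ch4_burden: np.ndarray
    forcing: np.ndarray
    baseline_forcing: np.ndarray
    delta_forcing: np.ndarray
    mode: str
    switchover_year: int | None = None

    @property
    def cumulative_delta(self) -> np.ndarray:
        return np.cumsum(self.delta_forcing)


def _forcing_from_burdens(co2_b, ch4_b, params: PerturbationParams):
    return params.re_co2 * co2_b + params.re_ch4 * params.ch4_indirect_multiplier * ch4_b


def radiative_balance(scenario: AnnualFluxScenario,
                      params: PerturbationParams | None = None) -> ForcingTrajectory:
    """Model the radiative balance of the scenario over its horizon."""
    params = params or PerturbationParams.default()
    co2_in, ch4_in, bco2_in, bch4_in = scenario.inputs()
    co2_b, ch4_b = simulate_burdens(co2_in, ch4_in, params)
    bco2_b, bch4_b = simulate_burdens(bco2_in, bch4_in, params)
    forcing = _forcing_from_burdens(co2_b, ch4_b, params)
    base = _forcing_from_burdens(bco2_b, bch4_b, params)
    traj = ForcingTrajectory(
        years=np.arange(1, scenario.horizon + 1),
        co2_burden=co2_b, ch4_burden=ch4_b,
        forcing=forcing, baseline_forcing=base,
        delta_forcing=forcing - base, mode=scenario.mode,
    )
    traj.switchover_year = switchover(traj.delta_forcing)
    return traj


def switchover(delta_forcing: np.ndarray, persistent: bool = True):
    """First year (1-based) the net forcing reaches zero, or None.

    With ``persistent`` (default) the crossing must hold for the rest of the
    horizon — transient dips from resampled interannual variability do not
    count. Returns None ("undeterminable") if no qualifying year exists
    within the horizon.
    """
    d = np.asarray(delta_forcing, dtype=float)
    nonpos = d <= 0.0
    if persistent:
        ok = np.flip(np.logical_and.accumulate(np.flip(nonpos)))
    else:
        ok = nonpos
    idx = np.flatnonzero(ok)
    return int(idx[0] + 1) if idx.size else None


def _switchover_vec(delta: np.ndarray, persistent: bool = True) -> np.ndarray:
    """Vectorized switchover over the leading replicate axis; NaN = undefined."""
    nonpos = delta <= 0.0
    if persistent:
        ok = np.flip(np.logical_and.accumulate(np.flip(nonpos, axis=-1), axis=-1), axis=-1)
    else:
        ok = nonpos
    any_ok = ok.any(axis=-1)
    first = ok.argmax(axis=-1) + 1.0
    return np.where(any_ok, first, np.nan)


@dataclass
class SwitchoverMC:
    """Monte-Carlo switchover distribution for one site record."""

    years: np.ndarray             # per-replicate switchover, NaN = undefined
    median: float
    ci: tuple                     # (2.5th, 97.5th percentile)
    undefined_fraction: float
    point_estimate: int | None = None

    @property
    def ci_width(self) -> float:
        return self.ci[1] - self.ci[0]


def switchover_mc(nee_record, ch4_record, baseline_nee=0.0, baseline_ch4=0.0,
                  params: PerturbationParams | None = None, n: int = 1000,
                  seed: int = 0, horizon: int = 200, paired: bool = True,
                  persistent: bool = True) -> SwitchoverMC:
    """Monte-Carlo uncertainty on the sustained-mode switchover year.

    Each replicate resamples the monitored years with replacement (paired
    NEE/CH4 by default, preserving their covariance) and recycles the
    resampled block to the horizon. Undefined switchovers (no crossing
    within the horizon) enter the percentiles as +inf and are additionally
    reported as a fraction.
    """
    params = params or PerturbationParams.default()
    nee = np.atleast_1d(np.asarray(nee_record, dtype=float))
    ch4 = np.atleast_1d(np.asarray(ch4_record, dtype=float))
    N = len(nee)
    if N < 2:
        warnings.warn("single-year record: no interannual variability; interval is degenerate")
    rng = np.random.default_rng(seed)
    idx_nee = rng.integers(0, N, size=(n, N))
    idx_ch4 = idx_nee if paired else rng.integers(0, N, size=(n, N))
    reps = int(np.ceil(horizon / N))
    nee_mc = np.tile(nee[idx_nee], (1, reps))[:, :horizon]
    ch4_mc = np.tile(ch4[idx_ch4], (1, reps))[:, :horizon]

    base_nee = np.broadcast_to(np.asarray(baseline_nee, dtype=float), (N,)) \
        if np.ndim(baseline_nee) else np.full(N, baseline_nee)
    base_ch4 = np.broadcast_to(np.asarray(baseline_ch4, dtype=float), (N,)) \
        if np.ndim(baseline_ch4) else np.full(N, baseline_ch4)
    base_nee = np.tile(base_nee, reps)[:horizon]
    base_ch4 = np.tile(base_ch4, reps)[:horizon]

    co2_b, ch4_b = simulate_burdens(mass_convert(nee_mc, "co2"),
                                    mass_convert(ch4_mc, "ch4"), params)
    bco2_b, bch4_b = simulate_burdens(mass_convert(base_nee, "co2"),
                                      mass_convert(base_ch4, "ch4"), params)
    delta = _forcing_from_burdens(co2_b, ch4_b, params) - \
        _forcing_from_burdens(bco2_b, bch4_b, params)
    so = _switchover_vec(delta, persistent=persistent)
    finite = np.nan_to_num(so, nan=np.inf)
    # nearest-rank percentiles: switchover years are integers and undefined
    # outcomes are +inf, which linear interpolation would turn into NaN
    lo, med, hi = np.percentile(finite, [2.5, 50.0, 97.5], method="nearest")
    point = switchover(
        radiative_balance(
            AnnualFluxScenario(nee, ch4, baseline_nee, baseline_ch4,
                               horizon=horizon, mode="sustained"),
            params,
        ).delta_forcing,
        persistent=persistent,
    )
    return SwitchoverMC(
        years=so,
        median=float(med),
        ci=(float(lo), float(hi)),
        undefined_fraction=float(np.isnan(so).mean()),
        point_estimate=point,
    )
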