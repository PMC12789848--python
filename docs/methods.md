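# Methods

This note records the models implemented in `wetlandghg`, the defaults and
why, and the choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data generator

The generator (`wetlandghg.synth`) produces half-hourly meteorology and
"true" CO2/CH4 fluxes with the statistical structure the analysis chain
assumes, so that every downstream stage can be tested against known truth.

**Calendar.** Fixed 365-day years (leap days dropped), 48 half-hours per day,
17,520 records per year, timestamps at interval start in local standard
time. Budgets are per calendar year, so a fixed-length year keeps annual
integrals exactly comparable.

**Meteorology.** Each variable is a seasonal harmonic plus a diurnal cycle
plus AR(1) noise (deterministic given the scenario seed). PAR follows solar
elevation from latitude and day of year and is exactly zero at night; VPD
comes from the Tetens saturation curve and a stochastic relative humidity;
the water table sits at a configurable offset above the soil surface
(default +0.15 m, a managed impounded wetland) and is forced below the
surface during drawdown events.

**Fluxes.**

- GPP = Amax · greenness · PAR/(PAR + k_PAR) · exp(−((TA − T_opt)/w)²),
  with Amax = 28 µmol m⁻² s⁻¹, k_PAR = 350 µmol m⁻² s⁻¹, T_opt = 24 °C.
  Greenness is the yearly vegetation trajectory times a Gaussian
  growing-season bump peaking near day 200.
- ER = R₁₀ · Q10^((TS−10)/10) with R₁₀ = 1.6 µmol m⁻² s⁻¹, Q10 = 2, plus an
  aerobic amplification when the water table is below the surface.
- FCH4 = F₁₀ · Q10^((TS−10)/10) · logistic((WT − w₀)/s) with F₁₀ = 55
  nmol m⁻² s⁻¹, Q10 = 3.2, w₀ = −0.05 m, s = 0.05 m, times multiplicative
  lognormal noise (σ = 0.25, mean-one). The logistic gate shuts methane off
  when the soil drains; soil temperature carries the seasonality.
- NEE = ER − GPP with additive Gaussian observation noise
  (sd = 0.3 + 0.08·|flux| µmol m⁻² s⁻¹). The noise is carried inside ER
  (floored so ER ≥ 0) so the identity NEE = ER − GPP holds exactly at every
  timestamp. The magnitudes are not stated by any monitoring protocol we
  emulate; they were chosen once as plausible for open-path eddy-covariance
  systems and are configurable.

With these defaults a fully vegetated year takes up roughly 400–700 gC CO2-C
m⁻² and emits ~35 gC CH4-C m⁻², i.e. magnitudes typical of mature temperate
restored wetlands; young or disturbed years are sources. Disturbances act as
multiplicative GPP suppression (severity in [0,1]; drawdown also suppresses
CH4 through the water-table gate and the explicit CH4 suppression factor).

The generator does **not** emulate: u*-filtering artifacts and their
systematic nighttime bias, storage-flux corrections, instrument-specific
spectral losses, gap mechanisms correlated with weather (gaps here are MCAR
plus random blocks), multi-modal vegetation phenology, or lateral carbon
export. Passing the recovery tests therefore shows the chain is correct and
unbiased under these idealized conditions, not that real-data error will be
this small.

## Gap-filling and partitioning

Predictors are TA, NETRAD, PAR, VPD, WT, GCC, WD and USTAR; wind direction
enters as (sin, cos) so the discontinuity at 360° disappears. Predictors are
standardized on the training rows; the target is centered and scaled (a
zero-variance target inverts to the constant exactly).

Complete-case rows are clustered by k-means (k = 10 by default) and each
cluster is split 70/15/15 into train/validation/test, which keeps all
seasons and times of day represented in every set. Candidate networks are
single-hidden-layer perceptrons of increasing width (2, 4, 8, 16 tanh
units, trained with L-BFGS); the selected architecture is the simplest one
whose successor improves validation RMSE by less than 5%. Training is
repeated (20 runs by default) from independent initializations; the median
prediction across runs fills the gaps, observed values are never modified,
and the per-run spread and held-out RMSE are retained as diagnostics.
Validation RMSE for the parsimony rule is averaged over repeats when more
than one repeat per candidate is requested. CH4 uses the same protocol and
predictor set as NEE. An optional `max_train` subsample bounds the cost of a
single run on multi-year records without changing the protocol.

Partitioning trains the same network family on nighttime rows only
(night = PAR < 10 µmol m⁻² s⁻¹, configurable), where NEE = ER because
photosynthesis is inactive, using non-radiation predictors, and predicts ER
at all timestamps; GPP = ER − NEE by construction. ER is not clipped at
zero — clipping would break the partition identity — and the fraction of
negative ER and daytime-negative GPP is reported instead.

## Budgets and uptake season

Annual sums convert flux densities to carbon: µmol CO2 m⁻² s⁻¹ × 1800 s ×
12×10⁻⁶ gC µmol⁻¹ per half-hour (so a constant −1 µmol m⁻² s⁻¹ is
−378.43 gC m⁻² yr⁻¹) and nmol CH4 m⁻² s⁻¹ × 1800 × 12×10⁻⁹. Only full
calendar years are admitted. Annual uncertainty is |cumulative flux| times
the fraction of gap-filled records in that year.

The uptake season uses the 10-day **trailing** moving average of daily NEE,
labeled by its last day and evaluated on full windows only (so it is first
defined on day 10): start = first day the average is below zero (exactly
zero counts as not below), end = the day before it first returns positive,
or day 365 if it never does. Only the first window per year is headline;
later windows are available separately. Whether the average is trailing or
centered was an open choice; trailing is causal and deterministic at the
year boundary. Site-to-site differences in uptake length are tested with
the Kruskal-Wallis rank test.

## Radiative forcing and switchover

The perturbation model tracks atmospheric inventories of ecosystem-derived
CO2 and CH4 with an annual time step and a pulse-at-start convention: each
year the standing burdens decay (CH4 by e^(−1/τ_CH4); each CO2 pool by
e^(−1/τᵢ)), the carbon of the decayed CH4 is oxidized to CO2 (mass factor
44/16 × yield) and joins the year's net CO2 input, which is distributed over
the pools by their fractions aᵢ. A single pulse therefore decays exactly as
IRF(t) = Σ aᵢ e^(−t/τᵢ), and the model is linear, so sustained trajectories
superpose from pulse trajectories — both properties are tested to 1e-9.

Defaults (all in `data/forcing_defaults.yaml`, never hard-coded): the
classic five-term impulse-response fit with one quasi-permanent pool
(a = 0.1756, τ = ∞) and four decaying pools (τ = 421, 70.6, 21.4, 3.42
years; the last fraction is adjusted by 10⁻⁶ so the set sums to exactly 1);
τ_CH4 = 12.4 yr; oxidation yield 1; per-kg radiative efficiencies derived
from per-ppb values (CO2 1.76×10⁻¹⁵, CH4 1.28×10⁻¹³ W m⁻² kg⁻¹); CH4
indirect-effects multiplier 1.65. The source literature for this model
family does not pin unique constants, so all figures downstream of them are
comparable only qualitatively across parameterizations.

Scenario modes: *sustained* recycles the monitored years cyclically to the
horizon (200 years by default), preserving the observed interannual
sequence; *instantaneous* emits the record-mean annual flux as a single
year-0 pulse (monitored years are exchangeable under the stationarity
assumption, so the mean pulse represents them). The forcing difference
wetland-minus-baseline defines Δ-forcing; the switchover year is the first
year Δ ≤ 0 that also persists to the horizon. The persistence requirement
exists because Monte-Carlo resampling produces transient dips; a
first-crossing variant is available by flag.

Monte Carlo: each of n = 1000 replicates resamples the N monitored years
with replacement — paired (NEE, CH4) by default, preserving their
covariance; independent resampling is available — and recycles the
resampled block to the horizon. Replicate-to-replicate variability of the
block mean shrinks roughly as 1/√N, which is why longer monitoring records
produce narrower switchover intervals. Undefined switchovers enter the
percentiles as +∞ (nearest-rank percentiles, since years are integers) and
are also reported as a fraction.

## Footprints and greenness

The source-weight field is f(x,y) = f_y(x)·D_y(x,y). The crosswind-
integrated part uses the published scaled parameterization
F*(X*) = a(X*−d)^b exp(−c/(X*−d)) with the fitted constants shipped in
`data/footprint_params.yaml`, mapped to real scale through the measurement
height, boundary-layer depletion factor (1 − zm/h) and the stability-
corrected log wind profile; D_y is Gaussian with the parameterized
distance-dependent spread. Inputs outside the published validity range
(u* ≤ 0.1 m s⁻¹, zm/L < −15.5, zm ≥ h, ...) raise a domain error rather
than computing silently. The grid is metric, 3-m resolution, symmetric
about the tower so quarter-turn rotations map cells onto cells.

Cumulative contours accumulate cells by decreasing weight (ties broken by
distance to the tower) until the requested share of captured weight is
reached; masks nest by construction. Footprint climatologies are
weight-normalized sums on a common grid (equal weighting by default — the
aggregation weighting was an open choice). GNDVI = (NIR−Green)/(NIR+Green)
with NaN where the denominator vanishes; seasonal maximum-greenness
composites are per-pixel maxima over valid observations; footprint
greenness is the mean GNDVI inside a contour. Rasters are plain arrays in
a metric, pre-projected CRS; reading single-band (Geo)TIFFs is supported
through `tifffile`, and no reprojection is performed.

## Driver importance, trends, clustering

Mutual information uses the first Kraskov k-nearest-neighbour estimator
(max-norm joint neighbourhoods, ψ(k) + ψ(n) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩) with
k = 3 by default and a tiny seeded jitter to break ties. Inputs are daily
means of measured (non-gap-filled) half-hours; rows with any missing value
are dropped. Raw MI may be slightly negative for independent data; it is
clipped at zero only when forming the normalized profile (share of the
predictor-set total, in percent — chosen because reported importances are
percentages that sum across the predictor set), never in the stored raw
values. Profiles whose raw MIs all fall below 0.1 nats (about the
estimator's own noise floor at a few hundred days) are flagged low-signal.

Trends: Theil-Sen slope (median of pairwise slopes) with a Mann-Kendall
significance test implemented in-package (normal approximation with tie
correction; none of the installed statistics packages provides it).

Clustering: k-means (k = 3 by default, 10 restarts, fixed seed) on
standardized (annual NEE, annual CH4, wetland age); PCA of the same matrix
gives the 2-D display coordinates. Labels are aligned across runs by
sorting centroids on the age axis, so "young / advanced / mature" labels
are stable.

## Problem sizes and numerical choices

The test suite and acceptance script run on one synthetic site-year
(17,520 half-hours) for gap-filling recovery, ten synthetic years for the
forcing record, 200-year horizons, 1000 Monte-Carlo replicates, n = 2000
samples for the Gaussian MI calibration, and a 201×201-cell footprint grid —
sizes at which every stage's behaviour is already asymptotic while a full
run stays within a coffee break on one CPU. Degenerate inputs are handled
explicitly: constant gap-fill targets invert exactly through the target
scaler; constant MI inputs return 0 with a warning; single-year Monte-Carlo
records warn and return a degenerate interval; all-positive Δ-forcing
returns an undefined ("undeterminable") switchover rather than a sentinel
year.

## Known limitations

- The ANN ensemble quantifies run-to-run dispersion, not full predictive
  uncertainty; the gap-fraction uncertainty rule is a coarse, deliberately
  simple proxy.
- The perturbation model assumes stationary background conditions and
  linear, non-interacting pools; no N2O term and no lateral aquatic export.
- The MI normalization makes importances relative to the chosen predictor
  set; adding a redundant predictor dilutes its copies' shares.
- The footprint stage assumes horizontally homogeneous turbulence and a
  pre-projected metric grid; no atmospheric correction or cloud masking for
  the reflectance inputs.
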