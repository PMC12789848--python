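"""Two-dimensional flux-footprint fields, contours, and footprint greenness.

The footprint source-weight field is the product of a crosswind-integrated
footprint function and a Gaussian crosswind dispersion function,

    f(x, y) = f_y(x) * D_y(x, y),

with both terms from a published scaled parameterization fitted to a
backward Lagrangian stochastic particle dispersion model (constants shipped
in ``data/footprint_params.yaml``). The grid is metric, 3 m resolution by
default, centered on the tower at (0, 0) and rotated into the wind.
Cumulative-contour masks (e.g. the 80% source area) are extracted by
accumulating cells in decreasing weight order; greenness is summarized as
the mean GNDVI of co-registered reflectance rasters inside a contour.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml


class FootprintDomainError(ValueError):
    """Inputs outside the parameterization's published validity range."""


def _load_params() -> dict:
    with resources.files("wetlandghg.data").joinpath("footprint_params.yaml").open() as f:
        return yaml.safe_load(f)


_P = _load_params()


@dataclass
class FootprintInputs:
    """Micrometeorological inputs for one footprint estimate."""

    zm: float          # measurement height above displacement, m
    z0: float          # roughness length, m
    ustar: float       # friction velocity, m s-1
    sigma_v: float     # crosswind velocity standard deviation, m s-1
    ol: float          # Obukhov length, m (negative = unstable)
    wind_dir: float    # direction the wind comes from, degrees from north
    h: float = 1500.0  # boundary-layer height, m

    def validate(self):
        if self.zm <= 0:
            raise FootprintDomainError("zm must be > 0")
        if self.h <= 10 or self.zm >= self.h:
            raise FootprintDomainError("boundary-layer height must exceed zm (and 10 m)")
        if self.ustar <= 0.1:
            raise FootprintDomainError("ustar must exceed 0.1 m s-1")
        if self.sigma_v <= 0:
            raise FootprintDomainError("sigma_v must be > 0")
        if self.zm / self.ol < -15.5:
            raise FootprintDomainError("zm/L below -15.5: outside validity range")
        if not 0 < self.z0 < self.zm:
            raise FootprintDomainError("need 0 < z0 < zm")


@dataclass
class FootprintGrid:
    """Source-weight field f(x, y) (m-2) on a metric tower-centered grid."""

    east: np.ndarray     # 2-D east coordinates, m
    north: np.ndarray    # 2-D north coordinates, m
    f: np.ndarray        # per-cell source weight density, m-2
    resolution: float

    @property
    def cell_area(self) -> float:
        return self.resolution ** 2

    @property
    def captured(self) -> float:
        """Total weight captured by the grid (<= 1 by truncation)."""
        return float(self.f.sum() * self.cell_area)

    def contour_mask(self, pct: float) -> np.ndarray:
        return contour_mask(self, pct)


def _psi_f(zm: float, ol: float, oln: float) -> float:
    """Stability correction to the log wind profile."""
    if ol <= 0 or ol >= oln:
        xx = (1.0 - 19.0 * zm / ol) ** 0.25
        return (np.log((1 + xx**2) / 2.0) + 2.0 * np.log((1 + xx) / 2.0)
                - 2.0 * np.arctan(xx) + np.pi / 2.0)
    return -5.3 * zm / ol


def crosswind_integrated(x: np.ndarray, inputs: FootprintInputs):
    """f_y(x) (m-1) and sigma_y(x) (m) along the upwind distance x.

    Real-scale distances map to the scaled coordinate X* through the
    measurement height, boundary-layer depletion and the log wind profile;
    the fitted scaled forms are then evaluated and scaled back.
    """
    inputs.validate()
    p = _P
    x = np.asarray(x, dtype=float)
    log_term = np.log(inputs.zm / inputs.z0) - _psi_f(inputs.zm, inputs.ol, p["oln"])
    if log_term <= 0:
        raise FootprintDomainError("log(zm/z0) - psi must be positive")
    bl = 1.0 - inputs.zm / inputs.h
    xstar = x / inputs.zm * bl / log_term
    fy = np.zeros_like(xstar)
    ok = xstar > p["d"]
    xs = xstar[ok] - p["d"]
    fstar = p["a"] * xs ** p["b"] * np.exp(-p["c"] / xs)
    fy[ok] = fstar / inputs.zm * bl / log_term

    sigystar = p["ac"] * np.sqrt(p["bc"] * xstar**2 / (1.0 + p["cc"] * np.abs(xstar)))
    ol = inputs.ol if abs(inputs.ol) <= p["oln"] else -1e6
    if ol <= 0:
        scale_const = 1e-5 * abs(inputs.zm / ol) ** (-1) + 0.80
    else:
        scale_const = 1e-5 * abs(inputs.zm / ol) ** (-1) + 0.55
    scale_const = min(scale_const, 1.0)
    sigma_y = sigystar / scale_const * inputs.zm * inputs.sigma_v / inputs.ustar
    return fy, sigma_y


def dispersion(y: np.ndarray, sigma_y: np.ndarray) -> np.ndarray:
    """Gaussian crosswind dispersion D_y(x, y); integrates to 1 over y."""
    sig = np.where(sigma_y > 0, sigma_y, np.nan)
    d = np.exp(-(y**2) / (2.0 * sig**2)) / (np.sqrt(2.0 * np.pi) * sig)
    return np.nan_to_num(d)


def footprint_2d(inputs: FootprintInputs, extent: float = 300.0,
                 resolution: float = 3.0) -> FootprintGrid:
    """Compute f(x, y) = f_y(x) D_y(x, y) on a tower-centered metric grid.

    ``wind_dir`` is the meteorological wind direction; the footprint extends
    upwind of the tower. The grid is symmetric about the origin so that
    rotations by 90 deg map cells onto cells exactly.
    """
    inputs.validate()
    n = int(round(extent / resolution))
    coords = np.arange(-n, n + 1) * resolution
    east, north = np.meshgrid(coords, coords)
    wd = np.deg2rad(inputs.wind_dir)
    # along-wind (positive upwind) and crosswind coordinates
    x = east * np.sin(wd) + north * np.cos(wd)
    y = east * np.cos(wd) - north * np.sin(wd)
    fy, sigy = crosswind_integrated(np.clip(x, 0.0, None), inputs)
    f = fy * dispersion(y, sigy)
    f[x <= 0] = 0.0
    return FootprintGrid(east=east, north=north, f=f, resolution=resolution)


def contour_mask(grid: FootprintGrid, pct: float) -> np.ndarray:
    """Cumulative source-area mask capturing ``pct`` of the grid's weight.

    Cells are accumulated in decreasing weight order (ties resolved by
    distance to the tower) until the target share of the captured weight is
    reached. Masks are nested: lower percentages are subsets of higher.
    """
    if not 0 < pct < 1:
        raise ValueError("pct must be in (0, 1)")
    w = grid.f.ravel()
    dist = np.hypot(grid.east, grid.north).ravel()
    order = np.lexsort((dist, -w))
    csum = np.cumsum(w[order])
    total = csum[-1]
    if total <= 0:
        raise ValueError("footprint grid has no weight")
    n_cells = int(np.searchsorted(csum, pct * total) + 1)
    mask = np.zeros(w.size, dtype=bool)
    mask[order[:n_cells]] = True
    return mask.reshape(grid.f.shape)


def climatology(grids, weights=None) -> FootprintGrid:
    """Weight-normalized aggregate of footprints on a common grid."""
    grids = list(grids)
    if not grids:
        raise ValueError("no grids to aggregate")
    ref = grids[0]
    for g in grids[1:]:
        if g.f.shape != ref.f.shape or g.resolution != ref.resolution:
            raise ValueError("grids do not share a common geometry")
    if weights is None:
        weights = np.ones(len(grids))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    f = sum(wi * g.f for wi, g in zip(weights, grids))
    return FootprintGrid(east=ref.east, north=ref.north, f=f, resolution=ref.resolution)


def gndvi(green: np.ndarray, nir: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """(NIR - Green) / (NIR + Green); NaN where the denominator vanishes."""
    green = np.asarray(green, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if green.shape != nir.shape:
        raise ValueError("green and NIR rasters must be co-registered (same shape)")
    denom = nir + green
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir - green) / denom
    out[~(denom > eps)] = np.nan
    return out


def max_greenness_mosaic(rasters) -> np.ndarray:
    """Per-pixel maximum over valid (non-NaN) observations."""
    stack = np.stack([np.asarray(r, dtype=float) for r in rasters])
    if stack.shape[0] == 0:
        raise ValueError("need at least one raster")
    import warnings

    with warnings.catch_warnings():
        # pixels invalid in every input are deliberately missing in the output
        warnings.filterwarnings("ignore", message="All-NaN slice")
        out = np.nanmax(stack, axis=0)
    return out


def zonal_mean(raster: np.ndarray, mask: np.ndarray) -> float:
    """Mean of valid raster pixels inside the mask."""
    raster = np.asarray(raster, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if raster.shape != mask.shape:
        raise ValueError("raster and mask shapes differ")
    vals = raster[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid pixels inside the mask")
    return float(vals.mean())
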