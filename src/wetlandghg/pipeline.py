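"""Pipeline orchestration: simulate -> gapfill -> budget -> drivers -> forcing.

A run is described by one hierarchical config (YAML). Every emitted CSV
carries a provenance header (config hash, seed, package version), and all
stochastic stages derive their seeds from the run seed, so a rerun with the
same config is hash-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import budgets as bud
from . import drivers as drv
from . import forcing as frc
from .gapfill import PredictorMatrix, gapfill_flux
from .io import read_site_csv, write_site_csv
from .synth import Disturbance, GapConfig, SiteScenario, generate_fluxes, generate_met, apply_gaps

log = logging.getLogger("wetlandghg")

STAGES = ("simulate", "gapfill", "budget", "drivers", "forcing")


class ConfigError(ValueError):
    pass


def default_demo_config(seed: int = 0) -> dict:
    """Three synthetic sites, five years each, with contrasting trajectories."""
    return {
        "seed": seed,
        "sites": [
            {"site_id": "RAPID", "years": 5,
             "vegetation_trajectory": [0.6, 0.8, 0.9, 1.0, 1.0],
             "disturbances": []},
            {"site_id": "SLOW", "years": 5,
             "vegetation_trajectory": [0.2, 0.35, 0.5, 0.6, 0.7],
             "disturbances": []},
            {"site_id": "DISTURBED", "years": 5,
             "vegetation_trajectory": [0.6, 0.8, 0.9, 1.0, 1.0],
             "disturbances": [{"year": 3, "kind": "drawdown", "severity": 0.8}]},
        ],
        "gaps": {"random_rate": 0.15, "blocks_per_year": 4, "block_mean_length": 48},
        "gapfill": {"n_runs": 3, "architecture": 8, "max_train": 1500, "k_clusters": 6},
        "forcing": {"baseline_nee": 100.0, "baseline_ch4": 2.0,
                    "horizon": 200, "n_mc": 1000},
        "drivers": {"k": 3, "min_days": 60},
    }


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict):
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "sites" not in cfg or not cfg["sites"]:
        raise ConfigError("config needs a non-empty 'sites' list")
    for s in cfg["sites"]:
        for key in ("site_id", "years"):
            if key not in s:
                raise ConfigError(f"site entry missing required key {key!r}")
        if s["years"] < 1:
            raise ConfigError("site years must be >= 1")
    frc_cfg = cfg.get("forcing", {})
    horizon = frc_cfg.get("horizon", 200)
    max_years = max(s["years"] for s in cfg["sites"])
    if horizon < max_years:
        raise ConfigError(
            f"forcing horizon ({horizon}) shorter than the longest site record ({max_years})"
        )


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _provenance(cfg: dict) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg.get("seed", 0),
            "package": f"wetlandghg {__version__}"}


def _scenario(site_cfg: dict, seed: int) -> SiteScenario:
    return SiteScenario(
        site_id=site_cfg["site_id"],
        years=int(site_cfg["years"]),
        vegetation_trajectory=tuple(site_cfg.get("vegetation_trajectory", ())),
        disturbances=tuple(
            Disturbance(year=d["year"], kind=d["kind"], severity=d["severity"])
            for d in site_cfg.get("disturbances", ())
        ),
        seed=seed,
    )


def _require(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs artifact {path.name} from upstream stage "
            f"'{upstream}'; run it first"
        )
    return path


def run_pipeline(cfg: dict, outdir, stages=STAGES) -> Path:
    """Execute the requested stage prefix, returning the artifact directory."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    seed = int(cfg.get("seed", 0))

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            _stage_simulate(cfg, outdir, prov, seed)
        elif stage == "gapfill":
            _stage_gapfill(cfg, outdir, prov, seed)
        elif stage == "budget":
            _stage_budget(cfg, outdir, prov)
        elif stage == "drivers":
            _stage_drivers(cfg, outdir, prov, seed)
        elif stage == "forcing":
            _stage_forcing(cfg, outdir, prov, seed)
        else:
            raise ConfigError(f"unknown stage {stage!r}")
        log.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
    return outdir

def _site_ids(cfg):
    return [s["site_id"] for s in cfg["sites"]]


def _stage_simulate(cfg, outdir, prov, seed):
    (outdir / "sites").mkdir(exist_ok=True)
    gcfg = cfg.get("gaps", {})
    for i, site_cfg in enumerate(cfg["sites"]):
        scn = _scenario(site_cfg, seed=seed * 1000 + i)
        met = generate_met(scn)
        truth = generate_fluxes(met, scn)
        observed, mask = apply_gaps(truth, met, GapConfig(
            random_rate=gcfg.get("random_rate", 0.15),
            blocks_per_year=gcfg.get("blocks_per_year", 4),
            block_mean_length=gcfg.get("block_mean_length", 48),
            seed=seed * 1000 + i + 500,
        ))
        write_site_csv(observed, outdir / "sites" / f"{scn.site_id}.csv", prov)
        truth_series = observed.__class__(data=truth.data, site_id=scn.site_id)
        write_site_csv(truth_series, outdir / "sites" / f"{scn.site_id}_truth.csv", prov)
        log.info("simulated %s: %d records", scn.site_id, len(observed.data))


def _stage_gapfill(cfg, outdir, prov, seed):
    gf = cfg.get("gapfill", {})
    (outdir / "filled").mkdir(exist_ok=True)
    for sid in _site_ids(cfg):
        path = _require(outdir / "sites" / f"{sid}.csv", "gapfill", "simulate")
        series = read_site_csv(path, site_id=sid)
        pm = PredictorMatrix.from_met(series.data)
        out = series.data.copy()
        for var in ("NEE", "FCH4"):
            if series.data[var].isna().any():
                res = gapfill_flux(
                    series.data[var], pm,
                    n_runs=gf.get("n_runs", 20),
                    architecture=gf.get("architecture"),
                    k_clusters=gf.get("k_clusters", 10),
                    max_train=gf.get("max_train"),
                    seed=seed + {"NEE": 11, "FCH4": 22}[var],
                )
                out[f"{var}_F"] = res.filled
                out[f"{var}_QC"] = res.fill_flag
            else:
                out[f"{var}_F"] = series.data[var]
                out[f"{var}_QC"] = 0
        filled = series.__class__(data=out, site_id=sid)
        write_site_csv(filled, outdir / "filled" / f"{sid}.csv", prov)


def _stage_budget(cfg, outdir, prov):
    rows = []
    for i, site_cfg in enumerate(cfg["sites"]):
        sid = site_cfg["site_id"]
        path = _require(outdir / "filled" / f"{sid}.csv", "budget", "gapfill")
        filled = read_site_csv(path, site_id=sid)
        d = filled.data
        budgets = bud.annual_budgets(
            d["NEE_F"], d["FCH4_F"], d["NEE_QC"] > 0, d["FCH4_QC"] > 0,
            site_id=sid, restoration_year=int(d.index.year.min()),
        )
        rows.extend(budgets)
    frame = bud.budgets_to_frame(rows)
    _write_table(frame, outdir / "budgets.csv", prov)


def _stage_drivers(cfg, outdir, prov, seed):
    dcfg = cfg.get("drivers", {})
    path = _require(outdir / "budgets.csv", "drivers", "budget")
    budgets = _read_table(path)
    results = []
    for sid in _site_ids(cfg):
        fpath = _require(outdir / "filled" / f"{sid}.csv", "drivers", "gapfill")
        filled = read_site_csv(fpath, site_id=sid)
        d = filled.data
        measured = d.copy()
        # importance uses measured (non-gap-filled) fluxes only
        measured.loc[d["NEE_QC"] > 0, "NEE"] = np.nan
        measured.loc[d["FCH4_QC"] > 0, "FCH4"] = np.nan
        daily = measured[["NEE", "FCH4", "PA", "PAR", "TA", "TS", "WT"]].resample("D").mean()
        for target in ("NEE", "FCH4"):
            try:
                res = drv.importance_profile(
                    daily, target, k=dcfg.get("k", 3),
                    min_days=dcfg.get("min_days", 60), site=sid, seed=seed,
                )
            except ValueError:
                continue
            for pred, imp in res.importance.items():
                results.append({"site_id": sid, "target": target, "predictor": pred,
                                "importance_pct": imp, "mi_nats": res.mi_raw[pred],
                                "n_days": res.n})
    _write_table(pd.DataFrame(results), outdir / "importance.csv", prov)

    cluster = drv.cluster_siteyears(budgets, k=min(3, len(budgets)), seed=seed)
    assign = budgets[["site_id", "year"]].copy()
    assign["cluster"] = cluster.labels
    assign[["pc1", "pc2"]] = cluster.pca_scores[:, :2]
    _write_table(assign, outdir / "clusters.csv", prov)


def _stage_forcing(cfg, outdir, prov, seed):
    fcfg = cfg.get("forcing", {})
    path = _require(outdir / "budgets.csv", "forcing", "budget")
    budgets = _read_table(path)
    params = frc.PerturbationParams.default()
    if "params" in fcfg:
        params = frc.PerturbationParams.from_dict(fcfg["params"])
    horizon = int(fcfg.get("horizon", 200))
    summary, trajectories = [], []
    for sid, g in budgets.groupby("site_id"):
        nee, ch4 = g["nee_cum"].to_numpy(), g["ch4_cum"].to_numpy()
        scenario = frc.AnnualFluxScenario(
            nee, ch4,
            baseline_nee=fcfg.get("baseline_nee", 0.0),
            baseline_ch4=fcfg.get("baseline_ch4", 0.0),
            horizon=horizon, mode="sustained",
        )
        traj = frc.radiative_balance(scenario, params)
        mc = frc.switchover_mc(
            nee, ch4, fcfg.get("baseline_nee", 0.0), fcfg.get("baseline_ch4", 0.0),
            params=params, n=int(fcfg.get("n_mc", 1000)), seed=seed, horizon=horizon,
        )
        summary.append({
            "site_id": sid, "mode": "sustained", "record_years": len(nee),
            "switchover_year": traj.switchover_year,
            "mc_median": mc.median, "mc_ci_lo": mc.ci[0], "mc_ci_hi": mc.ci[1],
            "undefined_fraction": mc.undefined_fraction,
        })
        tdf = pd.DataFrame({"site_id": sid, "year": traj.years,
                            "delta_forcing": traj.delta_forcing,
                            "co2_burden": traj.co2_burden,
                            "ch4_burden": traj.ch4_burden})
        trajectories.append(tdf)
    _write_table(pd.DataFrame(summary), outdir / "switchover_summary.csv", prov)
    _write_table(pd.concat(trajectories), outdir / "forcing_trajectories.csv", prov)


def _write_table(df: pd.DataFrame, path: Path, prov: dict):
    with open(path, "w") as f:
        for k, v in prov.items():
            f.write(f"# {k}: {v}\n")
        df.to_csv(f, index=False, lineterminator="\n")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
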