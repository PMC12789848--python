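"""ANN gap-filling of half-hourly fluxes and NEE partitioning.

Protocol: predictors are the standard meteorological set (TA, NETRAD, PAR,
VPD, WT, GCC, WD as sin/cos, USTAR); training/validation/test rows are drawn
within k-means clusters of the predictor space to minimize seasonal and diel
bias; the simplest single-hidden-layer network whose successor improves
validation RMSE by less than 5% is selected; training is repeated with
independent initializations and the median prediction across runs fills the
gaps. NEE is partitioned into ecosystem respiration (ER) and gross primary
productivity (GPP) by training on nighttime rows (photosynthesis inactive,
so nighttime NEE = ER) with non-radiation predictors and predicting ER at
all timestamps; GPP = ER − NEE.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

PREDICTORS = ("TA", "NETRAD", "PAR", "VPD", "WT", "GCC", "WD", "USTAR")
#: Predictors used for nighttime ER models (radiation terms excluded).
NIGHT_PREDICTORS = ("TA", "VPD", "WT", "GCC", "WD", "USTAR")
DEFAULT_CANDIDATES = (2, 4, 8, 16)
NIGHT_PAR_THRESHOLD = 10.0  # µmol m⁻² s⁻¹


@dataclass
class PredictorMatrix:
    """Standardized predictor matrix with wind direction as (sin, cos)."""

    X: np.ndarray
    columns: tuple
    complete: np.ndarray          # row-wise completeness mask
    center: np.ndarray
    scale: np.ndarray
    index: pd.DatetimeIndex

    @classmethod
    def from_met(cls, met: pd.DataFrame, predictors=PREDICTORS) -> "PredictorMatrix":
        cols, arrays = [], []
        for p in predictors:
            v = met[p].to_numpy(dtype=float)
            if p == "WD":
                rad = np.deg2rad(v)
                arrays += [np.sin(rad), np.cos(rad)]
                cols += ["WD_sin", "WD_cos"]
            else:
                arrays.append(v)
                cols.append(p)
        X = np.column_stack(arrays)
        complete = np.isfinite(X).all(axis=1)
        center = np.nanmean(X, axis=0)
        scale = np.nanstd(X, axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(X=(X - center) / scale, columns=tuple(cols), complete=complete,
                   center=center, scale=scale, index=met.index)


@dataclass
class FillResult:
    """Gap-filling outcome: filled series, flags, and per-run diagnostics."""

    filled: pd.Series
    fill_flag: pd.Series          # 0 = observed, 1 = filled
    runs: np.ndarray              # (n_runs, n_timestamps) predictions
    architecture: int             # hidden units of the selected network
    run_rmse: np.ndarray          # per-run RMSE on the held-out test rows
    selection_log: dict = field(default_factory=dict)


@dataclass
class PartitionResult:
    """NEE partition into ER and GPP (GPP = ER − NEE exactly)."""

    er: pd.Series
    gpp: pd.Series
    night_mask: pd.Series
    frac_er_negative: float
    frac_gpp_negative_day: float


def kmeans_folds(X: np.ndarray, k: int = 10, seed: int = 0,
                 proportions=(0.70, 0.15, 0.15)) -> np.ndarray:
    """Stratified train/val/test assignment within k-means clusters.

    Returns an integer array (0 = train, 1 = val, 2 = test) over the rows of
    X. Every cluster contributes rows to all three sets; clusters smaller
    than 3 rows are merged into the nearest cluster first. k = 1 reduces to
    a simple random split.
    """
    n = X.shape[0]
    if n < max(k, 3):
        raise ValueError(f"need at least {max(k, 3)} complete rows, got {n}")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    if k <= 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(X)
        labels = km.labels_
        # merge tiny clusters into the nearest surviving centroid
        counts = np.bincount(labels, minlength=k)
        small = np.flatnonzero(counts < 3)
        if small.size:
            keep = np.flatnonzero(counts >= 3)
            for c in small:
                rows = labels == c
                d = np.linalg.norm(km.cluster_centers_[keep] - km.cluster_centers_[c], axis=1)
                labels[rows] = keep[np.argmin(d)]
    folds = np.empty(n, dtype=int)
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        rng.shuffle(rows)
        n_train = int(round(proportions[0] * rows.size))
        n_val = int(round(proportions[1] * rows.size))
        # keep at least one row per set where the cluster allows it
        n_train = min(max(n_train, 1), rows.size - 2)
        n_val = min(max(n_val, 1), rows.size - n_train - 1)
        folds[rows[:n_train]] = 0
        folds[rows[n_train : n_train + n_val]] = 1
        folds[rows[n_train + n_val :]] = 2
    return folds


def select_by_rmse(rmses, threshold: float = 0.05) -> int:
    """Apply the parsimony rule to a validation-RMSE ladder.

    Candidates are ordered simplest-first; returns the index of the first
    candidate whose successor improves RMSE by less than ``threshold``
    (i.e. RMSE(next) > (1 − threshold) × RMSE(current)). If every step
    improves by at least the threshold, the most complex candidate wins.
    """
    rmses = list(rmses)
    if not rmses:
        raise ValueError("empty candidate list")
    for i in range(len(rmses) - 1):
        if rmses[i + 1] > (1.0 - threshold) * rmses[i]:
            return i
    return len(rmses) - 1


def _fit_mlp(X, y, hidden: int, seed: int) -> MLPRegressor:
    # lbfgs: full-batch quasi-Newton, well suited to small single-layer nets
    mlp = MLPRegressor(
        hidden_layer_sizes=(hidden,),
        activation="tanh",
        solver="lbfgs",
        max_iter=500,
        random_state=seed,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        # the iteration cap is a deliberate budget; ensemble members need
        # not individually reach the optimizer's tolerance
        warnings.simplefilter("ignore", ConvergenceWarning)
        return mlp.fit(X, y)


def select_architecture(candidates, X_train, y_train, X_val, y_val,
                        seed: int = 0, n_repeats: int = 1, threshold: float = 0.05):
    """Choose the simplest adequate hidden-layer size.

    Validation RMSE is averaged over ``n_repeats`` independently initialized
    trainings per candidate before the parsimony rule is applied. Returns
    (architecture, selection_log).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if len(y_val) == 0:
        raise ValueError("validation set is empty")
    mean_rmse = []
    for j, h in enumerate(candidates):
        rmses = []
        for r in range(n_repeats):
            mlp = _fit_mlp(X_train, y_train, h, seed=seed * 1000 + j * 10 + r)
            pred = mlp.predict(X_val)
            rmses.append(float(np.sqrt(np.mean((pred - y_val) ** 2))))
        mean_rmse.append(float(np.mean(rmses)))
    i = select_by_rmse(mean_rmse, threshold)
    log = {"candidates": candidates, "val_rmse": mean_rmse, "selected": candidates[i]}
    return candidates[i], log


class _ScaledTarget:
    """Center/scale a target; constant targets invert to the constant exactly."""

    def __init__(self, y):
        self.center = float(np.mean(y))
        self.sd = float(np.std(y))

    def forward(self, y):
        return (y - self.center) / (self.sd if self.sd > 0 else 1.0)

    def backward(self, z):
        return z * self.sd + self.center


def gapfill_flux(series: pd.Series, pm: PredictorMatrix, n_runs: int = 20,
                 seed: int = 0, architecture: int | None = None,
                 candidates=DEFAULT_CANDIDATES, k_clusters: int = 10,
                 max_train: int | None = None) -> FillResult:
    """Fill gaps in a half-hourly flux series with an ANN ensemble.

    Each of ``n_runs`` trainings uses an independent weight initialization
    (and fold shuffle); the median prediction across runs fills the gaps.
    Observed values are never modified. If ``architecture`` is None, the
    parsimony ladder is evaluated once on the first fold split.

    ``max_train`` optionally subsamples the training rows per run, which
    bounds cost on long records without touching the protocol.
    """
    y_all = series.to_numpy(dtype=float)
    obs = np.isfinite(y_all)
    gaps = ~obs
    if not obs.any():
        raise ValueError("flux series is entirely missing")
    usable = obs & pm.complete
    predictable = pm.complete
    if gaps.any() and (pm.complete[gaps].mean() < 0.5):
        raise ValueError("predictors missing at too many gap timestamps")

    rows = np.flatnonzero(usable)
    X_obs = pm.X[rows]
    scaler = _ScaledTarget(y_all[rows])
    z_obs = scaler.forward(y_all[rows])

    folds = kmeans_folds(X_obs, k=k_clusters, seed=seed)
    tr, va, te = (folds == 0), (folds == 1), (folds == 2)

    selection_log = {}
    if architecture is None:
        architecture, selection_log = select_architecture(
            candidates, X_obs[tr], z_obs[tr], X_obs[va], z_obs[va], seed=seed
        )

    rng = np.random.default_rng(seed)
    runs = np.full((n_runs, len(y_all)), np.nan)
    run_rmse = np.empty(n_runs)
    fit_rows = np.flatnonzero(tr | va)  # test rows held out of every fit
    for r in range(n_runs):
        sub = fit_rows
        if max_train is not None and fit_rows.size > max_train:
            sub = rng.choice(fit_rows, size=max_train, replace=False)
        mlp = _fit_mlp(X_obs[sub], z_obs[sub], architecture,
                       seed=int(rng.integers(0, 2**31 - 1)))
        pred = scaler.backward(mlp.predict(pm.X[predictable]))
        runs[r, predictable] = pred
        z_te = scaler.backward(mlp.predict(X_obs[te]))
        run_rmse[r] = float(np.sqrt(np.mean((z_te - y_all[rows][te]) ** 2)))

    median_pred = np.nanmedian(runs, axis=0)
    filled = y_all.copy()
    fill_here = gaps & predictable
    filled[fill_here] = median_pred[fill_here]
    flag = pd.Series(np.where(obs, 0, 1), index=series.index, name=f"{series.name}_QC")
    return FillResult(
        filled=pd.Series(filled, index=series.index, name=series.name),
        fill_flag=flag,
        runs=runs,
        architecture=architecture,
        run_rmse=run_rmse,
        selection_log=selection_log,
    )


def night_mask_from_par(par: pd.Series, threshold: float = NIGHT_PAR_THRESHOLD) -> pd.Series:
    """Nighttime = PAR below threshold (photosynthesis inactive)."""
    return par < threshold


def partition_nee(filled_nee: pd.Series, met: pd.DataFrame,
                  night_mask: pd.Series | None = None, n_runs: int = 5,
                  architecture: int = 8, seed: int = 0,
                  max_train: int | None = None) -> PartitionResult:
    """Partition NEE into ER and GPP via a nighttime-trained ER model.

    The model is trained on nighttime rows only (target = NEE, since GPP = 0
    at night) using non-radiation predictors, then predicts ER at every
    timestamp; GPP = ER − NEE holds exactly. ER is not clipped at zero — the
    fraction of negative predictions is recorded instead, because clipping
    would break the partition identity.
    """
    if night_mask is None:
        night_mask = night_mask_from_par(met["PAR"])
    night = night_mask.to_numpy(dtype=bool)
    if not night.any():
        raise ValueError("no night rows; cannot train ER model")
    pm = PredictorMatrix.from_met(met, predictors=NIGHT_PREDICTORS)
    y = filled_nee.to_numpy(dtype=float)
    if not night.all():
        rows = np.flatnonzero(night & np.isfinite(y) & pm.complete)
        scaler = _ScaledTarget(y[rows])
        z = scaler.forward(y[rows])
        rng = np.random.default_rng(seed)
        preds = np.empty((n_runs, len(y)))
        for r in range(n_runs):
            sub = rows
            if max_train is not None and rows.size > max_train:
                sub = rng.choice(rows, size=max_train, replace=False)
            mlp = _fit_mlp(pm.X[sub], scaler.forward(y[sub]),
                           architecture, seed=int(rng.integers(0, 2**31 - 1)))
            preds[r] = scaler.backward(mlp.predict(pm.X))
        er = np.median(preds, axis=0)
        er[night] = y[night]  # at night ER is observed directly
    else:
        er = y.copy()
    gpp = er - y
    day = ~night
    frac_neg_er = float((er < 0).mean())
    frac_neg_gpp = float((gpp[day] < 0).mean()) if day.any() else 0.0
    return PartitionResult(
        er=pd.Series(er, index=filled_nee.index, name="ER"),
        gpp=pd.Series(gpp, index=filled_nee.index, name="GPP"),
        night_mask=pd.Series(night, index=filled_nee.index, name="NIGHT"),
        frac_er_negative=frac_neg_er,
        frac_gpp_negative_day=frac_neg_gpp,
    )
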