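"""Environmental-driver importance, trends, and site-year clustering.

Driver importance uses mutual information (MI) estimated nonparametrically
from k-nearest neighbours (Kraskov-Grassberger-Stögbauer estimator I, with
the Ross convention for small samples):

    MI = psi(k) + psi(n) - < psi(n_x + 1) + psi(n_y + 1) >

where n_x, n_y count the marginal neighbours strictly inside each point's
k-th-neighbour Chebyshev distance in the joint space. MI is zero iff the
variables are independent and rises with dependence of any (also nonlinear)
form, which suits flux-driver relations where light, temperature and water
table act through saturating and threshold responses.

Per-predictor MI values are normalized to shares of the predictor-set total
(percent) so that importance profiles can be compared across sites and
years. Trends in drivers are quantified by the Theil-Sen slope with a
Mann-Kendall significance test; site-years are clustered by k-means on
standardized (annual NEE, annual CH4, wetland age) features with a PCA
projection for display.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import digamma
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

DEFAULT_PREDICTORS = ("PA", "PAR", "TA", "TS", "WT")


@dataclass
class MIResult:
    """Per-predictor MI and normalized importance for one target."""

    target: str
    mi_raw: dict                  # predictor -> nats (may be slightly negative)
    importance: dict              # predictor -> % of predictor-set total
    n: int
    k: int
    site: str = ""
    year: int | None = None
    low_signal: bool = False


def mi_knn(x: np.ndarray, y: np.ndarray, k: int = 3, seed: int = 0,
           jitter: float = 1e-10) -> float:
    """kNN mutual information (nats) between paired continuous samples.

    Implements the first Kraskov estimator with max-norm neighbourhoods.
    A tiny seeded jitter breaks ties in discrete-ish data (standard
    practice for this estimator). Constant inputs return 0. The raw value
    can be slightly negative for independent data; clipping is left to the
    caller so the estimator's diagnostics are preserved.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must be paired samples of equal length")
    n = x.size
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    if np.std(x) == 0 or np.std(y) == 0:
        import warnings
        warnings.warn("constant input: MI is 0 by convention")
        return 0.0
    rng = np.random.default_rng(seed)
    xs = x / np.std(x) + jitter * rng.standard_normal(n)
    ys = y / np.std(y) + jitter * rng.standard_normal(n)
    joint = np.column_stack([xs, ys])
    tree = cKDTree(joint)
    # distance to the k-th neighbour in the joint space (Chebyshev norm)
    dist, _ = tree.query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    tx = cKDTree(xs[:, None])
    ty = cKDTree(ys[:, None])
    r = np.nextafter(eps, 0)  # strictly-less-than the k-th joint distance
    nx = tx.query_ball_point(xs[:, None], r, return_length=True) - 1
    ny = ty.query_ball_point(ys[:, None], r, return_length=True) - 1
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(mi)


def importance_profile(daily: pd.DataFrame, target: str,
                       predictors=DEFAULT_PREDICTORS, k: int = 3,
                       min_days: int = 30, site: str = "",
                       year: int | None = None, seed: int = 0,
                       low_signal_threshold: float = 0.1) -> MIResult:
    """Normalized MI importance of each predictor for one target.

    Rows with any missing value are dropped (complete-case filtering); only
    measured, non-gap-filled days should be passed in. Negative raw MI is
    clipped to zero in the normalized profile only. If every raw MI is near
    zero the profile is flagged ``low_signal``.
    """
    cols = [target, *predictors]
    cc = daily[cols].dropna()
    if len(cc) < min_days:
        raise ValueError(f"only {len(cc)} complete days; need >= {min_days}")
    raw = {p: mi_knn(cc[p].to_numpy(), cc[target].to_numpy(), k=k, seed=seed)
           for p in predictors}
    clipped = {p: max(v, 0.0) for p, v in raw.items()}
    total = sum(clipped.values())
    if total > 0:
        importance = {p: 100.0 * v / total for p, v in clipped.items()}
    else:
        importance = {p: 0.0 for p in clipped}
    return MIResult(
        target=target, mi_raw=raw, importance=importance, n=len(cc), k=k,
        site=site, year=year,
        low_signal=all(v < low_signal_threshold for v in raw.values()),
    )


def mann_kendall(values: np.ndarray):
    """Mann-Kendall trend test (normal approximation, tie-corrected).

    Returns (S, z, p) for a two-sided test of monotone trend.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    s = int(np.sum(np.sign(v[None, :] - v[:, None])[np.triu_indices(n, 1)]))
    _, counts = np.unique(v, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5) - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var <= 0:
        return s, 0.0, 1.0
    z = (s - np.sign(s)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(z), float(p)


@dataclass
class TrendResult:
    slope: float           # per unit of t
    intercept: float
    p_value: float
    s_statistic: int


def theil_sen(values, t=None) -> TrendResult:
    """Robust trend: median of pairwise slopes + Mann-Kendall significance."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 points for a trend")
    tt = np.arange(v.size, dtype=float) if t is None else np.asarray(t, dtype=float)
    slope, intercept, _, _ = stats.theilslopes(v, tt)
    s, _, p = mann_kendall(v)
    return TrendResult(slope=float(slope), intercept=float(intercept),
                       p_value=p, s_statistic=s)


@dataclass
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray      # in original feature units
    pca_scores: np.ndarray     # (n, 2)
    explained_variance_ratio: np.ndarray
    feature_names: tuple


def cluster_siteyears(features: pd.DataFrame, k: int = 3, seed: int = 0,
                      feature_names=("nee_cum", "ch4_cum", "wetland_age")) -> ClusterResult:
    """k-means on standardized site-year features with a 2-D PCA projection.

    Labels are aligned across runs by sorting centroids on the wetland-age
    axis (young clusters get low labels), so cluster identities are stable
    and nameable.
    """
    X = features[list(feature_names)].to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError(f"k={k} exceeds the {len(X)} site-years available")
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    age_axis = list(feature_names).index("wetland_age") if "wetland_age" in feature_names else -1
    order = np.argsort(km.cluster_centers_[:, age_axis])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    centroids = scaler.inverse_transform(km.cluster_centers_[order])
    n_comp = min(2, Z.shape[1], len(Z))
    pca = PCA(n_components=n_comp, random_state=seed).fit(Z)
    return ClusterResult(
        labels=labels,
        centroids=centroids,
        pca_scores=pca.transform(Z),
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_names=tuple(feature_names),
    )
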