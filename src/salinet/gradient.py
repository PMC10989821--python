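"""Environmental-gradient statistics: distance-vs-environment correlations,
Mantel tests, alpha diversity, and the linear trend fit reused by every
"metric vs salinity" analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def linear_trend(x, y) -> TrendResult:
    """OLS fit of y on x with a two-sided p-value for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need at least 3 points for a trend, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; trend undefined")
    fit = stats.linregress(x, y)
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def haversine_matrix(lat, lon) -> np.ndarray:
    """Great-circle distance matrix (km) from decimal-degree coordinates."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass(frozen=True)
class GeoEnvResult:
    r: float
    p_value: float
    n_pairs: int
    defined: bool


def geo_env_correlation(meta: pd.DataFrame, variable: str) -> GeoEnvResult:
    """Pearson correlation between pairwise geographic distance and the
    pairwise absolute difference of an environmental variable, over all
    site pairs.  A constant variable yields an undefined correlation,
    flagged rather than raised."""
    if len(meta) < 3:
        raise ValueError("need at least 3 sites")
    d_geo = squareform(haversine_matrix(meta["latitude"], meta["longitude"]), checks=False)
    v = meta[variable].to_numpy(dtype=float)
    d_env = pdist(v[:, None], metric="cityblock")
    if np.ptp(v) == 0 or np.ptp(d_geo) == 0:
        return GeoEnvResult(r=float("nan"), p_value=float("nan"), n_pairs=d_geo.size, defined=False)
    r, p = stats.pearsonr(d_geo, d_env)
    return GeoEnvResult(r=float(r), p_value=float(p), n_pairs=d_geo.size, defined=True)


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def mantel_test(
    d1, d2, n_permutations: int = 999, seed: int | None = None
) -> MantelResult:
    """Mantel test: Pearson correlation of the condensed upper triangles,
    with a one-sided permutation p-value obtained by jointly permuting the
    rows and columns of the second matrix:

        p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations)
    """
    d1 = _check_distance_matrix(d1)
    d2 = _check_distance_matrix(d2)
    if d1.shape != d2.shape:
        raise ValueError(f"size mismatch: {d1.shape} vs {d2.shape}")
    n = d1.shape[0]
    if n < 3:
        raise ValueError("need at least 3 objects")
    iu = np.triu_indices(n, k=1)
    v1 = d1[iu]
    if np.ptp(v1) == 0 or np.ptp(d2[iu]) == 0:
        raise ValueError("degenerate (constant) distance matrix")
    v1 = (v1 - v1.mean()) / v1.std()

    def corr(mat: np.ndarray) -> float:
        v = mat[iu]
        v = (v - v.mean()) / v.std()
        return float(np.dot(v1, v) / v1.size)

    r_obs = corr(d2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(d2[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_permutations)


def alpha_diversity(table: pd.DataFrame, metric: str = "richness") -> pd.Series:
    """Per-sample alpha diversity on a (rarefied) count table.

    richness: number of taxa with nonzero counts; shannon: -sum p ln p over
    the nonzero relative abundances (natural log).
    """
    totals = table.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"empty samples: {empty}")
    if metric == "richness":
        return (table > 0).sum(axis=0).rename("richness")
    if metric == "shannon":
        p = (table / totals).to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        return pd.Series(-plogp.sum(axis=0), index=table.columns, name="shannon")
    raise ValueError(f"unknown metric {metric!r}; use 'richness' or 'shannon'")


def bray_curtis_matrix(table: pd.DataFrame) -> np.ndarray:
    """Bray-Curtis distance matrix between samples (columns) of a count or
    relative-abundance table."""
    x = table.to_numpy(dtype=float).T
    return squareform(pdist(x, metric="braycurtis"))
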