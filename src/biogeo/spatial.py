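"""Geographic distances, distance-decay regression, Mantel tests, and
diversity-latitude regressions.

The distance-decay relationship (DDR) is fitted as an ordinary least
squares regression of community similarity (1 - Bray-Curtis) on
great-circle distance over all unordered sample pairs; the slope is
reported per 100 km, a convention recorded in every output header.  The
default p-value comes from the slope's t-test (common practice even
though pairs are not independent); a permutation alternative is available
via ``p_method="permutation"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from ._utils import BiogeoError, align_distance_matrices, condensed

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class DdrFit:
    """OLS fit of similarity on geographic distance (slope per ``per_km`` km)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    per_km: float = 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str


@dataclass(frozen=True)
class LatRegression:
    """OLS of an alpha-diversity metric on latitude, with fitted-line CI."""

    metric: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ci_lower: np.ndarray  # 95% CI of the fitted mean, per sample
    ci_upper: np.ndarray


# ---------------------------------------------------------------------------
# Great-circle distances
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance between coordinate pairs in km (haversine form)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def haversine_matrix(meta: pd.DataFrame, radius_km: float = EARTH_RADIUS_KM) -> pd.DataFrame:
    """Symmetric site-by-site great-circle distance matrix in km."""
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    if ((lat < -90) | (lat > 90)).any():
        raise BiogeoError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise BiogeoError("longitude outside [-180, 180]")
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :], radius_km)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against rounding
    return pd.DataFrame(d, index=meta.index, columns=meta.index)


# ---------------------------------------------------------------------------
# Distance-decay regression
# ---------------------------------------------------------------------------

def distance_decay(
    community: pd.DataFrame,
    geo: pd.DataFrame,
    *,
    per_km: float = 100.0,
    p_method: str = "t",
    n_perm: int = 999,
    seed: int = 0,
) -> DdrFit:
    """Fit similarity = intercept + slope * (distance / per_km) over all pairs.

    ``p_method="t"`` uses the slope's t-test; ``"permutation"`` shuffles the
    sample order of the community matrix and recomputes the slope.
    """
    community, geo = align_distance_matrices(community, geo)
    n = len(community)
    if n < 3:
        raise BiogeoError("distance-decay needs at least 3 samples")
    sim = 1.0 - condensed(community)
    dist = condensed(geo) / per_km
    if np.ptp(dist) == 0:
        raise BiogeoError("geographic distances have zero variance")
    if np.ptp(sim) == 0:
        # flat similarity: slope 0 with nothing to explain
        return DdrFit(slope=0.0, intercept=float(sim[0]), r_squared=0.0,
                      p_value=1.0, n_pairs=len(sim), per_km=per_km)
    res = stats.linregress(dist, sim)
    p_value = float(res.pvalue)
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        cv = community.to_numpy(dtype=float)
        iu = np.triu_indices(n, k=1)
        obs = abs(res.slope)
        hits = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            sim_p = 1.0 - cv[np.ix_(idx, idx)][iu]
            slope_p = stats.linregress(dist, sim_p).slope
            hits += abs(slope_p) >= obs
        p_value = (hits + 1) / (n_perm + 1)
    elif p_method != "t":
        raise BiogeoError(f"unknown p_method {p_method!r}")
    return DdrFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=p_value,
        n_pairs=len(sim),
        per_km=per_km,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _rank_matrix(d: np.ndarray) -> np.ndarray:
    """Rank-transform the off-diagonal entries of a symmetric matrix.

    The multiset of upper-triangle entries is invariant under a joint
    row/column permutation, so ranking once lets Spearman permutations reuse
    Pearson machinery on the ranked matrix.
    """
    iu = np.triu_indices(d.shape[0], k=1)
    ranks = stats.rankdata(d[iu])
    out = np.zeros_like(d, dtype=float)
    out[iu] = ranks
    out = out + out.T
    return out


def mantel(
    a: pd.DataFrame,
    b: pd.DataFrame,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Permutation test of correlation between two distance matrices.

    The null shuffles the row/column order of ``b`` jointly; the two-sided
    p-value is (#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1).
    """
    a, b = align_distance_matrices(a, b)
    n = len(a)
    if n < 4:
        raise BiogeoError("Mantel test needs at least 4 samples")
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    if method == "spearman":
        av, bv = _rank_matrix(av), _rank_matrix(bv)
    elif method != "pearson":
        raise BiogeoError(f"unknown method {method!r}")
    iu = np.triu_indices(n, k=1)
    x = av[iu]
    if np.ptp(x) == 0 or np.ptp(bv[iu]) == 0:
        raise BiogeoError("constant distance matrix: correlation undefined")
    x = (x - x.mean()) / x.std()
    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        sy = y.std()
        if sy == 0:
            return 0.0
        return float((x * (y - y.mean())).mean() / sy)
    r_obs = corr(bv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if abs(corr(bv[np.ix_(idx, idx)])) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm, method=method)


# ---------------------------------------------------------------------------
# Diversity vs latitude
# ---------------------------------------------------------------------------

def diversity_vs_latitude(alpha: pd.DataFrame, meta: pd.DataFrame) -> dict[str, LatRegression]:
    """OLS of richness and Shannon on latitude with 95% CI of the fitted line."""
    joined = alpha.join(meta["latitude"], how="inner")
    if len(joined) < 3:
        raise BiogeoError("latitude regression needs at least 3 samples")
    lat = joined["latitude"].to_numpy(dtype=float)
    if np.ptp(lat) == 0:
        raise BiogeoError("latitude is constant: regression undefined")
    x = sm.add_constant(lat)
    out: dict[str, LatRegression] = {}
    for metric in ("richness", "shannon"):
        y = joined[metric].to_numpy(dtype=float)
        fit = sm.OLS(y, x).fit()
        ci = fit.get_prediction(x).conf_int(alpha=0.05)
        out[metric] = LatRegression(
            metric=metric,
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            r_squared=float(fit.rsquared),
            p_value=float(fit.pvalues[1]),
            ci_lower=ci[:, 0],
            ci_upper=ci[:, 1],
        )
    return out
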