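"""Permutation tests of between-group community structure (PERMANOVA,
ANOSIM, MRPP) and nonmetric multidimensional scaling.

All three tests operate directly on a distance matrix with a single
grouping factor (one-way designs), use label shuffling for the null, and
report p with the +1 correction, p = (#{extreme} + 1) / (n_perm + 1), so
p = 0 is impossible.

* PERMANOVA: Anderson's pseudo-F from squared distances,
  F = (SS_between / (g - 1)) / (SS_within / (n - g)).
* ANOSIM: R = (mean between-group rank - mean within-group rank) / (M / 2)
  with M = n(n-1)/2 pairwise distances (midranks for ties).
* MRPP: delta = sum_g (n_g / n) * mean within-group distance; small delta
  is evidence of structure, so the p-value counts delta_perm <= delta_obs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from ._utils import BiogeoError, condensed, validate_distance_matrix


@dataclass(frozen=True)
class PermTestResult:
    method: str
    statistic: float
    p: float
    n_perm: int
    group_sizes: dict[str, int]
    extras: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame  # samples x k, centred at the origin
    stress: float              # Kruskal stress-1
    n_restarts: int
    converged: bool


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _prepare(d: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    validate_distance_matrix(d)
    g = pd.Series(groups)
    if not g.index.equals(d.index):
        g = g.reindex(d.index)
    if g.isna().any():
        raise BiogeoError("every sample needs a group label")
    labels, codes = np.unique(g.to_numpy(), return_inverse=True)
    sizes = {str(lab): int((codes == i).sum()) for i, lab in enumerate(labels)}
    if len(labels) < 2:
        raise BiogeoError("need at least 2 groups")
    small = [lab for lab, n in sizes.items() if n < 2]
    if small:
        raise BiogeoError(f"groups of size 1 are not testable: {small}")
    return d.to_numpy(dtype=float), codes, sizes


def _perm_p(stat_fn, codes: np.ndarray, obs: float, n_perm: int, seed: int,
            alternative: str) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        s = stat_fn(rng.permutation(codes))
        if alternative == "greater":
            hits += s >= obs - 1e-12
        else:
            hits += s <= obs + 1e-12
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, float]:
    """(SS_total, SS_within, SS_between) from a squared-distance matrix."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for k in range(n_groups):
        m = codes == k
        nk = int(m.sum())
        ss_within += d2[np.ix_(m, m)].sum() / (2 * nk)
    return ss_total, ss_within, ss_total - ss_within


def permanova(d: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0) -> PermTestResult:
    dv, codes, sizes = _prepare(d, groups)
    n, g = len(codes), len(sizes)
    if n - g <= 0:
        raise BiogeoError("no residual degrees of freedom")
    d2 = dv**2
    ss_total, _, _ = permanova_ss(d2, codes, g)
    if ss_total <= 0:
        raise BiogeoError("all distances are zero: pseudo-F undefined")

    def pseudo_f(c: np.ndarray) -> float:
        st, sw, sb = permanova_ss(d2, c, g)
        if sw <= 0:
            return np.inf
        return (sb / (g - 1)) / (sw / (n - g))

    obs = pseudo_f(codes)
    p = _perm_p(pseudo_f, codes, obs, n_perm, seed, "greater")
    st, sw, sb = permanova_ss(d2, codes, g)
    return PermTestResult(
        "PERMANOVA", float(obs), p, n_perm, sizes,
        extras={"ss_total": st, "ss_within": sw, "ss_between": sb},
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim(d: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0) -> PermTestResult:
    dv, codes, sizes = _prepare(d, groups)
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dv[iu])
    denom = (n * (n - 1) / 2) / 2.0
    within_pair = lambda c: c[iu[0]] == c[iu[1]]

    def r_stat(c: np.ndarray) -> float:
        w = within_pair(c)
        return (ranks[~w].mean() - ranks[w].mean()) / denom

    obs = r_stat(codes)
    p = _perm_p(r_stat, codes, obs, n_perm, seed, "greater")
    return PermTestResult("ANOSIM", float(obs), p, n_perm, sizes)


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------

def mrpp(d: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0) -> PermTestResult:
    dv, codes, sizes = _prepare(d, groups)
    n = len(codes)
    g = len(sizes)

    def delta(c: np.ndarray) -> float:
        out = 0.0
        for k in range(g):
            m = c == k
            nk = int(m.sum())
            out += (nk / n) * dv[np.ix_(m, m)].sum() / (nk * (nk - 1))
        return out

    obs = delta(codes)
    # chance-corrected agreement A = 1 - delta / E[delta] with E over perms
    rng = np.random.default_rng(seed)
    perm_deltas = np.array([delta(rng.permutation(codes)) for _ in range(n_perm)])
    p = (int((perm_deltas <= obs + 1e-12).sum()) + 1) / (n_perm + 1)
    expected = float(perm_deltas.mean())
    a_stat = 1.0 - obs / expected if expected > 0 else 0.0
    return PermTestResult(
        "MRPP", float(obs), p, n_perm, sizes,
        extras={"expected_delta": expected, "A": a_stat},
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def kruskal_stress1(dissim: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 of a configuration: sqrt(sum (d - dhat)^2 / sum d^2), with
    disparities dhat from isotonic regression of configuration distances on
    the input dissimilarities (primary tie approach via midranked x)."""
    iu = np.triu_indices(dissim.shape[0], k=1)
    dx = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    dhat = IsotonicRegression().fit_transform(dissim[iu], dx)
    denom = (dx**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dx - dhat) ** 2).sum() / denom))


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NmdsResult:
    """Nonmetric MDS of a dissimilarity matrix (SMACOF with isotonic
    regression), best of ``n_restarts`` by Kruskal stress-1.

    Deterministic under ``seed``. If no restart converges within
    ``max_iter`` iterations the best configuration is still returned with
    ``converged=False``.
    """
    validate_distance_matrix(d)
    n = len(d)
    if n < k + 1:
        raise BiogeoError(f"NMDS with k={k} needs at least {k + 1} samples")
    dv = d.to_numpy(dtype=float)
    model = MDS(
        n_components=k,
        metric_mds=False,
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        eps=tol,
        metric="precomputed",
        random_state=int(seed) % (2**31 - 1),
        normalized_stress=True,
        n_jobs=1,
    )
    coords = model.fit_transform(dv)
    coords = coords - coords.mean(axis=0, keepdims=True)
    stress = kruskal_stress1(dv, coords)
    converged = bool(model.n_iter_ < max_iter)
    frame = pd.DataFrame(
        coords, index=d.index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(coordinates=frame, stress=stress,
                      n_restarts=n_restarts, converged=converged)


# ---------------------------------------------------------------------------
# table of results (one row per test / comparison)
# ---------------------------------------------------------------------------

def community_test_table(
    d: pd.DataFrame,
    groups,
    *,
    pairwise: bool = True,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Run PERMANOVA, ANOSIM and MRPP globally and (optionally) for every
    group pair; returns a tidy table of method, comparison, statistic, p."""
    g = pd.Series(groups)
    if not g.index.equals(d.index):
        g = g.reindex(d.index)
    rows = []
    tests = (("PERMANOVA", permanova), ("ANOSIM", anosim), ("MRPP", mrpp))
    for name, fn in tests:
        res = fn(d, g, n_perm=n_perm, seed=seed)
        rows.append((name, "global", res.statistic, res.p))
    if pairwise:
        labels = sorted(set(g.dropna()))
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                ids = g.index[g.isin([a, b])]
                sub_d = d.loc[ids, ids]
                sub_g = g.loc[ids]
                if min((sub_g == a).sum(), (sub_g == b).sum()) < 2:
                    continue
                for name, fn in tests:
                    res = fn(sub_d, sub_g, n_perm=n_perm, seed=seed)
                    rows.append((name, f"{a} vs {b}", res.statistic, res.p))
    return pd.DataFrame(rows, columns=["method", "comparison", "statistic", "p"])
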