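"""Constrained ordination: VIF pruning, canonical correspondence analysis
(CCA) with Monte-Carlo significance, variation partitioning, and
taxa-environment Spearman correlations.

CCA follows the classic weighted chi-square formulation: the abundance
table is converted to chi-square-standardized residuals
Qbar = (P - r c^T) / sqrt(r c^T) (so total inertia equals the table's
chi-square statistic divided by its grand total), the residuals are
regressed on the row-weighted, centred environmental matrix, and the
fitted part is eigen-decomposed.  Significance comes from shuffling the
environmental rows against a pseudo-F on constrained inertia.

Variation partitioning uses CCA-based R-squared adjusted by permutation
(R2_adj = 1 - (1 - R2) / (1 - mean R2_perm)), partitioned into pure
environmental, pure spatial, shared and residual fractions that sum to 1
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import BiogeoError


@dataclass(frozen=True)
class CcaResult:
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    constrained_eigenvalues: np.ndarray  # nonnegative, non-increasing
    total_inertia: float
    constrained_proportion: float
    kept_variables: list[str]
    permutation_p: float
    pseudo_f: float
    n_perm: int


@dataclass(frozen=True)
class VpaResult:
    """Adjusted-R2 fractions; pure/shared fractions may be slightly negative."""

    frac_E_pure: float
    frac_S_pure: float
    frac_shared: float
    frac_residual: float
    adj_r2_E: float
    adj_r2_S: float
    adj_r2_ES: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------

def variance_inflation(env: pd.DataFrame) -> pd.Series:
    """VIF_i = 1 / (1 - R^2) of regressing variable i on all others
    (with intercept). A single variable has VIF 1 by convention."""
    x = env.to_numpy(dtype=float)
    n, p = x.shape
    if p == 1:
        return pd.Series([1.0], index=env.columns)
    out = {}
    for i, col in enumerate(env.columns):
        others = np.column_stack([np.ones(n), np.delete(x, i, axis=1)])
        y = x[:, i]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1 - resid @ resid / ss_tot
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(env: pd.DataFrame, threshold: float = 10.0) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the variable with the largest VIF above ``threshold``.

    Perfectly collinear variables have infinite VIF and are dropped first
    (ties broken by column order, later columns dropped first). Returns the
    kept labels and a per-step trace of all VIFs with the dropped variable.
    """
    if env.shape[1] < 1:
        raise BiogeoError("need at least one environmental variable")
    if env.shape[0] <= env.shape[1]:
        raise BiogeoError("need more samples than environmental variables")
    kept = list(env.columns)
    trace_rows = []
    step = 0
    while True:
        vifs = variance_inflation(env[kept])
        worst = None
        if len(kept) > 1:
            vmax = vifs.max()
            if vmax > threshold:
                # among ties at the max, drop the rightmost column
                worst = [c for c in kept if vifs[c] == vmax][-1]
        for c in kept:
            trace_rows.append((step, c, float(vifs[c]), c == worst))
        if worst is None:
            break
        kept.remove(worst)
        step += 1
    trace = pd.DataFrame(trace_rows, columns=["step", "variable", "vif", "dropped"])
    return kept, trace


# ---------------------------------------------------------------------------
# CCA core
# ---------------------------------------------------------------------------

def _chi_square_residuals(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.Index]:
    """(Qbar, row weights r, column weights c, kept species index)."""
    y = table.to_numpy(dtype=float)
    keep = y.sum(axis=0) > 0
    y = y[:, keep]
    species = table.columns[keep]
    if (y.sum(axis=1) == 0).any():
        raise BiogeoError("all-zero samples are not allowed in CCA")
    total = y.sum()
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    e = np.outer(r, c)
    qbar = (p - e) / np.sqrt(e)
    return qbar, r, c, species


def _weighted_basis(env: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Orthonormal basis (n x q) of the row-weighted, weighted-centred
    environmental matrix; q is its numerical rank."""
    xc = env - (r @ env)  # weighted column means (weights sum to 1)
    xw = np.sqrt(r)[:, None] * xc
    q, s, _ = np.linalg.svd(xw, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    return q[:, :rank]


def _constrained_inertia(qbar: np.ndarray, basis: np.ndarray) -> float:
    proj = basis.T @ qbar
    return float((proj**2).sum())


def cca(
    table: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    vif_threshold: float = 10.0,
) -> CcaResult:
    """CCA of a count table on environmental covariates.

    Covariates are VIF-pruned (> ``vif_threshold`` removed) before the
    ordination; species with zero total are removed. The permutation p
    shuffles environmental rows against the pseudo-F of constrained inertia.
    """
    if not table.index.equals(env.index):
        env = env.loc[table.index]
    kept, _ = vif_prune(env, vif_threshold)
    x = env[kept].to_numpy(dtype=float)
    n = x.shape[0]
    if n <= x.shape[1]:
        raise BiogeoError("need more samples than environmental variables")
    qbar, r, c, species = _chi_square_residuals(table)
    total_inertia = float((qbar**2).sum())
    if total_inertia <= 0:
        raise BiogeoError("table has no inertia (all rows proportional)")

    basis = _weighted_basis(x, r)
    q_rank = basis.shape[1]
    if q_rank == 0:
        raise BiogeoError("environmental matrix has rank 0 after centring")
    yhat = basis @ (basis.T @ qbar)
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    eig = s**2
    n_axes = int((eig > eig[0] * 1e-12).sum()) if eig.size and eig[0] > 0 else 0
    eig = eig[:n_axes]
    ci = float(eig.sum())

    def pseudo_f(inertia: float) -> float:
        resid = total_inertia - inertia
        if resid <= 0:
            return np.inf
        return (inertia / q_rank) / (resid / (n - q_rank - 1))

    f_obs = pseudo_f(ci)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        xb = _weighted_basis(x[rng.permutation(n)], r)
        if pseudo_f(_constrained_inertia(qbar, xb)) >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)

    axes = [f"CCA{i + 1}" for i in range(n_axes)]
    site = (u[:, :n_axes] * s[:n_axes]) / np.sqrt(r)[:, None]
    spec = (vt[:n_axes].T * s[:n_axes]) / np.sqrt(c)[:, None]
    return CcaResult(
        site_scores=pd.DataFrame(site, index=table.index, columns=axes),
        species_scores=pd.DataFrame(spec, index=species, columns=axes),
        constrained_eigenvalues=eig,
        total_inertia=total_inertia,
        constrained_proportion=ci / total_inertia,
        kept_variables=kept,
        permutation_p=p,
        pseudo_f=f_obs,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Variation partitioning
# ---------------------------------------------------------------------------

def _adjusted_r2(qbar: np.ndarray, r: np.ndarray, x: np.ndarray,
                 total_inertia: float, perms: np.ndarray) -> float:
    """Permutation-adjusted CCA R-squared (Peres-Neto style):
    R2_adj = 1 - (1 - R2) / (1 - mean(R2_perm)).

    ``perms`` is a fixed (n_perm, n) array of row permutations; sharing it
    across models is a common-random-numbers device that makes identities
    such as "S identical to E => pure fractions 0" hold exactly.
    """
    r2 = _constrained_inertia(qbar, _weighted_basis(x, r)) / total_inertia
    perm = np.empty(len(perms))
    for i, idx in enumerate(perms):
        perm[i] = _constrained_inertia(
            qbar, _weighted_basis(x[idx], r)
        ) / total_inertia
    mean_null = perm.mean()
    if mean_null >= 1 - 1e-12:
        raise BiogeoError("adjusted R2 undefined: null saturates the table")
    return float(1 - (1 - r2) / (1 - mean_null))


def variation_partition(
    table: pd.DataFrame,
    env: pd.DataFrame,
    spatial: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> VpaResult:
    """Partition community variation into pure environmental (E), pure
    spatial (S), shared, and residual fractions via adjusted R2 of the
    three constrained models E, S and E+S.

    shared = adjR2(E) + adjR2(S) - adjR2(E+S);
    pure_E = adjR2(E+S) - adjR2(S); pure_S = adjR2(E+S) - adjR2(E);
    residual = 1 - adjR2(E+S). The four fractions sum to 1 identically.
    """
    if env.shape[1] == 0 or spatial.shape[1] == 0:
        raise BiogeoError("both explanatory matrices must be non-empty")
    if not table.index.equals(env.index):
        env = env.loc[table.index]
    if not table.index.equals(spatial.index):
        spatial = spatial.loc[table.index]
    n = len(table)
    if n <= env.shape[1] + spatial.shape[1] + 1:
        raise BiogeoError("too few samples for adjusted R2 of the joint model")
    qbar, r, _, _ = _chi_square_residuals(table)
    total = float((qbar**2).sum())
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    xe = env.to_numpy(dtype=float)
    xs = spatial.to_numpy(dtype=float)
    adj_e = _adjusted_r2(qbar, r, xe, total, perms)
    adj_s = _adjusted_r2(qbar, r, xs, total, perms)
    adj_es = _adjusted_r2(qbar, r, np.column_stack([xe, xs]), total, perms)
    return VpaResult(
        frac_E_pure=adj_es - adj_s,
        frac_S_pure=adj_es - adj_e,
        frac_shared=adj_e + adj_s - adj_es,
        frac_residual=1.0 - adj_es,
        adj_r2_E=adj_e,
        adj_r2_S=adj_s,
        adj_r2_ES=adj_es,
    )


# ---------------------------------------------------------------------------
# Forward selection (optional helper)
# ---------------------------------------------------------------------------

def forward_select(
    table: pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> list[str]:
    """Greedy forward selection of covariates on CCA adjusted R2 with a
    permutation stopping rule: a candidate enters only while its marginal
    gain is permutation-significant at ``alpha``."""
    qbar, r, _, _ = _chi_square_residuals(table)
    total = float((qbar**2).sum())
    rng = np.random.default_rng(seed)
    n = len(table)
    selected: list[str] = []
    remaining = list(env.columns)

    def r2_of(cols: list[str]) -> float:
        x = env[cols].to_numpy(dtype=float)
        return _constrained_inertia(qbar, _weighted_basis(x, r)) / total

    while remaining:
        base_r2 = r2_of(selected) if selected else 0.0
        gains = {c: r2_of(selected + [c]) - base_r2 for c in remaining}
        best = max(gains, key=gains.get)
        obs = gains[best]
        hits = 0
        col = env[best].to_numpy(dtype=float).copy()
        for _ in range(n_perm):
            permuted = env[selected].copy() if selected else pd.DataFrame(index=env.index)
            permuted[best] = col[rng.permutation(n)]
            x = permuted[selected + [best]].to_numpy(dtype=float)
            gain = _constrained_inertia(qbar, _weighted_basis(x, r)) / total - base_r2
            if gain >= obs - 1e-12:
                hits += 1
        if (hits + 1) / (n_perm + 1) > alpha:
            break
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------
# Taxa-environment correlations
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def taxa_env_correlations(
    agg: pd.DataFrame,
    meta: pd.DataFrame,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Spearman rho between the ``top_n`` most abundant taxa (by mean
    relative abundance) and every numeric covariate, with raw-p stars
    (p < 0.05 *, < 0.01 **, < 0.001 ***) and a BH-adjusted column.

    Constant taxa have undefined rho and are reported as NA.
    """
    from statsmodels.stats.multitest import multipletests

    if not agg.index.equals(meta.index):
        meta = meta.loc[agg.index]
    taxa = agg.mean(axis=0).sort_values(ascending=False).index
    if top_n is not None:
        taxa = taxa[:top_n]
    env_cols = [c for c in meta.columns
                if c != "region" and pd.api.types.is_numeric_dtype(meta[c])]
    rows = []
    for taxon in taxa:
        tvals = agg[taxon].to_numpy(dtype=float)
        for var in env_cols:
            evals = meta[var].to_numpy(dtype=float)
            if np.ptp(tvals) == 0 or np.ptp(evals) == 0:
                rows.append((taxon, var, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(tvals, evals)
            rows.append((taxon, var, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["taxon", "variable", "rho", "p_value"])
    mask = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(
            out.loc[mask, "p_value"], method="fdr_bh"
        )[1]
    out["p_bh"] = adj
    out["stars"] = [significance_stars(p) for p in out["p_value"]]
    return out
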