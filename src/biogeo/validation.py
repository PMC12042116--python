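"""Self-validation benchmarks: permutation-test calibration on null data,
FDR control of the co-occurrence edge procedure, and recovery of the
structure planted by the synthetic generator.

These routines exist so the whole pipeline can be audited end-to-end
without any external dataset: a valid permutation test must reject ~5% of
true nulls at alpha = 0.05, BH must keep the expected number of false
edges below alpha times the number of tested pairs, and the generator's
planted turnover ordering, specialists and correlation blocks must be
recovered by the corresponding analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import diversity, network, permtests, spatial, specocc, synth, tables

_GROUP_TESTS = {
    "permanova": permtests.permanova,
    "anosim": permtests.anosim,
    "mrpp": permtests.mrpp,
}


def _euclidean_frame(points: np.ndarray) -> pd.DataFrame:
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(d, index=ids, columns=ids)


def group_test_type_i_error(
    method: str,
    n_sims: int = 200,
    n_samples: int = 20,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of PERMANOVA / ANOSIM / MRPP when the two
    groups are drawn from the same distribution (true null)."""
    fn = _GROUP_TESTS[method]
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    hits = 0
    for i in range(n_sims):
        d = _euclidean_frame(rng.normal(size=(n_samples, 3)))
        groups = pd.Series(["A"] * half + ["B"] * (n_samples - half), index=d.index)
        res = fn(d, groups, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        hits += res.p <= alpha
    return hits / n_sims


def mantel_type_i_error(
    n_sims: int = 200,
    n_samples: int = 15,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the Mantel test for two distance
    matrices generated from independent point clouds (true null)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_sims):
        a = _euclidean_frame(rng.normal(size=(n_samples, 3)))
        b = _euclidean_frame(rng.normal(size=(n_samples, 3)))
        res = spatial.mantel(a, b, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        hits += res.p <= alpha
    return hits / n_sims


def null_edge_fdr(
    n_sims: int = 100,
    n_samples: int = 20,
    n_otus: int = 15,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, int]:
    """Mean number of BH-significant correlations per simulation on tables
    of fully independent OTUs, with the |rho| gate disabled so the count
    reflects the BH procedure alone.

    Returns (mean significant edges, number of tested pairs); FDR control
    requires the mean not to exceed alpha * pairs (within Monte-Carlo error).
    """
    rng = np.random.default_rng(seed)
    pairs = n_otus * (n_otus - 1) // 2
    counts = []
    for _ in range(n_sims):
        table = pd.DataFrame(
            rng.integers(0, 50, size=(n_samples, n_otus)),
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"o{j}" for j in range(n_otus)],
        )
        edges = network.correlation_edges(table, r_threshold=0.0, alpha=alpha)
        counts.append(len(edges))
    return float(np.mean(counts)), pairs


@dataclass(frozen=True)
class SlopeRecovery:
    seed: int
    slopes: dict[str, float]      # domain -> fitted slope per 100 km
    p_values: dict[str, float]
    ordered: bool                 # archaea < bacteria < fungi < 0
    all_significant: bool         # every p < 0.001


def _domain_ddr(config: synth.SynthConfig, meta: pd.DataFrame,
                geo: pd.DataFrame, domain: str) -> spatial.DdrFit:
    table = synth.generate_community(config, meta, domain)
    rare = tables.rarefy(table, int(table.sum(axis=1).min()),
                         seed=config.seed)
    return spatial.distance_decay(diversity.bray_curtis(rare), geo)


def ddr_slope_recovery(seeds, config: synth.SynthConfig | None = None) -> list[SlopeRecovery]:
    """Fit the distance-decay slope per domain for each seed and check the
    planted turnover ordering (archaea fastest, fungi slowest)."""
    out = []
    for seed in seeds:
        cfg = (config or synth.SynthConfig()).replace(seed=int(seed))
        meta = synth.generate_metadata(cfg)
        geo = spatial.haversine_matrix(meta)
        fits = {d: _domain_ddr(cfg, meta, geo, d) for d in cfg.n_otus_per_domain}
        slopes = {d: f.slope for d, f in fits.items()}
        ps = {d: f.p_value for d, f in fits.items()}
        ordered = slopes["archaea"] < slopes["bacteria"] < slopes["fungi"] < 0
        out.append(SlopeRecovery(
            seed=int(seed), slopes=slopes, p_values=ps, ordered=ordered,
            all_significant=all(p < 0.001 for p in ps.values()),
        ))
    return out


def specialist_recovery(seeds, domain: str = "archaea",
                        config: synth.SynthConfig | None = None,
                        threshold: float = 0.7) -> list[bool]:
    """True per seed iff classify_specialists returns exactly the planted
    (OTU, home region) set for the given domain."""
    out = []
    for seed in seeds:
        cfg = (config or synth.SynthConfig()).replace(seed=int(seed))
        meta = synth.generate_metadata(cfg)
        table = synth.generate_community(cfg, meta, domain)
        rel = tables.relative_abundance(table)
        rec = specocc.spec_occ(rel, meta["region"])
        specs = specocc.classify_specialists(rec, threshold)
        found = set(zip(specs["otu_id"], specs["habitat"]))
        truth = synth.planted_truth(cfg, domain)
        out.append(found == set(truth.specialist_home.items()))
    return out


def block_recovery(seeds, domain: str = "bacteria",
                   config: synth.SynthConfig | None = None) -> tuple[int, int]:
    """(blocks recovered as exact connected components, blocks planted)
    across seeds, using the full co-occurrence edge procedure."""
    ok = total = 0
    for seed in seeds:
        cfg = (config or synth.SynthConfig()).replace(seed=int(seed))
        meta = synth.generate_metadata(cfg)
        table = synth.generate_community(cfg, meta, domain)
        filtered = network.prevalence_filter(table)
        edges = network.correlation_edges(filtered)
        graph = network.build_network(edges).graph
        comps = [set(c) for c in nx.connected_components(graph)]
        truth = synth.planted_truth(cfg, domain)
        for block in truth.blocks:
            total += 1
            matches = [c for c in comps if set(block) & c]
            if len(matches) == 1 and matches[0] == set(block):
                ok += 1
    return ok, total
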