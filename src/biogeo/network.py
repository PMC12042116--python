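"""Co-occurrence network construction and topology metrics.

Per latitudinal region and domain: OTUs present in more than half the
region's samples are retained, all pairwise Spearman correlations are
computed (p-values from the t approximation, midranks for ties),
Benjamini-Hochberg adjustment is applied across all tested pairs of the
network, and an edge is kept when |rho| > 0.7 (strict) and adjusted
p < 0.05 (strict).  Topology reports node/link counts, average degree
avgK = 2L/N, average local clustering coefficient (degree-1 nodes count
as 0), Newman modularity of the greedy (CNM) partition on the unsigned,
unweighted skeleton, and the fraction of positive edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import BiogeoError

EDGE_COLUMNS = ["otu_a", "otu_b", "rho", "p_raw", "p_adj", "sign"]


@dataclass(frozen=True)
class NetworkTopology:
    n_nodes: int
    n_links: int
    avgK: float
    avgCC: float
    modularity: float
    frac_positive: float
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class CoocNetwork:
    graph: nx.Graph
    edges: pd.DataFrame
    topology: NetworkTopology = field(init=False)

    def __post_init__(self) -> None:
        self.topology = topology(self.graph)


# ---------------------------------------------------------------------------
# Filtering and correlation
# ---------------------------------------------------------------------------

def prevalence_filter(table: pd.DataFrame, min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep OTUs present (count > 0) in strictly more than ``min_fraction``
    of the samples. An OTU in exactly half the samples is removed."""
    if not 0 <= min_fraction < 1:
        raise BiogeoError("min_fraction must be in [0, 1)")
    prev = (table > 0).sum(axis=0)
    keep = prev > min_fraction * len(table)
    return table.loc[:, keep]


def correlation_edges(
    table: pd.DataFrame,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation edge list over all OTU pairs.

    BH adjustment is applied across every tested pair of this table (the
    whole upper triangle); an edge survives iff |rho| > r_threshold
    (strict) and adjusted p < alpha (strict). Pairs involving a constant
    OTU have undefined rho and are skipped with a warning.
    """
    n, m = table.shape
    if n < 4:
        raise BiogeoError("need at least 4 samples for correlation edges")
    if m < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    x = table.to_numpy(dtype=float)
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant OTU(s) skipped (rho undefined)",
            stacklevel=2,
        )
    x = x[:, ~constant]
    otus = table.columns.to_numpy()[~constant]
    m = x.shape[1]
    if m < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    if m == 2:  # spearmanr returns scalars for a single pair
        r12, p12 = stats.spearmanr(x[:, 0], x[:, 1])
        rho = np.array([[1.0, r12], [r12, 1.0]])
        p = np.array([[0.0, p12], [p12, 0.0]])
    else:
        rho, p = stats.spearmanr(x)  # m x m, t-approximation p-values
    iu = np.triu_indices(m, k=1)
    rho_v = rho[iu]
    p_v = p[iu]
    p_adj = multipletests(p_v, method="fdr_bh")[1]
    keep = (np.abs(rho_v) > r_threshold) & (p_adj < alpha)
    a = otus[iu[0]][keep]
    b = otus[iu[1]][keep]
    signs = np.where(rho_v[keep] >= 0, "positive", "negative")
    return pd.DataFrame(
        {
            "otu_a": a,
            "otu_b": b,
            "rho": rho_v[keep],
            "p_raw": p_v[keep],
            "p_adj": p_adj[keep],
            "sign": signs,
        },
        columns=EDGE_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Graph construction and topology
# ---------------------------------------------------------------------------

def build_network(edges: pd.DataFrame, taxonomy: pd.DataFrame | None = None) -> CoocNetwork:
    """Undirected signed graph from an edge list; nodes are OTUs incident to
    at least one edge, annotated with degree and phylum (when known)."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.otu_a, row.otu_b, rho=float(row.rho),
                   p_adj=float(row.p_adj), sign=row.sign)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
        if taxonomy is not None and node in taxonomy.index:
            g.nodes[node]["phylum"] = str(taxonomy.loc[node, "phylum"])
    return CoocNetwork(graph=g, edges=edges.reset_index(drop=True))


def modularity_cnm(g: nx.Graph) -> float:
    """Newman Q of the best partition found by greedy agglomeration (CNM)
    on the unweighted, unsigned skeleton. 0 for graphs without edges."""
    if g.number_of_edges() == 0:
        return 0.0
    communities = nx.community.greedy_modularity_communities(g, weight=None)
    return float(nx.community.modularity(g, communities, weight=None))


def topology(g: nx.Graph) -> NetworkTopology:
    """Topology summary; an empty network reports all-zero metrics, flagged."""
    n = g.number_of_nodes()
    links = g.number_of_edges()
    if n == 0:
        return NetworkTopology(0, 0, 0.0, 0.0, 0.0, 0.0, empty=True)
    avg_k = 2.0 * links / n
    avg_cc = float(nx.average_clustering(g, count_zeros=True))
    signs = [d.get("sign", "positive") for _, _, d in g.edges(data=True)]
    frac_pos = (sum(s == "positive" for s in signs) / links) if links else 0.0
    return NetworkTopology(
        n_nodes=n,
        n_links=links,
        avgK=avg_k,
        avgCC=avg_cc,
        modularity=modularity_cnm(g),
        frac_positive=frac_pos,
    )


def phylum_composition(net: CoocNetwork) -> pd.DataFrame:
    """Fraction of network nodes per phylum (requires taxonomy-annotated nodes)."""
    counts: dict[str, int] = {}
    for _, data in net.graph.nodes(data=True):
        phylum = data.get("phylum", "unclassified")
        counts[phylum] = counts.get(phylum, 0) + 1
    total = sum(counts.values())
    rows = [(p, c, c / total if total else 0.0) for p, c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["phylum", "n_nodes", "fraction"])


def write_graphml(net: CoocNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def region_networks(
    table: pd.DataFrame,
    regions: pd.Series,
    taxonomy: pd.DataFrame | None = None,
    *,
    min_fraction: float = 0.5,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
) -> dict[str, CoocNetwork]:
    """One co-occurrence network per region, each filtered, correlated and
    BH-adjusted independently."""
    out: dict[str, CoocNetwork] = {}
    for region in sorted(pd.Series(regions).unique()):
        sub = table.loc[regions == region]
        filtered = prevalence_filter(sub, min_fraction)
        if filtered.shape[1] < 2 or len(sub) < 4:
            out[region] = build_network(pd.DataFrame(columns=EDGE_COLUMNS), taxonomy)
            continue
        edges = correlation_edges(filtered, r_threshold, alpha)
        out[region] = build_network(edges, taxonomy)
    return out
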