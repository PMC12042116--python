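"""Alpha diversity, Bray-Curtis dissimilarity, and between-region
alpha-diversity comparisons.

Shannon entropy is reported in nats (natural log), the vegan default.
Both alpha diversity and Bray-Curtis are meant to be computed on rarefied
counts; un-rarefied input is accepted with a warning when sample totals
are visibly unequal.

Bray-Curtis is not a metric (the triangle inequality can fail), so no
triangle property is asserted anywhere downstream.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from ._utils import BiogeoError
from .tables import REGION_NA


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Richness (OTUs with count > 0) and Shannon index per sample.

    Shannon = -sum p_i ln p_i over nonzero proportions. All-zero samples get
    richness 0, Shannon 0 and ``flagged=True``.
    """
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if len(set(np.round(totals[totals > 0]).astype(int))) > 1:
        warnings.warn(
            "sample totals are unequal; alpha diversity is usually computed "
            "on rarefied counts",
            stacklevel=2,
        )
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} all-zero sample(s): richness and "
            "Shannon set to 0",
            stacklevel=2,
        )
    richness = (counts > 0).sum(axis=1)
    shannon = np.zeros(len(table))
    for i, row in enumerate(counts):
        nz = row[row > 0]
        if nz.size and totals[i] > 0:
            p = nz / totals[i]
            shannon[i] = float(-(p * np.log(p)).sum())
    return pd.DataFrame(
        {
            "richness": richness.astype(int),
            "shannon": shannon,
            "flagged": totals == 0,
        },
        index=table.index,
    )


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y).

    A pair of all-zero samples has an undefined quotient; by convention it is
    set to 0 with a warning. Similarity used elsewhere is 1 - d.
    """
    if len(table) < 2:
        raise BiogeoError("Bray-Curtis needs at least 2 samples")
    counts = table.to_numpy(dtype=float)
    d = squareform(pdist(counts, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn(
            "all-zero sample pair(s): Bray-Curtis undefined, set to 0 by convention",
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


def compare_regions_alpha(alpha: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of each alpha metric between every
    region pair (normal approximation with tie correction).

    Region pairs where either side has fewer than 2 samples are skipped and
    reported with a note instead of a p-value.
    """
    joined = alpha.join(meta["region"], how="inner")
    groups = {
        r: sub for r, sub in joined.groupby("region") if r != REGION_NA
    }
    rows = []
    for (ra, ga), (rb, gb) in itertools.combinations(sorted(groups.items()), 2):
        for metric in ("richness", "shannon"):
            x = ga[metric].to_numpy(dtype=float)
            y = gb[metric].to_numpy(dtype=float)
            if len(x) < 2 or len(y) < 2:
                rows.append((ra, rb, metric, len(x), len(y), np.nan, np.nan,
                             "skipped: fewer than 2 samples in a region"))
                continue
            stat, p = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            rows.append((ra, rb, metric, len(x), len(y), float(stat), float(p), ""))
    return pd.DataFrame(
        rows,
        columns=["region_a", "region_b", "metric", "n_a", "n_b",
                 "statistic", "p_value", "note"],
    )
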