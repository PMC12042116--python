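"""Specificity-occupancy (SPEC-OCCU) computation and habitat-specialist
classification.

For species S and habitat (latitudinal region) H:

* specificity(S, H) = mean abundance of S over samples of H, divided by the
  sum of those per-habitat means over all habitats — so specificity sums to
  1 across habitats for any species present anywhere;
* occupancy(S, H) = fraction of sites in H where S is present.

A species with specificity >= 0.7 AND occupancy >= 0.7 in a habitat
(inclusive thresholds) is a specialist of that habitat.  Abundances are
relative abundances per sample (post-rarefaction), and the per-habitat
mean includes zero samples.  With a threshold above 0.5 a species can be a
specialist of at most one habitat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import BiogeoError
from .tables import REGION_NA

SPECIALIST_THRESHOLD = 0.7


def spec_occ(rel_table: pd.DataFrame, regions: pd.Series) -> pd.DataFrame:
    """Specificity and occupancy for every (OTU, region) pair.

    ``rel_table`` holds per-sample relative abundances; ``regions`` maps each
    sample to its habitat label. OTUs absent everywhere get specificity NA
    and occupancy 0.
    """
    regions = pd.Series(regions)
    if not regions.index.equals(rel_table.index):
        regions = regions.reindex(rel_table.index)
    if regions.isna().any() or (regions == REGION_NA).any():
        raise BiogeoError("every sample must carry a valid region label")
    labels = sorted(regions.unique())
    means = np.vstack([
        rel_table.loc[regions == h].mean(axis=0).to_numpy(dtype=float)
        for h in labels
    ])  # habitats x OTUs
    occup = np.vstack([
        (rel_table.loc[regions == h] > 0).mean(axis=0).to_numpy(dtype=float)
        for h in labels
    ])
    totals = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = np.where(totals > 0, means / np.where(totals > 0, totals, 1.0), np.nan)
    rows = []
    for hi, h in enumerate(labels):
        for oi, otu in enumerate(rel_table.columns):
            rows.append((otu, h, specificity[hi, oi], occup[hi, oi]))
    return pd.DataFrame(rows, columns=["otu_id", "habitat", "specificity", "occupancy"])


def classify_specialists(
    records: pd.DataFrame,
    threshold: float = SPECIALIST_THRESHOLD,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Specialists: specificity >= threshold AND occupancy >= threshold
    (boundaries inclusive). Joined with taxonomy lineage when provided."""
    if not 0 <= threshold <= 1:
        raise BiogeoError("threshold must be in [0, 1]")
    flagged = records.copy()
    flagged["specialist"] = (
        records["specificity"].fillna(0).ge(threshold)
        & records["occupancy"].ge(threshold)
    )
    out = flagged[flagged["specialist"]].drop(columns="specialist").reset_index(drop=True)
    if taxonomy is not None:
        out = out.join(taxonomy, on="otu_id")
    return out


def specialist_phylum_tally(specialists: pd.DataFrame) -> pd.DataFrame:
    """Per-region, per-phylum counts of specialist OTUs."""
    if "phylum" not in specialists.columns:
        raise BiogeoError("specialists table lacks taxonomy; pass taxonomy to classify_specialists")
    return (
        specialists.groupby(["habitat", "phylum"])
        .size()
        .rename("n_specialists")
        .reset_index()
    )
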