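"""Count-table, metadata and taxonomy I/O plus rarefaction, aggregation and
latitudinal binning.

In-memory conventions
---------------------
* A *count table* is a ``pandas.DataFrame`` of nonnegative integers with
  samples as rows and OTUs as columns.  On disk the orientation is the
  classic one (OTUs as rows, samples as columns) and it is transposed on
  read/write.
* *Metadata* is a ``DataFrame`` indexed by sample id with geography
  (latitude °N, longitude signed °E, depth in metres below sea level) and
  environmental covariates (temperature °C, salinity PSU, pH, NO3, NH4,
  TOC) plus a derived ``region`` label.
* *Taxonomy* is a ``DataFrame`` indexed by OTU id with the ranked lineage
  columns ``domain, phylum, class, order, family, genus``; missing ranks
  are the explicit string ``"unclassified"``.

Files are UTF-8 TSV; leading ``#`` comment lines are permitted and used to
record the generating seed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import BiogeoError

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: region label for samples outside the configured latitude range
REGION_NA = "NA"


class TableParseError(BiogeoError):
    """Raised when an on-disk table violates the format contract."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise TableParseError(f"{path}: file is empty") from None
    if df.index.size == 0 and df.columns.size == 0:
        raise TableParseError(f"{path}: table has no rows or columns")
    return df


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read an OTU table (OTUs as rows on disk) into samples x OTUs integers.

    Raises :class:`TableParseError` for empty files, duplicate ids, or
    non-integer cells (named by row and column).
    """
    raw = _read_tsv(path)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise TableParseError(f"{path}: duplicate OTU id {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise TableParseError(f"{path}: duplicate sample id {dup!r}")
    counts = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != np.floor(converted.fillna(0)))
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise TableParseError(
                f"{path}: non-integer count at OTU {row!r}, sample {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        if (converted < 0).any():
            row = raw.index[(converted < 0).to_numpy().nonzero()[0][0]]
            raise TableParseError(f"{path}: negative count at OTU {row!r}, sample {col!r}")
        counts[col] = converted.astype(np.int64)
    table = counts.T  # samples x OTUs
    table.index.name = "sample_id"
    table.columns.name = "otu_id"
    return table


def write_count_table(table: pd.DataFrame, path: str | Path, *, comments: list[str] | None = None) -> None:
    """Write samples x OTUs counts as an OTUs-as-rows TSV (round-trip safe)."""
    path = Path(path)
    on_disk = table.T
    on_disk.index.name = "otu_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        on_disk.to_csv(fh, sep="\t", lineterminator="\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    raw = _read_tsv(path)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise TableParseError(f"{path}: duplicate sample id {dup!r}")
    meta = raw.copy()
    for col in meta.columns:
        if col == "region":
            continue
        meta[col] = pd.to_numeric(meta[col], errors="raise")
    meta.index.name = "sample_id"
    if "latitude" in meta and ((meta["latitude"] < -90) | (meta["latitude"] > 90)).any():
        raise TableParseError(f"{path}: latitude outside [-90, 90]")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path, *, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        meta.to_csv(fh, sep="\t", lineterminator="\n", float_format="%.10g")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    raw = _read_tsv(path)
    missing = [r for r in TAXONOMY_RANKS if r not in raw.columns]
    if missing:
        raise TableParseError(f"{path}: taxonomy missing rank columns {missing}")
    tax = raw[list(TAXONOMY_RANKS)].fillna("unclassified")
    tax.index.name = "otu_id"
    return tax


def write_taxonomy(tax: pd.DataFrame, path: str | Path, *, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        tax.to_csv(fh, sep="\t", lineterminator="\n")


def write_distance_matrix(d: pd.DataFrame, path: str | Path) -> None:
    d.to_csv(path, sep="\t", float_format="%.12g", lineterminator="\n")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    d.columns = d.columns.astype(str)
    d.index = d.index.astype(str)
    return d


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample each row of an integer matrix to ``depth`` reads without
    replacement (multivariate hypergeometric draw per row)."""
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        total = int(row.sum())
        if total == depth:
            out[i] = row  # exhaustive draw is the row itself
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return out


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Rarefy every sample to ``depth`` reads without replacement.

    All-zero OTU columns are retained so ids stay aligned across stages.
    Raises if any sample has fewer than ``depth`` reads, naming the
    offending samples.
    """
    if depth < 0:
        raise BiogeoError("rarefaction depth must be nonnegative")
    totals = table.sum(axis=1)
    short = totals[totals < depth]
    if len(short):
        raise BiogeoError(
            "rarefaction depth exceeds sample totals for: "
            + ", ".join(f"{s} ({int(t)})" for s, t in short.items())
        )
    rng = np.random.default_rng(seed)
    out = rarefy_counts(table.to_numpy(dtype=np.int64), int(depth), rng)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


# ---------------------------------------------------------------------------
# Proportions and taxonomic aggregation
# ---------------------------------------------------------------------------

def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions. All-zero samples stay all-zero (with a warning)."""
    totals = table.sum(axis=1).to_numpy(dtype=float)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero sample(s) left as all-zero proportions",
            stacklevel=2,
        )
        totals[zero] = 1.0
    return table.div(pd.Series(totals, index=table.index), axis=0)


def aggregate_by_rank(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str,
    *,
    split_proteobacteria: bool = False,
) -> pd.DataFrame:
    """Sum counts over OTUs sharing a taxonomic label.

    At ``rank="phylum"`` with ``split_proteobacteria=True`` the phylum
    Proteobacteria is replaced by its class labels (Alphaproteobacteria,
    Gammaproteobacteria, ...), the convention used when plotting community
    composition.
    """
    if rank not in TAXONOMY_RANKS:
        raise BiogeoError(f"unknown taxonomic rank {rank!r}; expected one of {TAXONOMY_RANKS}")
    missing = table.columns.difference(taxonomy.index)
    if len(missing):
        raise BiogeoError(f"OTUs missing from taxonomy: {list(missing[:5])}...")
    labels = taxonomy.loc[table.columns, rank].astype(str)
    if split_proteobacteria and rank == "phylum":
        is_proteo = labels == "Proteobacteria"
        labels = labels.where(~is_proteo, taxonomy.loc[table.columns, "class"].astype(str))
    agg = table.T.groupby(labels.to_numpy()).sum().T
    agg.columns.name = rank
    return agg


# ---------------------------------------------------------------------------
# Latitudinal regions
# ---------------------------------------------------------------------------

def region_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}"


def region_labels(width: float = 5.0, lat_range: tuple[float, float] = (60.0, 80.0)) -> list[str]:
    lo, hi = lat_range
    edges = np.arange(lo, hi + 1e-9, width)
    return [region_label(a, b) for a, b in zip(edges[:-1], edges[1:])]


def assign_regions(
    meta: pd.DataFrame,
    width: float = 5.0,
    lat_range: tuple[float, float] = (60.0, 80.0),
) -> pd.DataFrame:
    """Bin samples into latitudinal bands of ``width`` degrees.

    Bins are half-open ``[lo, lo+width)`` with the topmost edge inclusive, so
    every latitude inside the range gets exactly one region. Samples outside
    the range get region ``"NA"`` with a warning.
    """
    lo, hi = lat_range
    lat = meta["latitude"].to_numpy(dtype=float)
    labels = np.full(len(lat), REGION_NA, dtype=object)
    inside = (lat >= lo - 1e-9) & (lat <= hi + 1e-9)
    if (~inside).any():
        bad = list(meta.index[~inside])
        warnings.warn(f"samples outside latitude range assigned region NA: {bad}", stacklevel=2)
    idx = np.clip(np.floor((lat[inside] - lo) / width).astype(int), 0, int((hi - lo) / width) - 1)
    names = region_labels(width, lat_range)
    labels[inside] = [names[i] for i in idx]
    out = meta.copy()
    out["region"] = labels
    return out
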