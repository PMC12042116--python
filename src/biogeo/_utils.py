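"""Shared helpers: seeded substreams, distance-matrix validation, small numerics."""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd


class BiogeoError(ValueError):
    """Base class for user-facing errors raised by this package."""


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed from one root seed.

    The derived stream depends only on (root_seed, stage name), so a stage
    is reproducible regardless of which other stages ran before it.
    Result is kept below 2**31 so it is a valid seed everywhere.
    """
    h = zlib.crc32(stage.encode("utf-8"))
    return int((int(root_seed) * 0x9E3779B1 + h) % (2**31 - 1))


def rng_for(root_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(root_seed, stage))


def validate_distance_matrix(d: pd.DataFrame, *, max_value: float | None = None) -> None:
    """Check symmetry, zero diagonal, nonnegativity and id alignment."""
    if list(d.index) != list(d.columns):
        raise BiogeoError("distance matrix index and columns must carry the same ids")
    v = d.to_numpy(dtype=float)
    if v.shape[0] != v.shape[1]:
        raise BiogeoError("distance matrix must be square")
    if not np.allclose(v, v.T, atol=1e-12):
        raise BiogeoError("distance matrix must be symmetric")
    if not np.allclose(np.diag(v), 0.0, atol=1e-12):
        raise BiogeoError("distance matrix diagonal must be zero")
    if (v < -1e-12).any():
        raise BiogeoError("distance matrix entries must be nonnegative")
    if max_value is not None and (v > max_value + 1e-9).any():
        raise BiogeoError(f"distance matrix entries must not exceed {max_value}")


def align_distance_matrices(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reindex ``b`` onto ``a``'s ids; error if the id sets differ."""
    if set(a.index) != set(b.index):
        raise BiogeoError("distance matrices carry different sample ids")
    return a, b.loc[a.index, a.index]


def condensed(d: pd.DataFrame) -> np.ndarray:
    """Upper-triangle (i<j) entries of a square distance matrix, row-major."""
    v = d.to_numpy(dtype=float)
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]
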