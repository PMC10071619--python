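"""Subject-level Pearson functional connectivity and feature flattening.

A subject's functional connectome is the 379x379 matrix of Pearson
correlations between regional BOLD time series.  Including self-pairs the
matrix holds 379^2 = 143,641 correlations; the classifier consumes each
unordered off-diagonal pair once, i.e. 379*378/2 = 71,631 features (the
self-correlations are identically 1 and carry no information; a flag
restores the full redundant set for fidelity experiments).  No Fisher
z-transform is applied: raw correlation coefficients are the features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union
from pathlib import Path

import numpy as np

from .atlas import AtlasRegistry, N_REGIONS
from .errors import AlignmentError, UndefinedCorrelationError, ValidationError

N_CORRELATIONS_FULL = N_REGIONS * N_REGIONS  # 143,641 self-inclusive
N_PAIR_FEATURES = N_REGIONS * (N_REGIONS - 1) // 2  # 71,631 unique pairs

# row-major upper triangle, a < b (0-based region indices)
_TRIU = np.triu_indices(N_REGIONS, k=1)


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric 379x379 Pearson correlation matrix in registry order."""

    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (N_REGIONS, N_REGIONS):
            raise ValidationError(f"FC matrix must be {N_REGIONS}x{N_REGIONS}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValidationError("FC matrix diagonal must be exactly 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValidationError("correlations must lie in [-1, 1]")

    @property
    def n_correlations(self) -> int:
        """Self-inclusive correlation count (379^2 = 143,641)."""
        return self.values.size


@dataclass(frozen=True)
class FeatureVector:
    """Unique-pair flattening of an FC matrix (length 71,631).

    ``pair_index`` maps position -> (region_a, region_b) with a < b as
    0-based registry indices; the ordering is the row-major upper triangle
    and is identical for every subject.
    """

    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (N_PAIR_FEATURES,):
            raise ValidationError(
                f"feature vector must have length {N_PAIR_FEATURES}"
            )

    @staticmethod
    def pair_index() -> tuple[np.ndarray, np.ndarray]:
        """(ia, ib) arrays of 0-based endpoint indices, a < b."""
        return _TRIU

    @staticmethod
    def position_of(ia: int, ib: int) -> int:
        """Position of the (ia, ib) pair (0-based indices, ia < ib)."""
        if not 0 <= ia < ib < N_REGIONS:
            raise ValidationError("need 0 <= ia < ib < 379")
        # row-major upper triangle offset
        return ia * (2 * N_REGIONS - ia - 1) // 2 + (ib - ia - 1)


def fc_matrix(ts: np.ndarray, atlas: Optional[AtlasRegistry] = None) -> FCMatrix:
    """Pearson FC matrix from a T x 379 regional time-series array.

    Raises :class:`UndefinedCorrelationError` naming the offending
    region(s) when a column has zero variance (constant BOLD series).
    """
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2 or ts.shape[1] != N_REGIONS:
        raise ValidationError(f"time series must be T x {N_REGIONS}")
    if ts.shape[0] < 3:
        raise ValidationError("need at least 3 timepoints")
    constant = np.ptp(ts, axis=0) == 0
    if np.any(constant):
        bad = np.flatnonzero(constant)
        names = (
            [atlas.regions[i].name for i in bad]
            if atlas is not None
            else [f"region_{i + 1}" for i in bad]
        )
        raise UndefinedCorrelationError(names)
    r = np.corrcoef(ts, rowvar=False)
    # guard rounding excursions outside [-1, 1] and enforce an exact diagonal
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return FCMatrix(r)


def vectorize_features(fc: FCMatrix) -> FeatureVector:
    """Flatten the unique off-diagonal pairs (row-major upper triangle)."""
    return FeatureVector(fc.values[_TRIU].copy())


def unvectorize_features(fv: FeatureVector) -> FCMatrix:
    """Rebuild the symmetric FC matrix (diagonal set to 1)."""
    m = np.eye(N_REGIONS)
    m[_TRIU] = fv.values
    m[(_TRIU[1], _TRIU[0])] = fv.values
    return FCMatrix(m)


def full_matrix_features(fc: FCMatrix) -> np.ndarray:
    """The redundant self-inclusive flattening (143,641 values)."""
    return fc.values.ravel().copy()


def pair_names(atlas: AtlasRegistry) -> tuple[list[str], list[str]]:
    """Endpoint region names per feature position (parallel lists)."""
    names = atlas.names
    ia, ib = _TRIU
    return [names[i] for i in ia], [names[i] for i in ib]


# -- plain-text I/O ------------------------------------------------------


def write_fc_matrix(fc: FCMatrix, atlas: AtlasRegistry, path: Union[str, Path]) -> None:
    """TSV with a one-line region-order header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(atlas.names) + "\n")
        np.savetxt(fh, fc.values, fmt="%.10g", delimiter="\t")


def read_fc_matrix(path: Union[str, Path], atlas: AtlasRegistry) -> FCMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != atlas.names:
            raise AlignmentError("FC matrix region order does not match atlas")
        values = np.loadtxt(fh, delimiter="\t")
    return FCMatrix(values)
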