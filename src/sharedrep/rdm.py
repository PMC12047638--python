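"""Representational dissimilarity matrices and their comparison.

The dissimilarity metric is 1 - Pearson correlation between response (or
feature) patterns, the standard choice for fMRI RDMs; two RDMs are compared by
the Spearman rank correlation of their strictly-lower-triangle vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DataError

__all__ = ["RDM", "compute_rdm", "lower_triangle", "rsa_score"]

_SYMMETRY_TOL = 1e-8
_NORM_TOL = 1e-12


@dataclass
class RDM:
    """Symmetric items x items dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    item_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.item_ids = np.asarray(self.item_ids)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise DataError("RDM values must be a square matrix")
        if len(self.item_ids) != n:
            raise DataError("item_ids length does not match RDM size")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]


def compute_rdm(patterns: np.ndarray, item_ids: Sequence | None = None) -> RDM:
    """1 - Pearson correlation RDM of the rows of ``patterns``.

    ``patterns`` is items x dimensions (voxels or feature units); at least two
    columns are required and every row must have nonzero variance.  The result
    is exactly symmetrized, zero on the diagonal, with entries in [0, 2].
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise DataError("patterns must be 2D (items x dim)")
    if patterns.shape[1] < 2:
        raise DataError("patterns must have at least 2 columns")
    if not np.all(np.isfinite(patterns)):
        raise DataError("patterns contain non-finite values")
    if item_ids is None:
        item_ids = np.arange(patterns.shape[0])
    item_ids = np.asarray(item_ids)

    centered = patterns - patterns.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = np.nonzero(norms <= _NORM_TOL * max(1.0, float(np.abs(patterns).max())))[0]
    if bad.size:
        raise DataError(f"pattern row for item {item_ids[bad[0]]!r} has zero variance")
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    d = 1.0 - corr
    d = 0.5 * (d + d.T)  # kill numeric asymmetry
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 2.0, out=d)
    return RDM(d, item_ids)


def lower_triangle(rdm: RDM | np.ndarray) -> np.ndarray:
    """Strictly-below-diagonal entries in row-major order; length n(n-1)/2.

    Rejects matrices that are asymmetric beyond numeric tolerance.
    """
    values = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise DataError("input must be a square matrix")
    if not np.allclose(values, values.T, atol=_SYMMETRY_TOL):
        raise DataError("matrix is asymmetric beyond tolerance; not a valid RDM")
    n = values.shape[0]
    return values[np.tril_indices(n, k=-1)]


def _fast_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho via average ranks + Pearson; nan on a constant input."""
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def rsa_score(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman rank correlation of two RDMs' lower triangles.

    The two RDMs must share the same items in the same order.  If either
    lower triangle is constant the correlation is undefined: a warning is
    emitted and NaN returned.
    """
    if rdm_a.n_items != rdm_b.n_items or not np.array_equal(
        rdm_a.item_ids, rdm_b.item_ids
    ):
        raise DataError("RDMs must share the same item set and order")
    va = lower_triangle(rdm_a)
    vb = lower_triangle(rdm_b)
    rho = _fast_spearman(va, vb)
    if np.isnan(rho):
        warnings.warn(
            "rsa_score: a lower triangle is constant; Spearman correlation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return rho
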