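"""Whole-brain searchlight engine.

A sphere of fixed physical radius is centered on every in-mask voxel; a
user-supplied statistic is evaluated on the sphere's in-mask voxels and the
scalar is written to the center.  Spheres are truncated at the mask boundary
(they always contain at least the center) and centers are processed
independently, so the output is identical under any iteration order or
parallel chunking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .exceptions import ConfigurationError, DataError

__all__ = ["SphereSpec", "StatMap", "sphere_offsets", "run_searchlight"]


def sphere_offsets(
    radius_mm: float, voxel_size_mm: Sequence[float] = (3.0, 3.0, 3.0)
) -> np.ndarray:
    """All integer voxel offsets whose physical distance from the origin is
    <= ``radius_mm``, in lexicographic order.

    The origin is always included, so a radius smaller than the smallest voxel
    dimension still yields the single offset (0, 0, 0).
    """
    vs = np.asarray(voxel_size_mm, dtype=float)
    if radius_mm <= 0:
        raise ConfigurationError("radius_mm must be positive")
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ConfigurationError("voxel_size_mm must be three positive values")
    half = np.floor(radius_mm / vs).astype(int)
    grids = np.mgrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    offsets = grids.reshape(3, -1).T
    dist2 = ((offsets * vs) ** 2).sum(axis=1)
    offsets = offsets[dist2 <= radius_mm**2 + 1e-9]
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0]))
    return offsets[order]


@dataclass
class SphereSpec:
    """Searchlight sphere geometry.

    ``radius_mm`` defaults to 6 mm; with the emulated study's grid this is
    the stated "sphere of 3 voxels" when voxels are 2 mm isotropic.  Offsets
    are derived from the radius and the voxel size.
    """

    radius_mm: float = 6.0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.offsets = sphere_offsets(self.radius_mm, self.voxel_size_mm)

    @classmethod
    def from_voxels(
        cls, radius_voxels: float, voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    ) -> "SphereSpec":
        """Specify the radius in voxel units instead of millimeters."""
        return cls(radius_mm=radius_voxels * min(voxel_size_mm), voxel_size_mm=voxel_size_mm)

    @property
    def n_offsets(self) -> int:
        return len(self.offsets)


@dataclass
class StatMap:
    """A searchlight statistic on the shared grid.

    ``values`` holds the statistic at every in-mask center; centers whose
    callback failed (or returned NaN) are marked invalid in ``valid`` and hold
    ``fill_value`` in ``values``.
    """

    values: np.ndarray
    mask: np.ndarray
    valid: np.ndarray
    statistic_name: str = "statistic"

    def in_mask_values(self) -> np.ndarray:
        return self.values[self.mask]


def _neighbor_columns(
    center: np.ndarray, offsets: np.ndarray, col_index: np.ndarray
) -> np.ndarray:
    coords = center + offsets
    shape = col_index.shape
    ok = np.all((coords >= 0) & (coords < shape), axis=1)
    coords = coords[ok]
    cols = col_index[coords[:, 0], coords[:, 1], coords[:, 2]]
    return cols[cols >= 0]


def run_searchlight(
    data: np.ndarray | Sequence[np.ndarray],
    mask: np.ndarray,
    statistic: Callable[..., float],
    sphere: SphereSpec,
    n_jobs: int = 1,
    fill_value: float = 0.0,
    min_voxels: int = 1,
    statistic_name: str = "statistic",
) -> StatMap:
    """Evaluate ``statistic`` on every searchlight sphere inside ``mask``.

    Parameters
    ----------
    data:
        One ``(rows, n_mask_voxels)`` matrix, or a sequence of such matrices
        sharing the voxel axis (e.g. predicted and observed item responses).
        Columns follow the C-order of the mask, as in :class:`VolumeSet`.
    statistic:
        Called with the sphere slice of each data matrix (one positional
        argument per matrix) and must return a scalar.  An exception or a
        non-finite return marks the center invalid rather than aborting.
    n_jobs:
        Centers are chunked across threads; the output is bit-identical to
        the serial run for deterministic callbacks.
    min_voxels:
        Boundary-truncated spheres with fewer in-mask voxels than this are
        recorded as invalid instead of being evaluated (default 1: every
        sphere counts, since the center is always present).
    """
    if min_voxels < 1:
        raise ConfigurationError("min_voxels must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise DataError("mask must be a 3D boolean volume")
    matrices = [np.asarray(d, dtype=float) for d in (data if isinstance(data, (list, tuple)) else [data])]
    n_mask = int(mask.sum())
    for m in matrices:
        if m.ndim != 2 or m.shape[1] != n_mask:
            raise DataError(
                f"data matrix with {m.shape} does not have {n_mask} voxel columns"
            )

    col_index = np.full(mask.shape, -1, dtype=int)
    col_index[mask] = np.arange(n_mask)
    centers = np.argwhere(mask)

    results = np.full(n_mask, np.nan)

    def _process(lo: int, hi: int) -> np.ndarray:
        out = np.full(hi - lo, np.nan)
        for k in range(lo, hi):
            cols = _neighbor_columns(centers[k], sphere.offsets, col_index)
            if cols.size < min_voxels:
                continue
            try:
                out[k - lo] = statistic(*(m[:, cols] for m in matrices))
            except Exception:  # noqa: BLE001 -- a failing sphere must not kill the map
                out[k - lo] = np.nan
        return out

    if n_jobs == 1:
        results = _process(0, n_mask)
    else:
        bounds = np.linspace(0, n_mask, abs(n_jobs) * 4 + 1).astype(int)
        chunks = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(_process)(lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:])
        )
        results = np.concatenate(chunks)

    bad = ~np.isfinite(results)
    if bad.any():
        warnings.warn(
            f"searchlight: statistic undefined at {int(bad.sum())} of {n_mask} centers",
            RuntimeWarning,
            stacklevel=2,
        )
    values = np.full(mask.shape, float(fill_value))
    valid = np.zeros(mask.shape, dtype=bool)
    filled = np.where(bad, fill_value, results)
    values[mask] = filled
    valid[mask] = ~bad
    return StatMap(values=values, mask=mask, valid=valid, statistic_name=statistic_name)
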