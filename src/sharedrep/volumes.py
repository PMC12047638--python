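"""In-memory container for per-subject stacks of 3D response volumes.

All subjects are assumed to live on one shared voxel grid (a standardized
space); registration is outside the scope of this package.  A ``VolumeSet``
stores the stack as a dense ``(n_volumes, n_voxels)`` matrix over the in-mask
voxels, in C-order of the mask, which is what every downstream stage
(encoding fits, searchlights, decoders) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError

__all__ = ["VolumeSet"]


def _default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class VolumeSet:
    """A stack of 3D volumes restricted to a binary brain mask.

    Parameters
    ----------
    data:
        ``(n_volumes, n_voxels)`` float array.  Column ``j`` is the j-th
        in-mask voxel in C (row-major) order of the mask array, i.e. the
        order produced by ``volume_4d[mask]``.
    mask:
        3D boolean array; ``data.shape[1]`` must equal ``mask.sum()``.
    affine:
        4x4 voxel-to-world affine (NIfTI convention).
    subject_id:
        Optional label carried through the pipeline.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: _default_affine((3.0, 3.0, 3.0)))
    subject_id: int | str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 2:
            raise DataError("VolumeSet.data must be 2D (n_volumes, n_voxels)")
        if self.mask.ndim != 3:
            raise DataError("VolumeSet.mask must be a 3D boolean volume")
        n_mask = int(self.mask.sum())
        if self.data.shape[1] != n_mask:
            raise DataError(
                f"data has {self.data.shape[1]} voxel columns but the mask "
                f"contains {n_mask} voxels"
            )
        if self.affine.shape != (4, 4):
            raise DataError("affine must be a 4x4 matrix")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def to_4d(self, fill_value: float = 0.0) -> np.ndarray:
        """Expand to a dense ``(x, y, z, n_volumes)`` array (NIfTI layout)."""
        out = np.full(self.grid_shape + (self.n_volumes,), fill_value, dtype=float)
        out[self.mask] = self.data.T
        return out

    @classmethod
    def from_4d(
        cls,
        volume_4d: np.ndarray,
        mask: np.ndarray,
        affine: np.ndarray | None = None,
        subject_id: int | str | None = None,
    ) -> "VolumeSet":
        """Build from an ``(x, y, z, t)`` array by extracting in-mask voxels."""
        volume_4d = np.asarray(volume_4d, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if volume_4d.ndim == 3:
            volume_4d = volume_4d[..., np.newaxis]
        if volume_4d.shape[:3] != mask.shape:
            raise DataError(
                f"volume grid {volume_4d.shape[:3]} does not match mask grid {mask.shape}"
            )
        data = volume_4d[mask].T  # (t, n_voxels)
        if affine is None:
            affine = _default_affine((3.0, 3.0, 3.0))
        return cls(data=data, mask=mask, affine=affine, subject_id=subject_id)

    def select_volumes(self, indices: np.ndarray) -> "VolumeSet":
        """A new VolumeSet keeping only the given volume rows (e.g. one condition)."""
        return VolumeSet(
            data=self.data[np.asarray(indices)],
            mask=self.mask,
            affine=self.affine,
            subject_id=self.subject_id,
        )
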