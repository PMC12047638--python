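"""Group-level permutation inference with threshold-free cluster enhancement.

Replicates the Randomise-style one-sample test from scratch: the per-pair maps
are centered on the null value (0 for RSA correlations, 0.5 for AUC), the mean
map is enhanced by TFCE, and familywise-corrected p-values come from the
permutation distribution of the image-wide maximum TFCE under random sign
flips of the individual maps.  When the number of maps is small enough, sign
flips are enumerated exhaustively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .crossval import StatMapStack
from .exceptions import ConfigurationError, DataError

__all__ = ["TfceParams", "GroupResult", "tfce_transform", "permutation_test"]


@dataclass
class TfceParams:
    """TFCE parameters: the field-standard defaults H=2, E=0.5, 26-connectivity,
    and a 100-step staircase approximation of the threshold integral."""

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    dh: float | None = None  # None: max(map)/n_steps
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.dh is not None and self.dh <= 0:
            raise ConfigurationError("dh must be positive")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ConfigurationError("connectivity must be 6, 18 or 26")
        if not (np.isfinite(self.height_exponent) and np.isfinite(self.extent_exponent)):
            raise ConfigurationError("exponents must be finite")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


def tfce_transform(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    params: TfceParams | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D map.

    For each voxel p, TFCE(p) = sum over thresholds h in (0, v_p] of
    e(h)^E * h^H * dh, where e(h) is the size of the suprathreshold connected
    component containing p at height h.  Negative values contribute nothing.
    Thresholds are taken at step midpoints, so an isolated voxel of value v
    (extent 1, E=0.5, H=2) integrates to ~v^3/3.
    """
    if params is None:
        params = TfceParams()
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise DataError("tfce_transform expects a 3D volume")
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    pos = np.where(mask, np.clip(values, 0.0, None), 0.0)
    vmax = float(pos.max())
    out = np.zeros_like(pos)
    if vmax <= 0:
        return out
    dh = params.dh if params.dh is not None else vmax / params.n_steps
    structure = params.structure
    h = dh / 2.0
    while h < vmax:
        sup = pos >= h
        labels, n_comp = ndimage.label(sup, structure=structure)
        if n_comp == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes_pow = sizes.astype(float) ** params.extent_exponent
        out[sup] += sizes_pow[labels[sup]] * (h**params.height_exponent) * dh
        h += dh
    return out


@dataclass
class GroupResult:
    """Outcome of the one-sample TFCE permutation test."""

    mean_map: np.ndarray
    tfce_map: np.ndarray
    p_map: np.ndarray
    mask: np.ndarray
    n_permutations: int
    null_value: float
    seed: int
    exhaustive: bool

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean volume of voxels significant at the given FWER level."""
        return self.mask & (self.p_map < alpha)


def _sign_matrix(
    n_maps: int, n_permutations: int, seed: int, exhaustive: bool | None
) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix (n_flips, n_maps); exhaustive when 2^n fits the budget."""
    if exhaustive is None:
        exhaustive = n_maps <= 30 and 2**n_maps <= n_permutations
    if exhaustive:
        if n_maps > 30:
            raise ConfigurationError("exhaustive enumeration infeasible for > 30 maps")
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_maps)))
        return signs, True
    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_permutations, n_maps))
    return signs, False


def permutation_test(
    maps: Union[StatMapStack, np.ndarray],
    null_value: float = 0.0,
    params: TfceParams | None = None,
    n_permutations: int = 5000,
    seed: int = 0,
    mask: np.ndarray | None = None,
    exhaustive: bool | None = None,
) -> GroupResult:
    """One-sided one-sample max-TFCE sign-flip permutation test.

    Tests whether (map - null_value) > 0 at each voxel.  The observed
    statistic is the TFCE of the mean centered map; each permutation randomly
    flips the sign of every individual centered map, and the image-wide
    maximum TFCE over permutations forms the null distribution, yielding
    familywise-error-corrected p-values.  Sign flips are enumerated
    exhaustively when 2^n_maps <= n_permutations; the smallest attainable
    Monte-Carlo p is 1/(n_permutations + 1).
    """
    if params is None:
        params = TfceParams()
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    if isinstance(maps, StatMapStack):
        stack = maps.values_array()
        mask = maps.mask if mask is None else np.asarray(mask, dtype=bool)
    else:
        stack = np.asarray(maps, dtype=float)
        if mask is None:
            raise ConfigurationError("a mask is required when passing a raw array stack")
        mask = np.asarray(mask, dtype=bool)
    if stack.ndim != 4:
        raise DataError("maps must stack to a 4D array (n_maps, x, y, z)")
    if stack.shape[0] < 2:
        raise DataError("at least 2 maps are required for a permutation test")
    if not np.all(np.isfinite(stack[:, mask])):
        raise DataError("non-finite values inside the mask")

    centered = stack - null_value
    mean_map = centered.mean(axis=0)
    obs_tfce = tfce_transform(mean_map, mask, params)

    signs, exhaustive = _sign_matrix(stack.shape[0], n_permutations, seed, exhaustive)
    null_max = np.empty(len(signs))
    for i, s in enumerate(signs):
        perm_mean = np.tensordot(s, centered, axes=1) / stack.shape[0]
        null_max[i] = tfce_transform(perm_mean, mask, params)[mask].max()

    sorted_null = np.sort(null_max)
    exceed = len(sorted_null) - np.searchsorted(sorted_null, obs_tfce[mask], side="left")
    if exhaustive:
        p_in = exceed / len(signs)  # identity flip included: p >= 1/2^n
    else:
        p_in = (1.0 + exceed) / (len(signs) + 1.0)
    p_map = np.ones(mask.shape)
    p_map[mask] = p_in
    return GroupResult(
        mean_map=mean_map + null_value,
        tfce_map=obs_tfce,
        p_map=p_map,
        mask=mask,
        n_permutations=len(signs),
        null_value=float(null_value),
        seed=seed,
        exhaustive=exhaustive,
    )
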