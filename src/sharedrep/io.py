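"""Readers and writers for the on-disk formats.

Volumes and masks are NIfTI-1 (one 4D file per subject per condition); trial
tables are tab-separated with a header row (BIDS-events-like columns); feature
matrices are tab-separated numeric tables indexed by item_id; every pipeline
run writes a JSON manifest (config echo, seed, package version, input digests)
sufficient to re-execute it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .design import AWARENESS_LEVELS, CATEGORIES
from .exceptions import DataError
from .features import FeatureMatrix
from .searchlight import StatMap
from .volumes import VolumeSet

__all__ = [
    "read_volumes",
    "write_volumes",
    "read_mask",
    "write_mask",
    "read_events",
    "write_events",
    "read_features",
    "write_features",
    "write_statmap",
    "read_statmap",
    "write_manifest",
]

_AFFINE_TOL = 1e-4

EVENT_COLUMNS = [
    "subject_id",
    "session",
    "block",
    "trial_index",
    "item_id",
    "category",
    "awareness",
    "response",
    "correct",
]


def _check_affines(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if not np.allclose(a, b, atol=_AFFINE_TOL):
        raise DataError(
            f"{what}: affine mismatch beyond {_AFFINE_TOL}:\n{a}\nvs\n{b}"
        )


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), path)
    return path


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, img.affine


def write_volumes(volumes: VolumeSet, path: str | Path) -> Path:
    """Write a VolumeSet as a 4D NIfTI (out-of-mask voxels zero-filled)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(volumes.to_4d(), volumes.affine), path)
    return path


def read_volumes(
    path: str | Path, mask_path: str | Path, subject_id: int | str | None = None
) -> VolumeSet:
    """Load a 4D NIfTI restricted to the voxels of a mask NIfTI.

    The volume and mask must share grid and affine (tolerance 1e-4 on the
    affine); a mismatch is rejected with a diagnostic naming both affines.
    """
    img = nib.load(str(path))
    mask, mask_affine = read_mask(mask_path)
    if img.shape[:3] != mask.shape:
        raise DataError(
            f"{path}: volume grid {img.shape[:3]} does not match mask grid {mask.shape}"
        )
    _check_affines(img.affine, mask_affine, str(path))
    data_4d = np.asarray(img.dataobj, dtype=float)
    return VolumeSet.from_4d(data_4d, mask, affine=img.affine, subject_id=subject_id)


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated trial table."""
    path = Path(path)
    try:
        events = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataError(f"{path}: cannot parse events table: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    for col in ("subject_id", "session", "block", "trial_index", "item_id"):
        try:
            events[col] = pd.to_numeric(events[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(events[col], errors="coerce")
            row = int(bad.index[bad.isna()][0]) + 2  # +1 header, +1 one-based
            raise DataError(f"{path}: unparseable value in column {col!r} at line {row}") from exc
    bad_aw = set(events["awareness"].unique()) - set(AWARENESS_LEVELS)
    if bad_aw:
        raise DataError(f"{path}: unknown awareness label(s) {sorted(bad_aw)}")
    bad_cat = set(events["category"].unique()) - set(CATEGORIES)
    if bad_cat:
        raise DataError(f"{path}: unknown category label(s) {sorted(bad_cat)}")
    events["correct"] = events["correct"].astype(bool)
    return events


def write_features(features: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(features.values, index=pd.Index(features.item_ids, name="item_id"))
    df.to_csv(path, sep="\t")
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="item_id")
    return FeatureMatrix(df.to_numpy(dtype=float), df.index.to_numpy())


def write_statmap(statmap: StatMap, affine: np.ndarray, path: str | Path) -> Path:
    """Write a StatMap plus a companion validity mask (<stem>_valid.nii.gz)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(statmap.values, affine), path)
    stem = path.name[: -len("".join(path.suffixes))] if path.suffixes else path.stem
    valid_path = path.with_name(f"{stem}_valid.nii.gz")
    nib.save(nib.Nifti1Image(statmap.valid.astype(np.uint8), affine), valid_path)
    return path


def read_statmap(path: str | Path, mask_path: str | Path) -> StatMap:
    img = nib.load(str(path))
    mask, mask_affine = read_mask(mask_path)
    _check_affines(img.affine, mask_affine, str(path))
    values = np.asarray(img.dataobj, dtype=float)
    path = Path(path)
    stem = path.name[: -len("".join(path.suffixes))] if path.suffixes else path.stem
    valid_path = path.with_name(f"{stem}_valid.nii.gz")
    if valid_path.exists():
        valid = np.asarray(nib.load(str(valid_path)).dataobj) > 0
    else:
        valid = mask.copy()
    return StatMap(values=values, mask=mask, valid=valid)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_manifest(
    path: str | Path,
    config: Mapping,
    seed: int | None,
    inputs: Mapping[str, str | Path] | None = None,
    outputs: Mapping[str, str | Path] | None = None,
) -> Path:
    """Write a JSON run manifest: config echo, seed, version, input digests."""
    from . import __version__

    path = Path(path)
    manifest = {
        "package": "sharedrep",
        "version": __version__,
        "seed": seed,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()},
        "inputs": {
            k: {"path": str(p), "sha256_16": _digest(Path(p))}
            for k, p in (inputs or {}).items()
        },
        "outputs": {k: str(p) for k, p in (outputs or {}).items()},
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
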