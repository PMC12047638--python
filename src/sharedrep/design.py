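"""Synthetic experimental designs, behavior, item features, and BOLD volumes.

This module generates data with *known* representational ground truth so that
every downstream stage — encoding fits, searchlight RSA, cross-subject
decoding, TFCE group inference — has a recovery test.  The default design
matches the emulated study: 7 subjects, 96 items (48 animate / 48 inanimate),
6 sessions x 9 blocks x 32 trials = 1728 trials per subject, a per-trial
3-level awareness rating, and 300-dimensional item features with an
animate/inanimate block structure.

Volumes are trial-level response maps on a small shared grid: inside a
designated signal region each voxel responds linearly to the trial's item
features (through per-subject weight maps that mix a common map with
subject-specific ones), outside it carries pure Gaussian noise.  No
hemodynamics, staircases, or reaction times are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError
from .features import FeatureMatrix
from .volumes import VolumeSet, _default_affine

__all__ = [
    "AWARENESS_LEVELS",
    "CATEGORIES",
    "DesignSpec",
    "GroundTruth",
    "generate_design",
    "generate_item_features",
    "make_ground_truth",
    "generate_bold",
    "default_brain_mask",
    "default_signal_mask",
    "d_prime",
    "subject_d_primes",
    "SyntheticDataset",
    "simulate_dataset",
]

AWARENESS_LEVELS = ("unaware", "glimpse", "aware")
CATEGORIES = ("animate", "inanimate")

#: Probability that the category response is correct, per awareness level.
#: Unaware trials are at chance (null perceptual sensitivity); clear-experience
#: trials are nearly always correct.
DEFAULT_ACCURACY = {"unaware": 0.5, "glimpse": 0.7, "aware": 0.95}


@dataclass
class DesignSpec:
    """Parameters of a synthetic experiment.

    Defaults reproduce the emulated study's design: 7 subjects, 96 items
    split evenly between animate and inanimate, 6 sessions of 9 blocks of 32
    trials (1728 trials per subject).  ``awareness_probs`` is the i.i.d.
    per-trial distribution over (unaware, glimpse, aware); the adaptive
    staircase that produced these proportions in the real experiment is not
    simulated — only the labels matter downstream.
    """

    n_subjects: int = 7
    n_sessions: int = 6
    blocks_per_session: int = 9
    trials_per_block: int = 32
    n_items: int = 96
    n_animate: int = 48
    awareness_probs: tuple[float, float, float] = (0.55, 0.15, 0.30)
    accuracy_by_awareness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACCURACY)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "blocks_per_session", "n_items"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.trials_per_block < 0:
            raise ConfigurationError("trials_per_block must be >= 0")
        if not 0 <= self.n_animate <= self.n_items:
            raise ConfigurationError("n_animate must satisfy 0 <= n_animate <= n_items")
        probs = np.asarray(self.awareness_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError(
                "awareness_probs must be three nonnegative values summing to 1"
            )
        for level in AWARENESS_LEVELS:
            acc = self.accuracy_by_awareness.get(level)
            if acc is None or not 0.0 <= acc <= 1.0:
                raise ConfigurationError(
                    f"accuracy_by_awareness must map {level!r} to a probability"
                )

    @property
    def trials_per_session(self) -> int:
        return self.blocks_per_session * self.trials_per_block

    @property
    def trials_per_subject(self) -> int:
        return self.n_sessions * self.trials_per_session

    def item_category(self, item_id: int) -> str:
        """Category is a deterministic function of the item id."""
        return CATEGORIES[0] if item_id < self.n_animate else CATEGORIES[1]


def _subject_rng(seed: int, subject_id: int, stream: int = 0) -> np.random.Generator:
    """Independent generator per (seed, subject, stream): reproducible and
    invariant to the order subjects are processed in."""
    return np.random.default_rng(np.random.SeedSequence((seed, subject_id, stream)))


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate the trial table for all subjects.

    Each subject receives exactly ``spec.trials_per_subject`` trials laid out
    over sessions and blocks.  Items are balanced: each item appears
    ``trials // n_items`` times, with any remainder assigned to items drawn
    without replacement.  Awareness ratings are i.i.d. from
    ``awareness_probs``; the category response is correct with the
    awareness-dependent accuracy.

    Returns a tidy table with columns (subject_id, session, block,
    trial_index, item_id, category, awareness, response, correct).
    """
    n_trials = spec.trials_per_subject
    frames = []
    for subject in range(1, spec.n_subjects + 1):
        rng = _subject_rng(spec.seed, subject)
        reps = n_trials // spec.n_items
        items = np.repeat(np.arange(spec.n_items), reps)
        remainder = n_trials - items.size
        if remainder:
            extra = rng.choice(spec.n_items, size=remainder, replace=False)
            items = np.concatenate([items, extra])
        items = rng.permutation(items)

        sessions = np.repeat(np.arange(1, spec.n_sessions + 1), spec.trials_per_session)
        blocks = np.tile(
            np.repeat(np.arange(1, spec.blocks_per_session + 1), spec.trials_per_block),
            spec.n_sessions,
        )
        trial_index = np.tile(np.arange(spec.trials_per_block), n_trials // max(spec.trials_per_block, 1)) if spec.trials_per_block else np.empty(0, dtype=int)

        awareness = rng.choice(AWARENESS_LEVELS, size=n_trials, p=spec.awareness_probs)
        categories = np.where(items < spec.n_animate, CATEGORIES[0], CATEGORIES[1])
        acc = np.array([spec.accuracy_by_awareness[a] for a in awareness])
        correct = rng.random(n_trials) < acc
        other = np.where(categories == CATEGORIES[0], CATEGORIES[1], CATEGORIES[0])
        response = np.where(correct, categories, other)

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject,
                    "session": sessions[:n_trials],
                    "block": blocks[:n_trials],
                    "trial_index": trial_index[:n_trials],
                    "item_id": items,
                    "category": categories,
                    "awareness": awareness,
                    "response": response,
                    "correct": correct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_item_features(
    n_items: int = 96,
    dim: int = 300,
    within_animate_corr: float = 0.5,
    within_inanimate_corr: float = 0.3,
    n_animate: int | None = None,
    seed: int = 0,
) -> FeatureMatrix:
    """Sample item features with an animate/inanimate block-covariance structure.

    Across feature dimensions, two items' values correlate
    ``within_animate_corr`` if both are animate, ``within_inanimate_corr`` if
    both inanimate, and 0 across categories.  With positive within-category
    correlations the resulting 1 - Pearson RDM shows the two-block structure
    characteristic of CNN hidden representations of such images, with the
    tighter block being the more strongly correlated category.
    """
    if dim < 2:
        raise ConfigurationError("dim must be >= 2")
    for name, rho in (
        ("within_animate_corr", within_animate_corr),
        ("within_inanimate_corr", within_inanimate_corr),
    ):
        if not -1.0 < rho < 1.0:
            raise ConfigurationError(f"{name} must lie in (-1, 1)")
    if n_animate is None:
        n_animate = n_items // 2

    cov = np.zeros((n_items, n_items))
    a = slice(0, n_animate)
    b = slice(n_animate, n_items)
    cov[a, a] = within_animate_corr
    cov[b, b] = within_inanimate_corr
    np.fill_diagonal(cov, 1.0)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            "implied item covariance is not positive definite "
            f"(within_animate_corr={within_animate_corr}, "
            f"within_inanimate_corr={within_inanimate_corr}, n_items={n_items})"
        ) from exc
    rng = np.random.default_rng(seed)
    values = chol @ rng.standard_normal((n_items, dim))
    return FeatureMatrix(values, np.arange(n_items))


def default_brain_mask(grid_shape: tuple[int, int, int] = (24, 24, 24)) -> np.ndarray:
    """Ellipsoidal brain mask inscribed in the grid (semi-axes 0.45 * extent)."""
    nx, ny, nz = grid_shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    return (
        ((x - cx) / (0.45 * nx)) ** 2
        + ((y - cy) / (0.45 * ny)) ** 2
        + ((z - cz) / (0.45 * nz)) ** 2
    ) <= 1.0


def default_signal_mask(
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """A cuboid signal region in one hemisphere of the synthetic brain."""
    if brain_mask is None:
        brain_mask = default_brain_mask(grid_shape)
    nx, ny, nz = grid_shape
    sig = np.zeros(grid_shape, dtype=bool)
    sig[
        nx // 6 : nx // 6 + max(nx // 6, 2),
        ny // 3 : ny // 3 + max(ny // 4, 2),
        nz // 3 : nz // 3 + max(nz // 4, 2),
    ] = True
    return sig & brain_mask


@dataclass
class GroundTruth:
    """Planted linear encoding shared (to a configurable degree) across subjects.

    ``weight_tensor[s]`` is the (n_signal_voxels, dim) linear map for subject
    ``s`` (0-based order of sorted subject ids).  Each map is the convex mix
    ``shared_fraction * common + (1 - shared_fraction) * idiosyncratic``;
    ``shared_fraction = 1`` means every subject encodes the features
    identically, the premise behind cross-participant generalization.
    """

    signal_mask: np.ndarray
    weight_tensor: np.ndarray
    noise_sd: float
    shared_fraction: float

    def __post_init__(self) -> None:
        self.signal_mask = np.asarray(self.signal_mask, dtype=bool)
        self.weight_tensor = np.asarray(self.weight_tensor, dtype=float)
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        if self.weight_tensor.ndim != 3:
            raise ConfigurationError(
                "weight_tensor must be (n_subjects, n_signal_voxels, dim)"
            )
        if self.weight_tensor.shape[1] != int(self.signal_mask.sum()):
            raise ConfigurationError(
                "weight_tensor voxel axis does not match signal_mask size"
            )


def make_ground_truth(
    brain_mask: np.ndarray,
    signal_mask: np.ndarray,
    n_subjects: int,
    dim: int,
    shared_fraction: float = 1.0,
    noise_sd: float = 1.0,
    weight_scale: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw per-subject voxel weight maps over the signal region.

    Weight entries are scaled by ``weight_scale / sqrt(dim)`` so a unit-variance
    feature vector produces a signal of standard deviation ~``weight_scale``
    per voxel, making ``noise_sd`` directly interpretable as 1/SNR.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    if signal_mask.shape != brain_mask.shape:
        raise ConfigurationError("signal_mask and brain_mask grids differ")
    if np.any(signal_mask & ~brain_mask):
        raise ConfigurationError("signal_mask must lie inside the brain mask")
    n_vox = int(signal_mask.sum())
    scale = weight_scale / np.sqrt(dim)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2**20)))
    common = rng.standard_normal((n_vox, dim)) * scale
    weights = np.empty((n_subjects, n_vox, dim))
    for s in range(n_subjects):
        idio = _subject_rng(seed, s + 1, stream=1).standard_normal((n_vox, dim)) * scale
        weights[s] = shared_fraction * common + (1.0 - shared_fraction) * idio
    return GroundTruth(
        signal_mask=signal_mask,
        weight_tensor=weights,
        noise_sd=noise_sd,
        shared_fraction=shared_fraction,
    )


def generate_bold(
    design: pd.DataFrame,
    features: FeatureMatrix,
    truth: GroundTruth,
    brain_mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    seed: int = 0,
) -> dict[int, VolumeSet]:
    """Simulate trial-level response volumes for every subject in ``design``.

    Inside ``truth.signal_mask`` each voxel's response on a trial is the
    subject's linear map applied to that trial's item features plus Gaussian
    noise of sd ``truth.noise_sd``; all other in-mask voxels are pure noise.
    Volume row order matches the subject's row order in ``design``.
    Deterministic given ``seed`` and independent of subject processing order.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if truth.signal_mask.shape != brain_mask.shape:
        raise ConfigurationError("ground-truth grid does not match brain mask grid")
    if np.any(truth.signal_mask & ~brain_mask):
        raise ConfigurationError("signal_mask must lie inside the brain mask")
    missing = np.setdiff1d(design["item_id"].unique(), features.item_ids)
    if missing.size:
        raise DataError(f"design contains item(s) with no feature row: {missing.tolist()}")

    subjects = sorted(design["subject_id"].unique())
    if len(subjects) > truth.weight_tensor.shape[0]:
        raise ConfigurationError(
            f"ground truth holds {truth.weight_tensor.shape[0]} subject weight maps "
            f"but the design has {len(subjects)} subjects"
        )
    # column indices of signal voxels within the in-mask C-order layout
    flat_idx = np.full(brain_mask.shape, -1, dtype=int)
    flat_idx[brain_mask] = np.arange(int(brain_mask.sum()))
    signal_cols = flat_idx[truth.signal_mask]

    affine = _default_affine(voxel_size_mm)
    out: dict[int, VolumeSet] = {}
    for s_idx, subject in enumerate(subjects):
        rows = design[design["subject_id"] == subject]
        X = features.rows_for(rows["item_id"].to_numpy())
        rng = _subject_rng(seed, int(subject), stream=2)
        data = rng.standard_normal((len(rows), int(brain_mask.sum()))) * truth.noise_sd
        data[:, signal_cols] += X @ truth.weight_tensor[s_idx].T
        out[int(subject)] = VolumeSet(
            data=data, mask=brain_mask, affine=affine, subject_id=int(subject)
        )
    return out


def d_prime(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> float:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    A rate of exactly 0 or 1 is replaced by its log-linear corrected value
    (add 0.5 to the cell, 1 to the total) so that d' stays finite; non-extreme
    rates are left untouched.
    """
    for name, v in (
        ("hits", hits),
        ("misses", misses),
        ("false_alarms", false_alarms),
        ("correct_rejections", correct_rejections),
    ):
        if v < 0:
            raise ConfigurationError(f"{name} must be >= 0")
    n_signal = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_signal == 0 or n_noise == 0:
        raise ConfigurationError("both signal and noise trial totals must be > 0")

    def _rate(count: int, total: int) -> float:
        r = count / total
        if r in (0.0, 1.0):
            r = (count + 0.5) / (total + 1)
        return r

    return float(
        stats.norm.ppf(_rate(hits, n_signal)) - stats.norm.ppf(_rate(false_alarms, n_noise))
    )


@dataclass
class SyntheticDataset:
    """A complete simulated study: design, features, ground truth, volumes."""

    spec: DesignSpec
    design: pd.DataFrame
    features: FeatureMatrix
    brain_mask: np.ndarray
    signal_mask: np.ndarray
    truth: GroundTruth
    volumes: dict[int, VolumeSet]

    def signal_columns(self) -> np.ndarray:
        """In-mask column indices of the planted signal voxels."""
        flat = np.full(self.brain_mask.shape, -1, dtype=int)
        flat[self.brain_mask] = np.arange(int(self.brain_mask.sum()))
        return flat[self.signal_mask]


def simulate_dataset(
    n_subjects: int = 7,
    grid: tuple[int, int, int] = (24, 24, 24),
    n_items: int = 96,
    n_animate: int | None = None,
    dim: int = 300,
    n_sessions: int = 6,
    blocks_per_session: int = 9,
    trials_per_block: int = 32,
    awareness_probs: tuple[float, float, float] = (0.55, 0.15, 0.30),
    shared_fraction: float = 1.0,
    noise_sd: float = 1.0,
    weight_scale: float = 1.0,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a full synthetic study in one call.

    Defaults reproduce the emulated study's conditions (7 subjects, 96 items,
    1728 trials per subject, 300 feature dimensions) on a 24^3 grid with an
    ellipsoidal brain mask and a cuboid planted-signal region; pass smaller
    counts for desk-scale work.  The sub-seeds for design, features, weights
    and noise are derived from ``seed``.
    """
    if n_animate is None:
        n_animate = n_items // 2
    spec = DesignSpec(
        n_subjects=n_subjects,
        n_sessions=n_sessions,
        blocks_per_session=blocks_per_session,
        trials_per_block=trials_per_block,
        n_items=n_items,
        n_animate=n_animate,
        awareness_probs=awareness_probs,
        seed=seed,
    )
    design = generate_design(spec)
    features = generate_item_features(
        n_items=n_items, dim=dim, n_animate=n_animate, seed=seed + 1
    )
    brain_mask = default_brain_mask(grid)
    signal_mask = default_signal_mask(grid, brain_mask)
    truth = make_ground_truth(
        brain_mask,
        signal_mask,
        n_subjects=n_subjects,
        dim=dim,
        shared_fraction=shared_fraction,
        noise_sd=noise_sd,
        weight_scale=weight_scale,
        seed=seed + 2,
    )
    volumes = generate_bold(
        design, features, truth, brain_mask, voxel_size_mm, seed=seed + 3
    )
    return SyntheticDataset(
        spec=spec,
        design=design,
        features=features,
        brain_mask=brain_mask,
        signal_mask=signal_mask,
        truth=truth,
        volumes=volumes,
    )


def subject_d_primes(
    design: pd.DataFrame, awareness: str = "unaware", signal_category: str = "animate"
) -> pd.Series:
    """Per-subject d' on trials of one awareness level.

    Treats ``signal_category`` trials as signal ("animate" responses on them
    are hits) and the other category as noise ("animate" responses are false
    alarms).  Used to identify subjects with null perceptual sensitivity on
    unaware trials.
    """
    sub = design[design["awareness"] == awareness]
    out = {}
    for subject, grp in sub.groupby("subject_id"):
        sig = grp[grp["category"] == signal_category]
        noi = grp[grp["category"] != signal_category]
        hits = int((sig["response"] == signal_category).sum())
        fas = int((noi["response"] == signal_category).sum())
        out[subject] = d_prime(hits, len(sig) - hits, fas, len(noi) - fas)
    return pd.Series(out, name=f"d_prime_{awareness}")
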