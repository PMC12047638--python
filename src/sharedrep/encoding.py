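"""Voxelwise linear encoding models: item features -> BOLD responses.

The encoding model is ridge regression fit independently per voxel on
standardized features, solved in closed form.  Because the ridge solution is
separable across voxels, one whole-brain fit per training subject/condition is
mathematically identical to refitting inside every searchlight sphere; sphere
slices of the predicted responses are taken downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .exceptions import ConfigurationError, DataError
from .features import group_mean_by_label

__all__ = ["EncodingModel", "fit_encoding", "predict_bold", "summarize_by_item"]


@dataclass
class EncodingModel:
    """A fitted feature -> voxel linear map.

    ``weights`` is (dim, n_voxels); prediction for standardized features ``Z``
    is ``Z @ weights + intercepts``.  The feature standardizer (per-dimension
    center and scale) is learned at fit time and frozen thereafter.
    """

    weights: np.ndarray
    intercepts: np.ndarray
    feature_center: np.ndarray
    feature_scale: np.ndarray
    regularization_strength: float

    @property
    def dim(self) -> int:
        return self.weights.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant dims pass through centered
    return center, scale


def fit_encoding(
    features: np.ndarray,
    responses: np.ndarray,
    regularization_strength: float = 1.0,
) -> EncodingModel:
    """Fit the penalized least-squares encoding model.

    Features are standardized with training statistics only; responses are
    left on their native scale and the per-voxel intercept absorbs their mean.
    ``regularization_strength`` is the ridge penalty on the standardized
    design (0 gives the minimum-norm least-squares fit).
    """
    X = np.asarray(features, dtype=float)
    Y = np.asarray(responses, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise DataError("features and responses must be 2D")
    if X.shape[0] != Y.shape[0]:
        raise DataError(
            f"features have {X.shape[0]} trials but responses have {Y.shape[0]}"
        )
    if X.shape[0] < 2:
        raise DataError("at least 2 trials are required to fit an encoding model")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise DataError("non-finite values in features or responses")
    if regularization_strength < 0:
        raise ConfigurationError("regularization_strength must be nonnegative")

    center, scale = _standardize_params(X)
    Z = (X - center) / scale
    intercepts = Y.mean(axis=0)
    Yc = Y - intercepts
    dim = Z.shape[1]
    if regularization_strength > 0:
        A = Z.T @ Z + regularization_strength * np.eye(dim)
        W = linalg.solve(A, Z.T @ Yc, assume_a="pos")
    else:
        W, *_ = np.linalg.lstsq(Z, Yc, rcond=None)
    return EncodingModel(
        weights=W,
        intercepts=intercepts,
        feature_center=center,
        feature_scale=scale,
        regularization_strength=float(regularization_strength),
    )


def predict_bold(model: EncodingModel, features: np.ndarray) -> np.ndarray:
    """Predicted responses (rows x voxels) for new feature rows.

    Applies the frozen standardizer, then the linear map.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.dim:
        raise ConfigurationError(
            f"features have dim {X.shape[1] if X.ndim == 2 else '?'}, "
            f"model expects {model.dim}"
        )
    Z = (X - model.feature_center) / model.feature_scale
    return Z @ model.weights + model.intercepts


def summarize_by_item(
    responses: np.ndarray,
    item_labels: Sequence,
    expected_items: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean response pattern per item: (items x voxels matrix, item ids).

    Item rows are in canonical sorted order; same contract as
    :func:`sharedrep.features.average_by_item`.
    """
    return group_mean_by_label(responses, item_labels, expected_items)
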