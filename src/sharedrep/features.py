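"""Per-item stimulus feature representations and pluggable extraction backends.

The downstream pipeline only ever consumes a :class:`FeatureMatrix` — one row
of hidden-layer activations per visual item.  How those activations are
produced is a pluggable backend.  The reference configuration mirrors a
fine-tuned object-recognition CNN: a frozen convolutional stack, adaptive
global pooling, a 300-unit fully connected hidden layer with SELU activation,
trained with per-unit binary cross entropy and SGD, early-stopped after five
non-improving validation epochs.  That full training loop is deliberately not
executed here; a deterministic tiny convolutional backend with fixed weights
(``tiny-test``) provides an exactly checkable forward pass, and synthetic
feature matrices from :mod:`sharedrep.design` serve the same role for
pipeline-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError, DataError

__all__ = [
    "FeatureMatrix",
    "BackboneSpec",
    "average_by_item",
    "extract_features",
    "register_backend",
    "selu",
]

# SELU constants (Klambauer et al. self-normalizing networks).
_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def selu(x: np.ndarray) -> np.ndarray:
    """Scaled exponential linear unit, applied elementwise."""
    x = np.asarray(x, dtype=float)
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(x) - 1.0))


@dataclass
class FeatureMatrix:
    """Items x dimensions numeric matrix of stimulus representations.

    ``item_ids`` gives the row labels in order.  Rows must be finite; a row
    with zero variance cannot enter a Pearson-based RDM and is rejected by
    :func:`FeatureMatrix.validate`.
    """

    values: np.ndarray
    item_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.item_ids = np.asarray(self.item_ids)
        if self.values.ndim != 2:
            raise DataError("FeatureMatrix.values must be 2D (items x dim)")
        if len(self.item_ids) != self.values.shape[0]:
            raise DataError("item_ids length does not match number of rows")
        if len(np.unique(self.item_ids)) != len(self.item_ids):
            raise DataError("item_ids must be unique")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature matrix contains non-finite values")
        var = self.values.var(axis=1)
        if np.any(var == 0):
            bad = self.item_ids[np.nonzero(var == 0)[0][0]]
            raise DataError(f"feature row for item {bad!r} has zero variance")

    def rows_for(self, item_ids: Sequence) -> np.ndarray:
        """Feature rows for the given item ids, in the given order."""
        index = {iid: i for i, iid in enumerate(self.item_ids.tolist())}
        try:
            rows = [index[i] for i in item_ids]
        except KeyError as exc:
            raise DataError(f"item {exc.args[0]!r} has no feature row") from exc
        return self.values[rows]

    def subset(self, item_ids: Sequence) -> "FeatureMatrix":
        return FeatureMatrix(self.rows_for(item_ids), np.asarray(list(item_ids)))


def group_mean_by_label(
    values: np.ndarray,
    labels: Sequence,
    expected_labels: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` rows per distinct label, labels in sorted order.

    Shared workhorse behind :func:`average_by_item` and
    :func:`sharedrep.encoding.summarize_by_item`.  Returns ``(means, labels)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim != 2:
        raise DataError("values must be 2D (rows x dim)")
    if len(labels) != values.shape[0]:
        raise DataError("labels length does not match number of rows")
    uniq = np.unique(labels)
    if expected_labels is not None:
        expected = np.unique(np.asarray(expected_labels))
        missing = np.setdiff1d(expected, uniq)
        if missing.size:
            raise DataError(f"no rows observed for item(s) {missing.tolist()}")
        uniq = expected
    out = np.empty((len(uniq), values.shape[1]), dtype=float)
    for k, lab in enumerate(uniq):
        out[k] = values[labels == lab].mean(axis=0)
    return out, uniq


def average_by_item(
    trial_features: np.ndarray,
    item_labels: Sequence,
    expected_items: Sequence | None = None,
) -> FeatureMatrix:
    """Average trial-level feature rows into one row per item.

    The output row order is the canonical sorted item order.  When
    ``expected_items`` is given, every expected item must occur at least once.
    """
    means, uniq = group_mean_by_label(trial_features, item_labels, expected_items)
    return FeatureMatrix(means, uniq)


@dataclass
class BackboneSpec:
    """Configuration of a feature-extraction backend.

    Mirrors the fine-tuning head used on top of a frozen convolutional
    backbone: adaptive pooling, a dense hidden layer of ``hidden_dim`` units,
    SELU activation, per-unit binary cross-entropy loss, SGD, and early
    stopping after ``early_stop_patience`` non-improving epochs.  Only the
    interface and head architecture are enforced here; the ``tiny-test``
    backend realizes them at toy scale.
    """

    backbone_name: str = "tiny-test"
    hidden_dim: int = 300
    activation: str = "selu"
    pooling: str = "adaptive_avg"
    frozen_backbone: bool = True
    loss: str = "binary_cross_entropy"
    optimizer: str = "sgd"
    early_stop_patience: int = 5

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ConfigurationError("hidden_dim must be >= 1")
        if self.early_stop_patience < 1:
            raise ConfigurationError("early_stop_patience must be >= 1")


class TinyConvBackend:
    """A 2-layer deterministic toy network: conv (valid, 3x3) + SELU,
    adaptive global average pooling, dense to ``hidden_dim`` + SELU.

    Weights are drawn once from a fixed seed so the forward pass is exactly
    reproducible and can be checked by hand.
    """

    def __init__(self, spec: BackboneSpec, n_kernels: int = 4, weight_seed: int = 7):
        self.spec = spec
        self.n_kernels = n_kernels
        rng = np.random.default_rng(weight_seed)
        # kernels set lazily once the channel count is known
        self._rng_state = rng
        self._kernels: np.ndarray | None = None
        self._dense: np.ndarray | None = None
        self._dense_bias: np.ndarray | None = None

    def _init_weights(self, n_channels: int) -> None:
        rng = self._rng_state
        self._kernels = rng.standard_normal((self.n_kernels, 3, 3, n_channels)) * 0.5
        self._dense = rng.standard_normal((self.n_kernels, self.spec.hidden_dim)) * 0.5
        self._dense_bias = rng.standard_normal(self.spec.hidden_dim) * 0.1

    @staticmethod
    def _conv_valid(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
        """3x3 'valid' cross-correlation of an (H, W, C) image with a (3, 3, C) kernel."""
        h, w = image.shape[0] - 2, image.shape[1] - 2
        out = np.zeros((h, w))
        for di in range(3):
            for dj in range(3):
                out += image[di : di + h, dj : dj + w] @ kernel[di, dj]
        return out

    def __call__(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:  # (n, H, W) grayscale
            images = images[..., np.newaxis]
        if images.ndim != 4:
            raise DataError("images must be (n, H, W) or (n, H, W, C)")
        if min(images.shape[1], images.shape[2]) < 3:
            raise DataError("images must be at least 3x3 for the 3x3 conv")
        if self._kernels is None:
            self._init_weights(images.shape[3])
        feats = np.empty((images.shape[0], self.spec.hidden_dim))
        for i, img in enumerate(images):
            maps = np.stack([selu(self._conv_valid(img, k)) for k in self._kernels])
            pooled = maps.mean(axis=(1, 2))  # adaptive global average pool
            feats[i] = selu(pooled @ self._dense + self._dense_bias)
        return feats


_BACKENDS: dict[str, Callable[[BackboneSpec], Callable[[np.ndarray], np.ndarray]]] = {}


def register_backend(
    name: str,
    factory: Callable[[BackboneSpec], Callable[[np.ndarray], np.ndarray]],
) -> None:
    """Register a feature-extraction backend under ``name``.

    A factory receives the :class:`BackboneSpec` and returns a callable
    mapping an image stack to an ``(n_images, hidden_dim)`` array.
    """
    _BACKENDS[name] = factory


register_backend("tiny-test", TinyConvBackend)


def extract_features(
    images: np.ndarray,
    spec: BackboneSpec,
    item_ids: Sequence | None = None,
) -> FeatureMatrix:
    """Run the backend named by ``spec.backbone_name`` over an image stack.

    Returns post-activation hidden-layer features, one row per image.
    """
    if spec.backbone_name not in _BACKENDS:
        raise ConfigurationError(
            f"no backend registered under {spec.backbone_name!r}; "
            f"known: {sorted(_BACKENDS)}"
        )
    backend = _BACKENDS[spec.backbone_name](spec)
    values = np.asarray(backend(np.asarray(images)))
    if values.shape[1] != spec.hidden_dim:
        raise ConfigurationError(
            f"backend returned dim {values.shape[1]}, expected {spec.hidden_dim}"
        )
    if item_ids is None:
        item_ids = np.arange(values.shape[0])
    return FeatureMatrix(values, np.asarray(item_ids))
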