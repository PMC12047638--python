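"""Category decoding inside searchlight spheres.

The decoder is a per-feature standardizer followed by an L1-regularized
linear support vector machine (squared hinge, the standard convex formulation
that admits an L1 penalty).  Standardizer parameters are learned on the
training set and locked at test time.  Performance is the area under the ROC
curve computed from continuous decision values, so 0.5 is chance regardless of
class imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .exceptions import ConfigurationError, DataError

__all__ = ["Decoder", "fit_decoder", "score_decoder"]


@dataclass
class Decoder:
    """A fitted standardizer + L1 linear SVM with its ordered class pair."""

    scaler: StandardScaler
    classifier: LinearSVC
    classes: tuple

    @property
    def weights(self) -> np.ndarray:
        """The (sparse) linear decision weights."""
        return self.classifier.coef_.ravel()

    def decision_values(self, patterns: np.ndarray) -> np.ndarray:
        """Continuous decision-function values; positive favors ``classes[1]``."""
        return self.classifier.decision_function(self.scaler.transform(patterns))


def fit_decoder(
    patterns: np.ndarray,
    labels: np.ndarray,
    penalty_strength: float = 1.0,
    seed: int = 0,
) -> Decoder:
    """Fit the standardizer + L1 linear SVM on training trials only.

    ``penalty_strength`` is a regularization strength: the SVM cost parameter
    is C = 1/penalty_strength, so the default 1.0 corresponds to C = 1 and
    increasing the penalty drives weights to exact zeros (total sparsity in
    the limit).  The solver is deterministic (dual=False coordinate descent,
    tolerance 1e-4).
    """
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise DataError("patterns must be 2D (trials x voxels)")
    if len(y) != X.shape[0]:
        raise DataError("labels length does not match number of trials")
    if X.shape[0] < 2:
        raise DataError("at least 2 training trials are required")
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError(
            f"training labels must contain exactly 2 classes, got {classes.tolist()}"
        )
    if penalty_strength <= 0:
        raise ConfigurationError("penalty_strength must be positive")

    scaler = StandardScaler().fit(X)
    clf = LinearSVC(
        penalty="l1",
        loss="squared_hinge",
        dual=False,
        C=1.0 / penalty_strength,
        tol=1e-4,
        random_state=seed,
    ).fit(scaler.transform(X), y)
    return Decoder(scaler=scaler, classifier=clf, classes=tuple(clf.classes_))


def score_decoder(decoder: Decoder, patterns: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of the decoder's decision values on test trials.

    Positive class is ``decoder.classes[1]``; tied decision values count 1/2.
    A single-class test set leaves the AUC undefined: a warning is emitted and
    NaN returned.
    """
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        warnings.warn(
            "score_decoder: test labels contain a single class; AUC undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.nan
    scores = decoder.decision_values(X)
    return float(roc_auc_score(y == decoder.classes[1], scores))
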