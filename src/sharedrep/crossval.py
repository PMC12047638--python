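"""Cross-participant cross-validation scenarios for both pipelines.

Models are always trained on one subject and tested on a *different* subject,
over all ordered pairs (7 subjects -> 42 pairs), under three scenarios:
within-conscious (train and test on clear-experience trials), within-unconscious
(train and test on no-experience trials), and conscious-to-unconscious
generalization.  Glimpse trials are excluded throughout.  Each pair yields one
whole-brain statistic map — Spearman RSA correlation for the encoding-based
RSA pipeline, ROC AUC for the decoding pipeline — and the per-scenario stack
of maps feeds group inference.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decoding import fit_decoder, score_decoder
from .encoding import fit_encoding, predict_bold, summarize_by_item
from .exceptions import ConfigurationError, DataError
from .features import FeatureMatrix
from .rdm import _fast_spearman
from .searchlight import SphereSpec, StatMap, run_searchlight
from .volumes import VolumeSet

__all__ = [
    "Scenario",
    "SCENARIOS",
    "StatMapStack",
    "subject_pairs",
    "run_rsa_scenario",
    "run_decoding_scenario",
]


@dataclass
class Scenario:
    """One cross-validation scheme: which awareness condition trains and which tests.

    ``subject_subset`` restricts the analysis to a subset of subjects (e.g.
    the participants with null perceptual sensitivity on unaware trials).
    """

    name: str
    train_condition: str
    test_condition: str
    subject_subset: Sequence[int] | None = None

    def with_subjects(self, subjects: Sequence[int]) -> "Scenario":
        return Scenario(self.name, self.train_condition, self.test_condition, list(subjects))


SCENARIOS: dict[str, Scenario] = {
    "within_conscious": Scenario("within_conscious", "aware", "aware"),
    "within_unconscious": Scenario("within_unconscious", "unaware", "unaware"),
    "conscious_to_unconscious": Scenario("conscious_to_unconscious", "aware", "unaware"),
}


def subject_pairs(subject_ids: Sequence[int]) -> list[tuple[int, int]]:
    """All ordered (train, test) pairs with train != test; length n(n-1)."""
    ids = list(subject_ids)
    if len(ids) < 2:
        raise ConfigurationError("at least 2 subjects are required for cross-validation")
    if len(set(ids)) != len(ids):
        raise ConfigurationError("subject ids must be unique")
    return [(a, b) for a, b in itertools.permutations(ids, 2)]


@dataclass
class StatMapStack:
    """Per-pair searchlight maps on one shared grid."""

    maps: list[StatMap]
    pairs: list[tuple[int, int]]
    statistic_name: str = "statistic"

    def __post_init__(self) -> None:
        if len(self.maps) != len(self.pairs):
            raise DataError("maps and pairs must have equal length")

    @property
    def mask(self) -> np.ndarray:
        return self.maps[0].mask

    @property
    def n_maps(self) -> int:
        return len(self.maps)

    def values_array(self) -> np.ndarray:
        """Stack as an ``(n_maps, x, y, z)`` array."""
        return np.stack([m.values for m in self.maps])


def _condition_rows(
    events: pd.DataFrame, subject: int, condition: str
) -> tuple[np.ndarray, pd.DataFrame]:
    """Positional volume indices and event rows for one subject/condition.

    Volume row order is the subject's row order in the events table (the
    acquisition order the generator and the readers preserve).
    """
    sub = events[events["subject_id"] == subject].reset_index(drop=True)
    sel = np.nonzero((sub["awareness"] == condition).to_numpy())[0]
    return sel, sub.iloc[sel]


def _check_grids(volumes: Mapping[int, VolumeSet]) -> None:
    shapes = {vs.grid_shape for vs in volumes.values()}
    masks = [vs.mask for vs in volumes.values()]
    if len(shapes) != 1 or any(not np.array_equal(masks[0], m) for m in masks[1:]):
        raise DataError("all subjects must share one grid and mask")


def _scenario_subjects(
    scenario: Scenario, volumes: Mapping[int, VolumeSet]
) -> list[int]:
    subjects = (
        list(scenario.subject_subset)
        if scenario.subject_subset is not None
        else sorted(volumes)
    )
    missing = [s for s in subjects if s not in volumes]
    if missing:
        raise DataError(f"no volumes for subject(s) {missing}")
    return subjects


def _rsa_statistic(pred_slice: np.ndarray, obs_slice: np.ndarray) -> float:
    """Spearman correlation of the two RDM lower triangles for one sphere."""
    return _fast_spearman(_lower_rdm(pred_slice), _lower_rdm(obs_slice))


def _lower_rdm(patterns: np.ndarray) -> np.ndarray:
    # fast path: 1 - Pearson lower triangle without RDM object overhead
    if patterns.shape[1] < 2:
        raise DataError("sphere has a single voxel; RDM undefined")
    centered = patterns - patterns.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms == 0):
        raise DataError("constant pattern row in sphere")
    u = centered / norms[:, None]
    d = 1.0 - u @ u.T
    return d[np.tril_indices(d.shape[0], k=-1)]


def run_rsa_scenario(
    scenario: Scenario,
    volumes: Mapping[int, VolumeSet],
    events: pd.DataFrame,
    features: FeatureMatrix,
    sphere: SphereSpec | None = None,
    regularization_strength: float = 1.0,
    n_jobs: int = 1,
    model_sink: dict | None = None,
) -> StatMapStack:
    """Encoding-based searchlight RSA over all ordered subject pairs.

    For each pair (train A, test B): a whole-brain encoding model is fit on
    A's ``train_condition`` trials; item responses are predicted for the items
    B actually saw in ``test_condition``; B's observed trials are averaged by
    item; in every searchlight sphere the Spearman correlation between the
    predicted-response RDM and the observed-response RDM (lower triangles) is
    assigned to the center.  Pairs lacking trials (or enough common items) in
    a required condition are skipped with a warning.

    The encoding model depends only on the training subject, so it is fit
    once per train subject and reused across that subject's pairs; fitted
    models are exposed through ``model_sink`` (train subject -> model) when a
    dict is passed.
    """
    _check_grids(volumes)
    subjects = _scenario_subjects(scenario, volumes)
    if sphere is None:
        sphere = SphereSpec(voxel_size_mm=tuple(volumes[subjects[0]].voxel_size_mm))
    maps: list[StatMap] = []
    pairs_done: list[tuple[int, int]] = []
    model_cache: dict = model_sink if model_sink is not None else {}
    for train_s, test_s in subject_pairs(subjects):
        tr_idx, tr_rows = _condition_rows(events, train_s, scenario.train_condition)
        te_idx, te_rows = _condition_rows(events, test_s, scenario.test_condition)
        if len(tr_idx) < 2 or len(te_idx) < 1:
            warnings.warn(
                f"pair ({train_s}->{test_s}) skipped: insufficient "
                f"{scenario.train_condition}/{scenario.test_condition} trials",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        if train_s not in model_cache:
            model_cache[train_s] = fit_encoding(
                features.rows_for(tr_rows["item_id"].to_numpy()),
                volumes[train_s].data[tr_idx],
                regularization_strength,
            )
        model = model_cache[train_s]
        observed, item_ids = summarize_by_item(
            volumes[test_s].data[te_idx], te_rows["item_id"].to_numpy()
        )
        common = np.intersect1d(item_ids, features.item_ids)
        if len(common) < len(item_ids):
            warnings.warn(
                f"pair ({train_s}->{test_s}): restricting to {len(common)} common items",
                RuntimeWarning,
                stacklevel=2,
            )
        if len(common) < 3:
            warnings.warn(
                f"pair ({train_s}->{test_s}) skipped: fewer than 3 common items",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        keep = np.isin(item_ids, common)
        observed = observed[keep]
        predicted = predict_bold(model, features.rows_for(common))
        maps.append(
            run_searchlight(
                (predicted, observed),
                volumes[test_s].mask,
                _rsa_statistic,
                sphere,
                n_jobs=n_jobs,
                statistic_name="rsa_spearman",
            )
        )
        pairs_done.append((train_s, test_s))
    return StatMapStack(maps=maps, pairs=pairs_done, statistic_name="rsa_spearman")


def run_decoding_scenario(
    scenario: Scenario,
    volumes: Mapping[int, VolumeSet],
    events: pd.DataFrame,
    sphere: SphereSpec | None = None,
    penalty_strength: float = 1.0,
    seed: int = 0,
    n_jobs: int = 1,
) -> StatMapStack:
    """Cross-subject searchlight decoding over all ordered subject pairs.

    For each pair (train A, test B): within every sphere a standardizer + L1
    linear SVM is trained on A's ``train_condition`` trials to classify
    animate vs inanimate and scored by ROC AUC on B's ``test_condition``
    trials; the AUC is assigned to the sphere center.
    """
    _check_grids(volumes)
    subjects = _scenario_subjects(scenario, volumes)
    if sphere is None:
        sphere = SphereSpec(voxel_size_mm=tuple(volumes[subjects[0]].voxel_size_mm))
    maps: list[StatMap] = []
    pairs_done: list[tuple[int, int]] = []
    for train_s, test_s in subject_pairs(subjects):
        tr_idx, tr_rows = _condition_rows(events, train_s, scenario.train_condition)
        te_idx, te_rows = _condition_rows(events, test_s, scenario.test_condition)
        y_train = tr_rows["category"].to_numpy()
        y_test = te_rows["category"].to_numpy()
        if len(np.unique(y_train)) != 2 or len(np.unique(y_test)) != 2:
            warnings.warn(
                f"pair ({train_s}->{test_s}) skipped: a condition lacks both categories",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        train_data = volumes[train_s].data[tr_idx]
        test_data = volumes[test_s].data[te_idx]

        def _decode_stat(train_slice: np.ndarray, test_slice: np.ndarray) -> float:
            dec = fit_decoder(train_slice, y_train, penalty_strength, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return score_decoder(dec, test_slice, y_test)

        maps.append(
            run_searchlight(
                (train_data, test_data),
                volumes[test_s].mask,
                _decode_stat,
                sphere,
                n_jobs=n_jobs,
                statistic_name="roc_auc",
            )
        )
        pairs_done.append((train_s, test_s))
    return StatMapStack(maps=maps, pairs=pairs_done, statistic_name="roc_auc")
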