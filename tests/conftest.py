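"""Shared fixtures: a desk-scale synthetic dataset factory.

Everything is generated at test time; sizes are kept small (12-voxel grids,
a dozen items) so the whole suite runs in minutes while still exercising the
full pipeline: design -> features -> planted BOLD -> searchlight -> group test.
"""

from __future__ import annotations

import numpy as np
import pytest

from sharedrep import simulate_dataset


def build_dataset(
    n_subjects=3,
    grid=(12, 12, 12),
    n_items=12,
    n_animate=6,
    dim=10,
    n_sessions=2,
    blocks_per_session=3,
    trials_per_block=8,
    shared_fraction=1.0,
    noise_sd=0.5,
    weight_scale=1.0,
    awareness_probs=(0.5, 0.1, 0.4),
    seed=0,
):
    """Small-default wrapper around :func:`sharedrep.simulate_dataset`,
    returned as a plain dict for concise test code."""
    ds = simulate_dataset(
        n_subjects=n_subjects,
        grid=grid,
        n_items=n_items,
        n_animate=n_animate,
        dim=dim,
        n_sessions=n_sessions,
        blocks_per_session=blocks_per_session,
        trials_per_block=trials_per_block,
        awareness_probs=awareness_probs,
        shared_fraction=shared_fraction,
        noise_sd=noise_sd,
        weight_scale=weight_scale,
        seed=seed,
    )
    return {
        "spec": ds.spec,
        "design": ds.design,
        "features": ds.features,
        "brain_mask": ds.brain_mask,
        "signal_mask": ds.signal_mask,
        "truth": ds.truth,
        "volumes": ds.volumes,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def dataset_factory():
    return build_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """One shared small dataset for read-only tests."""
    return build_dataset()
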