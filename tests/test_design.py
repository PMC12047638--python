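"""Tests for the synthetic design generator and signal-detection sensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sharedrep import (
    ConfigurationError,
    DataError,
    DesignSpec,
    compute_rdm,
    d_prime,
    default_brain_mask,
    default_signal_mask,
    fit_encoding,
    generate_bold,
    generate_design,
    generate_item_features,
    lower_triangle,
    make_ground_truth,
    predict_bold,
    subject_d_primes,
    summarize_by_item,
)


def _spec(**kw):
    defaults = dict(
        n_subjects=2, n_sessions=2, blocks_per_session=3, trials_per_block=4,
        n_items=12, n_animate=6, seed=0,
    )
    defaults.update(kw)
    return DesignSpec(**defaults)


@pytest.mark.parametrize(
    "sessions, blocks, tpb, expected",
    [(6, 9, 32, 1728), (1, 1, 0, 0), (2, 3, 4, 24)],
)
def test_trial_counts(sessions, blocks, tpb, expected):
    spec = _spec(n_subjects=1, n_sessions=sessions, blocks_per_session=blocks,
                 trials_per_block=tpb, n_items=96, n_animate=48)
    design = generate_design(spec)
    assert len(design) == expected


def test_trials_split_evenly_across_sessions():
    design = generate_design(_spec(n_subjects=1, n_sessions=2, blocks_per_session=3,
                                   trials_per_block=4))
    assert design.groupby("session").size().tolist() == [12, 12]


def test_design_reproducible_and_subject_order_invariant():
    spec = _spec(n_subjects=3)
    a = generate_design(spec)
    b = generate_design(spec)
    pd.testing.assert_frame_equal(a, b)
    # subject 2's trials do not depend on how many other subjects exist
    two = generate_design(_spec(n_subjects=2))
    sub2_in_three = a[a.subject_id == 2].reset_index(drop=True)
    sub2_in_two = two[two.subject_id == 2].reset_index(drop=True)
    pd.testing.assert_frame_equal(sub2_in_three, sub2_in_two)


def test_items_balanced_and_category_deterministic():
    spec = _spec(n_subjects=2, n_sessions=3, blocks_per_session=2, trials_per_block=10,
                 n_items=9, n_animate=4)
    design = generate_design(spec)
    for _, grp in design.groupby("subject_id"):
        counts = grp["item_id"].value_counts()
        assert counts.max() - counts.min() <= 1  # balanced up to rounding
        assert grp["item_id"].max() < spec.n_items
    expected_cat = np.where(design["item_id"] < spec.n_animate, "animate", "inanimate")
    assert (design["category"] == expected_cat).all()


def test_awareness_labels_follow_probabilities():
    spec = _spec(n_subjects=1, n_sessions=6, blocks_per_session=9, trials_per_block=32,
                 awareness_probs=(0.6, 0.1, 0.3))
    design = generate_design(spec)
    freqs = design["awareness"].value_counts(normalize=True)
    assert freqs["unaware"] == pytest.approx(0.6, abs=0.05)
    assert freqs["aware"] == pytest.approx(0.3, abs=0.05)


def test_invalid_design_counts_rejected():
    with pytest.raises(ConfigurationError):
        _spec(n_items=4, n_animate=6)
    with pytest.raises(ConfigurationError):
        _spec(awareness_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ConfigurationError):
        _spec(n_sessions=0)


class TestDPrime:
    def test_no_sensitivity_is_zero(self):
        assert d_prime(30, 70, 30, 70) == pytest.approx(0.0)

    def test_inverse_normal_oracle(self):
        expected = stats.norm.ppf(0.69) - stats.norm.ppf(0.31)
        assert d_prime(69, 31, 31, 69) == pytest.approx(expected, abs=1e-12)

    def test_loglinear_correction_on_perfect_hit_rate(self):
        # hit rate 1 -> corrected to (100 + 0.5) / 101; FA rate untouched
        got = d_prime(100, 0, 31, 69)
        expected = stats.norm.ppf(100.5 / 101) - stats.norm.ppf(0.31)
        assert np.isfinite(got) and got > 0
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_totals_rejected(self):
        with pytest.raises(ConfigurationError):
            d_prime(0, 0, 10, 10)
        with pytest.raises(ConfigurationError):
            d_prime(-1, 5, 5, 5)

    def test_per_subject_dprime_near_zero_on_unaware_trials(self):
        # default accuracy on unaware trials is chance -> d' centered on 0
        spec = _spec(n_subjects=4, n_sessions=4, blocks_per_session=9,
                     trials_per_block=32, n_items=96, n_animate=48)
        dprimes = subject_d_primes(generate_design(spec), awareness="unaware")
        assert len(dprimes) == 4
        assert np.abs(dprimes.mean()) < 0.2


class TestItemFeatures:
    def test_shape_matches_request(self):
        fm = generate_item_features(96, 300, seed=0)
        assert fm.values.shape == (96, 300)

    def test_zero_correlations_give_exchangeable_blocks(self):
        diffs = []
        for seed in range(30):
            fm = generate_item_features(16, 60, 0.0, 0.0, seed=seed)
            d = compute_rdm(fm.values).values
            within = d[:8, :8][np.tril_indices(8, -1)].mean()
            between = d[8:, :8].mean()
            diffs.append(within - between)
        assert abs(np.mean(diffs)) < 0.02

    def test_planted_block_contrast_recovered(self):
        # Monte-Carlo estimate of block means over >= 100 seeds
        within_list, between_list = [], []
        for seed in range(100):
            fm = generate_item_features(16, 40, within_animate_corr=0.6,
                                        within_inanimate_corr=0.0, seed=seed)
            d = compute_rdm(fm.values).values
            within_list.append(d[:8, :8][np.tril_indices(8, -1)].mean())
            between_list.append(d[8:, :8].mean())
        assert np.mean(within_list) < np.mean(between_list) - 0.3

    def test_non_positive_definite_covariance_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_item_features(16, 10, within_animate_corr=-0.5, seed=0)
        with pytest.raises(ConfigurationError):
            generate_item_features(16, 10, within_animate_corr=1.5, seed=0)


class TestGenerateBold:
    def test_noiseless_shared_weights_give_identical_item_patterns(self, dataset_factory):
        ds = dataset_factory(noise_sd=0.0, shared_fraction=1.0, n_subjects=2)
        sig_cols = _signal_columns(ds)
        patterns = []
        for s in (1, 2):
            rows = ds["design"][ds["design"].subject_id == s]
            items, _ = summarize_by_item(ds["volumes"][s].data, rows["item_id"].to_numpy())
            patterns.append(items[:, sig_cols])
        np.testing.assert_allclose(patterns[0], patterns[1], atol=1e-10)

    def test_zero_weights_leave_signal_region_at_noise_level(self, dataset_factory):
        ds = dataset_factory(weight_scale=0.0, noise_sd=1.0)
        sig_cols = _signal_columns(ds)
        data = ds["volumes"][1].data
        null_cols = np.setdiff1d(np.arange(data.shape[1]), sig_cols)
        assert data[:, sig_cols].std() == pytest.approx(data[:, null_cols].std(), rel=0.1)

    def test_missing_feature_row_rejected(self, dataset_factory):
        ds = dataset_factory()
        short = ds["features"].subset(ds["features"].item_ids[:-2])
        with pytest.raises(DataError):
            generate_bold(ds["design"], short, ds["truth"], ds["brain_mask"], seed=0)

    def test_cross_subject_encoding_recovery_over_seeds(self):
        """Encoding fit on subject A predicts B's signal-region RDM (20 seeds)."""
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(20):
            spec = _spec(n_subjects=2, n_sessions=1, blocks_per_session=3,
                         trials_per_block=12, seed=seed)
            design = generate_design(spec)
            fm = generate_item_features(12, 10, n_animate=6, seed=seed + 100)
            mask = default_brain_mask((10, 10, 10))
            sig = default_signal_mask((10, 10, 10), mask)
            truth = make_ground_truth(mask, sig, 2, 10, shared_fraction=1.0,
                                      noise_sd=0.5, seed=seed + 200)
            vols = generate_bold(design, fm, truth, mask, seed=seed + 300)
            flat = np.full(mask.shape, -1, int)
            flat[mask] = np.arange(mask.sum())
            cols = flat[sig]
            rows_a = design[design.subject_id == 1]
            rows_b = design[design.subject_id == 2]
            model = fit_encoding(fm.rows_for(rows_a["item_id"].to_numpy()),
                                 vols[1].data[:, cols])
            pred = predict_bold(model, fm.values)
            obs, _ = summarize_by_item(vols[2].data[:, cols], rows_b["item_id"].to_numpy())
            rho = spearmanr(lower_triangle(compute_rdm(pred).values),
                            lower_triangle(compute_rdm(obs).values)).statistic
            rhos.append(rho)
        assert np.mean(rhos) > 0.3
        assert np.mean(np.array(rhos) > 0) >= 0.9


def _signal_columns(ds):
    mask = ds["brain_mask"]
    flat = np.full(mask.shape, -1, int)
    flat[mask] = np.arange(int(mask.sum()))
    return flat[ds["signal_mask"]]
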