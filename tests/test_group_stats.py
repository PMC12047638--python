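"""Tests for TFCE and the sign-flip max-stat permutation test."""

import numpy as np
import pytest

from sharedrep import (
    ConfigurationError,
    DataError,
    TfceParams,
    permutation_test,
    tfce_transform,
)


class TestTfce:
    def test_zero_map_stays_zero(self):
        assert np.all(tfce_transform(np.zeros((5, 5, 5))) == 0.0)

    def test_negative_values_contribute_nothing(self):
        vol = -np.ones((4, 4, 4))
        assert np.all(tfce_transform(vol) == 0.0)

    @pytest.mark.parametrize("v", [0.5, 1.0, 2.5])
    def test_isolated_voxel_closed_form(self, v):
        """Single voxel of value v: TFCE -> integral of h^2 dh = v^3/3."""
        vol = np.zeros((7, 7, 7))
        vol[3, 3, 3] = v
        got = tfce_transform(vol)[3, 3, 3]
        assert got == pytest.approx(v**3 / 3.0, rel=0.02)

    def test_uniform_block_closed_form(self):
        """N-voxel block at value v: each voxel -> N^0.5 * v^3/3."""
        vol = np.zeros((8, 8, 8))
        vol[3:5, 3:5, 3:5] = 1.2  # 8-voxel cube, one 26-connected component
        got = tfce_transform(vol)[3, 3, 3]
        assert got == pytest.approx(np.sqrt(8) * 1.2**3 / 3.0, rel=0.02)

    def test_numerical_integration_oracle(self):
        """Staircase sum matches an independent fine numerical integral."""
        vol = np.zeros((6, 6, 6))
        vol[2, 2, 2] = 1.7
        params = TfceParams(n_steps=400)
        got = tfce_transform(vol, params=params)[2, 2, 2]
        hs = np.linspace(0, 1.7, 100001)
        oracle = np.trapezoid(hs**2, hs)  # extent term is 1
        assert got == pytest.approx(oracle, rel=0.005)

    def test_monotone_in_voxel_values(self, rng):
        vol = np.abs(rng.standard_normal((6, 6, 6)))
        base = tfce_transform(vol)
        raised = vol.copy()
        raised[2, 3, 4] += 0.7
        higher = tfce_transform(raised)
        assert np.all(higher >= base - 1e-12)

    def test_connectivity_affects_component_extent(self):
        vol = np.zeros((5, 5, 5))
        vol[1, 1, 1] = vol[2, 2, 2] = 1.0  # corner-adjacent voxels
        p26 = tfce_transform(vol, params=TfceParams(connectivity=26))[1, 1, 1]
        p6 = tfce_transform(vol, params=TfceParams(connectivity=6))[1, 1, 1]
        assert p26 > p6  # one 2-voxel component vs two isolated voxels

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            TfceParams(dh=0.0)
        with pytest.raises(ConfigurationError):
            TfceParams(connectivity=10)


class TestPermutationTest:
    def _stack(self, rng, n_maps=5, shape=(6, 6, 6), effect=0.0):
        maps = rng.standard_normal((n_maps,) + shape) * 0.1
        maps[:, 2:4, 2:4, 2:4] += effect
        mask = np.ones(shape, dtype=bool)
        return maps, mask

    def test_identical_strong_maps_reach_minimal_exhaustive_p(self, rng):
        shape = (6, 6, 6)
        one = np.zeros(shape)
        one[2:4, 2:4, 2:4] = 1.0
        maps = np.stack([one] * 5)
        mask = np.ones(shape, dtype=bool)
        res = permutation_test(maps, 0.0, n_permutations=5000, seed=0, mask=mask)
        assert res.exhaustive and res.n_permutations == 32
        assert np.all(res.p_map[2:4, 2:4, 2:4] == pytest.approx(1.0 / 32))

    def test_maps_at_null_value_give_p_one(self):
        maps = np.full((4, 5, 5, 5), 0.5)
        mask = np.ones((5, 5, 5), dtype=bool)
        res = permutation_test(maps, null_value=0.5, n_permutations=200, seed=0, mask=mask)
        assert np.all(res.p_map[mask] == 1.0)

    def test_p_map_invariant_to_map_order_when_exhaustive(self, rng):
        maps, mask = self._stack(rng, n_maps=6, effect=0.3)
        a = permutation_test(maps, 0.0, n_permutations=64, seed=1, mask=mask)
        b = permutation_test(maps[::-1], 0.0, n_permutations=64, seed=1, mask=mask)
        assert a.exhaustive and b.exhaustive
        np.testing.assert_array_equal(a.p_map, b.p_map)

    def test_monte_carlo_agrees_with_exhaustive(self, rng):
        maps, mask = self._stack(rng, n_maps=6, effect=0.25)
        exact = permutation_test(maps, 0.0, n_permutations=64, seed=0, mask=mask)
        mc = permutation_test(maps, 0.0, n_permutations=4000, seed=0, mask=mask,
                              exhaustive=False)
        assert not mc.exhaustive
        diff = np.abs(exact.p_map[mask] - mc.p_map[mask])
        assert diff.max() < 0.06

    def test_minimum_monte_carlo_p_is_one_over_nplus1(self, rng):
        shape = (5, 5, 5)
        one = np.zeros(shape)
        one[2, 2, 2] = 5.0
        maps = np.stack([one] * 12) + 0.01 * rng.standard_normal((12,) + shape)
        mask = np.ones(shape, dtype=bool)
        res = permutation_test(maps, 0.0, n_permutations=99, seed=0, mask=mask)
        assert res.p_map[mask].min() == pytest.approx(1.0 / 100)

    def test_seed_reproducibility(self, rng):
        maps, mask = self._stack(rng, n_maps=12, effect=0.2)
        a = permutation_test(maps, 0.0, n_permutations=150, seed=3, mask=mask)
        b = permutation_test(maps, 0.0, n_permutations=150, seed=3, mask=mask)
        np.testing.assert_array_equal(a.p_map, b.p_map)

    def test_input_validation(self, rng):
        maps, mask = self._stack(rng)
        with pytest.raises(ConfigurationError):
            permutation_test(maps, 0.0, n_permutations=0, mask=mask)
        with pytest.raises(DataError):
            permutation_test(maps[:1], 0.0, n_permutations=10, mask=mask)
        with pytest.raises(ConfigurationError):
            permutation_test(maps, 0.0, n_permutations=10)  # mask required for arrays

    def test_type_one_control_on_independent_null_maps(self):
        """Familywise error on independent sign-symmetric noise maps stays near
        the nominal 5% level (binomial-tolerant bound over 40 replicates)."""
        rng = np.random.default_rng(77)
        mask = np.ones((8, 8, 8), dtype=bool)
        flagged = 0
        for rep in range(40):
            maps = rng.standard_normal((12, 8, 8, 8))
            res = permutation_test(maps, 0.0, n_permutations=300, seed=rep,
                                   mask=mask, exhaustive=False)
            flagged += bool((res.p_map[mask] < 0.05).any())
        # under exact 5% control, P(flagged > 5) < 2%
        assert flagged <= 5

    def test_significant_region_detected_not_background(self, rng):
        maps, mask = self._stack(rng, n_maps=10, effect=0.5)
        res = permutation_test(maps, 0.0, n_permutations=400, seed=0, mask=mask)
        sig = res.significant(0.05)
        assert sig[2:4, 2:4, 2:4].all()
        background = mask.copy()
        background[1:5, 1:5, 1:5] = False
        assert sig[background].mean() < 0.05
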