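import math

import numpy as np
import pytest
from scipy.linalg import pinvh

from rwrnet.mi_estimation import MIMatrix
from rwrnet.topology_priors import (
    build_modules,
    build_roaming,
    build_seeding,
    commute_kernel,
    expression_levels,
    initial_vector,
    select_centres,
)

from .conftest import random_mi


class TestCommuteKernel:
    @pytest.mark.parametrize("m", [0.3, 1.0, 42.0])
    def test_two_gene_hand_case(self, m):
        mi = MIMatrix(["A", "B"], np.array([[0.0, m], [m, 0.0]]))
        with pytest.warns(UserWarning, match="clamped"):
            k = commute_kernel(mi)
        np.testing.assert_allclose(k.laplacian, [[1, -1], [-1, 1]], atol=1e-12)
        np.testing.assert_allclose(k.pinv, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-12)
        assert k.act[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(k.acf, 1.0)
        assert k.alpha_raw == pytest.approx(1.0)
        assert k.alpha == pytest.approx(0.99)

    def test_acf_diagonal_all_ones(self, mi5):
        k = commute_kernel(mi5)
        np.testing.assert_allclose(np.diag(k.acf), 1.0)

    def test_act_agrees_with_generic_pinv(self, mi5):
        # independent oracle: scipy's pinvh instead of our eigendecomposition
        k = commute_kernel(mi5)
        lp = pinvh(k.laplacian)
        act = np.diag(lp)[:, None] + np.diag(lp)[None, :] - 2 * lp
        np.fill_diagonal(act, 0.0)
        np.testing.assert_allclose(k.act, act, atol=1e-8)

    def test_act_symmetric_nonnegative_zero_diag(self, mi5):
        k = commute_kernel(mi5)
        np.testing.assert_allclose(k.act, k.act.T)
        assert np.all(np.diag(k.act) == 0)
        assert np.all(k.act >= 0)

    def test_act_squared_distance_relaxed_triangle(self):
        for seed in range(10):
            k = commute_kernel(random_mi(6, seed=seed))
            act = k.act
            n = act.shape[0]
            for i in range(n):
                for j in range(n):
                    for l in range(n):
                        assert act[i, j] <= 2 * (act[i, l] + act[l, j]) + 1e-9

    def test_strengthening_edge_never_increases_act(self):
        for seed in range(30):
            r = np.random.default_rng(seed)
            mi = random_mi(int(r.integers(4, 8)), seed=seed)
            before = commute_kernel(mi).act[0, 1]
            bumped = mi.values.copy()
            bumped[0, 1] = bumped[1, 0] = bumped[0, 1] + r.uniform(0.1, 1.0)
            after = commute_kernel(
                MIMatrix(mi.gene_ids, bumped)
            ).act[0, 1]
            assert after <= before + 1e-10

    def test_rejects_asymmetric(self):
        vals = np.array([[0.0, 1.0, 0.2], [1.0, 0.0, 0.4], [0.2, 0.4, 0.0]])
        mi = random_mi(3)
        mi.values = vals
        mi.values[0, 1] = 9.0  # break symmetry after construction
        with pytest.raises(ValueError, match="symmetric"):
            commute_kernel(mi)

    def test_alpha_within_bounds(self, mi5):
        k = commute_kernel(mi5)
        assert 0.01 <= k.alpha <= 0.99


class TestExpressionLevels:
    def test_row_sums(self):
        mi = random_mi(3)
        mi.values = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        np.testing.assert_allclose(expression_levels(mi), [3, 4, 5])

    def test_all_zero(self):
        mi = random_mi(4)
        mi.values = np.zeros((4, 4))
        np.testing.assert_allclose(expression_levels(mi), 0.0)

    def test_permutation_equivariance(self, mi5, rng):
        el = expression_levels(mi5)
        perm = rng.permutation(5)
        permuted = MIMatrix(
            [mi5.gene_ids[p] for p in perm], mi5.values[np.ix_(perm, perm)]
        )
        np.testing.assert_allclose(expression_levels(permuted), el[perm])


class TestSelectCentres:
    def test_derived_three_gene(self):
        # mean 4, sample std 1 -> only EL=5 exceeds the mean; none below 3
        assert select_centres(np.array([3.0, 4.0, 5.0])) == {2}

    def test_all_equal_empty(self):
        assert select_centres(np.array([2.0, 2.0, 2.0, 2.0])) == set()

    def test_derived_low_branch(self):
        # mean 5, std 4.082 -> high branch {0}; 0 < 0.918 adds {3}
        assert select_centres(np.array([10.0, 5.0, 5.0, 0.0])) == {0, 3}


class TestModules:
    def test_module_size_n4(self):
        mods = build_modules(random_mi(4), centres={0})
        assert len(mods[0]) == 2  # ceil(ln 4) = 2

    def test_module_size_n100(self):
        mods = build_modules(random_mi(100), centres={0})
        assert len(mods[0]) == 5  # ceil(ln 100) = 5

    def test_tie_break_by_ascending_index(self):
        mi = random_mi(4)
        mi.values = np.array(
            [
                [0.0, 0.5, 0.5, 0.5],
                [0.5, 0.0, 0.1, 0.1],
                [0.5, 0.1, 0.0, 0.1],
                [0.5, 0.1, 0.1, 0.0],
            ]
        )
        mods = build_modules(mi, centres={0})
        assert mods[0] == [1, 2]

    def test_non_centres_empty(self):
        mods = build_modules(random_mi(5), centres={2})
        assert mods[0] == [] and mods[4] == []
        assert len(mods[2]) == 2  # ceil(ln 5) = 2

    def test_members_exclude_centre(self, mi5):
        mods = build_modules(mi5, centres=set(range(5)))
        for g, members in mods.items():
            assert g not in members

    def test_log_base_override(self):
        mods = build_modules(random_mi(100), centres={0}, log_base=10.0)
        assert len(mods[0]) == 2  # ceil(log10 100) = 2


class TestInitialVector:
    def test_one_hot_off_centre(self):
        p0 = initial_vector(2, centres=set(), modules={2: []}, n=5)
        np.testing.assert_allclose(p0, [0, 0, 1, 0, 0])

    def test_uniform_over_centre_plus_module(self):
        p0 = initial_vector(0, centres={0}, modules={0: [3, 4]}, n=5)
        np.testing.assert_allclose(p0[[0, 3, 4]], 1 / 3)
        assert p0.sum() == pytest.approx(1.0, abs=1e-12)

    def test_seeding_matrix_rows_sum_to_one(self, mi5):
        seeding = build_seeding(mi5)
        np.testing.assert_allclose(seeding.p0.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(seeding.p0 >= 0)


class TestRoaming:
    def test_all_equal_mi_first_branch_everywhere(self):
        mi = random_mi(4)
        vals = np.full((4, 4), 0.6)
        np.fill_diagonal(vals, 0.0)
        mi.values = vals
        roam = build_roaming(mi)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(roam.rank_factor[off], 1.0)
        np.testing.assert_allclose(roam.weights, vals)

    def test_three_gene_hand_case(self):
        mi = random_mi(3)
        mi.values = np.array([[0.0, 0.9, 0.1], [0.9, 0.0, 0.5], [0.1, 0.5, 0.0]])
        roam = build_roaming(mi)
        assert roam.rank_factor[0, 2] == pytest.approx(0.1)
        assert roam.rank_factor[1, 2] == pytest.approx(1 - 2 / 3)
        assert roam.rank_factor[2, 1] == pytest.approx(1.0)
        assert roam.weights[0, 2] == pytest.approx(0.01)
        assert roam.weights[1, 2] == pytest.approx(0.5 / 3)
        assert roam.weights[2, 1] == pytest.approx(0.5)
        assert not np.allclose(roam.weights, roam.weights.T)

    def test_rank_factor_in_unit_interval(self):
        for seed in range(5):
            roam = build_roaming(random_mi(7, seed=seed))
            assert np.all(roam.rank_factor > 0)
            assert np.all(roam.rank_factor <= 1)

    def test_transition_column_stochastic(self, mi5):
        roam = build_roaming(mi5)
        np.testing.assert_allclose(roam.transition.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_mi_gives_uniform_columns(self):
        mi = random_mi(4)
        mi.values = np.zeros((4, 4))
        roam = build_roaming(mi)
        np.testing.assert_allclose(roam.transition, 0.25)

    def test_column_stochastic_under_permutation(self, mi5, rng):
        perm = rng.permutation(5)
        permuted = MIMatrix(
            [mi5.gene_ids[p] for p in perm], mi5.values[np.ix_(perm, perm)]
        )
        roam = build_roaming(permuted)
        np.testing.assert_allclose(roam.transition.sum(axis=0), 1.0, atol=1e-9)

    def test_weights_zero_diagonal(self, mi5):
        assert np.all(np.diag(build_roaming(mi5).weights) == 0)
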