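"""Sponge statistic: discretization, MI/CMI plug-in, dI permutation test."""

import numpy as np
import pytest

import spongenet as sn
from spongenet.sponge import (
    _batch_cmi,
    conditional_mutual_information,
    delta_i,
    discretize,
    mutual_information,
    permutation_test,
    screen_triplets,
)

from conftest import cmi_oracle, mi_oracle, toy_matrix


class TestDiscretize:
    def test_nine_values_three_equal_bins(self):
        bins = discretize(np.arange(1, 10), 3)
        assert sorted(np.bincount(bins)) == [3, 3, 3]
        assert list(bins) == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_constant_vector_single_bin_with_warning(self):
        with pytest.warns(UserWarning):
            bins = discretize(np.full(10, 3.3), 4)
        assert set(bins) == {0}

    def test_100_draws_8_bins_sizes_differ_by_at_most_one(self, rng):
        bins = discretize(rng.lognormal(size=100), 8)
        assert sorted(np.bincount(bins)) == [12, 12, 12, 12, 13, 13, 13, 13]

    def test_ties_broken_by_stable_input_order(self):
        bins = discretize(np.zeros(4) + [0, 0, 1, 1], 2)
        assert list(bins) == [0, 0, 1, 1]


class TestMutualInformation:
    def test_identical_uniform_binary_is_one_bit(self):
        x = np.array([0, 1, 0, 1])
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_partner_is_zero(self):
        assert mutual_information(np.array([0, 1, 2, 0]), np.zeros(4, int)) == 0.0

    def test_toy_joint_matches_cell_sum_oracle(self):
        # joint counts [[2,1],[1,2]] over 6 samples
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3, int), np.zeros(4, int))

    def test_symmetry_and_entropy_bound(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=30)
            y = rng.integers(0, 3, size=30)
            assert mutual_information(x, y) == pytest.approx(
                mutual_information(y, x), abs=1e-12
            )
            hx = mi_oracle(x, x)
            hy = mi_oracle(y, y)
            assert mutual_information(x, y) <= min(hx, hy) + 1e-12


class TestConditionalMutualInformation:
    def test_constant_condition_equals_mi(self, rng):
        x = rng.integers(0, 3, 40)
        y = rng.integers(0, 3, 40)
        z = np.zeros(40, int)
        assert conditional_mutual_information(x, y, z) == mutual_information(x, y)

    def test_x_equals_z_independent_y_is_zero(self, rng):
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 3, 200)
        assert conditional_mutual_information(x, y, x) == pytest.approx(
            cmi_oracle(x, y, x), abs=1e-12
        )
        assert conditional_mutual_information(x, y, x) == pytest.approx(0.0, abs=1e-12)

    def test_chain_rule_identity(self, rng):
        # I(x; y,z) = I(x; z) + I(x; y | z), all plug-in
        for _ in range(10):
            x = rng.integers(0, 3, 50)
            y = rng.integers(0, 3, 50)
            z = rng.integers(0, 3, 50)
            yz = y * 3 + z
            lhs = mutual_information(x, yz)
            rhs = mutual_information(x, z) + conditional_mutual_information(x, y, z)
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_matches_cell_sum_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, 40)
            y = rng.integers(0, 4, 40)
            z = rng.integers(0, 3, 40)
            assert conditional_mutual_information(x, y, z) == pytest.approx(
                cmi_oracle(x, y, z), abs=1e-12
            )

    def test_batched_equals_scalar_path(self, rng):
        x = rng.integers(0, 6, 120)
        y = rng.integers(0, 6, 120)
        Z = rng.integers(0, 3, size=(7, 120))
        batch = _batch_cmi(x, y, Z)
        for row, got in zip(Z, batch):
            assert got == pytest.approx(
                conditional_mutual_information(x, y, row), abs=1e-12
            )


class TestDeltaI:
    def test_constant_lncrna_gives_exact_zero(self, rng):
        vals = rng.lognormal(size=(2, 50))
        m = toy_matrix(np.vstack([np.full(50, 5.0), vals]),
                       ["lncRNA", "miRNA", "mRNA"])
        res = delta_i(("g0", "g1", "g2"), m)
        assert res.delta_i == 0.0

    def test_missing_feature_errors(self, rng):
        m = toy_matrix(rng.lognormal(size=(3, 30)), ["lncRNA", "miRNA", "mRNA"])
        with pytest.raises(KeyError):
            delta_i(("nope", "g1", "g2"), m)

    def test_planted_triplet_delta_positive_across_seeds(self):
        hits = total = 0
        for seed in range(20):
            spec = sn.CohortSpec(
                n_tumor=300, n_normal=40, n_mrna=60, n_lncrna=15, n_mirna=8,
                n_sponge_triplets=1, module_sizes=(10,), sponge_strength=0.8,
                seed=seed,
            )
            matrix, meta, truth = sn.generate_cohort(spec)
            norm = sn.normalize_counts(matrix).subset_samples(
                meta.index[meta["group"] == "tumor"]
            )
            for t in truth.sponge_triplets:
                total += 1
                hits += delta_i(t, norm).delta_i > 0
        assert hits >= 0.9 * total


class TestPermutationTest:
    def test_extreme_observation_gives_add_one_floor(self):
        rng = np.random.default_rng(0)
        n = 400
        z = rng.normal(size=n)
        u = (np.argsort(np.argsort(z)) + 1) / (n + 1)
        x = rng.normal(size=n)
        y = np.where(u > 0.5, x, -x)          # dependence visible only given z
        m = toy_matrix(np.vstack([z, x, y]), ["lncRNA", "miRNA", "mRNA"])
        res = permutation_test(("g0", "g1", "g2"), m, n_permutations=500, seed=1)
        assert res.p_value == pytest.approx(1 / 501)

    def test_same_seed_reproduces_p(self, small_normalized):
        norm, meta, truth = small_normalized
        t = truth.sponge_triplets[0]
        r1 = permutation_test(t, norm, seed=42)
        r2 = permutation_test(t, norm, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.delta_i == r2.delta_i

    def test_p_value_bounds_and_delta_consistency(self, small_normalized):
        norm, _, truth = small_normalized
        for t in truth.sponge_triplets:
            r = permutation_test(t, norm, n_permutations=200, seed=0)
            assert 1 / 201 <= r.p_value <= 1.0
            assert r.delta_i == r.cmi - r.mi
            assert r.mi >= 0 and r.cmi >= 0

    def test_invalid_permutation_count(self, small_normalized):
        norm, _, truth = small_normalized
        with pytest.raises(ValueError):
            permutation_test(truth.sponge_triplets[0], norm, n_permutations=0)

    def test_joint_sample_relabeling_invariance(self, rng):
        """Permuting all three profiles by one shared shuffle leaves p unchanged."""
        vals = rng.lognormal(size=(3, 80))
        m1 = toy_matrix(vals, ["lncRNA", "miRNA", "mRNA"])
        perm = rng.permutation(80)
        m2 = toy_matrix(vals[:, perm], ["lncRNA", "miRNA", "mRNA"])
        r1 = permutation_test(("g0", "g1", "g2"), m1, n_permutations=300, seed=9)
        r2 = permutation_test(("g0", "g1", "g2"), m2, n_permutations=300, seed=9)
        assert r1.delta_i == pytest.approx(r2.delta_i, abs=1e-12)
        assert abs(r1.p_value - r2.p_value) < 0.05


class TestScreen:
    def test_empty_list(self, small_normalized):
        norm, _, _ = small_normalized
        assert screen_triplets([], norm) == ([], [])

    def test_p_equal_to_alpha_not_selected(self):
        rng = np.random.default_rng(3)
        n = 400
        z = rng.normal(size=n)
        u = (np.argsort(np.argsort(z)) + 1) / (n + 1)
        x = rng.normal(size=n)
        y = np.where(u > 0.5, x, -x)
        m = toy_matrix(np.vstack([z, x, y]), ["lncRNA", "miRNA", "mRNA"])
        significant, results = screen_triplets(
            [("g0", "g1", "g2")], m, alpha=0.01, n_permutations=99, seed=0
        )
        assert results[0].p_value == pytest.approx(0.01)
        assert significant == []
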