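"""Lennard-Jones stack, the sequence free-energy surrogate, and the combined
refinement energy with its analytic gradient."""

import numpy as np
import pytest

from rnacodesign.cg_io import CGRNAStructure
from rnacodesign.energy import (EnergyParams, energy_E, energy_gradient,
                                fit_sdfe, lj_pair, lj_total,
                                lj_total_gradient, load_stacking_table,
                                nn_free_energy_oracle, sequence_to_soft,
                                total_physical_energy)

PARAMS = EnergyParams()


def random_structure(rng, lr=8, scale=6.0):
    return rng.normal(scale=scale, size=(lr, 3, 3))


def lj_bruteforce(coords, params):
    cloud = coords.reshape(-1, 3)
    res = np.repeat(np.arange(coords.shape[0]), 3)
    total = 0.0
    for i in range(len(cloud)):
        for j in range(i + 1, len(cloud)):
            if abs(res[i] - res[j]) < params.exclusion:
                continue
            d = np.linalg.norm(cloud[i] - cloud[j])
            if d > params.cutoff:
                continue
            s6 = (params.sigma_lj / d) ** 6
            total += 4 * params.epsilon * (s6 * s6 - s6)
    return total


class TestLJPair:
    def test_zero_crossing_at_sigma(self):
        assert lj_pair(PARAMS.sigma_lj, PARAMS) == 0.0

    def test_well_depth_at_minimum(self):
        d_min = PARAMS.sigma_lj * 2 ** (1 / 6)
        assert lj_pair(d_min, PARAMS) == pytest.approx(-PARAMS.epsilon,
                                                       rel=1e-12)

    def test_repulsive_below_sigma(self):
        # independent scalar evaluation of the formula
        d, eps, sig = 3.0, 0.2, 3.5
        expected = 4 * eps * ((sig / d) ** 12 - (sig / d) ** 6)
        assert expected > 0
        assert lj_pair(d, PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_at_long_range(self):
        assert abs(lj_pair(10 * PARAMS.sigma_lj, PARAMS)) < 1e-6

    def test_unique_minimum_on_grid(self):
        grid = np.linspace(0.8 * PARAMS.sigma_lj, 3 * PARAMS.sigma_lj, 2001)
        vals = lj_pair(grid, PARAMS)
        assert grid[np.argmin(vals)] == pytest.approx(
            PARAMS.sigma_lj * 2 ** (1 / 6), abs=5e-3)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            lj_pair(0.0, PARAMS)
        with pytest.raises(ValueError):
            lj_pair(-1.0, PARAMS)


class TestLJTotal:
    def test_adjacent_only_structure_scores_zero(self):
        # 2 residues: all inter-residue separations are 1 < exclusion=2
        coords = np.random.default_rng(0).normal(size=(2, 3, 3))
        assert lj_total(coords, PARAMS) == 0.0

    def test_matches_bruteforce(self, rng):
        coords = random_structure(rng)
        assert lj_total(coords, PARAMS) == pytest.approx(
            lj_bruteforce(coords, PARAMS), rel=1e-10)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        coords = random_structure(rng)
        rot = Rotation.random(random_state=1).as_matrix()
        moved = (coords.reshape(-1, 3) @ rot.T + [4, 5, 6]).reshape(coords.shape)
        assert lj_total(moved, PARAMS) == pytest.approx(
            lj_total(coords, PARAMS), rel=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        coords = random_structure(rng, lr=5)
        grad = lj_total_gradient(coords, PARAMS)
        eps = 1e-6
        for idx in [(0, 0, 0), (2, 1, 2), (4, 2, 1)]:
            up, dn = coords.copy(), coords.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd = (lj_total(up, PARAMS) - lj_total(dn, PARAMS)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestFreeEnergyOracle:
    def test_length_two_equals_single_table_entry(self):
        table = load_stacking_table()
        # G/C-free dinucleotide: the composition term contributes zero
        assert nn_free_energy_oracle("UA") == pytest.approx(table["UA"])

    def test_gc_rich_more_stable(self):
        assert nn_free_energy_oracle("GCGCGC") < nn_free_energy_oracle("AUAUAU")

    def test_hand_summed_values(self):
        table = load_stacking_table()
        seq = "GAUC"
        expected = table["GA"] + table["AU"] + table["UC"] + 2 * (-0.1)
        assert nn_free_energy_oracle(seq) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            nn_free_energy_oracle("A")
        with pytest.raises(ValueError):
            nn_free_energy_oracle("ACGT")

    def test_table_has_all_16_dinucleotides(self):
        table = load_stacking_table()
        assert len(table) == 16
        assert all(v < 0 for v in table.values())


def random_sequences(rng, n, lmin=10, lmax=30):
    return ["".join(rng.choice(list("ACGU"), size=rng.integers(lmin, lmax + 1)))
            for _ in range(n)]


class TestSDFE:
    def test_constant_oracle_is_learned(self, rng):
        seqs = random_sequences(rng, 200)
        model = fit_sdfe(seqs, oracle=lambda s: 0.0, seed=0)
        assert model.heldout_rmse < 0.05
        assert model.predict("ACGUACGU") == pytest.approx(0.0, abs=0.05)

    def test_surrogate_generalizes_to_oracle(self, rng):
        seqs = random_sequences(rng, 2000)
        sd = np.std([nn_free_energy_oracle(s) for s in seqs])
        model = fit_sdfe(seqs, nn_free_energy_oracle, seed=1)
        assert model.heldout_rmse < 0.1 * sd

    def test_seeded_determinism(self, rng):
        seqs = random_sequences(rng, 150)
        m1 = fit_sdfe(seqs, nn_free_energy_oracle, seed=5)
        m2 = fit_sdfe(seqs, nn_free_energy_oracle, seed=5)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.bias == m2.bias

    def test_too_few_sequences(self, rng):
        with pytest.raises(ValueError):
            fit_sdfe(random_sequences(rng, 50), nn_free_energy_oracle)

    def test_soft_gradient_matches_finite_differences(self, sdfe):
        rng = np.random.default_rng(3)
        soft = rng.dirichlet(np.ones(4), size=8)
        grad = sdfe.gradient_soft(soft)
        eps = 1e-6
        for idx in [(0, 0), (3, 2), (7, 1)]:
            up, dn = soft.copy(), soft.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd = (sdfe.predict_soft(up) - sdfe.predict_soft(dn)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_hard_sequence_equals_onehot_prediction(self, sdfe):
        seq = "GCAUGCAU"
        assert sdfe.predict(seq) == pytest.approx(
            sdfe.predict_soft(sequence_to_soft(seq)))


class TestCombinedEnergy:
    def test_additive_decomposition(self, sdfe, rng):
        coords = random_structure(rng)
        seq = "ACGUACGU"
        assert total_physical_energy(coords, seq, sdfe, PARAMS) == \
            pytest.approx(lj_total(coords, PARAMS) + sdfe.predict(seq))

    def test_energy_E_perfect_prediction(self, sdfe, rng):
        coords = random_structure(rng)
        seq = "ACGUACGU"
        u = total_physical_energy(coords, seq, sdfe, PARAMS)
        assert energy_E(coords, coords, seq, sdfe, PARAMS) == \
            pytest.approx(PARAMS.alpha * u, abs=1e-9)

    def test_energy_E_component_reassembly(self, sdfe, rng):
        from rnacodesign.geometry import kabsch_align
        pred = random_structure(rng)
        target = random_structure(rng)
        seq = "ACGUACGU"
        _, aligned = kabsch_align(pred.reshape(-1, 3), target.reshape(-1, 3))
        quad = np.sum((aligned - target.reshape(-1, 3)) ** 2)
        expected = quad / (2 * PARAMS.sigma_gauss ** 2) + \
            PARAMS.alpha * total_physical_energy(pred, seq, sdfe, PARAMS)
        assert energy_E(pred, target, seq, sdfe, PARAMS) == \
            pytest.approx(expected, rel=1e-10)

    def test_gradient_zero_at_target_without_energy(self, sdfe, rng):
        params = EnergyParams(alpha=0.0)
        coords = random_structure(rng)
        grad = energy_gradient(coords, coords, "ACGUACGU", sdfe, params)
        np.testing.assert_allclose(grad, 0.0, atol=1e-9)

    def test_gradient_closed_form_without_energy(self, sdfe, rng):
        from rnacodesign.geometry import kabsch_align
        params = EnergyParams(alpha=0.0, sigma_gauss=2.0)
        pred = random_structure(rng, lr=6)
        target = random_structure(rng, lr=6)
        sup, aligned = kabsch_align(pred.reshape(-1, 3), target.reshape(-1, 3))
        expected = ((aligned - target.reshape(-1, 3)) @ sup.rotation /
                    params.sigma_gauss ** 2).reshape(pred.shape)
        grad = energy_gradient(pred, target, "ACGUAC", sdfe, params)
        np.testing.assert_allclose(grad, expected, atol=1e-10)

    def test_gradient_matches_central_finite_differences(self, sdfe):
        rng = np.random.default_rng(5)
        pred = rng.normal(scale=4.0, size=(6, 3, 3))
        target = rng.normal(scale=4.0, size=(6, 3, 3))
        seq = "ACGUAC"
        grad = energy_gradient(pred, target, seq, sdfe, PARAMS)
        eps = 1e-4
        fd = np.zeros_like(grad)
        for idx in np.ndindex(pred.shape):
            up, dn = pred.copy(), pred.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd[idx] = (energy_E(up, target, seq, sdfe, PARAMS) -
                       energy_E(dn, target, seq, sdfe, PARAMS)) / (2 * eps)
        rel = np.abs(grad - fd).max() / np.abs(fd).max()
        assert rel < 1e-3

    def test_descent_direction_reduces_energy(self, sdfe):
        rng = np.random.default_rng(8)
        seq = "ACGUACGU"
        pred = rng.normal(scale=4.0, size=(8, 3, 3))
        target = rng.normal(scale=4.0, size=(8, 3, 3))
        e0 = energy_E(pred, target, seq, sdfe, PARAMS)
        grad = energy_gradient(pred, target, seq, sdfe, PARAMS)
        step = 1e-2
        for _ in range(30):  # backtracking
            e1 = energy_E(pred - step * grad, target, seq, sdfe, PARAMS)
            if e1 < e0:
                break
            step /= 2
        assert e1 < e0

    def test_length_mismatch(self, sdfe):
        with pytest.raises(ValueError):
            energy_E(np.zeros((3, 3, 3)), np.zeros((4, 3, 3)), "ACG", sdfe)


class TestEnergyParams:
    @pytest.mark.parametrize("kwargs", [
        {"epsilon": 0.0}, {"sigma_lj": -1.0}, {"sigma_gauss": 0.0},
        {"alpha": -0.1}, {"exclusion": 0}, {"cutoff": 2.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnergyParams(**kwargs)
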