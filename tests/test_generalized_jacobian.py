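"""Parameter sampling and the analytic local Jacobian vs its oracle."""

import numpy as np
import pytest

import trophicmeta as tm
from trophicmeta.generalized_jacobian import (
    PARAMETER_RANGES,
    params_from_frame,
    params_to_frame,
)

from conftest import chain_web


def random_instance(seed, S_max=15):
    rng = np.random.default_rng(seed)
    S = int(rng.integers(4, S_max + 1))
    web = tm.generate_niche_web(S, 0.2, rng)
    params = tm.sample_patch_params(web, 3, rng)
    return web, params, rng


class TestSampling:
    def test_branching_invariants(self, small_web, rng):
        params = tm.sample_patch_params(small_web, 10, rng)
        params.validate(small_web)
        has_pred = small_web.has_predator
        has_prey = small_web.consumers
        assert np.allclose(params.beta.sum(axis=2)[:, has_pred], 1.0)
        assert np.allclose(params.chi.sum(axis=2)[:, has_prey], 1.0)
        assert np.all(params.sigma[:, ~has_pred] == 0.0)
        assert np.array_equal(params.rho.astype(bool), has_prey)

    def test_single_predator_gets_full_share(self):
        feeding = np.zeros((2, 2), dtype=bool)
        feeding[1, 0] = True
        web = chain_web(feeding)
        params = tm.sample_patch_params(web, 4, np.random.default_rng(0))
        assert np.all(params.beta[:, 0, 1] == 1.0)
        assert np.all(params.chi[:, 1, 0] == 1.0)

    def test_uniform_range_means(self):
        # mortality elasticity is Uniform(1, 1.5): mean 1.25 over many draws
        feeding = np.zeros((2, 2), dtype=bool)
        feeding[1, 0] = True
        web = chain_web(feeding)
        params = tm.sample_patch_params(web, 5000, np.random.default_rng(3))
        assert params.mu.mean() == pytest.approx(1.25, abs=0.01)
        for name, (lo, hi) in PARAMETER_RANGES.items():
            vals = getattr(params, name)
            assert vals.min() >= lo and vals.max() <= hi

    def test_draws_independent_across_patches(self, small_web):
        params = tm.sample_patch_params(small_web, 2, np.random.default_rng(4))
        assert not np.array_equal(params.phi[0], params.phi[1])

    def test_csv_roundtrip(self, small_web, rng, tmp_path):
        params = tm.sample_patch_params(small_web, 3, rng)
        frame = params_to_frame(params)
        path = tmp_path / "params.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        back = params_from_frame(pd.read_csv(path))
        for name in ("rho", "sigma", "beta", "chi", "phi", "psi", "gamma", "mu"):
            assert np.allclose(getattr(back, name), getattr(params, name))


class TestLocalJacobian:
    def test_isolated_producer(self):
        feeding = np.zeros((1, 1), dtype=bool)
        web = tm.FoodWebTopology(
            S=1, C_target=0.0, niche_values=np.array([0.5]), feeding=feeding,
            trophic_position=np.array([0]),
        )
        web = tm.assign_allometry(web, 42.0)
        params = tm.GeneralizedParams(
            rho=np.zeros(1), sigma=np.zeros((1, 1)),
            beta=np.zeros((1, 1, 1)), chi=np.zeros((1, 1, 1)),
            phi=np.full((1, 1), 0.5), psi=np.full((1, 1), 0.7),
            gamma=np.full((1, 1), 1.0), mu=np.full((1, 1), 1.0),
        )
        J = tm.build_local_jacobian(web, params, 0).matrix
        assert J == pytest.approx(np.array([[-0.5]]))  # alpha * (phi - mu)

    def test_two_species_chain_hand_derivation(self):
        feeding = np.zeros((2, 2), dtype=bool)
        feeding[1, 0] = True
        web = chain_web(feeding)
        alpha = web.turnover
        params = tm.GeneralizedParams(
            rho=np.array([0.0, 1.0]),
            sigma=np.array([[1.0, 0.0]]),
            beta=np.array([[[0.0, 1.0], [0.0, 0.0]]]),
            chi=np.array([[[0.0, 0.0], [1.0, 0.0]]]),
            phi=np.array([[0.8, 0.8]]),
            psi=np.array([[0.7, 0.7]]),
            gamma=np.array([[1.2, 1.2]]),
            mu=np.array([[1.0, 1.0]]),
        )
        J = tm.build_local_jacobian(web, params, 0).matrix
        expected = np.array(
            [
                [alpha[0] * (0.8 - 1.2), -alpha[0] * 0.7],
                [alpha[1] * 1.2, alpha[1] * (0.7 - 1.0)],
            ]
        )
        assert J == pytest.approx(expected)
        # and the hand result agrees with the finite-difference oracle
        assert tm.finite_difference_jacobian(web, params, 0) == pytest.approx(
            J, abs=1e-8
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_finite_difference_oracle(self, seed):
        web, params, _ = random_instance(seed)
        for k in range(3):
            J = tm.build_local_jacobian(web, params, k).matrix
            Jfd = tm.finite_difference_jacobian(web, params, k)
            assert np.abs(J - Jfd).max() < 1e-6

    def test_structural_sparsity(self, small_web, rng):
        params = tm.sample_patch_params(small_web, 2, rng)
        J = tm.build_local_jacobian(small_web, params, 0).matrix
        feeding = small_web.feeding
        shared_pred = feeding.T @ feeding  # n and m share a predator
        mask = (
            np.eye(small_web.S, dtype=bool)
            | feeding
            | feeding.T
            | shared_pred.astype(bool)
        )
        assert np.all(J[~mask] == 0.0)

    def test_producer_row_diagonal_only_when_unpredated(self):
        # two independent producers, one consumer eating only the first
        feeding = np.zeros((3, 3), dtype=bool)
        feeding[2, 0] = True
        web = chain_web(feeding)
        params = tm.sample_patch_params(web, 1, np.random.default_rng(8))
        J = tm.build_local_jacobian(web, params, 0).matrix
        # producer 1 has sigma = 0 and no predators: only its diagonal entry
        row = J[1].copy()
        row[1] = 0.0
        assert np.all(row == 0.0)
        assert J[1, 1] != 0.0

    def test_turnover_scaling_scales_spectrum(self, small_web, rng):
        from dataclasses import replace

        params = tm.sample_patch_params(small_web, 1, rng)
        J1 = tm.build_local_jacobian(small_web, params, 0).matrix
        scaled = replace(
            small_web, turnover=3.0 * small_web.turnover
        )
        J3 = tm.build_local_jacobian(scaled, params, 0).matrix
        e1 = np.sort_complex(np.linalg.eigvals(J1))
        e3 = np.sort_complex(np.linalg.eigvals(J3))
        assert np.allclose(3.0 * e1, e3)


class TestNormalizedRhs:
    def test_steady_state_at_unit_densities(self, small_web, rng):
        params = tm.sample_patch_params(small_web, 3, rng)
        for k in range(3):
            rates = tm.normalized_rhs(small_web, params, k, np.ones(small_web.S))
            assert np.abs(rates).max() < 1e-14

    def test_producer_power_law(self):
        # isolated producer with phi = mu = 1: b - b = 0 at any density
        feeding = np.zeros((1, 1), dtype=bool)
        web = tm.FoodWebTopology(
            S=1, C_target=0.0, niche_values=np.array([0.5]), feeding=feeding,
            trophic_position=np.array([0]),
        )
        web = tm.assign_allometry(web, 42.0)
        params = tm.GeneralizedParams(
            rho=np.zeros(1), sigma=np.zeros((1, 1)),
            beta=np.zeros((1, 1, 1)), chi=np.zeros((1, 1, 1)),
            phi=np.ones((1, 1)), psi=np.ones((1, 1)),
            gamma=np.ones((1, 1)), mu=np.ones((1, 1)),
        )
        assert tm.normalized_rhs(web, params, 0, np.array([2.0])) == pytest.approx(
            [0.0]
        )

    def test_rejects_non_positive_density(self, small_web, rng):
        params = tm.sample_patch_params(small_web, 1, rng)
        b = np.ones(small_web.S)
        b[0] = 0.0
        with pytest.raises(ValueError):
            tm.normalized_rhs(small_web, params, 0, b)
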