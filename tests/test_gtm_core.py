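"""Unit and property tests for the core GTM machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pgtm
from pgtm.gtm import manifold_from_pca


# ---------------------------------------------------------------------------
# Latent grid
# ---------------------------------------------------------------------------


class TestLatentGrid:
    def test_small_lattice_coordinates(self):
        grid = pgtm.build_latent_grid(3, 2)
        assert sorted(map(tuple, grid.node_coords.tolist())) == sorted(
            (x, y) for x in (-1.0, 0.0, 1.0) for y in (-1.0, 0.0, 1.0)
        )
        assert sorted(map(tuple, grid.rbf_coords.tolist())) == sorted(
            (x, y) for x in (-1.0, 1.0) for y in (-1.0, 1.0)
        )

    @pytest.mark.parametrize(
        "k_side,m_side,n_nodes,n_rbf", [(29, 18, 841, 324), (3, 2, 9, 4)]
    )
    def test_grid_sizes(self, k_side, m_side, n_nodes, n_rbf):
        grid = pgtm.build_latent_grid(k_side, m_side)
        assert grid.n_nodes == n_nodes
        assert grid.n_rbf == n_rbf

    @pytest.mark.parametrize("k_side,m_side", [(1, 1), (2, 1), (1, 2), (2, 3)])
    def test_degenerate_grids_rejected(self, k_side, m_side):
        with pytest.raises(ValueError):
            pgtm.build_latent_grid(k_side, m_side)


# ---------------------------------------------------------------------------
# RBF basis
# ---------------------------------------------------------------------------


class TestRBFBasis:
    def test_hand_computed_width_and_value(self):
        # 2x2 centers at the corners of [-1,1]^2: distinct-pair squared
        # distances are {8, 8, 4, 4, 4, 4} (duplicated), mean 16/3.
        grid = pgtm.build_latent_grid(3, 2)
        basis = pgtm.compute_rbf_basis(grid, 0.5)
        assert basis.sigma2 == pytest.approx(0.5 * 16 / 3)
        # a node on top of a center activates it fully
        assert basis.phi.max() == pytest.approx(1.0)
        # corner node vs opposite corner center: exp(-8 / (2 sigma2))
        k = np.flatnonzero((grid.node_coords == [1, 1]).all(axis=1))[0]
        m = np.flatnonzero((grid.rbf_coords == [-1, -1]).all(axis=1))[0]
        assert basis.phi[k, m] == pytest.approx(np.exp(-8 / (2 * basis.sigma2)))

    def test_two_center_derived_value(self):
        # centers (-1,-1) and (1,1): mean squared distance 8, w=0.5 ->
        # sigma2 = 4; a node at (1,1) vs the far center gives e^-1.
        grid = pgtm.LatentGrid(
            node_coords=np.array([[1.0, 1.0]]),
            rbf_coords=np.array([[-1.0, -1.0], [1.0, 1.0]]),
            k_side=1,
            m_side=2,
        )
        basis = pgtm.compute_rbf_basis(grid, 0.5)
        assert basis.sigma2 == pytest.approx(4.0)
        assert basis.phi[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert basis.phi[0, 1] == pytest.approx(1.0)

    def test_entries_in_unit_interval(self, small_grid):
        basis = pgtm.compute_rbf_basis(small_grid, 0.4)
        assert ((basis.phi > 0) & (basis.phi <= 1)).all()

    def test_rotation_invariance(self):
        # rotating nodes and centers together by 90 deg permutes rows and
        # columns of phi but leaves its multiset of entries unchanged
        grid = pgtm.build_latent_grid(4, 3)
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        rotated = pgtm.LatentGrid(
            node_coords=grid.node_coords @ rot.T,
            rbf_coords=grid.rbf_coords @ rot.T,
            k_side=4,
            m_side=3,
        )
        a = pgtm.compute_rbf_basis(grid, 0.4)
        b = pgtm.compute_rbf_basis(rotated, 0.4)
        assert a.sigma2 == pytest.approx(b.sigma2)
        assert np.allclose(np.sort(a.phi.ravel()), np.sort(b.phi.ravel()))

    def test_single_center_rejected(self):
        grid = pgtm.LatentGrid(
            node_coords=np.array([[0.0, 0.0]]),
            rbf_coords=np.array([[0.0, 0.0]]),
            k_side=1,
            m_side=1,
        )
        with pytest.raises(ValueError):
            pgtm.compute_rbf_basis(grid, 0.4)


# ---------------------------------------------------------------------------
# PCA initialization
# ---------------------------------------------------------------------------


class TestInitialization:
    def test_planted_plane_noise_variance(self):
        # data on a 2-plane plus isotropic noise of variance v: the third
        # eigenvalue (initial 1/beta) estimates v
        rng = np.random.default_rng(0)
        v = 1e-3
        basis_plane = rng.normal(size=(2, 6))
        data = rng.normal(size=(4000, 2)) @ basis_plane + rng.normal(
            scale=np.sqrt(v), size=(4000, 6)
        )
        grid = pgtm.build_latent_grid(5, 3)
        basis = pgtm.compute_rbf_basis(grid, 0.4)
        manifold = pgtm.initialize_manifold(basis, grid, pgtm.DescriptorMatrix(data))
        assert 1.0 / manifold.beta == pytest.approx(v, rel=0.15)

    def test_node_images_lie_in_principal_plane(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(200, 5)) * np.array([3.0, 2.0, 0.5, 0.3, 0.1])
        data -= data.mean(axis=0)
        grid = pgtm.build_latent_grid(4, 3)
        basis = pgtm.compute_rbf_basis(grid, 0.4)
        manifold = pgtm.initialize_manifold(basis, grid, pgtm.DescriptorMatrix(data))
        from pgtm.gtm import pca_spectrum

        _, _, vecs = pca_spectrum(data)
        Y = manifold.node_positions
        # residual of Y after projection on the first two principal axes
        proj = Y @ vecs[:, :2] @ vecs[:, :2].T
        assert np.abs(Y - proj).max() < 1e-8

    def test_w_matches_normal_equations_oracle(self):
        # independent least-squares oracle on a 5-node toy grid
        rng = np.random.default_rng(2)
        grid = pgtm.LatentGrid(
            node_coords=np.array(
                [[-1.0, -1.0], [1.0, -1.0], [0.0, 0.0], [-1.0, 1.0], [1.0, 1.0]]
            ),
            rbf_coords=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            k_side=0,
            m_side=0,
        )
        basis = pgtm.compute_rbf_basis(grid, 0.7)
        data = pgtm.DescriptorMatrix(rng.normal(size=(50, 4)))
        manifold = pgtm.initialize_manifold(basis, grid, data)
        from pgtm.gtm import pca_spectrum

        mean, eigvals, vecs = pca_spectrum(data.values)
        target = mean + grid.node_coords @ vecs[:, :2].T
        phi = basis.phi
        W_oracle = np.linalg.solve(phi.T @ phi, phi.T @ target)
        assert np.allclose(manifold.W, W_oracle, atol=1e-8)

    def test_rank_deficient_data_triggers_guard(self):
        # data spanning only 2 dimensions: third eigenvalue ~ 0, beta capped
        rng = np.random.default_rng(3)
        data = np.zeros((100, 4))
        data[:, :2] = rng.normal(size=(100, 2))
        grid = pgtm.build_latent_grid(3, 2)
        basis = pgtm.compute_rbf_basis(grid, 0.4)
        manifold = pgtm.initialize_manifold(basis, grid, pgtm.DescriptorMatrix(data))
        assert np.isfinite(manifold.beta) and manifold.beta > 0


# ---------------------------------------------------------------------------
# Responsibilities and log-likelihood vs naive oracles
# ---------------------------------------------------------------------------


def naive_responsibilities(manifold, data):
    """Double-loop evaluation of the conditional densities and posteriors."""
    Y = manifold.basis.phi @ manifold.W
    N, K, D = data.values.shape[0], Y.shape[0], data.dim
    beta = manifold.beta
    dens = np.zeros((N, K))
    for n in range(N):
        for k in range(K):
            d2 = np.sum((Y[k] - data.values[n]) ** 2)
            dens[n, k] = (beta / (2 * np.pi)) ** (D / 2) * np.exp(-beta / 2 * d2)
    resp = dens / dens.sum(axis=1, keepdims=True)
    llh = np.log(dens.mean(axis=1))
    return resp, llh


class TestResponsibilities:
    def test_matches_naive_oracle(self, toy_setup):
        manifold, data = toy_setup
        resp = pgtm.responsibilities(manifold, data)
        oracle_r, oracle_llh = naive_responsibilities(manifold, data)
        assert np.allclose(resp.values, oracle_r, atol=1e-12)
        assert np.allclose(resp.per_molecule_llh, oracle_llh, atol=1e-12)
        assert pgtm.log_likelihood(manifold, data) == pytest.approx(
            oracle_llh.mean(), abs=1e-12
        )

    def test_single_node_gives_unit_responsibility(self):
        grid = pgtm.LatentGrid(
            node_coords=np.array([[0.0, 0.0]]),
            rbf_coords=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            k_side=1,
            m_side=2,
        )
        basis = pgtm.compute_rbf_basis(grid, 0.4)
        manifold = pgtm.Manifold(
            W=np.ones((2, 3)), beta=2.0, basis=basis, grid=grid, dim=3
        )
        resp = pgtm.responsibilities(
            manifold, pgtm.DescriptorMatrix(np.random.default_rng(0).normal(size=(5, 3)))
        )
        assert np.allclose(resp.values, 1.0)

    def test_equidistant_point_splits_half_half(self):
        # two near nodes equidistant from the point, a third far away
        grid = pgtm.LatentGrid(
            node_coords=np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            rbf_coords=np.eye(3, 2) * 0,  # unused
            k_side=0,
            m_side=0,
        )
        basis = pgtm.RBFBasis(phi=np.eye(3), sigma2=1.0, width_factor=1.0)
        W = np.array([[0.0, 1.0], [0.0, -1.0], [50.0, 0.0]])
        manifold = pgtm.Manifold(W=W, beta=3.0, basis=basis, grid=grid, dim=2)
        resp = pgtm.responsibilities(
            manifold, pgtm.DescriptorMatrix(np.array([[0.0, 0.0]]))
        )
        assert resp.values[0, 0] == pytest.approx(0.5, abs=1e-10)
        assert resp.values[0, 1] == pytest.approx(0.5, abs=1e-10)
        assert resp.values[0, 2] < 1e-10

    def test_closed_form_single_node_1d(self):
        # K=1, D=1, beta=1, point on the node: ln((1/2pi)^(1/2))
        grid = pgtm.LatentGrid(
            node_coords=np.array([[0.0, 0.0]]),
            rbf_coords=np.zeros((1, 2)),
            k_side=1,
            m_side=1,
        )
        basis = pgtm.RBFBasis(phi=np.array([[1.0]]), sigma2=1.0, width_factor=1.0)
        manifold = pgtm.Manifold(
            W=np.array([[0.0]]), beta=1.0, basis=basis, grid=grid, dim=1
        )
        llh = pgtm.log_likelihood(manifold, pgtm.DescriptorMatrix(np.array([[0.0]])))
        assert llh == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)
        assert llh == pytest.approx(-0.91894, abs=1e-5)

    def test_duplicating_molecules_preserves_mean_llh(self, toy_setup):
        manifold, data = toy_setup
        doubled = pgtm.DescriptorMatrix(np.vstack([data.values, data.values]))
        assert pgtm.log_likelihood(manifold, doubled) == pytest.approx(
            pgtm.log_likelihood(manifold, data), abs=1e-12
        )

    def test_llh_decreases_with_distance_from_manifold(self, toy_setup):
        manifold, data = toy_setup
        shift = np.ones(3) / np.sqrt(3)
        llhs = [
            pgtm.log_likelihood(
                manifold, pgtm.DescriptorMatrix(data.values + t * shift)
            )
            for t in (0.0, 2.0, 5.0, 10.0)
        ]
        assert all(a > b for a, b in zip(llhs, llhs[1:]))

    def test_small_beta_drives_llh_down(self, toy_setup):
        manifold, data = toy_setup
        from dataclasses import replace

        llh_small = pgtm.log_likelihood(replace(manifold, beta=1e-8), data)
        assert llh_small < pgtm.log_likelihood(manifold, data)
        assert llh_small < -10

    def test_translation_equivariance(self):
        # translating the data (and hence the PCA initialization) by a
        # constant vector leaves responsibilities unchanged.  Exactness
        # requires the constant function to lie in the RBF span; at the
        # published basis resolution (18x18 RBFs, w=0.4) the representation
        # error is < 1e-6.
        rng = np.random.default_rng(42)
        grid = pgtm.build_latent_grid(29, 18)
        basis = pgtm.compute_rbf_basis(grid, 0.4)
        data = pgtm.DescriptorMatrix(rng.normal(size=(50, 4)))
        shift = np.array([5.0, -3.0, 2.0, 1.0])
        shifted = pgtm.DescriptorMatrix(data.values + shift)
        m0 = pgtm.initialize_manifold(basis, grid, data)
        m1 = pgtm.initialize_manifold(basis, grid, shifted)
        r0 = pgtm.responsibilities(m0, data).values
        r1 = pgtm.responsibilities(m1, shifted).values
        assert np.abs(r0 - r1).max() < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(1, 12),
        beta=st.floats(0.05, 50.0),
    )
    def test_rows_sum_to_one_property(self, seed, n, beta):
        rng = np.random.default_rng(seed)
        grid = pgtm.build_latent_grid(3, 2)
        basis = pgtm.compute_rbf_basis(grid, 0.4)
        manifold = pgtm.Manifold(
            W=rng.normal(scale=3.0, size=(4, 3)),
            beta=beta,
            basis=basis,
            grid=grid,
            dim=3,
        )
        data = pgtm.DescriptorMatrix(rng.normal(scale=4.0, size=(n, 3)))
        resp = pgtm.responsibilities(manifold, data)
        assert np.allclose(resp.values.sum(axis=1), 1.0, atol=1e-10)
        assert (resp.values >= 0).all() and (resp.values <= 1).all()


# ---------------------------------------------------------------------------
# EM step and training
# ---------------------------------------------------------------------------


def naive_beta_update(manifold_new_w, data, R):
    """Loop evaluation of the noise update: responsibility-weighted mean
    squared node-molecule distance per dimension."""
    Y = manifold_new_w.basis.phi @ manifold_new_w.W
    total = 0.0
    for n in range(data.n):
        for k in range(Y.shape[0]):
            total += R[n, k] * np.sum((Y[k] - data.values[n]) ** 2)
    return total / (data.n * data.dim)


class TestEMStep:
    @pytest.mark.parametrize("lam", [0.0, 3.236])
    def test_penalized_objective_non_decreasing(self, toy_setup, lam):
        manifold, data = toy_setup
        prev = pgtm.penalized_objective(manifold, data, lam)
        for _ in range(30):
            manifold = pgtm.em_step(manifold, data, lam)
            cur = pgtm.penalized_objective(manifold, data, lam)
            assert cur >= prev - 1e-9 * abs(prev)
            assert manifold.beta > 0
            prev = cur

    def test_beta_update_matches_loop_oracle(self, toy_setup):
        manifold, data = toy_setup
        R = pgtm.responsibilities(manifold, data).values
        stepped = pgtm.em_step(manifold, data, 0.5)
        assert 1.0 / stepped.beta == pytest.approx(
            naive_beta_update(stepped, data, R), rel=1e-12
        )

    def test_fixed_point_of_em(self):
        # a converged model is (nearly) invariant under one more EM step
        universe = pgtm.generate_gtm_universe(
            k_side=6, m_side=3, D=10, N=400, true_beta=4.0, seed=3
        )
        data = universe.as_descriptor_matrix()
        config = pgtm.TrainingConfig(k_side=6, m_side=3, max_iter=3000, rel_tol=0.0)
        manifold = pgtm.train_sgtm(data, config)
        stepped = pgtm.em_step(manifold, data, config.lambda_reg)
        rel_dw = np.linalg.norm(stepped.W - manifold.W) / np.linalg.norm(manifold.W)
        assert rel_dw < 1e-6

    def test_ill_conditioned_lambda_zero_warns(self):
        # more RBFs than occupied nodes makes the normal equations singular
        rng = np.random.default_rng(5)
        grid = pgtm.build_latent_grid(5, 5)
        basis = pgtm.compute_rbf_basis(grid, 0.4)
        data = pgtm.DescriptorMatrix(rng.normal(size=(6, 3)))
        manifold = pgtm.initialize_manifold(basis, grid, data)
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            pgtm.em_step(manifold, data, 0.0)


class TestTrainSGTM:
    def test_history_matches_composed_em_steps(self, planted_universe):
        data = pgtm.DescriptorMatrix(planted_universe.descriptors[:200])
        config = pgtm.TrainingConfig(k_side=5, m_side=3, max_iter=7, rel_tol=0.0)
        trained = pgtm.train_sgtm(data, config)
        grid = pgtm.build_latent_grid(5, 3)
        basis = pgtm.compute_rbf_basis(grid, config.width_factor)
        manual = pgtm.initialize_manifold(basis, grid, data)
        history = [pgtm.penalized_objective(manual, data, config.lambda_reg)]
        for _ in range(7):
            manual = pgtm.em_step(manual, data, config.lambda_reg,
                                  config.reg_convention)
            history.append(pgtm.penalized_objective(manual, data, config.lambda_reg))
        assert np.allclose([h for _, h in trained.training_history], history)
        assert np.array_equal(trained.W, manual.W)

    def test_beta_recovery_on_planted_data(self, trained_small, planted_universe):
        manifold, _ = trained_small
        assert manifold.beta == pytest.approx(planted_universe.true_beta, rel=0.2)

    def test_final_llh_at_least_initial(self, trained_small):
        manifold, _ = trained_small
        history = [v for _, v in manifold.training_history]
        assert history[-1] >= history[0]
        assert all(b >= a - 1e-9 * abs(a) for a, b in zip(history, history[1:]))

    def test_non_convergence_flagged_not_fatal(self, planted_universe):
        data = pgtm.DescriptorMatrix(planted_universe.descriptors[:300])
        config = pgtm.TrainingConfig(k_side=6, m_side=3, max_iter=2, rel_tol=1e-14)
        trained = pgtm.train_sgtm(data, config)
        assert trained.converged is False
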