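import numpy as np
import pytest

import pgtm


@pytest.fixture(scope="session")
def small_grid():
    return pgtm.build_latent_grid(3, 2)


@pytest.fixture(scope="session")
def toy_setup():
    """A tiny manifold + data pair for oracle comparisons (K=9, M=4, D=3)."""
    rng = np.random.default_rng(42)
    grid = pgtm.build_latent_grid(3, 2)
    basis = pgtm.compute_rbf_basis(grid, 0.4)
    W = rng.normal(size=(grid.n_rbf, 3))
    manifold = pgtm.Manifold(W=W, beta=1.7, basis=basis, grid=grid, dim=3)
    data = pgtm.DescriptorMatrix(rng.normal(size=(7, 3)))
    return manifold, data


@pytest.fixture(scope="session")
def planted_universe():
    """2000 compounds sampled from a planted GTM (beta=4, D=20)."""
    return pgtm.generate_gtm_universe(
        k_side=10, m_side=5, D=20, N=2000, true_beta=4.0, seed=1
    )


@pytest.fixture(scope="session")
def trained_small(planted_universe):
    """An sGTM fitted on the planted universe (unstandardized space)."""
    config = pgtm.TrainingConfig(k_side=10, m_side=5, max_iter=100, rel_tol=1e-5)
    data = planted_universe.as_descriptor_matrix()
    return pgtm.train_sgtm(data, config), data


@pytest.fixture(scope="session")
def small_resp(trained_small):
    manifold, data = trained_small
    return pgtm.responsibilities(manifold, data)
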