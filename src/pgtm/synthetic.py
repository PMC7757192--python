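"""Synthetic universes with known GTM generative structure.

Every fixture the other modules need is generated here, with ground truth
attached:

* :func:`generate_gtm_universe` samples compounds exactly from the GTM
  generative model -- a node is drawn uniformly, the observation is the
  node's image on a planted manifold plus isotropic Gaussian noise of
  variance 1/beta -- so trained models can be checked against the planted
  W and beta.
* :func:`generate_activity_universe` plants per-target activity: potency
  (log IC50) increases with latent distance from a target-specific active
  region, so class landscapes are learnable and the IC50 labeling protocol
  has realistic input.
* :func:`generate_sparse_countlike_descriptors` emulates the statistical
  shape of fragment-count descriptors (sparse non-negative integers, with
  constant and near-constant columns) to exercise the descriptor filter.

The planted W is drawn as smooth random functions on the RBF grid and
rescaled to unit per-dimension spread, so the manifold is curved but
recoverable (a flat planted manifold would make the PCA initialization
trivially perfect and hide EM bugs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtm import DescriptorMatrix, build_latent_grid, compute_rbf_basis

# Activity placement: log10(IC50/nM) ramps from ~0.5 (3 nM) at a target's
# active center to ~4.5 (30 uM) at the far side of the map, spanning the
# labeling protocol's threshold grid.
_LOG_IC50_BASE = 0.5
_LOG_IC50_SLOPE = 2.0
_DEFAULT_NOISE_SCALE = 0.3


@dataclass(frozen=True)
class SyntheticUniverse:
    """Descriptors sampled from a planted GTM, with the generative truth."""

    descriptors: np.ndarray
    true_W: np.ndarray
    true_beta: float
    node_assignments: np.ndarray
    node_coords: np.ndarray
    k_side: int
    m_side: int
    width_factor: float
    seed: int

    @property
    def compound_ids(self) -> list[str]:
        return [f"CPD{i:06d}" for i in range(self.descriptors.shape[0])]

    def as_descriptor_matrix(self) -> DescriptorMatrix:
        return DescriptorMatrix(self.descriptors, ids=self.compound_ids)


@dataclass(frozen=True)
class SyntheticActivityUniverse:
    """A universe plus per-target IC50 tables with planted spatial activity."""

    universe: SyntheticUniverse
    targets: pd.DataFrame
    active_centers: dict[str, np.ndarray]
    noise_scale: float


def generate_gtm_universe(
    k_side: int = 10,
    m_side: int = 5,
    D: int = 20,
    N: int = 2000,
    true_beta: float = 4.0,
    seed: int = 0,
    width_factor: float = 0.4,
) -> SyntheticUniverse:
    """Sample N compounds from a planted GTM mixture.

    The planted manifold is Y = phi W with W random and rescaled so Y has
    unit per-dimension spread; each compound picks a node uniformly and
    adds N(0, 1/true_beta) noise in every dimension.
    """
    if D < 3:
        raise ValueError("D must be >= 3")
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    grid = build_latent_grid(k_side, m_side)
    basis = compute_rbf_basis(grid, width_factor)
    W = rng.normal(size=(grid.n_rbf, D))
    Y = basis.phi @ W
    scale = Y.std()
    if scale > 0:
        W = W / scale
        Y = Y / scale
    nodes = rng.integers(0, grid.n_nodes, size=N)
    noise = rng.normal(scale=1.0 / np.sqrt(true_beta), size=(N, D))
    return SyntheticUniverse(
        descriptors=Y[nodes] + noise,
        true_W=W,
        true_beta=float(true_beta),
        node_assignments=nodes,
        node_coords=grid.node_coords,
        k_side=k_side,
        m_side=m_side,
        width_factor=width_factor,
        seed=seed,
    )


def generate_activity_universe(
    universe: SyntheticUniverse,
    n_targets: int = 10,
    per_target_n: int = 200,
    seed: int = 0,
    noise_scale: float = _DEFAULT_NOISE_SCALE,
) -> SyntheticActivityUniverse:
    """Plant spatially coherent activity for ``n_targets`` targets.

    Each target gets a random active center in latent space; the log10
    IC50 of a sampled compound grows linearly with its (true) latent
    distance from that center, plus Gaussian noise of ``noise_scale`` log
    units.  With ``noise_scale=0`` actives and inactives occupy disjoint
    map regions and are perfectly separable.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if per_target_n < 30:
        raise ValueError("per_target_n must be >= 30 (activity prefilter)")
    rng = np.random.default_rng(seed)
    n = universe.descriptors.shape[0]
    latent = universe.node_coords[universe.node_assignments]
    ids = np.asarray(universe.compound_ids)
    rows = []
    centers: dict[str, np.ndarray] = {}
    for t in range(n_targets):
        tid = f"T{t:03d}"
        center = rng.uniform(-0.8, 0.8, size=2)
        centers[tid] = center
        chosen = rng.choice(n, size=min(per_target_n, n), replace=False)
        dist = np.linalg.norm(latent[chosen] - center, axis=1)
        log_ic50 = (
            _LOG_IC50_BASE
            + _LOG_IC50_SLOPE * dist
            + rng.normal(scale=noise_scale, size=len(chosen))
        )
        for cid, v in zip(ids[chosen], 10.0**log_ic50):
            rows.append((tid, cid, v))
    table = pd.DataFrame(rows, columns=["target_id", "compound_id", "ic50_nM"])
    return SyntheticActivityUniverse(
        universe=universe,
        targets=table,
        active_centers=centers,
        noise_scale=noise_scale,
    )


def generate_sparse_countlike_descriptors(
    N: int, D: int, density: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Sparse non-negative integer counts mimicking fragment descriptors.

    Column j is nonzero with probability ~``density`` (log-spread across
    columns, as fragment frequencies are heavy-tailed); nonzero entries
    are Poisson counts.  The first column is constant and the second holds
    a single outlier, so its std/range ratio is ~1/sqrt(N) and it falls
    under the 2 % near-constant rule for N > 2500; both exercise the
    descriptor filter.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    col_density = density * 10.0 ** rng.uniform(-1, 0.3, size=D)
    col_density = np.clip(col_density, 0.0, 1.0)
    mask = rng.random(size=(N, D)) < col_density
    counts = rng.poisson(lam=2.0, size=(N, D)) + 1
    X = np.where(mask, counts, 0).astype(float)
    if D >= 1:
        X[:, 0] = 3.0  # constant column
    if D >= 2 and N >= 2:
        X[:, 1] = 0.0
        X[0, 1] = 100.0  # near-constant: std << 2 % of range for large N
    return X
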