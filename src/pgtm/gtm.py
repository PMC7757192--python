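"""Standard Generative Topographic Mapping (sGTM).

GTM models a cloud of N compounds in a D-dimensional descriptor space as a
constrained mixture of K isotropic Gaussians whose centers y_k = phi(x_k) W
lie on a smooth 2-D surface (the *manifold*).  The latent points x_k form a
regular square grid in [-1, 1]^2, phi is a fixed radial-basis-function
expansion of the latent coordinates, W is the M x D mixing matrix and beta
the shared noise precision.  W and beta are fitted by EM, maximizing the
per-compound mean log-likelihood with an optional quadratic (weight-decay)
penalty on W.

The module provides the latent grid, the RBF basis, the PCA-based
initialization, the E-step (responsibilities), the log-likelihood, a single
EM step and the full training loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

logger = logging.getLogger("pgtm")

# Default hyperparameters: a 29 x 29 node grid (841 nodes), an 18 x 18 RBF
# grid (324 centers), weight-decay 3.236 and RBF width factor 0.4 -- the
# published "universal map" setting for ChEMBL-scale libraries.
DEFAULT_K_SIDE = 29
DEFAULT_M_SIDE = 18
DEFAULT_LAMBDA = 3.236
DEFAULT_WIDTH_FACTOR = 0.4
DEFAULT_BLOCK_SIZE = 5000

_EIG_FLOOR = 1e-12  # guard for 1/beta when the 3rd eigenvalue is ~0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatentGrid:
    """Square lattices of latent nodes and RBF centers spanning [-1, 1]^2.

    ``node_coords`` is K x 2 and ``rbf_coords`` is M x 2, both in row-major
    order (y varies slowest).  K = k_side**2, M = m_side**2.
    """

    node_coords: np.ndarray
    rbf_coords: np.ndarray
    k_side: int
    m_side: int

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_rbf(self) -> int:
        return self.rbf_coords.shape[0]


@dataclass(frozen=True)
class RBFBasis:
    """The K x M design matrix phi of Gaussian RBF activations.

    ``sigma2`` is the squared RBF width: the mean squared distance between
    distinct RBF-center pairs times the tunable ``width_factor`` w (with the
    default ``sigma_convention='squared'``; see :func:`compute_rbf_basis`).
    """

    phi: np.ndarray
    sigma2: float
    width_factor: float


@dataclass
class Manifold:
    """A fitted GTM: mixing matrix W (M x D), noise precision beta, basis.

    ``training_history`` records (iteration, penalized mean log-likelihood)
    pairs; iteration 0 is the initialization.  ``converged`` is False when
    training stopped at max_iter without reaching the relative tolerance.
    """

    W: np.ndarray
    beta: float
    basis: RBFBasis
    grid: LatentGrid
    dim: int
    training_history: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = True

    @property
    def node_positions(self) -> np.ndarray:
        """Y = phi W: the K x D images of the latent nodes in data space."""
        return self.basis.phi @ self.W


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for GTM training (defaults: published ChEMBL map)."""

    k_side: int = DEFAULT_K_SIDE
    m_side: int = DEFAULT_M_SIDE
    lambda_reg: float = DEFAULT_LAMBDA
    width_factor: float = DEFAULT_WIDTH_FACTOR
    max_iter: int = 100
    rel_tol: float = 1e-4
    seed: int = 0
    block_size: int = DEFAULT_BLOCK_SIZE
    sigma_convention: str = "squared"
    reg_convention: str = "prior"

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")
        if self.width_factor <= 0:
            raise ValueError("width_factor must be positive")
        if self.sigma_convention not in ("squared", "direct"):
            raise ValueError("sigma_convention must be 'squared' or 'direct'")
        if self.reg_convention not in ("prior", "literal"):
            raise ValueError("reg_convention must be 'prior' or 'literal'")


@dataclass
class DescriptorMatrix:
    """An N x D block of (standardized) descriptor values.

    ``column_means`` / ``column_stds`` are the statistics of the frame set
    the standardization was fitted on; they travel with the matrix so that
    library compounds can be projected consistently.
    """

    values: np.ndarray
    descriptor_names: list[str] | None = None
    column_means: np.ndarray | None = None
    column_stds: np.ndarray | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("descriptor values must be a 2-D array")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "DescriptorMatrix":
        ids = [self.ids[i] for i in indices] if self.ids is not None else None
        return DescriptorMatrix(
            self.values[np.asarray(indices)],
            descriptor_names=self.descriptor_names,
            column_means=self.column_means,
            column_stds=self.column_stds,
            ids=ids,
        )


@dataclass
class Responsibilities:
    """Row-stochastic N x K posterior node memberships r_nk.

    ``per_molecule_llh`` holds ln p(t_n) for each compound, i.e. the inner
    term of the mean log-likelihood.
    """

    values: np.ndarray
    per_molecule_llh: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "Responsibilities":
        idx = np.asarray(indices)
        return Responsibilities(self.values[idx], self.per_molecule_llh[idx])


# ---------------------------------------------------------------------------
# Latent grid and RBF basis
# ---------------------------------------------------------------------------


def _square_lattice(side: int) -> np.ndarray:
    axis = np.linspace(-1.0, 1.0, side)
    yy, xx = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def build_latent_grid(k_side: int, m_side: int) -> LatentGrid:
    """Regular node and RBF-center lattices over [-1, 1]^2.

    ``k_side`` and ``m_side`` are the grid sides: K = k_side**2 nodes and
    M = m_side**2 RBF centers.  Both must be at least 2 and the RBF grid may
    not be finer than the node grid.
    """
    if k_side < 2 or m_side < 2:
        raise ValueError("grid sides must be >= 2 (degenerate grid)")
    if m_side > k_side:
        raise ValueError("RBF grid may not be finer than the node grid")
    return LatentGrid(
        node_coords=_square_lattice(k_side),
        rbf_coords=_square_lattice(m_side),
        k_side=k_side,
        m_side=m_side,
    )


def compute_rbf_basis(
    grid: LatentGrid,
    width_factor: float,
    sigma_convention: str = "squared",
) -> RBFBasis:
    """Gaussian RBF activations phi[k, m] = exp(-|x_k - mu_m|^2 / (2 sigma^2)).

    The width is tied to the RBF-center spacing: with the default
    ``sigma_convention='squared'`` the squared width sigma^2 is the mean
    squared Euclidean distance between distinct RBF-center pairs multiplied
    by ``width_factor``; with ``'direct'`` that product is taken as sigma
    itself and squared.
    """
    if width_factor <= 0:
        raise ValueError("width_factor must be positive")
    if grid.n_rbf < 2:
        raise ValueError("need at least 2 RBF centers to define a width")
    d2 = cdist(grid.rbf_coords, grid.rbf_coords, metric="sqeuclidean")
    mean_sq = d2[~np.eye(grid.n_rbf, dtype=bool)].mean()
    if sigma_convention == "squared":
        sigma2 = width_factor * mean_sq
    elif sigma_convention == "direct":
        sigma2 = (width_factor * mean_sq) ** 2
    else:
        raise ValueError("sigma_convention must be 'squared' or 'direct'")
    node_d2 = cdist(grid.node_coords, grid.rbf_coords, metric="sqeuclidean")
    phi = np.exp(-node_d2 / (2.0 * sigma2))
    return RBFBasis(phi=phi, sigma2=float(sigma2), width_factor=float(width_factor))


# ---------------------------------------------------------------------------
# PCA initialization
# ---------------------------------------------------------------------------


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic PCA)."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_spectrum(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, eigenvalues (descending) and sign-fixed eigenvectors of the
    sample covariance (ddof=1)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    centered = values - mean
    cov = centered.T @ centered / max(values.shape[0] - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return mean, eigvals[order], _fix_eigenvector_signs(eigvecs[:, order])


def manifold_from_pca(
    basis: RBFBasis,
    grid: LatentGrid,
    mean: np.ndarray,
    eigvecs2: np.ndarray,
    third_eigenvalue: float,
    dim: int,
) -> Manifold:
    """Build the initial manifold from PCA results.

    W is the least-squares solution of phi W = mean + X U, where X is the
    K x 2 node-coordinate matrix and U the (2 x D) matrix of the first two
    eigenvectors; phi is K x M and non-square, so a pseudo-inverse solve is
    used.  The initial noise variance 1/beta is the third eigenvalue (the
    variance unexplained by the 2-D plane), floored at 1e-12.
    """
    target = mean[None, :] + grid.node_coords @ eigvecs2
    W, *_ = np.linalg.lstsq(basis.phi, target, rcond=None)
    beta = 1.0 / max(float(third_eigenvalue), _EIG_FLOOR)
    return Manifold(W=W, beta=beta, basis=basis, grid=grid, dim=dim)


def initialize_manifold(
    basis: RBFBasis, grid: LatentGrid, data: DescriptorMatrix
) -> Manifold:
    """PCA initialization of W and beta on the given (frame-set) data."""
    if data.dim < 3:
        raise ValueError("need at least 3 descriptors (beta uses the 3rd eigenvalue)")
    if data.n < 3:
        raise ValueError("need at least 3 compounds for PCA initialization")
    mean, eigvals, eigvecs = pca_spectrum(data.values)
    return manifold_from_pca(basis, grid, mean, eigvecs[:, :2].T, eigvals[2], data.dim)


# ---------------------------------------------------------------------------
# E-step, likelihood, EM
# ---------------------------------------------------------------------------


def responsibilities(manifold: Manifold, data: DescriptorMatrix) -> Responsibilities:
    """Posterior node memberships r_nk and per-compound log-likelihoods.

    r_nk is the softmax over nodes of -(beta/2) |y_k - t_n|^2 (the shared
    (beta/2pi)^(D/2) prefactor cancels); the per-compound log-likelihood is
    ln[(1/K) sum_k (beta/2pi)^(D/2) exp(-(beta/2)|y_k - t_n|^2)], computed
    with a max-shift to avoid underflow.
    """
    if data.dim != manifold.dim:
        raise ValueError(
            f"descriptor dimension {data.dim} != manifold dimension {manifold.dim}"
        )
    Y = manifold.node_positions
    d2 = cdist(data.values, Y, metric="sqeuclidean")
    logits = -(manifold.beta / 2.0) * d2
    lse = logsumexp(logits, axis=1)
    R = np.exp(logits - lse[:, None])
    D = manifold.dim
    llh = (
        (D / 2.0) * np.log(manifold.beta / (2.0 * np.pi))
        - np.log(manifold.grid.n_nodes)
        + lse
    )
    return Responsibilities(values=R, per_molecule_llh=llh)


def log_likelihood(manifold: Manifold, data: DescriptorMatrix) -> float:
    """Per-compound mean log-likelihood of the data under the manifold."""
    return float(responsibilities(manifold, data).per_molecule_llh.mean())


def penalized_objective(
    manifold: Manifold, data: DescriptorMatrix, lambda_reg: float
) -> float:
    """Mean log-likelihood minus the weight-decay penalty lambda |W|^2 / (2N).

    With the default ``reg_convention='prior'`` (a fixed zero-mean Gaussian
    prior of precision lambda on the weights) this is the MAP objective the
    EM iteration provably never decreases.
    """
    llh = log_likelihood(manifold, data)
    penalty = lambda_reg * float(np.sum(manifold.W**2)) / (2.0 * data.n)
    return llh - penalty


def _m_step(
    manifold: Manifold,
    data: DescriptorMatrix,
    R: np.ndarray,
    lambda_reg: float,
    reg_convention: str = "prior",
) -> tuple[np.ndarray, float]:
    """One M-step: returns (W_new, beta_new) given responsibilities R (N x K).

    ``reg_convention='prior'`` solves (phi' G phi + (lambda/beta) I) W =
    phi' R T -- the MAP M-step for a fixed Gaussian weight prior of
    precision lambda, which guarantees ascent of the penalized objective.
    ``'literal'`` drops the 1/beta factor (an effective prior precision
    lambda*beta that tightens as the fit sharpens); with it no fixed
    objective is guaranteed monotone.
    """
    phi = manifold.basis.phi
    g = R.sum(axis=0)  # K; diagonal of G
    A = phi.T @ (g[:, None] * phi)
    lam_eff = lambda_reg / manifold.beta if reg_convention == "prior" else lambda_reg
    if lam_eff > 0:
        A = A + lam_eff * np.eye(A.shape[0])
    B = phi.T @ (R.T @ data.values)
    if lam_eff == 0:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            warnings.warn(
                "M-step normal equations ill-conditioned with lambda=0; "
                "solving the weighted least-squares system directly "
                "(consider lambda_reg > 0)",
                RuntimeWarning,
                stacklevel=3,
            )
            # min_W sum_k g_k |phi_k W - z_k|^2 with z_k the responsibility-
            # weighted data mean at node k; numerically far better
            # conditioned than the squared normal equations.
            keep = g > g.max() * 1e-300
            sqrt_g = np.sqrt(g[keep])
            design = sqrt_g[:, None] * phi[keep]
            rhs = (R.T[keep] @ data.values) / sqrt_g[:, None]
            W_new, *_ = np.linalg.lstsq(design, rhs, rcond=None)
        else:
            W_new = np.linalg.solve(A, B)
    else:
        W_new = np.linalg.solve(A, B)
    # beta update with the NEW W (standard EM ordering): 1/beta is the
    # responsibility-weighted mean squared node-compound distance per dim.
    Y_new = phi @ W_new
    d2 = cdist(data.values, Y_new, metric="sqeuclidean")
    inv_beta = float((R * d2).sum() / (data.n * data.dim))
    beta_new = 1.0 / max(inv_beta, _EIG_FLOOR)
    return W_new, beta_new


def em_step(
    manifold: Manifold,
    data: DescriptorMatrix,
    lambda_reg: float,
    reg_convention: str = "prior",
) -> Manifold:
    """One EM iteration: E-step at the current parameters, then W and beta
    updates.  Returns a new Manifold; the input is not mutated."""
    R = responsibilities(manifold, data).values
    W_new, beta_new = _m_step(manifold, data, R, lambda_reg, reg_convention)
    return replace(manifold, W=W_new, beta=beta_new,
                   training_history=list(manifold.training_history))


def train_sgtm(
    data: DescriptorMatrix,
    config: TrainingConfig | None = None,
    init: Manifold | None = None,
) -> Manifold:
    """Standard GTM training: PCA initialization, then EM to convergence.

    Stops when the relative change of the penalized objective falls below
    ``config.rel_tol`` or after ``config.max_iter`` iterations (the latter
    flags ``converged=False``).  ``init`` injects a pre-built initialization
    (used by the parallel trainer to share one PCA across blocks).
    """
    config = config or TrainingConfig()
    if init is None:
        grid = build_latent_grid(config.k_side, config.m_side)
        basis = compute_rbf_basis(grid, config.width_factor, config.sigma_convention)
        manifold = initialize_manifold(basis, grid, data)
    else:
        manifold = replace(init, training_history=[])
    obj = penalized_objective(manifold, data, config.lambda_reg)
    history = [(0, obj)]
    converged = False
    for it in range(1, config.max_iter + 1):
        manifold = em_step(manifold, data, config.lambda_reg, config.reg_convention)
        new_obj = penalized_objective(manifold, data, config.lambda_reg)
        history.append((it, new_obj))
        logger.info("EM iteration %d: penalized LLh = %.6f", it, new_obj)
        if abs(new_obj - obj) <= config.rel_tol * abs(obj):
            converged = True
            obj = new_obj
            break
        obj = new_obj
    if not converged:
        logger.warning("EM did not converge within %d iterations", config.max_iter)
    manifold.training_history = history
    manifold.converged = converged
    return manifold
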