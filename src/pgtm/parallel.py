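"""Incremental and parallel GTM training.

Standard GTM needs every compound in memory at every EM iteration, which
caps the frame set at a few 10^4 compounds.  Two block-based strategies
lift that cap:

* **iGTM** (incremental): the frame set is split into blocks; the manifold
  is initialized on the first block and then refined by running EM to
  convergence on each subsequent block, warm-starting from the previous
  state.  The result depends on the block order.
* **pGTM** (parallel): a single PCA of the *whole* frame set is computed
  incrementally (streaming sufficient statistics), every block is fitted
  independently from that shared initialization, and the per-block
  manifolds are merged by element-wise averaging of W and beta.  Block
  tasks are side-effect free, so they can be dispatched to any number of
  workers without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .gtm import (
    DescriptorMatrix,
    Manifold,
    TrainingConfig,
    build_latent_grid,
    compute_rbf_basis,
    manifold_from_pca,
    pca_spectrum,
    train_sgtm,
)


@dataclass(frozen=True)
class BlockPartition:
    """A disjoint cover of 0..n-1 by consecutive (optionally shuffled) blocks.

    Every block has exactly ``block_size_limit`` members except possibly the
    last one.
    """

    block_index_ranges: tuple[np.ndarray, ...]
    block_size_limit: int
    shuffled: bool
    seed: int

    @property
    def n_blocks(self) -> int:
        return len(self.block_index_ranges)


@dataclass(frozen=True)
class PCABasis:
    """PCA sufficient results for manifold initialization: data mean, the
    first two eigenvectors (2 x D) and the third eigenvalue (the initial
    noise-variance guess 1/beta)."""

    mean_vector: np.ndarray
    eigenvectors: np.ndarray
    third_eigenvalue: float
    accumulated_count: int


@dataclass(frozen=True)
class MergeReport:
    """Bookkeeping for a manifold merge: per-block noise precisions and
    final penalized log-likelihoods."""

    n_blocks: int
    per_block_beta: tuple[float, ...]
    per_block_final_llh: tuple[float, ...]


def split_blocks(
    n: int, block_size: int, shuffle: bool = False, seed: int = 0
) -> BlockPartition:
    """Partition indices 0..n-1 into ceil(n / block_size) consecutive blocks.

    With ``shuffle=True`` the indices are permuted reproducibly under
    ``seed`` before the split.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    indices = np.arange(n)
    if shuffle:
        indices = np.random.default_rng(seed).permutation(indices)
    blocks = tuple(indices[i : i + block_size] for i in range(0, n, block_size))
    return BlockPartition(
        block_index_ranges=blocks,
        block_size_limit=block_size,
        shuffled=shuffle,
        seed=seed,
    )


def incremental_pca(data_blocks: Iterable[np.ndarray | DescriptorMatrix]) -> PCABasis:
    """Streaming PCA: one pass over blocks, exact batch equivalence.

    Accumulates the count, mean and centered scatter matrix with the
    pairwise (Chan et al.) merge update, then eigendecomposes the sample
    covariance (ddof=1).  Eigenvector signs are fixed by making each
    column's largest-magnitude entry positive.
    """
    n_tot = 0
    mean = None
    scatter = None
    for block in data_blocks:
        x = block.values if isinstance(block, DescriptorMatrix) else np.asarray(block, float)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("each block must be a non-empty 2-D array")
        m = x.shape[0]
        b_mean = x.mean(axis=0)
        xc = x - b_mean
        b_scatter = xc.T @ xc
        if mean is None:
            n_tot, mean, scatter = m, b_mean, b_scatter
        else:
            if x.shape[1] != mean.shape[0]:
                raise ValueError("descriptor dimension mismatch between blocks")
            delta = b_mean - mean
            new_n = n_tot + m
            scatter = scatter + b_scatter + np.outer(delta, delta) * (n_tot * m / new_n)
            mean = mean + delta * (m / new_n)
            n_tot = new_n
    if mean is None:
        raise ValueError("empty block stream")
    if n_tot < 3:
        raise ValueError("need at least 3 compounds in total for PCA")
    cov = scatter / (n_tot - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return PCABasis(
        mean_vector=mean,
        eigenvectors=eigvecs[:, :2].T,
        third_eigenvalue=float(eigvals[2]),
        accumulated_count=n_tot,
    )


def shared_initialization(pca: PCABasis, config: TrainingConfig, dim: int) -> Manifold:
    """Build the common initial manifold all pGTM blocks start from."""
    grid = build_latent_grid(config.k_side, config.m_side)
    basis = compute_rbf_basis(grid, config.width_factor, config.sigma_convention)
    return manifold_from_pca(
        basis, grid, pca.mean_vector, pca.eigenvectors, pca.third_eigenvalue, dim
    )


def train_block(
    shared_init: Manifold, block: DescriptorMatrix, config: TrainingConfig
) -> Manifold:
    """Fit one data block by standard EM from the shared initialization.

    ``shared_init`` is never mutated; each call returns a fresh manifold.
    """
    if block.dim != shared_init.dim:
        raise ValueError("block dimension does not match the shared initialization")
    return train_sgtm(block, config, init=shared_init)


def train_igtm(
    partition: BlockPartition, data: DescriptorMatrix, config: TrainingConfig
) -> Manifold:
    """Incremental GTM: PCA-initialize on the first block, then run EM to
    convergence on every block in sequence, warm-starting each time.

    The result depends on the block order (reshuffling the frame set gives
    a different manifold)."""
    if partition.n_blocks < 1:
        raise ValueError("partition must contain at least one block")
    for idx in partition.block_index_ranges:
        if len(idx) == 0:
            raise ValueError("empty block in partition")
    first = data.subset(partition.block_index_ranges[0])
    manifold = train_sgtm(first, config)
    history = list(manifold.training_history)
    for idx in partition.block_index_ranges[1:]:
        manifold = train_sgtm(data.subset(idx), config, init=manifold)
        offset = history[-1][0]
        history.extend((offset + it, llh) for it, llh in manifold.training_history)
    manifold.training_history = history
    return manifold


def merge_manifolds(manifolds: Sequence[Manifold]) -> Manifold:
    """Merge per-block manifolds by arithmetic averaging of W and beta.

    All inputs must share the latent grid, RBF basis and data dimension.
    Uniform per-block weights are used even when the last block is smaller;
    a MergeReport with per-block beta and final objective values is attached
    as ``merge_report``.
    """
    if len(manifolds) == 0:
        raise ValueError("cannot merge an empty list of manifolds")
    ref = manifolds[0]
    for m in manifolds[1:]:
        if m.W.shape != ref.W.shape or m.dim != ref.dim:
            raise ValueError("manifold shapes do not match")
        if (
            m.grid.k_side != ref.grid.k_side
            or m.grid.m_side != ref.grid.m_side
            or m.basis.sigma2 != ref.basis.sigma2
        ):
            raise ValueError("manifold grids/bases do not match")
    W_bar = np.mean([m.W for m in manifolds], axis=0)
    beta_bar = float(np.mean([m.beta for m in manifolds]))
    report = MergeReport(
        n_blocks=len(manifolds),
        per_block_beta=tuple(float(m.beta) for m in manifolds),
        per_block_final_llh=tuple(
            float(m.training_history[-1][1]) if m.training_history else float("nan")
            for m in manifolds
        ),
    )
    merged = replace(
        ref,
        W=W_bar,
        beta=beta_bar,
        training_history=[],
        converged=all(m.converged for m in manifolds),
    )
    merged.merge_report = report
    return merged


def train_pgtm(
    data: DescriptorMatrix,
    config: TrainingConfig | None = None,
    n_workers: int = 1,
    partition: BlockPartition | None = None,
) -> Manifold:
    """Parallel GTM: shared incremental-PCA initialization, independent
    per-block EM, merge by averaging.

    The block tasks are pure functions of (shared_init, block, config), so
    the merged manifold is identical for any ``n_workers``; worker count
    affects wall time only.  A pre-built ``partition`` may be supplied;
    otherwise consecutive blocks of ``config.block_size`` are used (frame
    sets are assumed already randomly ordered).
    """
    config = config or TrainingConfig()
    if data.n < 3:
        raise ValueError("need at least 3 compounds")
    if partition is None:
        partition = split_blocks(data.n, config.block_size, shuffle=False,
                                 seed=config.seed)
    blocks = [data.subset(idx) for idx in partition.block_index_ranges]
    pca = incremental_pca(blocks)
    init = shared_initialization(pca, config, data.dim)
    if n_workers > 1:
        fitted = Parallel(n_jobs=n_workers)(
            delayed(train_block)(init, b, config) for b in blocks
        )
    else:
        fitted = [train_block(init, b, config) for b in blocks]
    merged = merge_manifolds(fitted)
    merged.partition = partition
    return merged
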