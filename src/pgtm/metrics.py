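"""Map-quality metrics: frame-set representativity (KLD), density
uniformity (normalized Shannon entropy) and the cross-validated
balanced-accuracy benchmark.

* **KLD**: per descriptor, the frame set and the full collection are
  binned on common edges and compared by discrete Kullback-Leibler
  divergence (natural log); the per-descriptor values are averaged.  A
  perfectly representative frame set scores 0.
* **Normalized entropy**: the Shannon entropy of the (renormalized)
  cumulated-responsibility vector divided by log K, scaled to [0, 100]:
  0 = all compounds in one node, 100 = perfectly uniform coverage.
* **Balanced accuracy**: mean of per-class recalls of landscape-based
  class predictions, estimated by stratified 3-fold cross-validation of
  the class landscape (the manifold itself is never refitted); targets
  with mean BA >= 0.7 are counted as "predictable".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .gtm import DescriptorMatrix, Responsibilities
from .landscapes import (
    ACTIVE,
    INACTIVE,
    DensityLandscape,
    class_landscape,
    predict_classes,
)

DEFAULT_KLD_BINS = 20
DEFAULT_KLD_EPS = 1e-10
BA_THRESHOLD = 0.7


@dataclass(frozen=True)
class KLDReport:
    per_descriptor_kld: np.ndarray
    mean_kld: float
    std_kld: float
    n_bins: int
    smoothing_eps: float


@dataclass(frozen=True)
class CVResult:
    target_id: str
    fold_bas: tuple[float, ...]
    mean_ba: float
    n_active: int
    n_inactive: int


@dataclass(frozen=True)
class BenchmarkSummary:
    entropy_norm: float
    n_ba: int


def _discrete_kld(p_counts: np.ndarray, q_counts: np.ndarray, eps: float) -> float:
    p = p_counts.astype(float) + eps
    q = q_counts.astype(float) + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def descriptor_kld(
    fs: DescriptorMatrix,
    full: DescriptorMatrix,
    n_bins: int = DEFAULT_KLD_BINS,
    eps: float = DEFAULT_KLD_EPS,
) -> KLDReport:
    """Per-descriptor KLD between frame-set and full-collection histograms.

    Bin edges are equal-width over the full collection's per-descriptor
    range; both histograms are smoothed by ``eps`` before normalization so
    empty bins stay finite.  Descriptors with zero range in the full
    collection contribute 0 by convention.
    """
    if fs.dim != full.dim:
        raise ValueError("frame set and collection use different descriptor sets")
    if fs.n == 0 or full.n == 0:
        raise ValueError("both data sets must be non-empty")
    klds = np.zeros(full.dim)
    for j in range(full.dim):
        lo, hi = full.values[:, j].min(), full.values[:, j].max()
        if hi == lo:
            klds[j] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        p, _ = np.histogram(fs.values[:, j], bins=edges)
        q, _ = np.histogram(full.values[:, j], bins=edges)
        klds[j] = _discrete_kld(p, q, eps)
    return KLDReport(
        per_descriptor_kld=klds,
        mean_kld=float(klds.mean()),
        std_kld=float(klds.std()),
        n_bins=n_bins,
        smoothing_eps=eps,
    )


def normalized_entropy(landscape: DensityLandscape) -> float:
    """Normalized Shannon entropy of a density landscape, in [0, 100].

    The cumulated responsibilities are renormalized to a probability
    vector p, then E = -sum p_k ln p_k (0 ln 0 := 0) is divided by ln K
    and scaled by 100.
    """
    mass = np.asarray(landscape.cumulated, dtype=float)
    total = mass.sum()
    if mass.size == 0 or total <= 0:
        raise ValueError("landscape has no positive mass")
    if mass.size == 1:
        return 0.0
    p = mass / total
    nz = p > 0
    entropy = -float(np.sum(p[nz] * np.log(p[nz])))
    # clamp float round-off (-0.0 at the single-node anchor, 100+eps at
    # the uniform one) to the theoretical range
    return float(np.clip(100.0 * entropy / np.log(mass.size), 0.0, 100.0)) + 0.0


def balanced_accuracy(true_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Mean of per-class recalls over the classes present in true_labels.

    Compounds with no prediction (label 0) count as errors for their true
    class.  Both classes must be present in the true labels.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label arrays must have the same shape")
    recalls = []
    for c in (INACTIVE, ACTIVE):
        mask = t == c
        if not mask.any():
            raise ValueError(f"true class {c} absent: balanced accuracy undefined")
        recalls.append(float((p[mask] == c).mean()))
    return float(np.mean(recalls))


def cross_validate_target(
    resp_all: Responsibilities,
    labels: np.ndarray,
    target_id: str = "",
    folds: int = 3,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of a landscape-based classifier.

    The manifold (and hence every compound's responsibility vector) is
    fixed; only the class landscape is re-trained on the train folds and
    evaluated on the held-out fold.  Requires at least 15 compounds of
    each class.
    """
    labels = np.asarray(labels)
    n_act = int((labels == ACTIVE).sum())
    n_inact = int((labels == INACTIVE).sum())
    if n_act < 15 or n_inact < 15:
        raise ValueError(
            f"need >= 15 actives and >= 15 inactives (got {n_act}/{n_inact})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_bas = []
    for train_idx, test_idx in skf.split(labels[:, None], labels):
        scape = class_landscape(resp_all.subset(train_idx), labels[train_idx])
        _, pred = predict_classes(scape, resp_all.subset(test_idx))
        fold_bas.append(balanced_accuracy(labels[test_idx], pred))
    return CVResult(
        target_id=target_id,
        fold_bas=tuple(fold_bas),
        mean_ba=float(np.mean(fold_bas)),
        n_active=n_act,
        n_inactive=n_inact,
    )


def count_predictable(
    results: list[CVResult], ba_threshold: float = BA_THRESHOLD
) -> int:
    """Number of targets with mean cross-validated BA >= threshold (inclusive)."""
    return int(sum(r.mean_ba >= ba_threshold for r in results))
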