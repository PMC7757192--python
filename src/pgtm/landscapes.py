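"""Density landscapes, class landscapes and the applicability domain.

Once compounds are projected on a fitted manifold, their responsibilities
can be cumulated per node (a *density landscape*, the map's population
histogram) or averaged against class labels (a *class landscape*, a
responsibility-weighted mean class score per node in [1, 2] with
1 = inactive, 2 = active).  New compounds are classified by projecting them
and reading the landscape: the responsibility-weighted node score is the
predicted class likelihood, rounded to the nearest integer class.

The applicability domain (AD) discards compounds the manifold describes
poorly: a Gaussian is fitted to the histogram of per-compound
log-likelihoods of the frame set, and compounds whose LLh falls below
peak - 3*sigma are considered outside the domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .gtm import Responsibilities

INACTIVE, ACTIVE = 1, 2
NO_PREDICTION = 0  # label marker for compounds with no defined-node mass

# a node with less responsibility mass than this is "undefined" in a
# class landscape (no training compound meaningfully lands there)
_WEIGHT_FLOOR = 1e-12


@dataclass(frozen=True)
class DensityLandscape:
    """Per-node cumulated responsibilities; the mass sums to n_compounds."""

    cumulated: np.ndarray
    n_compounds: int


@dataclass(frozen=True)
class ClassLandscape:
    """Per-node mean class score (in [1, 2]) and responsibility weight.

    Nodes with (near-)zero weight are undefined: ``defined`` is False there
    and ``node_scores`` holds NaN.
    """

    node_scores: np.ndarray
    node_weights: np.ndarray
    defined: np.ndarray
    classes: tuple[int, int] = (INACTIVE, ACTIVE)


@dataclass(frozen=True)
class ADThreshold:
    """Applicability-domain cut-off: threshold = llh_peak - 3 * gaussian_sigma."""

    llh_peak: float
    gaussian_sigma: float
    threshold: float
    n_bins: int


def density_landscape(resp: Responsibilities) -> DensityLandscape:
    """Column sums of the responsibility matrix (per-node compound density)."""
    if resp.n == 0:
        raise ValueError("empty responsibilities")
    return DensityLandscape(cumulated=resp.values.sum(axis=0), n_compounds=resp.n)


def class_landscape(resp: Responsibilities, labels: np.ndarray) -> ClassLandscape:
    """Responsibility-weighted mean class score per node.

    s_k = sum_n r_nk c_n / sum_n r_nk with labels c_n in {1, 2}; nodes that
    receive no responsibility mass are flagged undefined.
    """
    labels = np.asarray(labels)
    if resp.n == 0:
        raise ValueError("at least one compound required")
    if labels.shape[0] != resp.n:
        raise ValueError("labels length does not match responsibilities")
    if not np.isin(labels, (INACTIVE, ACTIVE)).all():
        raise ValueError("labels must be coded 1 (inactive) or 2 (active)")
    weights = resp.values.sum(axis=0)
    defined = weights > _WEIGHT_FLOOR
    scores = np.full(weights.shape, np.nan)
    scores[defined] = (resp.values[:, defined] * labels[:, None]).sum(axis=0) / weights[
        defined
    ]
    return ClassLandscape(node_scores=scores, node_weights=weights, defined=defined)


def predict_classes(
    landscape: ClassLandscape, resp_new: Responsibilities
) -> tuple[np.ndarray, np.ndarray]:
    """Project compounds through a class landscape.

    Returns (scores, labels): score_n = sum_k r_nk s_k over defined nodes,
    renormalized by the defined-node responsibility mass; the label is the
    nearest integer class with ties at exactly 1.5 going to the active
    class.  Compounds whose entire responsibility mass sits on undefined
    nodes get score NaN and label 0 (no prediction).
    """
    if resp_new.n_nodes != landscape.node_scores.shape[0]:
        raise ValueError("responsibilities and landscape use different grids")
    r = resp_new.values[:, landscape.defined]
    mass = r.sum(axis=1)
    scores = np.full(resp_new.n, np.nan)
    labels = np.full(resp_new.n, NO_PREDICTION, dtype=int)
    ok = mass > _WEIGHT_FLOOR
    scores[ok] = (r[ok] @ landscape.node_scores[landscape.defined]) / mass[ok]
    # round-half-up: 1.5 -> active
    labels[ok] = np.where(scores[ok] >= 1.5, ACTIVE, INACTIVE)
    return scores, labels


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_ad(llh_values: np.ndarray, n_bins: int | None = None) -> ADThreshold:
    """Fit a Gaussian to the binned LLh distribution; threshold = peak - 3 sigma.

    ``n_bins`` defaults to Sturges' rule.  The fit is unweighted least
    squares of bin counts against bin centers.  If all values coincide the
    threshold degenerates to that value (sigma = 0).
    """
    llh = np.asarray(llh_values, dtype=float)
    if llh.size < 10:
        raise ValueError("need at least 10 LLh values to fit the AD")
    if np.ptp(llh) == 0.0:
        return ADThreshold(
            llh_peak=float(llh[0]), gaussian_sigma=0.0,
            threshold=float(llh[0]), n_bins=1,
        )
    if n_bins is None:
        n_bins = int(np.ceil(np.log2(llh.size))) + 1  # Sturges
    counts, edges = np.histogram(llh, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(centers[np.argmax(counts)]), float(llh.std()))
    try:
        (a, mu, sigma), _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=10000)
        sigma = abs(float(sigma))
        mu = float(mu)
    except RuntimeError:  # fit failure: fall back to sample moments
        mu, sigma = float(llh.mean()), float(llh.std())
    return ADThreshold(
        llh_peak=mu, gaussian_sigma=sigma, threshold=mu - 3.0 * sigma, n_bins=n_bins
    )


def apply_ad(threshold: ADThreshold, llh_values: np.ndarray) -> np.ndarray:
    """Inclusion mask: True where LLh >= threshold (strictly-below discarded)."""
    return np.asarray(llh_values, dtype=float) >= threshold.threshold
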