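"""Data preparation: descriptor filtering/standardization, heavy-atom
filtering, per-target IC50 activity labeling and frame-set sampling.

The labeling protocol assigns, per biological target, an "active" IC50
threshold (smallest value of a fixed nanomolar grid yielding at least 15
actives) and an "inactive" threshold (smallest value of a 10x coarser grid
classifying 30 % of the records, or at least 15 compounds, as inactive,
subject to Inact/Act >= 10).  Compounds strictly between the two
thresholds are discarded as ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gtm import DescriptorMatrix

# IC50 threshold grids, in nM.  The inactive grid is 10x the active one,
# scanned ascending.
ACT_GRID_NM = (10.0, 50.0, 100.0, 300.0, 500.0, 700.0, 1000.0)
INACT_GRID_NM = tuple(10.0 * v for v in ACT_GRID_NM)

MIN_RECORDS = 30          # per-target prefilter on measured IC50 values
MIN_CLASS_SIZE = 15       # actives and inactives each
INACT_FRACTION = 0.30
MIN_RATIO = 10.0          # Inact_IC50 / Act_IC50

MIN_HEAVY_ATOMS = 5
MAX_HEAVY_ATOMS = 100

NEAR_CONSTANT_FRACTION = 0.02  # drop descriptors with std < 2 % of range

LABEL_ACTIVE = "active"
LABEL_INACTIVE = "inactive"
LABEL_DISCARDED = "discarded"


@dataclass(frozen=True)
class FilterReport:
    """Which descriptor columns the standardization kept and why others fell."""

    kept: np.ndarray
    removed_constant: np.ndarray
    removed_near_constant: np.ndarray

    @property
    def n_original(self) -> int:
        return len(self.kept) + len(self.removed_constant) + len(
            self.removed_near_constant
        )


@dataclass(frozen=True)
class LabeledSet:
    """Per-target activity labels and the IC50 thresholds that produced them."""

    target_id: str
    act_threshold_nM: float
    inact_threshold_nM: float
    compound_ids: tuple[str, ...]
    labels: tuple[str, ...]

    @property
    def n_active(self) -> int:
        return sum(label == LABEL_ACTIVE for label in self.labels)

    @property
    def n_inactive(self) -> int:
        return sum(label == LABEL_INACTIVE for label in self.labels)


@dataclass(frozen=True)
class FrameSetSpec:
    """One sampled frame set: which compounds, at which size/replicate."""

    size: int
    replicate: int
    seed: int
    indices: np.ndarray


def standardize_descriptors(
    raw: np.ndarray,
    fit_indices: np.ndarray | None = None,
    descriptor_names: list[str] | None = None,
    ids: list[str] | None = None,
) -> tuple[DescriptorMatrix, FilterReport]:
    """Drop (near-)constant descriptors and z-score the rest.

    Statistics are computed on the frame-set rows (``fit_indices``; all
    rows when None) and applied to every row.  A column is removed when
    its frame-set standard deviation is zero or below 2 % of its frame-set
    range (max - min).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw descriptors must be 2-D")
    fs = raw if fit_indices is None else raw[np.asarray(fit_indices)]
    if fs.shape[0] == 0:
        raise ValueError("frame set is empty")
    stds = fs.std(axis=0)
    ranges = fs.max(axis=0) - fs.min(axis=0)
    constant = stds == 0.0
    near_constant = ~constant & (stds < NEAR_CONSTANT_FRACTION * ranges)
    keep = ~(constant | near_constant)
    if not keep.any():
        raise ValueError("all descriptor columns were removed by the filter")
    means = fs[:, keep].mean(axis=0)
    kept_stds = stds[keep]
    values = (raw[:, keep] - means) / kept_stds
    names = (
        [descriptor_names[j] for j in np.flatnonzero(keep)]
        if descriptor_names is not None
        else None
    )
    report = FilterReport(
        kept=np.flatnonzero(keep),
        removed_constant=np.flatnonzero(constant),
        removed_near_constant=np.flatnonzero(near_constant),
    )
    matrix = DescriptorMatrix(
        values,
        descriptor_names=names,
        column_means=means,
        column_stds=kept_stds,
        ids=ids,
    )
    return matrix, report


def filter_by_heavy_atoms(
    counts,
    min_atoms: int = MIN_HEAVY_ATOMS,
    max_atoms: int = MAX_HEAVY_ATOMS,
) -> np.ndarray:
    """Keep compounds with min_atoms <= heavy atoms <= max_atoms (inclusive).

    Missing counts (NaN) exclude the compound with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    missing = np.isnan(counts)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} compounds without heavy-atom counts excluded",
            UserWarning,
            stacklevel=2,
        )
    return ~missing & (counts >= min_atoms) & (counts <= max_atoms)


def deduplicate_activities(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (target, compound) IC50 records to their median."""
    required = {"target_id", "compound_id", "ic50_nM"}
    if not required.issubset(table.columns):
        raise ValueError(f"activity table must have columns {sorted(required)}")
    if (table["ic50_nM"] <= 0).any():
        raise ValueError("IC50 values must be strictly positive")
    return (
        table.groupby(["target_id", "compound_id"], as_index=False)["ic50_nM"]
        .median()
    )


def assign_labels(records: pd.DataFrame, target_id: str = "") -> LabeledSet | None:
    """Three-stage per-target labeling from IC50 values (in nM).

    1. Act_IC50 = smallest grid value with >= 15 compounds at IC50 <= Act.
    2. Inact_IC50 = smallest candidate (10x grid, ascending) classifying
       >= 30 % of records or >= 15 compounds as inactive, with
       Inact/Act >= 10.
    3. If Inact/Act > 10, Act is relaxed to Inact/10 to collect more
       actives.

    Compounds strictly between the thresholds are discarded.  Returns None
    when no grid value satisfies a stage (target unlabeled).  Requires at
    least 30 records.
    """
    if "compound_id" not in records.columns or "ic50_nM" not in records.columns:
        raise ValueError("records need 'compound_id' and 'ic50_nM' columns")
    ic50 = records["ic50_nM"].to_numpy(dtype=float)
    if (ic50 <= 0).any():
        raise ValueError("IC50 values must be strictly positive")
    n = len(ic50)
    if n < MIN_RECORDS:
        raise ValueError(f"need at least {MIN_RECORDS} IC50 records, got {n}")

    act = next(
        (t for t in ACT_GRID_NM if (ic50 <= t).sum() >= MIN_CLASS_SIZE), None
    )
    if act is None:
        return None
    inact = next(
        (
            t
            for t in INACT_GRID_NM
            if t / act >= MIN_RATIO
            and (
                (ic50 >= t).sum() >= INACT_FRACTION * n
                or (ic50 >= t).sum() >= MIN_CLASS_SIZE
            )
        ),
        None,
    )
    if inact is None:
        return None
    if inact / act > MIN_RATIO:
        act = inact / MIN_RATIO

    labels = np.where(
        ic50 <= act, LABEL_ACTIVE, np.where(ic50 >= inact, LABEL_INACTIVE,
                                            LABEL_DISCARDED)
    )
    return LabeledSet(
        target_id=target_id,
        act_threshold_nM=float(act),
        inact_threshold_nM=float(inact),
        compound_ids=tuple(records["compound_id"].astype(str)),
        labels=tuple(labels),
    )


def label_activity_table(table: pd.DataFrame) -> dict[str, LabeledSet]:
    """Deduplicate and label every target with >= 30 records; targets the
    protocol cannot label are silently dropped."""
    table = deduplicate_activities(table)
    out: dict[str, LabeledSet] = {}
    for tid, grp in table.groupby("target_id"):
        if len(grp) < MIN_RECORDS:
            continue
        labeled = assign_labels(grp.reset_index(drop=True), target_id=str(tid))
        if labeled is not None:
            out[str(tid)] = labeled
    return out


def filter_targets(labeled_sets: dict[str, LabeledSet]) -> dict[str, LabeledSet]:
    """Keep targets with at least 15 actives and 15 inactives."""
    return {
        tid: ls
        for tid, ls in labeled_sets.items()
        if ls.n_active >= MIN_CLASS_SIZE and ls.n_inactive >= MIN_CLASS_SIZE
    }


def sample_frame_sets(
    n_total: int,
    sizes: list[int],
    replicates: int = 5,
    seed: int = 0,
) -> list[FrameSetSpec]:
    """Uniform without-replacement frame-set samples, ``replicates`` per size.

    When a size equals the collection size the "sample" is a reshuffled
    permutation.  Reproducible per (size, replicate, seed).
    """
    specs = []
    for size in sizes:
        if size > n_total:
            raise ValueError(f"frame-set size {size} exceeds collection ({n_total})")
        for rep in range(1, replicates + 1):
            rng = np.random.default_rng([seed, size, rep])
            if size == n_total:
                idx = rng.permutation(n_total)
            else:
                idx = rng.choice(n_total, size=size, replace=False)
            specs.append(FrameSetSpec(size=size, replicate=rep, seed=seed, indices=idx))
    return specs
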