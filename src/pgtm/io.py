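"""File formats: descriptor matrices (dense CSV / sparse SVM-light), model
containers, landscape exports, activity tables and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gtm import (
    DescriptorMatrix,
    LatentGrid,
    Manifold,
    build_latent_grid,
    compute_rbf_basis,
)
from .landscapes import ClassLandscape, DensityLandscape

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Descriptor files
# ---------------------------------------------------------------------------


def read_descriptors_csv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense CSV with a mandatory header; first column is the compound id.

    Returns (values, ids, descriptor_names).  Ragged rows, duplicate ids
    and non-numeric cells each raise with a distinct message.
    """
    try:
        frame = pd.read_csv(path, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed CSV rows ({exc})") from exc
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus at least one descriptor")
    ids = frame.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = frame.iloc[:, 0][frame.iloc[:, 0].duplicated()].unique()[:5]
        raise ValueError(f"{path}: duplicate compound ids {list(dupes)}")
    if frame.iloc[:, 1:].isna().any().any():
        raise ValueError(f"{path}: missing values in descriptor columns")
    try:
        values = frame.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric descriptor cell ({exc})") from exc
    return values, ids, list(frame.columns[1:])


def write_descriptors_csv(
    path: str | Path,
    values: np.ndarray,
    ids: list[str],
    descriptor_names: list[str] | None = None,
) -> None:
    values = np.asarray(values)
    names = descriptor_names or [f"d{j + 1}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, columns=names)
    frame.insert(0, "compound_id", ids)
    frame.to_csv(path, index=False)


def read_descriptors_svmlight(
    path: str | Path, n_features: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Sparse SVM-light lines ``label idx:val ...`` with 1-based indices.

    The leading label token is kept as the compound id.  Returns a dense
    (values, ids) pair.
    """
    ids: list[str] = []
    rows: list[dict[int, float]] = []
    max_idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            ids.append(tokens[0])
            entries: dict[int, float] = {}
            for tok in tokens[1:]:
                try:
                    idx_s, val_s = tok.split(":", 1)
                    idx = int(idx_s)
                    val = float(val_s)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed feature token {tok!r}"
                    ) from exc
                if idx < 1:
                    raise ValueError(f"{path}:{lineno}: indices are 1-based, got {idx}")
                entries[idx] = val
                max_idx = max(max_idx, idx)
            rows.append(entries)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate compound ids")
    d = n_features or max_idx
    values = np.zeros((len(rows), d))
    for i, entries in enumerate(rows):
        for idx, val in entries.items():
            if idx > d:
                raise ValueError(f"{path}: feature index {idx} exceeds n_features={d}")
            values[i, idx - 1] = val
    return values, ids


def write_descriptors_svmlight(
    path: str | Path, values: np.ndarray, ids: list[str]
) -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        for cid, row in zip(ids, values):
            nz = np.flatnonzero(row)
            feats = " ".join(f"{j + 1}:{row[j]:g}" for j in nz)
            fh.write(f"{cid} {feats}\n".rstrip() + "\n")


def read_descriptors(path: str | Path, fmt: str | None = None):
    """Format-dispatching reader; ``fmt`` in {'csv', 'svmlight'} or inferred
    from the extension."""
    path = Path(path)
    if fmt is None:
        fmt = "svmlight" if path.suffix in (".svm", ".svmlight", ".txt") else "csv"
    if fmt == "csv":
        values, ids, names = read_descriptors_csv(path)
        return values, ids, names
    if fmt == "svmlight":
        values, ids = read_descriptors_svmlight(path)
        return values, ids, [f"d{j + 1}" for j in range(values.shape[1])]
    raise ValueError(f"unknown descriptor format {fmt!r}")


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


def write_model(path: str | Path, manifold: Manifold,
                standardization: dict | None = None) -> None:
    """Single-file model container (npz with an embedded JSON header).

    Stores W, beta, the grid/basis parameters, training history,
    convergence flag and (optionally) the frame-set standardization
    statistics needed to project raw descriptors.
    """
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "k_side": manifold.grid.k_side,
        "m_side": manifold.grid.m_side,
        "width_factor": manifold.basis.width_factor,
        "sigma2": manifold.basis.sigma2,
        "dim": manifold.dim,
        "beta": manifold.beta,
        "converged": manifold.converged,
        "has_standardization": standardization is not None,
    }
    arrays = {
        "header_json": np.frombuffer(
            json.dumps(header).encode("utf-8"), dtype=np.uint8
        ),
        "W": manifold.W,
        "history": np.asarray(manifold.training_history, dtype=float).reshape(-1, 2),
    }
    if standardization is not None:
        arrays["column_means"] = np.asarray(standardization["column_means"])
        arrays["column_stds"] = np.asarray(standardization["column_stds"])
        arrays["kept_columns"] = np.asarray(standardization.get(
            "kept_columns", np.arange(len(arrays["column_means"]))))
    np.savez(path, **arrays)


def read_model(path: str | Path) -> tuple[Manifold, dict | None]:
    """Load a model container; refuses unknown format versions or
    truncated files."""
    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise ValueError(f"{path}: unreadable or truncated model file ({exc})") from exc
    if "header_json" not in data or "W" not in data:
        raise ValueError(f"{path}: truncated model file (missing sections)")
    header = json.loads(bytes(data["header_json"]).decode("utf-8"))
    version = header.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {version} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    grid = build_latent_grid(header["k_side"], header["m_side"])
    basis = compute_rbf_basis(grid, header["width_factor"])
    manifold = Manifold(
        W=data["W"],
        beta=float(header["beta"]),
        basis=basis,
        grid=grid,
        dim=int(header["dim"]),
        training_history=[(int(i), float(v)) for i, v in data["history"]],
        converged=bool(header["converged"]),
    )
    standardization = None
    if header.get("has_standardization"):
        standardization = {
            "column_means": data["column_means"],
            "column_stds": data["column_stds"],
            "kept_columns": data["kept_columns"],
        }
    return manifold, standardization


def project_raw(
    manifold: Manifold, raw: np.ndarray, standardization: dict | None
) -> DescriptorMatrix:
    """Standardize raw descriptors with the model's stored frame-set stats.

    Refuses to project when the model carries no standardization (raw
    values would be on the wrong scale)."""
    if standardization is None:
        raise ValueError(
            "model carries no standardization statistics; cannot project raw data"
        )
    raw = np.asarray(raw, dtype=float)
    kept = np.asarray(standardization["kept_columns"], dtype=int)
    values = (raw[:, kept] - standardization["column_means"]) / standardization[
        "column_stds"
    ]
    return DescriptorMatrix(
        values,
        column_means=standardization["column_means"],
        column_stds=standardization["column_stds"],
    )


# ---------------------------------------------------------------------------
# Landscapes, labels, manifests
# ---------------------------------------------------------------------------


def write_landscape_csv(
    path: str | Path,
    grid: LatentGrid,
    density: DensityLandscape | None = None,
    classes: ClassLandscape | None = None,
) -> None:
    """Node table: index, latent x/y, cumulated density, class score, weight."""
    table = pd.DataFrame(
        {
            "node": np.arange(grid.n_nodes),
            "x": grid.node_coords[:, 0],
            "y": grid.node_coords[:, 1],
        }
    )
    if density is not None:
        table["cumulated_density"] = density.cumulated
    if classes is not None:
        table["class_score"] = classes.node_scores
        table["class_weight"] = classes.node_weights
    table.to_csv(path, index=False)


def render_landscape_png(path: str | Path, grid: LatentGrid,
                         values: np.ndarray, title: str = "") -> None:
    """Optional heatmap rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.asarray(values, dtype=float).reshape(grid.k_side, grid.k_side)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(img, origin="lower", extent=(-1, 1, -1, 1), cmap="viridis")
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_activity_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"target_id", "compound_id", "ic50_nM"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: activity TSV must have columns {sorted(required)}")
    return table


def write_activity_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict, inputs: list[str | Path],
                   extra: dict | None = None) -> None:
    """JSON run manifest: configuration, seeds and input digests, enough to
    replay the run exactly."""
    manifest = {
        "config": config,
        "inputs": {str(p): file_digest(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
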