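"""Plain-text file dialects shared by the library and the CLI.

All matrices are tab-delimited text with a header row.  Voxel indices in
every output file are 0-based; cluster labels are 1-based.  The expression
matrix and the coordinate table must align row for row (row i of both is
voxel i).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binarize import LuminescenceMatrix
from .containers import BinaryExpressionMatrix, FitResult, Partition
from .graph import VoxelGraph, build_graph
from .simulate import SimulationReference

__all__ = [
    "read_expression",
    "write_expression",
    "read_coordinates",
    "write_coordinates",
    "read_graph",
    "read_luminescence",
    "read_thresholds",
    "write_thresholds",
    "read_partition",
    "write_partition",
    "write_params",
    "read_params",
    "write_fit_metadata",
    "write_reference",
    "read_reference",
]

_SEP = "\t"


def read_expression(path: str | Path) -> BinaryExpressionMatrix:
    """Read a binary expression matrix (N x G, header = gene names)."""
    df = pd.read_csv(path, sep=_SEP)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = np.argwhere(~np.isin(values, (0, 1)))
        raise ValueError(
            f"{path}: non-binary entries, first at row {bad[0][0]}, column {df.columns[bad[0][1]]!r}"
        )
    return BinaryExpressionMatrix(y=values.astype(np.int8), gene_names=list(df.columns))


def write_expression(y: BinaryExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(y.y, columns=list(y.gene_names)).to_csv(path, sep=_SEP, index=False)


def read_coordinates(path: str | Path) -> np.ndarray:
    """Read the voxel coordinate table (columns x, y, z; row = voxel index)."""
    df = pd.read_csv(path, sep=_SEP)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing coordinate columns {sorted(missing)}")
    return df[["x", "y", "z"]].to_numpy().astype(np.int64)


def write_coordinates(coords: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(coords), columns=["x", "y", "z"]).to_csv(path, sep=_SEP, index=False)


def read_graph(expression_path: str | Path, coordinates_path: str | Path) -> tuple[BinaryExpressionMatrix, VoxelGraph]:
    """Read aligned expression + coordinates and build the voxel graph."""
    y = read_expression(expression_path)
    coords = read_coordinates(coordinates_path)
    if coords.shape[0] != y.n_voxels:
        raise ValueError(
            f"expression matrix has {y.n_voxels} rows but coordinates file has {coords.shape[0]}"
        )
    return y, build_graph(coords)


def read_luminescence(path: str | Path) -> LuminescenceMatrix:
    df = pd.read_csv(path, sep=_SEP)
    return LuminescenceMatrix(values=df.to_numpy(dtype=float), gene_names=list(df.columns))


def read_thresholds(path: str | Path) -> pd.Series:
    """Two-column file (gene, threshold) -> Series indexed by gene."""
    df = pd.read_csv(path, sep=_SEP)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (gene, threshold)")
    return df.set_index(df.columns[0])[df.columns[1]].astype(float)


def write_thresholds(thresholds: pd.Series, path: str | Path) -> None:
    thresholds.rename("threshold").rename_axis("gene").reset_index().to_csv(
        path, sep=_SEP, index=False
    )


def read_partition(path: str | Path, n_clusters: int | None = None) -> Partition:
    df = pd.read_csv(path, sep=_SEP)
    if not {"voxel_index", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns voxel_index, label")
    df = df.sort_values("voxel_index")
    if not np.array_equal(df["voxel_index"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: voxel_index must be 0..N-1 without gaps")
    labels = df["label"].to_numpy().astype(np.int64)
    return Partition(labels=labels, n_clusters=n_clusters or int(labels.max()))


def write_partition(partition: Partition, path: str | Path) -> None:
    pd.DataFrame(
        {"voxel_index": np.arange(partition.n_voxels), "label": partition.labels}
    ).to_csv(path, sep=_SEP, index=False)


def write_params(theta: np.ndarray, beta: np.ndarray, gene_names, theta_path: str | Path, beta_path: str | Path) -> None:
    pd.DataFrame(theta, columns=list(gene_names)).to_csv(theta_path, sep=_SEP, index=False)
    pd.DataFrame({"cluster": np.arange(1, len(beta) + 1), "beta": beta}).to_csv(
        beta_path, sep=_SEP, index=False
    )


def read_params(theta_path: str | Path, beta_path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    tdf = pd.read_csv(theta_path, sep=_SEP)
    bdf = pd.read_csv(beta_path, sep=_SEP)
    return tdf.to_numpy(dtype=float), bdf["beta"].to_numpy(dtype=float), list(tdf.columns)


def write_fit_metadata(fit: FitResult, path: str | Path, extra: dict | None = None) -> None:
    """Run metadata (seed, K, iterations, BIC, convergence, trace) as JSON."""
    meta = {
        "model": fit.model,
        "n_clusters": fit.partition.n_clusters,
        "seed": fit.seed,
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "bic": None if np.isnan(fit.bic) else float(fit.bic),
        "n_params": fit.n_params,
        "log_likelihood": float(fit.log_likelihood),
        "log_likelihood_trace": [float(v) for v in fit.log_likelihood_trace],
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def write_reference(ref: SimulationReference, outdir: str | Path, seed: int | None = None) -> dict:
    """Serialize a simulation reference (partition, theta, coordinates, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_partition(ref.partition, outdir / "reference_partition.tsv")
    gene_names = [f"g{i + 1:04d}" for i in range(ref.n_genes)]
    write_params(ref.theta, np.zeros(ref.n_clusters), gene_names, outdir / "reference_theta.tsv", outdir / "reference_beta.tsv")
    write_coordinates(ref.graph.coords, outdir / "coordinates.tsv")
    manifest = {
        "provenance": ref.provenance,
        "n_clusters": ref.n_clusters,
        "n_genes": ref.n_genes,
        "n_voxels": ref.graph.n_voxels,
        "seed": seed,
        "files": {
            "partition": "reference_partition.tsv",
            "theta": "reference_theta.tsv",
            "coordinates": "coordinates.tsv",
        },
    }
    (outdir / "reference_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_reference(outdir: str | Path) -> SimulationReference:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "reference_manifest.json").read_text())
    files = manifest["files"]
    partition = read_partition(outdir / files["partition"], n_clusters=manifest["n_clusters"])
    theta, _, _ = read_params(outdir / files["theta"], outdir / "reference_beta.tsv")
    coords = read_coordinates(outdir / files["coordinates"])
    return SimulationReference(
        partition=partition,
        theta=theta,
        graph=build_graph(coords),
        provenance=manifest.get("provenance", "synthetic"),
    )
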