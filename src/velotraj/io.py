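"""Readers and writers for datasets and results.

Datasets are accepted as AnnData ``.h5ad`` (X = expression,
``layers['velocity']``, ``obsm['X_pca']``, optional ``obsm['X_umap']`` and
``obs['clusters']``) or as a directory of MTX + delimited-text sidecars.
Result writers emit plain CSV/JSON (plus MTX for sparse matrices and parquet
for simulation ensembles) so downstream tooling needs nothing exotic.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .consensus import Trajectory
from .datasets import VelocityDataset
from .sampling import Simulation, SimulationEnsemble
from .transition import StationaryAnnotation, TransitionModel

__all__ = [
    "read_dataset",
    "read_h5ad",
    "write_h5ad",
    "read_mtx_dir",
    "write_mtx_dir",
    "write_transition_model",
    "write_stationary",
    "write_trajectories",
    "write_ensemble",
    "read_ensemble",
]

_MTX_REQUIRED = ("matrix.mtx", "velocity.mtx", "barcodes.tsv", "genes.tsv", "pca.tsv")


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def read_h5ad(path: str | Path) -> VelocityDataset:
    adata = ad.read_h5ad(path)
    if "velocity" not in adata.layers:
        raise ValueError(f"{path}: missing layer 'velocity'")
    if "X_pca" not in adata.obsm:
        raise ValueError(f"{path}: missing obsm 'X_pca'")
    expr = _dense(adata.X)
    vel = _dense(adata.layers["velocity"])
    bad = np.isnan(expr).any(axis=1) | np.isnan(vel).any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} cells contain NaN values")
    clusters = None
    if "clusters" in adata.obs:
        clusters = adata.obs["clusters"].astype(str).to_numpy()
    return VelocityDataset(
        expression=expr,
        velocity=vel,
        pca_coords=np.asarray(adata.obsm["X_pca"], dtype=float),
        embedding_2d=(
            np.asarray(adata.obsm["X_umap"], dtype=float)
            if "X_umap" in adata.obsm
            else None
        ),
        cluster_labels=clusters,
        cell_ids=adata.obs_names.to_numpy(),
        gene_ids=adata.var_names.to_numpy(),
        pca_loadings=(
            np.asarray(adata.varm["PCs"], dtype=float) if "PCs" in adata.varm else None
        ),
    )


def write_h5ad(dataset: VelocityDataset, path: str | Path) -> None:
    adata = ad.AnnData(
        X=dataset.expression,
        layers={"velocity": dataset.velocity},
        obsm={"X_pca": dataset.pca_coords},
    )
    adata.obs_names = pd.Index(dataset.cell_ids)
    adata.var_names = pd.Index(dataset.gene_ids)
    if dataset.embedding_2d is not None:
        adata.obsm["X_umap"] = dataset.embedding_2d
    if dataset.cluster_labels is not None:
        adata.obs["clusters"] = pd.Categorical(dataset.cluster_labels)
    if dataset.pca_loadings is not None:
        adata.varm["PCs"] = dataset.pca_loadings
    adata.write_h5ad(Path(path))


def read_mtx_dir(path: str | Path) -> VelocityDataset:
    """Read a dataset from ``matrix.mtx`` + TSV sidecars in a directory."""
    path = Path(path)
    for name in _MTX_REQUIRED:
        if not (path / name).exists():
            raise FileNotFoundError(f"{path}: required file {name!r} is missing")
    expr = _dense(scipy.io.mmread(path / "matrix.mtx"))
    vel = _dense(scipy.io.mmread(path / "velocity.mtx"))
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].to_numpy()
    pca = pd.read_csv(path / "pca.tsv", sep="\t", header=None).to_numpy(dtype=float)
    embed = None
    if (path / "embedding.tsv").exists():
        embed = pd.read_csv(path / "embedding.tsv", sep="\t", header=None).to_numpy(
            dtype=float
        )
    clusters = None
    if (path / "clusters.tsv").exists():
        clusters = pd.read_csv(path / "clusters.tsv", sep="\t", header=None)[
            0
        ].to_numpy()
    return VelocityDataset(
        expression=expr,
        velocity=vel,
        pca_coords=pca,
        embedding_2d=embed,
        cluster_labels=clusters,
        cell_ids=cells,
        gene_ids=genes,
    )


def write_mtx_dir(dataset: VelocityDataset, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.csr_matrix(dataset.expression))
    scipy.io.mmwrite(path / "velocity.mtx", sp.csr_matrix(dataset.velocity))
    pd.Series(dataset.cell_ids).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(dataset.gene_ids).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame(dataset.pca_coords).to_csv(
        path / "pca.tsv", sep="\t", header=False, index=False
    )
    if dataset.embedding_2d is not None:
        pd.DataFrame(dataset.embedding_2d).to_csv(
            path / "embedding.tsv", sep="\t", header=False, index=False
        )
    if dataset.cluster_labels is not None:
        pd.Series(dataset.cluster_labels).to_csv(
            path / "clusters.tsv", sep="\t", header=False, index=False
        )


def read_dataset(path: str | Path) -> VelocityDataset:
    """Dispatch on path type: ``.h5ad`` file or MTX + TSV directory."""
    path = Path(path)
    if path.is_dir():
        return read_mtx_dir(path)
    if path.suffix == ".h5ad":
        return read_h5ad(path)
    raise ValueError(f"cannot read {path}: expected .h5ad file or MTX directory")


def write_transition_model(model: TransitionModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "transition_matrix.mtx", model.P)
    scipy.io.mmwrite(outdir / "velocity_graph.mtx", model.velocity_graph)


def write_stationary(
    annotation: StationaryAnnotation, cell_ids: np.ndarray, path: str | Path
) -> None:
    n = len(cell_ids)
    is_root = np.zeros(n, dtype=bool)
    is_root[annotation.root_cells] = True
    is_term = np.zeros(n, dtype=bool)
    is_term[annotation.terminal_cells] = True
    pd.DataFrame(
        {
            "cell_id": cell_ids,
            "root_prob": annotation.root_prob,
            "terminal_prob": annotation.terminal_prob,
            "is_root": is_root,
            "is_terminal": is_term,
        }
    ).to_csv(path, index=False)


def write_trajectories(trajectories: list[Trajectory], outdir: str | Path) -> None:
    """CSV of step coordinates plus a JSON manifest per trajectory set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    manifest = []
    for tid, traj in enumerate(trajectories):
        for step in range(traj.n_steps):
            row = {"trajectory_id": tid, "step": step}
            row.update(
                {f"coord_{j + 1}": traj.steps[step, j] for j in range(traj.steps.shape[1])}
            )
            if traj.embedding is not None:
                row["embed_x"] = traj.embedding[step, 0]
                row["embed_y"] = traj.embedding[step, 1]
            rows.append(row)
        manifest.append(
            {
                "trajectory_id": tid,
                "terminal_region": traj.terminal_region,
                "n_steps": int(traj.n_steps),
                "anchored": bool(traj.anchored),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "trajectories.csv", index=False)
    (outdir / "trajectories.json").write_text(json.dumps(manifest, indent=2))


def write_ensemble(ensemble: SimulationEnsemble, path: str | Path) -> None:
    """Columnar (sim_id, step, cell_index, terminal_region) parquet table."""
    frames = []
    for sid, sim in enumerate(ensemble.simulations):
        frames.append(
            pd.DataFrame(
                {
                    "sim_id": sid,
                    "step": np.arange(len(sim.cell_indices)),
                    "cell_index": sim.cell_indices,
                    "terminal_region": str(sim.terminal_region),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_parquet(path, index=False)


def read_ensemble(path: str | Path) -> SimulationEnsemble:
    df = pd.read_parquet(path)
    sims = []
    for sid, grp in df.groupby("sim_id", sort=True):
        grp = grp.sort_values("step")
        region = grp["terminal_region"].iloc[0]
        sims.append(
            Simulation(
                cell_indices=grp["cell_index"].to_numpy(dtype=np.int64),
                terminal_region=None if region == "None" else region,
            )
        )
    return SimulationEnsemble(simulations=sims)
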