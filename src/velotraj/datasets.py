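"""Container for a single-cell dataset with RNA velocity.

The central object is :class:`VelocityDataset`, holding a cells × genes
expression matrix, a velocity matrix of identical shape (the estimated time
derivative of expression per cell), a low-dimensional representation
(principal components), an optional 2-D embedding for display, and optional
cluster labels. Velocity estimation itself (spliced/unspliced modelling) is
out of scope: velocities are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VelocityDataset"]


@dataclass
class VelocityDataset:
    """Cells × genes expression and velocity with low-dimensional coordinates.

    Parameters
    ----------
    expression
        Non-negative array of shape ``(n_cells, n_genes)``.
    velocity
        Array of the same shape; per-cell estimate of d(expression)/dt.
    pca_coords
        Array of shape ``(n_cells, d)``; the low-dimensional representation
        used for neighbor search, simulation alignment and scoring.
    embedding_2d
        Optional ``(n_cells, 2)`` display embedding (e.g. UMAP).
    cluster_labels
        Optional per-cell categorical labels (a grouping ``fs: C -> S`` with
        fewer groups than cells); any clustering or expert annotation works.
    cell_ids
        Unique string identifiers; generated as ``cell_0 ...`` if omitted.
    pca_loadings
        Optional ``(n_genes, d)`` component matrix, needed only to project
        velocity vectors into PC space.
    """

    expression: np.ndarray
    velocity: np.ndarray
    pca_coords: np.ndarray
    embedding_2d: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    cell_ids: np.ndarray | None = None
    pca_loadings: np.ndarray | None = None
    gene_ids: np.ndarray | None = None
    uns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.pca_coords = np.asarray(self.pca_coords, dtype=float)
        if self.expression.ndim != 2:
            raise ValueError("expression must be 2-D (cells x genes)")
        if self.expression.shape != self.velocity.shape:
            raise ValueError(
                f"expression {self.expression.shape} and velocity "
                f"{self.velocity.shape} must have identical shape"
            )
        if self.pca_coords.shape[0] != self.n_cells:
            raise ValueError(
                "pca_coords row count does not match the number of cells"
            )
        if np.any(self.expression < 0):
            raise ValueError("expression must be non-negative")
        if self.embedding_2d is not None:
            self.embedding_2d = np.asarray(self.embedding_2d, dtype=float)
            if self.embedding_2d.shape != (self.n_cells, 2):
                raise ValueError("embedding_2d must have shape (n_cells, 2)")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels).astype(str)
            if self.cluster_labels.shape != (self.n_cells,):
                raise ValueError("cluster_labels must be per-cell")
            if len(set(self.cluster_labels)) == 0:
                raise ValueError("cluster label set is empty")
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{i}" for i in range(self.n_cells)])
        else:
            self.cell_ids = np.asarray(self.cell_ids).astype(str)
            if len(set(self.cell_ids)) != self.n_cells:
                raise ValueError("cell_ids must be unique")
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene_{j}" for j in range(self.n_genes)])
        else:
            self.gene_ids = np.asarray(self.gene_ids).astype(str)

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def clusters_of(self, cells: np.ndarray) -> np.ndarray:
        """Cluster labels of the given cell indices (labels required)."""
        if self.cluster_labels is None:
            raise ValueError("dataset has no cluster labels")
        return self.cluster_labels[np.asarray(cells, dtype=int)]
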