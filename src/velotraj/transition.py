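"""Velocity-derived cell-to-cell transition model.

Builds, from expression + velocity, the three graphs the sampler runs on:

1. a k-nearest-neighbor graph in the low-dimensional (PCA) representation;
2. the *velocity graph* gamma: for each cell, the cosine similarity between
   its velocity vector and the displacement to each of its neighbors;
3. the row-stochastic transition matrix ``P`` obtained by an exponential
   kernel on gamma, normalized over each cell's neighbors.

Root and terminal state probabilities are the stationary distributions of the
reversed and forward Markov chain respectively, rescaled to a maximum of 1;
cells above a probability threshold (default 0.99) are the root set Cr and
terminal set Ct, and the clusters covering Ct are the terminal regions St.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datasets import VelocityDataset

__all__ = [
    "TransitionModel",
    "StationaryAnnotation",
    "build_neighbor_graph",
    "compute_velocity_graph",
    "transition_probabilities",
    "velocity_cohesiveness",
    "stationary_probabilities",
    "select_stationary_cells",
    "build_transition_model",
]


@dataclass
class TransitionModel:
    """Neighbor graph, velocity-cosine graph and transition matrix.

    ``neighbors`` and ``gamma`` are dense ``(n_cells, k)`` arrays (neighbor
    indices and velocity-displacement cosines); ``probs`` holds the per-row
    transition probabilities over the same neighbor columns.
    """

    neighbors: np.ndarray
    gamma: np.ndarray
    probs: np.ndarray
    kernel_scale: float

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def _to_sparse(self, data: np.ndarray) -> sp.csr_matrix:
        n, k = self.neighbors.shape
        indptr = np.arange(0, n * k + 1, k)
        return sp.csr_matrix(
            (data.ravel().copy(), self.neighbors.ravel().copy(), indptr),
            shape=(n, n),
        )

    @property
    def velocity_graph(self) -> sp.csr_matrix:
        """Sparse cells × cells matrix of velocity-displacement cosines."""
        return self._to_sparse(self.gamma)

    @property
    def P(self) -> sp.csr_matrix:
        """Sparse row-stochastic transition matrix."""
        return self._to_sparse(self.probs)


@dataclass
class StationaryAnnotation:
    """Root/terminal probabilities and the selected stationary cell sets."""

    root_prob: np.ndarray
    terminal_prob: np.ndarray
    root_cells: np.ndarray
    terminal_cells: np.ndarray
    terminal_regions: list
    threshold: float


def build_neighbor_graph(dataset: VelocityDataset, k: int = 30) -> np.ndarray:
    """Find each cell's ``k`` nearest neighbors in the PCA representation.

    Euclidean distance; self excluded; ties broken by cell index so the
    graph is deterministic. Returns an ``(n_cells, k)`` integer array.
    """
    coords = dataset.pca_coords
    if coords is None or coords.size == 0:
        raise ValueError("dataset has no low-dimensional coordinates")
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if k < 1:
        raise ValueError("k must be a positive integer")
    neighbors = np.empty((n, k), dtype=np.int64)
    # chunked brute force: stable argsort makes tie-breaking by index exact
    chunk = max(1, int(2e7) // max(n, 1))
    sq = np.einsum("ij,ij->i", coords, coords)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * coords[start:stop] @ coords.T
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        order = np.argsort(d2, axis=1, kind="stable")
        neighbors[start:stop] = order[:, :k]
    return neighbors


def compute_velocity_graph(
    dataset: VelocityDataset,
    neighbors: np.ndarray,
    space: str = "gene",
) -> np.ndarray:
    """Cosine similarity between each cell's velocity and neighbor displacements.

    The displacement of neighbor ``k`` of cell ``c`` is
    ``position(k) - position(c)`` in the configured space (``"gene"`` uses
    the expression matrix, ``"pca"`` the PC coordinates with velocity
    projected through the component loadings). Zero-norm velocity or
    displacement vectors yield cosine 0.
    """
    if space == "gene":
        pos = dataset.expression
        vel = dataset.velocity
    elif space == "pca":
        if dataset.pca_loadings is None:
            raise ValueError("pca space requires dataset.pca_loadings")
        pos = dataset.pca_coords
        vel = dataset.velocity @ dataset.pca_loadings
    else:
        raise ValueError(f"unknown space {space!r}")
    if vel.shape != pos.shape:
        raise ValueError("velocity shape does not match coordinate space")
    n, k = neighbors.shape
    disp = pos[neighbors] - pos[:, None, :]  # (n, k, d)
    dots = np.einsum("nkd,nd->nk", disp, vel)
    disp_norm = np.linalg.norm(disp, axis=2)
    vel_norm = np.linalg.norm(vel, axis=1)
    denom = disp_norm * vel_norm[:, None]
    gamma = np.zeros((n, k))
    np.divide(dots, denom, out=gamma, where=denom > 0)
    return gamma


def transition_probabilities(gamma: np.ndarray, kernel_scale: float = 0.1) -> np.ndarray:
    """Row-stochastic transition probabilities ``exp(gamma / scale)``, normalized.

    A smaller ``kernel_scale`` sharpens the kernel toward the best-aligned
    neighbor; the default 0.1 is a sharpened exponential-of-cosine.
    """
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be positive")
    if gamma.ndim != 2 or gamma.shape[1] == 0:
        raise ValueError("each cell needs at least one neighbor")
    z = gamma / kernel_scale
    z = z - z.max(axis=1, keepdims=True)  # stable softmax
    w = np.exp(z)
    return w / w.sum(axis=1, keepdims=True)


def velocity_cohesiveness(gamma: np.ndarray) -> np.ndarray:
    """Per-cell mean of the stored neighbor cosines; in [-1, 1].

    Cells whose whole row is zero (zero velocity) keep the value 0 and are
    flagged with a warning.
    """
    coh = gamma.mean(axis=1)
    empty = ~np.any(gamma != 0, axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} cells have an all-zero velocity-graph row; "
            "cohesiveness reported as 0 for them",
            stacklevel=2,
        )
        coh[empty] = 0.0
    return coh


def _stationary(P: sp.spmatrix, tol: float, max_iter: int) -> np.ndarray:
    n = P.shape[0]
    PT = sp.csr_matrix(P).T.tocsr()
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = PT @ x
        s = x_new.sum()
        if s <= 0:
            raise RuntimeError("stationary iteration lost all mass")
        x_new /= s
        resid = np.abs(x_new - x).max()
        x = x_new
        if resid < tol:
            return x
    raise RuntimeError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(residual {resid:.3e} > tol {tol:.1e})"
    )


def stationary_probabilities(
    P: sp.spmatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Root and terminal state probabilities from the transition matrix.

    The terminal probability is the stationary distribution of the forward
    chain ``P`` (power iteration); the root probability is the stationary
    distribution of the reversed chain (transpose of ``P`` with rows
    re-normalized). Both are rescaled to a maximum of 1 over the dataset so
    they read as per-cell probabilities.
    """
    P = sp.csr_matrix(P)
    rowsum = np.asarray(P.sum(axis=1)).ravel()
    if np.any(np.abs(rowsum - 1.0) > 1e-6):
        raise ValueError("P must be row-stochastic")
    terminal = _stationary(P, tol, max_iter)
    R = P.T.tolil()
    rsum = np.asarray(R.sum(axis=1)).ravel()
    for i in np.flatnonzero(rsum <= 0):
        R[i, i] = 1.0  # no in-edges: hold mass in place in the reversed chain
        rsum[i] = 1.0
    Rn = sp.diags(1.0 / rsum) @ R.tocsr()
    root = _stationary(Rn, tol, max_iter)
    return root / root.max(), terminal / terminal.max()


def select_stationary_cells(
    root_prob: np.ndarray,
    terminal_prob: np.ndarray,
    cluster_labels: np.ndarray,
    threshold: float = 0.99,
    root_cells: np.ndarray | None = None,
    terminal_cells: np.ndarray | None = None,
    root_clusters: list | None = None,
    terminal_clusters: list | None = None,
) -> StationaryAnnotation:
    """Threshold the stationary probabilities into root/terminal cell sets.

    ``Cr = {c : root_prob(c) >= threshold}`` and likewise for ``Ct``; the
    terminal regions ``St`` are the cluster labels of the terminal cells.
    User-supplied cells or whole clusters override the inference (prior
    biological knowledge beats the data-driven selection).
    """
    cluster_labels = np.asarray(cluster_labels).astype(str)
    n = len(cluster_labels)

    def _from_clusters(names: list) -> np.ndarray:
        names = [str(x) for x in names]
        missing = set(names) - set(cluster_labels)
        if missing:
            raise ValueError(f"unknown cluster labels: {sorted(missing)}")
        return np.flatnonzero(np.isin(cluster_labels, names))

    if root_cells is not None:
        Cr = np.asarray(root_cells, dtype=int)
    elif root_clusters is not None:
        Cr = _from_clusters(root_clusters)
    else:
        Cr = np.flatnonzero(root_prob >= threshold)
    if terminal_cells is not None:
        Ct = np.asarray(terminal_cells, dtype=int)
    elif terminal_clusters is not None:
        Ct = _from_clusters(terminal_clusters)
    else:
        Ct = np.flatnonzero(terminal_prob >= threshold)
    if len(Cr) == 0:
        raise ValueError(
            "no root cells selected; reduce the threshold or supply root "
            "cells/clusters manually"
        )
    if len(Ct) == 0:
        raise ValueError(
            "no terminal cells selected; reduce the threshold or supply "
            "terminal cells/clusters manually"
        )
    if Cr.max() >= n or Ct.max() >= n:
        raise ValueError("cell index out of range")
    St = sorted(set(cluster_labels[Ct]))
    return StationaryAnnotation(
        root_prob=np.asarray(root_prob, dtype=float),
        terminal_prob=np.asarray(terminal_prob, dtype=float),
        root_cells=Cr,
        terminal_cells=Ct,
        terminal_regions=St,
        threshold=threshold,
    )


def build_transition_model(
    dataset: VelocityDataset,
    k: int = 30,
    kernel_scale: float = 0.1,
    space: str = "gene",
) -> TransitionModel:
    """Convenience constructor: neighbor graph -> velocity graph -> P."""
    neighbors = build_neighbor_graph(dataset, k=k)
    gamma = compute_velocity_graph(dataset, neighbors, space=space)
    probs = transition_probabilities(gamma, kernel_scale=kernel_scale)
    return TransitionModel(
        neighbors=neighbors, gamma=gamma, probs=probs, kernel_scale=kernel_scale
    )
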