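"""Consensus trajectories from ensembles of simulations.

Simulations terminating in one terminal region are compared with the
Euclidean Hausdorff distance, clustered with Louvain community detection on a
Gaussian-affinity k-NN graph of that distance, and each cluster is collapsed
into a single ordered sequence by greedy-pairwise dynamic time warping: the
per-step mean of the aligned sequences is the (sub-)trajectory coordinate. A
second clustering + alignment round over the sub-trajectories yields the
trajectories that are reported.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff

from ._kernels import dtw_path, dtw_path_fast, pairwise_hausdorff
from .datasets import VelocityDataset
from .sampling import SimulationEnsemble

__all__ = [
    "Trajectory",
    "AlignedSimulations",
    "hausdorff_distance",
    "cluster_simulations",
    "dtw_align",
    "consensus_coordinates",
    "infer_trajectories",
]


def hausdorff_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Euclidean Hausdorff distance between two point sequences.

    ``H(A, B) = max(max_a min_b d(a, b), max_b min_a d(b, a))`` with
    Euclidean ``d``; symmetric, zero iff the point sets coincide.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("point sequences must be non-empty")
    return max(directed_hausdorff(A, B)[0], directed_hausdorff(B, A)[0])


def cluster_simulations(
    distance_matrix: np.ndarray,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Louvain communities on an affinity graph derived from distances.

    The affinity is a Gaussian kernel ``exp(-H^2 / sigma^2)`` with ``sigma``
    the median off-diagonal distance, sparsified to each node's
    ``min(15, n - 1)`` strongest edges (kept if in either endpoint's list).
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if n == 1:
        return np.zeros(1, dtype=int)
    off = D[~np.eye(n, dtype=bool)]
    sigma = np.median(off)
    if sigma <= 0:
        return np.zeros(n, dtype=int)  # all sequences identical
    A = np.exp(-(D**2) / sigma**2)
    np.fill_diagonal(A, 0.0)
    k = min(15, n - 1)
    keep = np.zeros_like(A, dtype=bool)
    order = np.argsort(-A, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    keep[rows, order[:, :k].ravel()] = True
    keep |= keep.T
    src, dst = np.nonzero(np.triu(keep, 1))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    weights = A[src, dst].tolist()
    state = _random.getstate()
    try:
        ig.set_random_number_generator(_random.Random(seed))
        part = g.community_multilevel(weights=weights, resolution=resolution)
    finally:
        ig.set_random_number_generator(_random)
        _random.setstate(state)
    return np.asarray(part.membership, dtype=int)


@dataclass
class AlignedSimulations:
    """Result of greedy-pairwise DTW over one cluster of sequences.

    ``index_maps[s, p]`` is the step of original sequence ``s`` matched to
    consensus position ``p``; the aligned step matrix repeats each sequence's
    coordinates along its warped positions.
    """

    sequences: list
    index_maps: np.ndarray
    sum_coords: np.ndarray
    counts: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.sum_coords.shape[0]

    def matrix(self) -> np.ndarray:
        """Aligned step matrix of shape (n_sequences, n_steps, dim)."""
        return np.stack(
            [np.asarray(s)[self.index_maps[i]] for i, s in enumerate(self.sequences)]
        )

    def consensus(self) -> np.ndarray:
        """Per-step mean coordinate across the aligned sequences."""
        return self.sum_coords / self.counts[:, None]


@dataclass
class Trajectory:
    """Ordered consensus coordinates of one inferred differentiation path."""

    steps: np.ndarray
    terminal_region: str | None = None
    anchored: bool = False
    anchor_cells: np.ndarray | None = None
    embedding: np.ndarray | None = None
    source_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.steps = np.atleast_2d(np.asarray(self.steps, dtype=float))
        if self.steps.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 steps")

    @property
    def n_steps(self) -> int:
        return self.steps.shape[0]

    @property
    def segments(self) -> np.ndarray:
        """Consecutive step-difference vectors (n_steps - 1, dim)."""
        return np.diff(self.steps, axis=0)


def dtw_align(sequences: list, max_exact: int = 200, radius: int = 1) -> AlignedSimulations:
    """Greedy-pairwise DTW alignment of a cluster of point sequences.

    Sequences are taken longest-first (ties by input order); each next
    sequence is aligned to the running consensus and both are expanded along
    the warping path, so all sequences end up with a common step axis.
    """
    if len(sequences) == 0:
        raise ValueError("no sequences to align")
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    n = len(seqs)
    order = sorted(range(n), key=lambda i: (-seqs[i].shape[0], i))
    first = seqs[order[0]]
    sum_coords = first.copy()
    counts = np.ones(first.shape[0])
    paths: list[tuple[np.ndarray, np.ndarray]] = []
    for t in range(1, n):
        s = seqs[order[t]]
        cons = sum_coords / counts[:, None]
        if max(cons.shape[0], s.shape[0]) > max_exact:
            ia, ib, _ = dtw_path_fast(cons, s, radius=radius, max_exact=max_exact)
        else:
            ia, ib, _ = dtw_path(cons, s)
        sum_coords = sum_coords[ia] + s[ib]
        counts = counts[ia] + 1.0
        paths.append((ia, ib))
    # compose per-sequence index maps from last alignment back to the first
    L = sum_coords.shape[0]
    maps = np.empty((n, L), dtype=np.int64)
    comp = np.arange(L)
    for t in range(n - 1, 0, -1):
        ia, ib = paths[t - 1]
        maps[order[t]] = ib[comp]
        comp = ia[comp]
    maps[order[0]] = comp
    return AlignedSimulations(
        sequences=seqs, index_maps=maps, sum_coords=sum_coords, counts=counts
    )


def consensus_coordinates(
    aligned: AlignedSimulations,
    dataset: VelocityDataset | None = None,
    anchor: bool = False,
    terminal_region: str | None = None,
    source_ids: list | None = None,
) -> Trajectory:
    """Collapse an aligned cluster into a trajectory (per-step means).

    With ``anchor=True`` each mean coordinate is replaced by the nearest
    observed cell state (requires the dataset; alignment space must be its
    PCA space). The 2-D embedding of each step is taken from the nearest
    cell when the dataset provides one.
    """
    steps = aligned.consensus()
    anchor_cells = None
    embedding = None
    if dataset is not None:
        tree = cKDTree(dataset.pca_coords)
        _, anchor_cells = tree.query(steps)
        anchor_cells = np.asarray(anchor_cells, dtype=int)
        if anchor:
            steps = dataset.pca_coords[anchor_cells]
        if dataset.embedding_2d is not None:
            embedding = dataset.embedding_2d[anchor_cells]
    elif anchor:
        raise ValueError("anchoring requires the dataset")
    return Trajectory(
        steps=steps,
        terminal_region=terminal_region,
        anchored=anchor,
        anchor_cells=anchor_cells,
        embedding=embedding,
        source_ids=source_ids or [],
    )


def _merge_to_count(
    groups: list[list[np.ndarray]], target: int
) -> list[list[np.ndarray]]:
    """Merge the two closest groups (consensus Hausdorff) until ``target``."""
    while len(groups) > target:
        cons = [dtw_align(g).consensus() for g in groups]
        H = pairwise_hausdorff(cons)
        np.fill_diagonal(H, np.inf)
        i, j = np.unravel_index(np.argmin(H), H.shape)
        i, j = min(i, j), max(i, j)
        groups[i] = groups[i] + groups.pop(j)
    return groups


def infer_trajectories(
    ensemble: SimulationEnsemble,
    dataset: VelocityDataset,
    n_per_region: int | None = None,
    resolution: float = 1.0,
    anchor: bool = False,
    seed: int = 0,
) -> list[Trajectory]:
    """Two-round consensus: simulations -> sub-trajectories -> trajectories.

    Per terminal region: cluster the simulations' PCA-coordinate sequences
    (Hausdorff + Louvain), DTW-align each cluster into a sub-trajectory, then
    cluster and align the sub-trajectories into the reported trajectories.
    ``n_per_region`` optionally enforces a trajectory count by merging the
    closest sub-trajectory groups; regions yielding fewer warn.
    """
    trajectories: list[Trajectory] = []
    for region, sims in sorted(
        ensemble.by_region().items(), key=lambda kv: str(kv[0])
    ):
        if region is None:
            continue
        if len(sims) == 0:
            warnings.warn(f"region {region} has no simulations; skipped", stacklevel=2)
            continue
        seqs = [dataset.pca_coords[s.cell_indices] for s in sims]
        H = pairwise_hausdorff(seqs)
        labels = cluster_simulations(H, resolution=resolution, seed=seed)
        sub_groups: list[list[np.ndarray]] = []
        sub_trajectories: list[np.ndarray] = []
        for lab in np.unique(labels):
            members = [seqs[i] for i in np.flatnonzero(labels == lab)]
            sub_groups.append(members)
            sub_trajectories.append(dtw_align(members).consensus())
        # second round over sub-trajectories
        if len(sub_trajectories) == 1:
            final_groups = [[sub_trajectories[0]]]
        else:
            H2 = pairwise_hausdorff(sub_trajectories)
            labels2 = cluster_simulations(H2, resolution=resolution, seed=seed)
            final_groups = []
            for lab in np.unique(labels2):
                idx = np.flatnonzero(labels2 == lab)
                final_groups.append([sub_trajectories[i] for i in idx])
        if n_per_region is not None:
            if len(final_groups) > n_per_region:
                final_groups = _merge_to_count(final_groups, n_per_region)
            elif len(final_groups) < n_per_region:
                warnings.warn(
                    f"region {region}: {len(final_groups)} trajectories found, "
                    f"{n_per_region} requested; cannot split",
                    stacklevel=2,
                )
        for gi, group in enumerate(final_groups):
            aligned = dtw_align(group)
            trajectories.append(
                consensus_coordinates(
                    aligned,
                    dataset=dataset,
                    anchor=anchor,
                    terminal_region=str(region),
                    source_ids=[f"{region}:{gi}"],
                )
            )
    return trajectories
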