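"""Cell-to-trajectory association: alignment score, pseudotime, fate, potential.

A cell is compared to a trajectory segment through its transition partners
(its neighbors in the transition model): the score of segment ``b`` is the
mean over partners ``k`` of ``cos(eta_kb) * exp(gamma_k)``, where ``eta`` is
the angle between the segment and the displacement to partner ``k`` and
``gamma`` is the velocity-displacement cosine already stored in the velocity
graph. The per-step score is the larger of the backward/forward segment
scores; the step-weighted mean gives pseudotime, the across-trajectory
normalization gives fate probabilities, and the entropy of the fate
distribution (min-max scaled) is the differentiation potential.

Scoring is restricted to cells of the trajectory's *compositional clusters*
— clusters sufficiently represented (frequency > 0.3 by default) in the
neighborhood of at least one trajectory step — and, by default, to the cells
inside each step's neighborhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.stats import entropy

from .consensus import Trajectory
from .datasets import VelocityDataset
from .transition import TransitionModel

__all__ = [
    "CompositionalClusters",
    "TrajectoryAlignment",
    "compositional_clusters",
    "alignment_score",
    "trajectory_alignment",
    "pseudotime",
    "fate_score",
    "differentiation_potential",
    "consensus_pseudotime",
    "euclidean_pseudotime",
    "rolling_rate_comparison",
]


@dataclass
class CompositionalClusters:
    """Clusters represented along a trajectory and the step neighborhoods."""

    clusters: list
    neighborhoods: np.ndarray  # (n_steps, neighborhood_size) cell indices
    threshold: float


@dataclass
class TrajectoryAlignment:
    """Per-cell step scores and summary alignment for one trajectory."""

    scores: sp.csr_matrix  # cells x steps, floored at 0
    p: np.ndarray  # per-cell summary; NaN where unaligned
    compositional: CompositionalClusters


def compositional_clusters(
    trajectory: Trajectory,
    dataset: VelocityDataset,
    neighborhood_size: int = 50,
    threshold: float = 0.3,
) -> CompositionalClusters:
    """Clusters whose frequency exceeds ``threshold`` in some step neighborhood.

    For each trajectory step the neighborhood ``Mi`` is the fixed number of
    nearest cells in PCA space (k-d tree search).
    """
    if dataset.cluster_labels is None:
        raise ValueError("dataset must carry cluster labels")
    size = min(neighborhood_size, dataset.n_cells)
    tree = cKDTree(dataset.pca_coords)
    _, nbhd = tree.query(trajectory.steps, k=size)
    nbhd = np.atleast_2d(np.asarray(nbhd, dtype=int))
    if nbhd.size == 0:
        raise ValueError("degenerate trajectory projection: empty neighborhoods")
    labels = dataset.cluster_labels
    comp = set()
    for i in range(nbhd.shape[0]):
        vals, counts = np.unique(labels[nbhd[i]], return_counts=True)
        freq = counts / counts.sum()
        comp.update(vals[freq > threshold])
    return CompositionalClusters(
        clusters=sorted(comp), neighborhoods=nbhd, threshold=threshold
    )


def _segment_scores(
    cells: np.ndarray,
    segment: np.ndarray,
    disp: np.ndarray,
    exp_gamma: np.ndarray,
) -> np.ndarray:
    """Mean over partners of cos(eta) * exp(gamma) for one segment vector."""
    seg_norm = np.linalg.norm(segment)
    if seg_norm == 0:
        return np.zeros(len(cells))
    d = disp[cells]  # (n, k, dim)
    dots = d @ segment
    dn = np.linalg.norm(d, axis=2)
    cos_eta = np.zeros_like(dots)
    denom = dn * seg_norm
    np.divide(dots, denom, out=cos_eta, where=denom > 0)
    return (cos_eta * exp_gamma[cells]).mean(axis=1)


def alignment_score(
    cell: int,
    trajectory: Trajectory,
    dataset: VelocityDataset,
    model: TransitionModel,
    steps: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Step scores and summary alignment ``p`` of a single cell.

    Convenience wrapper over the batch implementation; scores every step
    unless ``steps`` restricts the candidates. Negative step scores are
    floored at 0; the summary is the mean over positively scoring steps
    (NaN if none).
    """
    disp = dataset.pca_coords[model.neighbors] - dataset.pca_coords[:, None, :]
    eg = np.exp(model.gamma)
    L = trajectory.n_steps
    candidates = np.arange(L) if steps is None else np.asarray(steps, dtype=int)
    segs = trajectory.segments
    out = np.zeros(L)
    cell_arr = np.array([cell])
    for i in candidates:
        xi = []
        if i > 0:
            xi.append(_segment_scores(cell_arr, segs[i - 1], disp, eg)[0])
        if i < L - 1:
            xi.append(_segment_scores(cell_arr, segs[i], disp, eg)[0])
        out[i] = max(xi)
    out = np.maximum(out, 0.0)
    pos = out[out > 0]
    return out, (float(pos.mean()) if pos.size else float("nan"))


def trajectory_alignment(
    trajectory: Trajectory,
    dataset: VelocityDataset,
    model: TransitionModel,
    neighborhood_size: int = 50,
    threshold: float = 0.3,
    restrict: bool = True,
) -> TrajectoryAlignment:
    """Score all eligible cells against all steps of one trajectory.

    With ``restrict=True`` (default) a cell is scored at step ``i`` only if
    it belongs to a compositional cluster and lies in the step's
    neighborhood ``Mi``; ``restrict=False`` scores every cell at every step.
    """
    comp = compositional_clusters(
        trajectory, dataset, neighborhood_size=neighborhood_size, threshold=threshold
    )
    n, L = dataset.n_cells, trajectory.n_steps
    disp = dataset.pca_coords[model.neighbors] - dataset.pca_coords[:, None, :]
    eg = np.exp(model.gamma)
    segs = trajectory.segments
    in_comp = (
        np.isin(dataset.cluster_labels, comp.clusters)
        if dataset.cluster_labels is not None
        else np.ones(n, dtype=bool)
    )
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for i in range(L):
        if restrict:
            cells = np.unique(comp.neighborhoods[i])
            cells = cells[in_comp[cells]]
        else:
            cells = np.flatnonzero(in_comp)
        if cells.size == 0:
            continue
        xi_b = _segment_scores(cells, segs[i - 1], disp, eg) if i > 0 else None
        xi_f = _segment_scores(cells, segs[i], disp, eg) if i < L - 1 else None
        if xi_b is None:
            p_i = xi_f
        elif xi_f is None:
            p_i = xi_b
        else:
            p_i = np.maximum(xi_b, xi_f)
        p_i = np.maximum(p_i, 0.0)
        keep = p_i > 0
        rows.append(cells[keep])
        cols.append(np.full(int(keep.sum()), i))
        vals.append(p_i[keep])
    if rows:
        scores = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, L),
        )
    else:
        scores = sp.csr_matrix((n, L))
    counts = np.diff(scores.indptr)
    sums = np.asarray(scores.sum(axis=1)).ravel()
    p = np.full(n, np.nan)
    aligned = counts > 0
    p[aligned] = sums[aligned] / counts[aligned]
    return TrajectoryAlignment(scores=scores, p=p, compositional=comp)


def pseudotime(alignment: TrajectoryAlignment) -> np.ndarray:
    """Alignment-weighted mean step index per cell; NaN where unaligned."""
    scores = alignment.scores
    n, L = scores.shape
    weights = np.asarray(scores.sum(axis=1)).ravel()
    weighted = scores @ np.arange(L, dtype=float)
    pt = np.full(n, np.nan)
    pos = weights > 0
    pt[pos] = weighted[pos] / weights[pos]
    return pt


def fate_score(p_matrix: np.ndarray) -> np.ndarray:
    """Row-normalize summary scores over trajectories (cells x trajectories).

    Missing alignments (NaN) contribute 0; cells aligned to no trajectory get
    all-NaN rows. Rows of scored cells lie on the probability simplex.
    """
    P = np.asarray(p_matrix, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    filled = np.nan_to_num(P, nan=0.0)
    totals = filled.sum(axis=1)
    fates = np.full_like(filled, np.nan)
    pos = totals > 0
    fates[pos] = filled[pos] / totals[pos, None]
    return fates


def differentiation_potential(fates: np.ndarray) -> np.ndarray:
    """Shannon entropy of each fate row, min-max rescaled to [0, 1].

    Uncommitted cells (even fates across lineages) score high; committed
    cells score 0. Unscored cells stay NaN; a degenerate dataset (all
    entropies equal) maps to all zeros with a warning.
    """
    fates = np.asarray(fates, dtype=float)
    scored = ~np.isnan(fates).any(axis=1)
    out = np.full(fates.shape[0], np.nan)
    if not scored.any():
        return out
    H = entropy(fates[scored], axis=1)
    lo, hi = H.min(), H.max()
    if hi == lo:
        warnings.warn(
            "all fate entropies equal; differentiation potential set to 0",
            stacklevel=2,
        )
        out[scored] = 0.0
    else:
        out[scored] = (H - lo) / (hi - lo)
    return out


def consensus_pseudotime(
    pseudotimes: np.ndarray, fates: np.ndarray
) -> np.ndarray:
    """Fate-weighted mean pseudotime across trajectories (cells x traj in)."""
    T = np.asarray(pseudotimes, dtype=float)
    F = np.asarray(fates, dtype=float)
    w = np.where(np.isnan(T) | np.isnan(F), 0.0, F)
    t = np.nan_to_num(T, nan=0.0)
    tot = w.sum(axis=1)
    out = np.full(T.shape[0], np.nan)
    pos = tot > 0
    out[pos] = (t * w).sum(axis=1)[pos] / tot[pos]
    return out


def euclidean_pseudotime(
    trajectory: Trajectory,
    dataset: VelocityDataset,
    cells: np.ndarray | None = None,
) -> np.ndarray:
    """Non-velocity baseline: index of the nearest trajectory segment.

    Each cell is assigned the end-step index of the segment (consecutive
    step pair) with minimal point-to-segment Euclidean distance in PCA
    space; ties resolve to the lower index. Velocity plays no role.
    """
    pts = dataset.pca_coords if cells is None else dataset.pca_coords[cells]
    starts = trajectory.steps[:-1]
    vecs = trajectory.segments  # (L-1, d)
    lens2 = np.einsum("ld,ld->l", vecs, vecs)
    diff = pts[:, None, :] - starts[None, :, :]  # (n, L-1, d)
    tproj = np.einsum("nld,ld->nl", diff, vecs)
    with np.errstate(invalid="ignore", divide="ignore"):
        tproj = np.where(lens2 > 0, tproj / lens2, 0.0)
    tproj = np.clip(tproj, 0.0, 1.0)
    closest = starts[None] + tproj[..., None] * vecs[None]
    d2 = np.einsum("nld,nld->nl", pts[:, None, :] - closest, pts[:, None, :] - closest)
    seg = np.argmin(d2, axis=1)  # argmin takes the first (lowest) on ties
    return (seg + 1).astype(float)


def rolling_rate_comparison(
    pseudotime_a: np.ndarray,
    pseudotime_b: np.ndarray,
    window: int = 50,
) -> np.ndarray:
    """Per-cell local slope of pseudotime ``b`` against pseudotime ``a``.

    Cells are ordered by ``a``; for each cell a window of ``window`` cells
    centered on it (clamped at the boundaries) is fit by ordinary least
    squares and the slope reported, in the original cell order.
    """
    a = np.asarray(pseudotime_a, dtype=float)
    b = np.asarray(pseudotime_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pseudotimes must cover a common cell set")
    ok = ~(np.isnan(a) | np.isnan(b))
    n_ok = int(ok.sum())
    if window > n_ok:
        raise ValueError(f"window {window} exceeds the {n_ok} scored cells")
    if window < 2:
        raise ValueError("window must be >= 2")
    order = np.argsort(a[ok], kind="stable")
    ao, bo = a[ok][order], b[ok][order]
    half = window // 2
    slopes = np.empty(n_ok)
    for pos in range(n_ok):
        lo = max(0, min(pos - half, n_ok - window))
        x = ao[lo : lo + window]
        y = bo[lo : lo + window]
        xc = x - x.mean()
        denom = (xc**2).sum()
        slopes[pos] = (xc * (y - y.mean())).sum() / denom if denom > 0 else np.nan
    out = np.full(a.shape, np.nan)
    idx = np.flatnonzero(ok)[order]
    out[idx] = slopes
    return out
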