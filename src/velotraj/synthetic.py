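"""Seeded synthetic differentiation manifolds with ground-truth dynamics.

Cells are placed on smooth curves in gene space: each gene carries one
Gaussian-bump expression program along the process time ``t in [0, 1]``
(periodic von-Mises-style bumps for the cyclic topology). Branching
topologies assign genes to a trunk or to one branch; branch programs switch
on after the branch point. The velocity of a cell is the analytic tangent
``d(expression)/dt`` scaled by an optional per-time magnitude profile, so
velocities point exactly along progression before noise is added. Ground
truth (process time and branch) is returned with every dataset.

Topologies: linear, bifurcating (1 -> 2 fates), multifurcating (1 -> 3),
cyclic (closed curve) and convergent (2 roots -> 1 fate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.decomposition import PCA

from .datasets import VelocityDataset

__all__ = ["TopologySpec", "GroundTruth", "generate", "toy_chain_fixtures"]

_KINDS = ("linear", "bifurcating", "multifurcating", "cyclic", "convergent")
_BUMP_WIDTH = 0.12  # sd of the Gaussian gene programs, in process-time units


@dataclass
class TopologySpec:
    """Recipe for one synthetic dataset.

    ``branch_time`` is the process-time fraction of the branch (or merge)
    point; ``velocity_magnitude`` optionally rescales the tangent per cell as
    a function of t (callable or scalar). ``noise_sd`` is the iid Gaussian
    expression noise (truncated at 0); velocity noise defaults to the same
    scale.
    """

    kind: str = "linear"
    n_cells: int = 500
    n_genes: int = 50
    branch_time: float = 0.5
    noise_sd: float = 0.05
    velocity_noise_sd: float | None = None
    velocity_magnitude: Callable[[np.ndarray], np.ndarray] | float | None = None
    n_pcs: int = 10
    bins_per_branch: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.n_cells < 20:
            raise ValueError("n_cells must be at least 20")
        if not 0 < self.branch_time < 1:
            raise ValueError("branch_time must lie strictly inside (0, 1)")


@dataclass
class GroundTruth:
    true_time: np.ndarray
    true_branch: np.ndarray
    root_clusters: list = field(default_factory=list)
    terminal_clusters: list = field(default_factory=list)


def _n_branches(kind: str) -> int:
    return {"linear": 1, "bifurcating": 2, "multifurcating": 3, "cyclic": 1, "convergent": 2}[kind]


def _gene_programs(spec: TopologySpec, rng: np.random.Generator):
    """Assign each gene a component (trunk or branch) and a bump center."""
    nb = _n_branches(spec.kind)
    w = _BUMP_WIDTH
    tb = spec.branch_time
    components = np.zeros(spec.n_genes, dtype=int)  # 0 = trunk, 1..nb = branch
    centers = np.empty(spec.n_genes)
    if spec.kind in ("linear", "cyclic"):
        centers[:] = rng.uniform(0, 1, spec.n_genes)
    elif spec.kind == "convergent":
        # branch programs live before the merge point, trunk after
        n_branch_genes = spec.n_genes // 2
        idx = rng.permutation(spec.n_genes)
        bgenes = idx[:n_branch_genes]
        components[bgenes] = 1 + (np.arange(n_branch_genes) % nb)
        lo, hi = 0.0, max(tb - 3 * w, 0.05)
        centers[bgenes] = rng.uniform(lo, hi, n_branch_genes)
        tgenes = idx[n_branch_genes:]
        centers[tgenes] = rng.uniform(min(tb, 0.95), 1.0, len(tgenes))
    else:  # bifurcating / multifurcating
        n_branch_genes = spec.n_genes // 2
        idx = rng.permutation(spec.n_genes)
        bgenes = idx[:n_branch_genes]
        components[bgenes] = 1 + (np.arange(n_branch_genes) % nb)
        lo = min(tb + 3 * w, 0.95)
        centers[bgenes] = rng.uniform(lo, 1.0, n_branch_genes)
        tgenes = idx[n_branch_genes:]
        centers[tgenes] = rng.uniform(0.0, max(tb, 0.05), len(tgenes))
    return components, centers


def expression_curve(
    spec: TopologySpec,
    t: np.ndarray,
    branch: np.ndarray,
    components: np.ndarray,
    centers: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless expression and its exact time derivative at (t, branch).

    A gene contributes when it belongs to the trunk or to the cell's branch.
    Linear/branching programs are Gaussian bumps ``exp(-(t - mu)^2 / 2w^2)``;
    the cyclic topology uses the periodic bump
    ``exp(kappa (cos(2 pi (t - mu)) - 1))`` so the curve closes on itself.
    """
    t = np.asarray(t, dtype=float)
    branch = np.asarray(branch, dtype=int)
    n, g = len(t), len(components)
    active = (components[None, :] == 0) | (components[None, :] == branch[:, None])
    if spec.kind == "cyclic":
        kappa = 1.0 / (2 * np.pi * _BUMP_WIDTH) ** 2
        phase = 2 * np.pi * (t[:, None] - centers[None, :])
        expr = np.exp(kappa * (np.cos(phase) - 1.0))
        dexpr = expr * (-kappa * np.sin(phase)) * 2 * np.pi
    else:
        w2 = _BUMP_WIDTH**2
        delta = t[:, None] - centers[None, :]
        expr = np.exp(-(delta**2) / (2 * w2))
        dexpr = expr * (-delta / w2)
    expr = np.where(active, expr, 0.0)
    dexpr = np.where(active, dexpr, 0.0)
    return expr, dexpr


def _magnitude(spec: TopologySpec, t: np.ndarray) -> np.ndarray:
    prof = spec.velocity_magnitude
    if prof is None:
        return np.ones_like(t)
    if callable(prof):
        return np.asarray(prof(t), dtype=float) * np.ones_like(t)
    return float(prof) * np.ones_like(t)


def _cluster_labels(spec: TopologySpec, t: np.ndarray, branch: np.ndarray) -> np.ndarray:
    """Equal-width process-time bins per branch stand in for Louvain clusters."""
    nbins = spec.bins_per_branch if spec.kind != "cyclic" else max(spec.bins_per_branch, 8)
    bins = np.minimum((t * nbins).astype(int), nbins - 1)
    return np.array([f"b{b}_t{i}" for b, i in zip(branch, bins)])


def generate(spec: TopologySpec) -> tuple[VelocityDataset, GroundTruth]:
    """Sample a synthetic dataset and its ground truth, deterministically.

    Process times are uniform on [0, 1]; cells past the branch point are
    split evenly across branches (before it they sit on the trunk, branch 0;
    the convergent topology reverses this). Expression noise is iid Gaussian
    truncated at 0; velocity noise is isotropic Gaussian.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    t = np.sort(rng.uniform(0, 1, n))
    nb = _n_branches(spec.kind)
    branch = np.zeros(n, dtype=int)
    if spec.kind in ("bifurcating", "multifurcating"):
        post = t > spec.branch_time
        branch[post] = 1 + rng.integers(0, nb, int(post.sum()))
    elif spec.kind == "convergent":
        pre = t <= spec.branch_time
        branch[pre] = 1 + rng.integers(0, nb, int(pre.sum()))
    components, centers = _gene_programs(spec, rng)
    expr, dexpr = expression_curve(spec, t, branch, components, centers)
    velocity = dexpr * _magnitude(spec, t)[:, None]
    if spec.noise_sd > 0:
        expr = np.maximum(expr + rng.normal(0, spec.noise_sd, expr.shape), 0.0)
    vnoise = spec.velocity_noise_sd if spec.velocity_noise_sd is not None else spec.noise_sd
    if vnoise > 0:
        velocity = velocity + rng.normal(0, vnoise, velocity.shape)
    d = min(spec.n_pcs, spec.n_genes, n)
    pca = PCA(n_components=d, svd_solver="full", random_state=0)
    coords = pca.fit_transform(expr)
    loadings = pca.components_.T
    labels = _cluster_labels(spec, t, branch)
    dataset = VelocityDataset(
        expression=expr,
        velocity=velocity,
        pca_coords=coords,
        embedding_2d=coords[:, :2].copy(),
        cluster_labels=labels,
        pca_loadings=loadings,
        uns={"topology": spec.kind, "seed": spec.seed},
    )
    if spec.kind == "convergent":
        roots = sorted({lab for lab in labels if lab.endswith("_t0") and not lab.startswith("b0")})
        terminal = [labels[np.argmax(t)]]
    elif spec.kind == "cyclic":
        roots = [labels[np.argmin(t)]]
        terminal = [labels[np.argmax(t)]]  # the phase bin just before closing
    else:
        roots = [labels[np.argmin(t)]]
        last_bin = spec.bins_per_branch - 1
        terminal = sorted({lab for lab in labels if lab.endswith(f"_t{last_bin}")})
    truth = GroundTruth(
        true_time=t,
        true_branch=branch,
        root_clusters=roots,
        terminal_clusters=terminal,
    )
    return dataset, truth


def toy_chain_fixtures() -> dict[str, np.ndarray]:
    """Hand-written tiny transition matrices with known stationary behavior.

    - ``absorbing4``: 0 -> 1 -> 2 -> 3 with 3 absorbing; all forward
      stationary mass sits on state 3.
    - ``uniform3``: doubly stochastic 3-state chain; stationary uniform.
    - ``twobranch6``: root 0 -> 1, then 1 -> 2 (p=0.7) or 1 -> 3 (p=0.3),
      2 -> 4 and 3 -> 5 absorbing; absorption probabilities are the
      first-split probabilities (0.7, 0.3).
    - ``cycle4``: deterministic 4-cycle; stationary uniform.
    """
    absorbing4 = np.array(
        [
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    uniform3 = np.full((3, 3), 1.0 / 3.0)
    twobranch6 = np.array(
        [
            [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.7, 0.3, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
        ]
    )
    cycle4 = np.roll(np.eye(4), 1, axis=1)
    return {
        "absorbing4": absorbing4,
        "uniform3": uniform3,
        "twobranch6": twobranch6,
        "cycle4": cycle4,
    }
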