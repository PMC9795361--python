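"""Markov-chain simulation of differentiation paths.

Simulations start at root cells (or, for terminal-state discovery, at random
cells) and take a fixed number of transitions through the row-stochastic
matrix ``P``. Each step draws kappa ~ U[0, 1) and selects the first neighbor
whose cumulative transition probability reaches kappa (inverse-CDF over the
cell's ordered neighbor list).

The number of steps ``i_max`` and the minimum number of unique terminating
simulations per terminal region ``m`` scale with dataset size
(``round(5 * log10(n))`` and ``round(500 * log10(n))``) and are adjusted
iteratively: if at most a fraction ``double_trigger`` (default 0.1) of an
iteration's simulations terminate, the step count doubles; if the lagging
terminal region holds fewer than ``lag_trigger * m`` (default 0.6) unique
simulations, the step count is incremented proportionally; sampling continues
until every region has ``m`` unique terminating simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .transition import StationaryAnnotation, TransitionModel

__all__ = [
    "SamplingConfig",
    "Simulation",
    "SimulationEnsemble",
    "auto_init_params",
    "sample_markov_chain",
    "sample_until_converged",
    "undirected_simulations",
    "terminal_state_frequency",
    "simulation_step_density",
]


@dataclass
class SamplingConfig:
    """Knobs of the adaptive sampler; defaults follow the method's formulas."""

    n_steps: int
    min_sims_per_region: int
    double_trigger: float = 0.1
    lag_trigger: float = 0.6
    max_iterations: int = 10
    sims_per_iteration: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.min_sims_per_region < 1:
            raise ValueError("n_steps and min_sims_per_region must be >= 1")
        for t in (self.double_trigger, self.lag_trigger):
            if not 0 < t < 1:
                raise ValueError("triggers must lie in (0, 1)")


@dataclass
class Simulation:
    """One sampled cell-state sequence c0..ci and its terminal-region tag."""

    cell_indices: np.ndarray
    terminal_region: str | None = None

    def __len__(self) -> int:
        return len(self.cell_indices)


@dataclass
class SimulationEnsemble:
    simulations: list[Simulation]
    config: SamplingConfig | None = None
    region_counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.simulations)

    def by_region(self) -> dict:
        out: dict = {}
        for sim in self.simulations:
            out.setdefault(sim.terminal_region, []).append(sim)
        return out


def auto_init_params(
    n_cells: int,
    n_terminal_regions: int = 1,
    seed: int = 0,
) -> SamplingConfig:
    """Initialize step count and ensemble size from the dataset size.

    ``i_max = round(5 * log10(n_cells))`` — five extra simulation steps per
    order of magnitude of dataset size — and
    ``m = round(500 * log10(n_cells))`` unique simulations per terminal
    region. Below 10 cells the values are floored at (5, 500) with a warning.
    """
    if n_cells < 10:
        warnings.warn(
            "fewer than 10 cells; flooring simulation parameters at "
            "i_max=5, m=500",
            stacklevel=2,
        )
        imax, m = 5, 500
    else:
        imax = int(round(5 * np.log10(n_cells)))
        m = int(round(500 * np.log10(n_cells)))
    n_regions = max(1, int(n_terminal_regions))
    return SamplingConfig(
        n_steps=imax,
        min_sims_per_region=m,
        sims_per_iteration=max(1000, 4 * m * n_regions),
        seed=seed,
    )


class _RowChain:
    """Padded (neighbors, cumulative-probability) representation of P.

    Rows of unequal out-degree are padded; the last real entry of each
    cumulative row is forced to exactly 1 so padding can never be drawn.
    """

    def __init__(self, neighbors: np.ndarray, probs: np.ndarray, valid: np.ndarray):
        self.neighbors = neighbors
        self.cum = np.cumsum(probs, axis=1)
        n, k = probs.shape
        self.cum[np.arange(n), valid - 1] = 1.0
        if k > 1:
            pad = np.arange(k)[None, :] >= valid[:, None]
            self.cum[pad] = 1.0
        self.n = n

    @classmethod
    def from_any(cls, P) -> "_RowChain":
        if isinstance(P, TransitionModel):
            n, k = P.neighbors.shape
            return cls(P.neighbors, P.probs, np.full(n, k))
        M = sp.csr_matrix(P)
        rowsum = np.asarray(M.sum(axis=1)).ravel()
        if np.any(rowsum <= 0):
            bad = int(np.flatnonzero(rowsum <= 0)[0])
            raise ValueError(f"cell {bad} has zero outgoing transition mass")
        M = sp.diags(1.0 / rowsum) @ M
        M = M.tocsr()
        M.sort_indices()
        n = M.shape[0]
        valid = np.diff(M.indptr)
        kmax = int(valid.max())
        nbr = np.zeros((n, kmax), dtype=np.int64)
        pr = np.zeros((n, kmax))
        for i in range(n):
            lo, hi = M.indptr[i], M.indptr[i + 1]
            nbr[i, : hi - lo] = M.indices[lo:hi]
            pr[i, : hi - lo] = M.data[lo:hi]
        return cls(nbr, pr, valid)

    def step(self, current: np.ndarray, kappa: np.ndarray) -> np.ndarray:
        # first neighbor with cumulative probability >= kappa
        choice = (self.cum[current] >= kappa[:, None]).argmax(axis=1)
        return self.neighbors[current, choice]


def _sample_paths(
    chain: _RowChain,
    starts: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``len(starts)`` chains for ``n_steps`` transitions each."""
    n_sims = len(starts)
    paths = np.empty((n_sims, n_steps + 1), dtype=np.int64)
    paths[:, 0] = starts
    current = np.asarray(starts, dtype=np.int64)
    for i in range(1, n_steps + 1):
        kappa = rng.random(n_sims)
        current = chain.step(current, kappa)
        paths[:, i] = current
    return paths


def sample_markov_chain(
    P,
    start_cell: int,
    n_steps: int,
    rng: np.random.Generator,
) -> Simulation:
    """Sample a single simulation of ``n_steps`` transitions from ``P``."""
    chain = P if isinstance(P, _RowChain) else _RowChain.from_any(P)
    if not 0 <= start_cell < chain.n:
        raise ValueError("start cell out of range")
    path = _sample_paths(chain, np.array([start_cell]), n_steps, rng)[0]
    return Simulation(cell_indices=path)


def sample_until_converged(
    P,
    annotation: StationaryAnnotation,
    config: SamplingConfig,
    cluster_labels: np.ndarray,
) -> SimulationEnsemble:
    """Sample directed simulations until every terminal region is covered.

    Simulations are initialized uniformly at random within the root cells and
    run for the current step count; only simulations terminating inside a
    terminal region are retained, deduplicated on their exact cell-index
    sequence. Step count adjustments follow the two triggers described in the
    module docstring; after ``max_iterations`` the ensemble is returned with
    a warning even if some region is short.
    """
    chain = _RowChain.from_any(P)
    cluster_labels = np.asarray(cluster_labels).astype(str)
    roots = np.asarray(annotation.root_cells, dtype=int)
    regions = [str(s) for s in annotation.terminal_regions]
    if len(roots) == 0 or len(regions) == 0:
        raise ValueError("root cells and terminal regions must be non-empty")
    terminal_mask = np.isin(cluster_labels, regions)

    rng = np.random.default_rng(config.seed)
    m = config.min_sims_per_region
    imax = config.n_steps
    batch = config.sims_per_iteration or max(1000, 4 * m * len(regions))
    # a chain several times longer than the cell count has had every chance
    # to traverse the manifold; bound the runaway growth of the adjustments
    step_cap = max(4 * len(cluster_labels), imax)

    unique: dict[str, dict] = {s: {} for s in regions}
    any_terminated = False
    for _ in range(config.max_iterations):
        starts = roots[rng.integers(0, len(roots), size=batch)]
        paths = _sample_paths(chain, starts, imax, rng)
        final = paths[:, -1]
        term = terminal_mask[final]
        n_term = int(term.sum())
        any_terminated = any_terminated or n_term > 0
        for row in np.flatnonzero(term):
            region = cluster_labels[final[row]]
            pool = unique[region]
            if len(pool) >= m:  # sampling for a region stops at m unique
                continue
            key = paths[row].tobytes()
            if key not in pool:
                pool[key] = paths[row].copy()
        counts = {s: len(unique[s]) for s in regions}
        if all(c >= m for c in counts.values()):
            break
        # adjust the step count from this iteration's termination statistics;
        # when overall termination is poor the lag statistic is meaningless,
        # so the two rules are mutually exclusive within one iteration
        lag = min(counts.values())
        if n_term <= config.double_trigger * batch:
            imax *= 2
        elif lag < config.lag_trigger * m:
            imax += int(round(imax * (m / max(imax, max(lag, 1)))))
        imax = min(imax, step_cap)
    else:
        short = {s: c for s, c in counts.items() if c < m}
        if not any_terminated:
            raise RuntimeError(
                "no simulation reached any terminal region after "
                f"{config.max_iterations} iterations; check that the terminal "
                "regions are reachable from the root cells through P"
            )
        warnings.warn(
            f"maximum iterations reached with under-sampled regions {short} "
            f"(target m={m})",
            stacklevel=2,
        )

    sims = []
    for s in regions:
        for path in unique[s].values():
            sims.append(Simulation(cell_indices=path, terminal_region=s))
    final_config = replace(config, n_steps=imax)
    counts = {s: len(unique[s]) for s in regions}
    return SimulationEnsemble(simulations=sims, config=final_config, region_counts=counts)


def first_passage_calibration(
    P,
    annotation: StationaryAnnotation,
    cluster_labels: np.ndarray,
    n_sims: int = 500,
    max_steps: int | None = None,
    seed: int = 0,
) -> int:
    """Median first-arrival step from the root cells into a terminal region.

    For cyclic processes the flow continues through the terminal checkpoint,
    so a fixed-step simulation ending *inside* the terminal region needs a
    step count near the first-passage time; longer simulations lap the cycle
    and blur the consensus. This pilot run measures that time so the step
    count can be set to one traversal.
    """
    chain = _RowChain.from_any(P)
    cluster_labels = np.asarray(cluster_labels).astype(str)
    terminal_mask = np.isin(cluster_labels, [str(s) for s in annotation.terminal_regions])
    roots = np.asarray(annotation.root_cells, dtype=int)
    cap = max_steps if max_steps is not None else chain.n
    rng = np.random.default_rng(seed)
    starts = roots[rng.integers(0, len(roots), size=n_sims)]
    paths = _sample_paths(chain, starts, cap, rng)
    hits = terminal_mask[paths]
    # ignore a start already inside the terminal region; look for re-entry
    hits[:, 0] = False
    arrival = np.where(hits.any(axis=1), hits.argmax(axis=1), -1)
    arrived = arrival[arrival > 0]
    if arrived.size == 0:
        raise RuntimeError(
            "no pilot simulation reached a terminal region within "
            f"{cap} steps; the terminal regions may be unreachable"
        )
    return int(np.median(arrived))


def undirected_simulations(
    P,
    n_cells: int | None = None,
    n_sims: int = 5000,
    n_steps: int = 30,
    seed: int = 0,
) -> SimulationEnsemble:
    """Simulations initialized at randomly chosen cells, no terminal filter.

    Used for terminal-state discovery: the defaults (5000 simulations of 30
    steps) make the termination pattern a dataset-level statistic.
    """
    chain = _RowChain.from_any(P)
    n = n_cells if n_cells is not None else chain.n
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n, size=n_sims)
    paths = _sample_paths(chain, starts, n_steps, rng)
    sims = [Simulation(cell_indices=paths[i]) for i in range(n_sims)]
    return SimulationEnsemble(simulations=sims)


def terminal_state_frequency(ensemble: SimulationEnsemble, n_cells: int) -> np.ndarray:
    """Per-cell log termination count, min-max rescaled to [0, 1].

    ``log1p`` of the number of simulations whose final state is the cell,
    rescaled over the dataset. High values flag terminal states or regions of
    transcriptional-program switching. A constant profile degenerates to all
    zeros (flagged).
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    finals = np.array([s.cell_indices[-1] for s in ensemble.simulations])
    counts = np.bincount(finals, minlength=n_cells).astype(float)
    score = np.log1p(counts)
    lo, hi = score.min(), score.max()
    if hi == lo:
        warnings.warn("uniform termination counts; frequency set to 0", stacklevel=2)
        return np.zeros(n_cells)
    return (score - lo) / (hi - lo)


def simulation_step_density(ensemble: SimulationEnsemble, n_cells: int) -> np.ndarray:
    """Per-cell ``log1p`` of the number of simulation steps arriving at it.

    Only arrivals count (steps >= 1, not the initial state). Low density
    along a lineage flags fast transitions through a region.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    counts = np.zeros(n_cells)
    for sim in ensemble.simulations:
        arrivals = np.bincount(sim.cell_indices[1:], minlength=n_cells)
        counts += arrivals
    return np.log1p(counts)
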