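"""End-to-end orchestration: transition model -> sampling -> consensus -> scores."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .consensus import Trajectory, infer_trajectories
from .datasets import VelocityDataset
from .sampling import (
    SamplingConfig,
    SimulationEnsemble,
    auto_init_params,
    first_passage_calibration,
    sample_until_converged,
)
from .scoring import (
    TrajectoryAlignment,
    consensus_pseudotime,
    differentiation_potential,
    fate_score,
    pseudotime,
    trajectory_alignment,
)
from .transition import (
    StationaryAnnotation,
    TransitionModel,
    build_transition_model,
    select_stationary_cells,
    stationary_probabilities,
    velocity_cohesiveness,
)

__all__ = ["PipelineResult", "run_pipeline", "write_results"]

log = logging.getLogger("velotraj")


def k_effective(k: int, n_cells: int) -> int:
    """Clamp the neighbor count below the cell count for small datasets."""
    return min(k, n_cells - 1)


@dataclass
class PipelineResult:
    dataset: VelocityDataset
    config: RunConfig
    model: TransitionModel
    annotation: StationaryAnnotation
    ensemble: SimulationEnsemble
    trajectories: list[Trajectory]
    alignments: list[TrajectoryAlignment]
    cell_scores: pd.DataFrame
    manifest: dict


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def score_cells(
    dataset: VelocityDataset,
    model: TransitionModel,
    trajectories: list[Trajectory],
    neighborhood_size: int = 50,
    compositional_threshold: float = 0.3,
    restrict: bool = True,
) -> tuple[list[TrajectoryAlignment], pd.DataFrame]:
    """Per-cell pseudotime, fate and differentiation potential table."""
    alignments = [
        trajectory_alignment(
            traj,
            dataset,
            model,
            neighborhood_size=neighborhood_size,
            threshold=compositional_threshold,
            restrict=restrict,
        )
        for traj in trajectories
    ]
    n, T = dataset.n_cells, len(trajectories)
    p_matrix = np.column_stack([a.p for a in alignments]) if T else np.empty((n, 0))
    pt_matrix = (
        np.column_stack([pseudotime(a) for a in alignments]) if T else np.empty((n, 0))
    )
    fates = fate_score(p_matrix) if T else np.empty((n, 0))
    potential = differentiation_potential(fates) if T else np.full(n, np.nan)
    cons_pt = consensus_pseudotime(pt_matrix, fates) if T else np.full(n, np.nan)
    coh = velocity_cohesiveness(model.gamma)
    table = pd.DataFrame({"cell_id": dataset.cell_ids})
    for j in range(T):
        table[f"pseudotime_{j}"] = pt_matrix[:, j]
        table[f"fate_{j}"] = fates[:, j]
    table["pseudotime"] = cons_pt
    table["potential"] = potential
    table["cohesiveness"] = coh
    return alignments, table


def run_pipeline(dataset: VelocityDataset, config: RunConfig) -> PipelineResult:
    """Run the four stages and collect every artifact plus a run manifest."""
    try:
        t0 = time.perf_counter()
        model = build_transition_model(
            dataset, k=k_effective(config.k, dataset.n_cells), kernel_scale=config.kernel_scale, space=config.space
        )
        supervised_root = config.root_cells is not None or config.root_clusters is not None
        supervised_term = (
            config.terminal_cells is not None or config.terminal_clusters is not None
        )
        if supervised_root and supervised_term:
            # full supervision: the stationary inference is not needed
            root_prob = np.zeros(dataset.n_cells)
            terminal_prob = np.zeros(dataset.n_cells)
        else:
            root_prob, terminal_prob = stationary_probabilities(model.P)
        annotation = select_stationary_cells(
            root_prob,
            terminal_prob,
            dataset.cluster_labels,
            threshold=config.stationary_threshold,
            root_cells=config.root_cells,
            terminal_cells=config.terminal_cells,
            root_clusters=config.root_clusters,
            terminal_clusters=config.terminal_clusters,
        )
        t0 = _stage("transition", t0)
    except Exception as exc:
        raise RuntimeError(f"[transition_model] {exc}") from exc
    try:
        auto = auto_init_params(
            dataset.n_cells, len(annotation.terminal_regions), seed=config.seed
        )
        n_steps = config.n_steps
        if n_steps is None and config.calibrate_steps:
            n_steps = first_passage_calibration(
                model, annotation, dataset.cluster_labels, seed=config.seed
            )
        sampling_config = SamplingConfig(
            n_steps=n_steps or auto.n_steps,
            min_sims_per_region=config.min_sims_per_region or auto.min_sims_per_region,
            double_trigger=config.double_trigger,
            lag_trigger=config.lag_trigger,
            max_iterations=config.max_iterations,
            sims_per_iteration=config.sims_per_iteration or auto.sims_per_iteration,
            seed=config.seed,
        )
        ensemble = sample_until_converged(
            model, annotation, sampling_config, dataset.cluster_labels
        )
        t0 = _stage("sampling", t0)
    except Exception as exc:
        raise RuntimeError(f"[sampling] {exc}") from exc
    try:
        trajectories = infer_trajectories(
            ensemble,
            dataset,
            n_per_region=config.n_per_region,
            resolution=config.resolution,
            anchor=config.anchor,
            seed=config.seed,
        )
        t0 = _stage("consensus", t0)
    except Exception as exc:
        raise RuntimeError(f"[trajectory_consensus] {exc}") from exc
    try:
        alignments, table = score_cells(
            dataset,
            model,
            trajectories,
            neighborhood_size=config.neighborhood_size,
            compositional_threshold=config.compositional_threshold,
            restrict=config.restrict_alignment,
        )
        _stage("scoring", t0)
    except Exception as exc:
        raise RuntimeError(f"[cell_scoring] {exc}") from exc
    manifest = {
        "velotraj_version": __version__,
        "seed": config.seed,
        "n_cells": dataset.n_cells,
        "n_genes": dataset.n_genes,
        "parameters": config.to_dict(),
        "n_steps_final": ensemble.config.n_steps if ensemble.config else None,
        "terminal_regions": list(annotation.terminal_regions),
        "n_root_cells": int(len(annotation.root_cells)),
        "n_terminal_cells": int(len(annotation.terminal_cells)),
        "n_simulations": len(ensemble),
        "region_counts": {str(k): int(v) for k, v in ensemble.region_counts.items()},
        "n_trajectories": len(trajectories),
        "trajectories": [
            {"terminal_region": t.terminal_region, "n_steps": int(t.n_steps)}
            for t in trajectories
        ],
    }
    return PipelineResult(
        dataset=dataset,
        config=config,
        model=model,
        annotation=annotation,
        ensemble=ensemble,
        trajectories=trajectories,
        alignments=alignments,
        cell_scores=table,
        manifest=manifest,
    )


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    from .io import (
        write_ensemble,
        write_stationary,
        write_trajectories,
        write_transition_model,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_transition_model(result.model, outdir)
    write_stationary(
        result.annotation, result.dataset.cell_ids, outdir / "stationary.csv"
    )
    write_ensemble(result.ensemble, outdir / "ensemble.parquet")
    write_trajectories(result.trajectories, outdir)
    result.cell_scores.to_csv(outdir / "cell_scores.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
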