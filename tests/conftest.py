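"""Shared fixtures: synthetic datasets and full pipeline runs.

The 500-cell pipeline runs are session-scoped because several test modules
interrogate different aspects of the same run (topology recovery, pseudotime
quality, fate calls, supervision plumbing).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import velotraj as vt


@pytest.fixture(scope="session")
def toy_chains():
    return vt.toy_chain_fixtures()


@pytest.fixture(scope="session")
def linear_data():
    return vt.generate(vt.TopologySpec(kind="linear", n_cells=500, seed=1))


@pytest.fixture(scope="session")
def linear_run(linear_data):
    dataset, truth = linear_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = vt.run_pipeline(dataset, vt.RunConfig(seed=1))
    return dataset, truth, result


@pytest.fixture(scope="session")
def bifurcating_run():
    dataset, truth = vt.generate(vt.TopologySpec(kind="bifurcating", n_cells=500, seed=1))
    # terminal regions supervised from the annotation, the protocol used when
    # the stationary threshold recovers only the dominant terminal state
    config = vt.RunConfig(seed=1, terminal_clusters=truth.terminal_clusters)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = vt.run_pipeline(dataset, config)
    return dataset, truth, result


@pytest.fixture(scope="session")
def cyclic_run():
    dataset, truth = vt.generate(vt.TopologySpec(kind="cyclic", n_cells=500, seed=1))
    config = vt.RunConfig(
        seed=1,
        root_clusters=truth.root_clusters,
        terminal_clusters=truth.terminal_clusters,
        calibrate_steps=True,
        n_per_region=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = vt.run_pipeline(dataset, config)
    return dataset, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_line_dataset(n: int = 60, seed: int = 0) -> vt.VelocityDataset:
    """Tiny 2-gene dataset on a line with forward velocity, for unit tests."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)
    expr = np.column_stack([t, 1 - t]) + 1.0
    vel = np.tile([1.0, -1.0], (n, 1))
    coords = np.column_stack([t, np.zeros(n)]) + rng.normal(0, 1e-6, (n, 2))
    labels = np.array(["early"] * (n // 2) + ["late"] * (n - n // 2))
    return vt.VelocityDataset(
        expression=expr,
        velocity=vel,
        pca_coords=coords,
        cluster_labels=labels,
        pca_loadings=np.eye(2),
    )
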