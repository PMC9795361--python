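"""Run configuration: every tunable of the pipeline in one serializable place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of the full pipeline; defaults are the documented values.

    ``n_steps`` / ``min_sims_per_region`` of None means "derive from the
    dataset size" (5 and 500 per order of magnitude of cell count).
    """

    # transition model
    k: int = 30
    kernel_scale: float = 0.1
    space: str = "gene"
    stationary_threshold: float = 0.99
    # sampling
    n_steps: int | None = None
    min_sims_per_region: int | None = None
    double_trigger: float = 0.1
    lag_trigger: float = 0.6
    max_iterations: int = 10
    sims_per_iteration: int | None = None
    calibrate_steps: bool = False  # set n_steps to the root->terminal first-passage time
    # trajectory inference
    n_per_region: int | None = None
    resolution: float = 1.0
    anchor: bool = False
    # scoring
    neighborhood_size: int = 50
    compositional_threshold: float = 0.3
    restrict_alignment: bool = True
    # supervision
    root_clusters: list | None = None
    terminal_clusters: list | None = None
    root_cells: list | None = None
    terminal_cells: list | None = None
    # bookkeeping
    seed: int = 0
    output_dir: str | None = None
    extras: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)} - {"extras"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("extras")
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
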