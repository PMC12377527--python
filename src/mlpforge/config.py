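"""Schema-validated run configuration for the concurrent-learning loop.

A run config JSON bundles the random seed, the curriculum stage table, the
selection-policy thresholds, sampler/descriptor settings and the fixture
suite to explore.  Everything has a default, and the full resolved config
is echoed into the run log so a run can be reproduced from its artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field

from .active_learning import CurriculumStage, SelectionPolicy
from .ensemble import DescriptorConfig


class StageConfig(BaseModel):
    label: str
    max_heavy_atoms: int = Field(ge=1)
    temperature: float = Field(gt=0)
    steps: int = Field(ge=1)
    max_iterations: int = Field(default=5, ge=1)
    bias: bool = False

    def build(self) -> CurriculumStage:
        return CurriculumStage(
            label=self.label,
            max_heavy_atoms=self.max_heavy_atoms,
            temperature=self.temperature,
            steps=self.steps,
            max_iterations=self.max_iterations,
            bias=self.bias,
        )


class PolicyConfig(BaseModel):
    sigma_u: float = Field(default=0.5, gt=0)
    r_candi: float = Field(default=0.12, gt=0, le=1)
    band_lower: float = 0.15
    band_upper: float = 0.45
    subsample_min: int = Field(default=50, ge=1)
    subsample_max: int = Field(default=200, ge=1)
    seed: int = 0

    def build(self) -> SelectionPolicy:
        return SelectionPolicy(**self.model_dump())


class DescriptorConfigModel(BaseModel):
    cutoff: float = Field(default=6.0, gt=0)
    n_centers: int = Field(default=10, ge=2)
    center_min: float = Field(default=0.8, gt=0)
    width_factor: float = Field(default=0.6, gt=0)
    include_vector_moment: bool = True

    def build(self) -> DescriptorConfig:
        return DescriptorConfig(**self.model_dump())


class FixtureConfig(BaseModel):
    family: str = "chain"
    size: int = 4
    barriers: list[float] = [3.0]
    seed: int = 0
    name: str = ""


class RunConfig(BaseModel):
    """Top-level configuration of a `forge run` invocation."""

    seed: int = 0
    ensemble_seeds: list[int] = [11, 22, 33, 44]
    n_hidden: int = 64
    timestep: float = 0.5  # fs
    friction: float = 0.05  # 1/fs
    record_stride: int = 10
    convergence_window: int = 8
    convergence_tol: float = 0.01
    stages: list[StageConfig] = [
        StageConfig(label="stage-0", max_heavy_atoms=4, temperature=300.0, steps=400),
        StageConfig(label="stage-1", max_heavy_atoms=12, temperature=600.0, steps=400),
    ]
    policy: PolicyConfig = PolicyConfig()
    descriptor: DescriptorConfigModel = DescriptorConfigModel()
    fixtures: list[FixtureConfig] = [
        FixtureConfig(family="chain", size=4, barriers=[3.0], name="chain4"),
        FixtureConfig(family="biaryl-like", size=12, barriers=[6.0], name="biaryl"),
    ]
    output_dir: str = "forge-out"


def load_run_config(path: str | Path) -> RunConfig:
    return RunConfig.model_validate(json.loads(Path(path).read_text()))
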