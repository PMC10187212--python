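"""Run configuration: a validated JSON document with simulation-study defaults.

An empty document ``{}`` resolves to the full default configuration (λ grid
1.5:0.2:7, δ = 10 ms, M = 1 kg, τ = 0.06 s, C = 1.5, motor covariance scale
0.4, 50 ms sensory delay, U = 10, q = v = 1e4, ±10 cm workspace, 6 s analyzed
/ 8 s simulated).  Unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

from .model import NoiseSpec, PlantParams, TaskConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration document violates the schema."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TaskSettings(_Strict):
    c: float = 10.0
    trial_duration: float = 6.0
    sim_duration: float = 8.0
    dt: float = 0.01


class PlantSettings(_Strict):
    M: float = 1.0
    tau: float = 0.06


class NoiseSettings(_Strict):
    C: float = 1.5
    motor_scale: float = 0.4
    sensory_sd: float = 0.05
    seed: int = 0


class CostSettings(_Strict):
    weight: float = 1e4  # q (position) or v (velocity), per objective
    U: float = 10.0


class GridSettings(_Strict):
    lam_min: float = 1.5
    lam_max: float = 7.0
    lam_step: float = 0.2


class RunConfig(_Strict):
    task: TaskSettings = TaskSettings()
    plant: PlantSettings = PlantSettings()
    noise: NoiseSettings = NoiseSettings()
    cost: CostSettings = CostSettings()
    grid: GridSettings = GridSettings()
    n_per_lam: int = 500
    n_train: int = 2250
    n_test: int = 2500
    delay_steps: int = 5
    base_seed: int = 0
    out_dir: str = "."

    def lam_grid(self) -> np.ndarray:
        g = self.grid
        return np.round(np.arange(g.lam_min, g.lam_max - 1e-9, g.lam_step), 10)

    def task_config(self, lam: float | None = None) -> TaskConfig:
        lam = float(self.lam_grid()[0]) if lam is None else lam
        return TaskConfig(lam=lam, c=self.task.c, trial_duration=self.task.trial_duration,
                          sim_duration=self.task.sim_duration, dt=self.task.dt)

    def plant_params(self) -> PlantParams:
        return PlantParams(M=self.plant.M, tau=self.plant.tau)

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(C=self.noise.C, motor_scale=self.noise.motor_scale,
                         sensory_sd=self.noise.sensory_sd, seed=self.noise.seed)


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration, filling in defaults."""
    text = Path(path).read_text().strip() or "{}"
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as err:
        raise ConfigError(f"invalid JSON in {path}: {err}") from err
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as err:
        keys = ", ".join(".".join(str(p) for p in e["loc"]) for e in err.errors())
        raise ConfigError(f"invalid configuration keys/values: {keys}") from err
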