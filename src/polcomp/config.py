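"""Run configuration: strict-schema YAML for the simulation CLI.

Unknown keys are rejected so that typos fail loudly, and every stochastic
run must carry a ``master_seed``.  Task specs are either a built-in name —

* ``experiment`` — the 6-state / 7-action safety-action task;
* ``symmetric:<n>`` — n-state identity-structured task;
* ``random:<S>x<A>:<seed>`` — i.i.d. Uniform(0, 1) rewards;
* ``scarce:<S>x<A>:<rich>:<seed>`` — reward centred on a few columns —

or a path to a task JSON file.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .tasks import (
    Task,
    make_experiment_task,
    make_random_task,
    make_scarce_task,
    make_symmetric_task,
)

__all__ = ["SuiteConfig", "resolve_task", "load_config"]


def resolve_task(spec: str) -> Task:
    """Resolve a task spec string (built-in name or JSON path) to a Task."""
    if spec == "experiment":
        return make_experiment_task()
    m = re.fullmatch(r"symmetric:(\d+)", spec)
    if m:
        return make_symmetric_task(int(m.group(1)))
    m = re.fullmatch(r"random:(\d+)x(\d+):(\d+)", spec)
    if m:
        return make_random_task(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    m = re.fullmatch(r"scarce:(\d+)x(\d+):(\d+):(\d+)", spec)
    if m:
        return make_scarce_task(
            int(m.group(1)), int(m.group(2)), int(m.group(3)), int(m.group(4))
        )
    path = Path(spec)
    if path.exists():
        return Task.from_json(path)
    raise ValueError(f"unrecognized task spec: {spec!r}")


class SuiteConfig(BaseModel):
    """Schema for the ``polcomp simulate`` YAML config."""

    model_config = ConfigDict(extra="forbid")

    task: str
    master_seed: int
    suite: Literal["grid", "noisy"] = "grid"
    beta_grid: list[float] | None = None
    proposals: list[Literal["flat", "general_value", "oracle"]] = [
        "flat",
        "general_value",
        "oracle",
    ]
    na_grid: list[int] = [2, 4, 8, 16, 32]
    n_grid: list[int] = [2, 4, 8, 16, 32]
    n_reps: int = 200
    # noisy-suite-only parameters
    noise_sds: list[float] | None = None
    set_sizes: list[int] | None = None

    @field_validator("n_reps")
    @classmethod
    def _positive_reps(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_reps must be positive")
        return v

    def validate_suite(self) -> None:
        if self.suite == "noisy" and (self.noise_sds is None or self.set_sizes is None):
            raise ValueError("noisy suite requires noise_sds and set_sizes")


def load_config(path: str | Path) -> SuiteConfig:
    """Load and validate a YAML config; raises with a field path on error."""
    raw = yaml.safe_load(Path(path).read_text())
    cfg = SuiteConfig.model_validate(raw)
    cfg.validate_suite()
    return cfg
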