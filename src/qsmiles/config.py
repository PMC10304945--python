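"""Run configuration: a YAML file merged with command-line overrides.

Every stochastic step of a run flows from the single top-level ``seed``.
Unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .optimize import OptimizationConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Union of the knobs a command-line run can set."""

    seed: int = 0
    # optimization
    tf_kind: str = "TF2"
    T: int = 1
    N: int = 15
    step: float = 0.1
    penalty_weight: float = 0.1
    ideality_weight: float = 0.3
    init: str = "zeros"
    persistence: int = 3
    runs: int = 1
    # splitting
    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # generation
    n: int = 200
    noise_sd: float = 0.1
    # logging
    log_level: str = "INFO"

    def optimization(self, seed: int | None = None) -> OptimizationConfig:
        return OptimizationConfig(
            tf_kind=self.tf_kind,
            T=self.T,
            N=self.N,
            seed=self.seed if seed is None else seed,
            step=self.step,
            penalty_weight=self.penalty_weight,
            ideality_weight=self.ideality_weight,
            init=self.init,
            persistence=self.persistence,
        )


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    Overrides with value ``None`` are ignored (unset CLI flags).
    """
    known = {f.name for f in fields(RunConfig)}
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(loaded)
    for k, v in (overrides or {}).items():
        if v is None:
            continue
        if k not in known:
            raise ValueError(f"unknown config key: {k}")
        data[k] = v
    if "fractions" in data:
        data["fractions"] = tuple(float(x) for x in data["fractions"])
    return RunConfig(**data)
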