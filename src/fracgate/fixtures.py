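"""Seeded parameter-sweep generation and run-configuration validation.

A :class:`RunConfig` pairs a subcommand name with a validated, flat
parameter map; :func:`fixture_sweep` draws reproducible families of them
covering the physically interesting ranges — anomalous exponents down to
0.3, composite rates over two decades, voltage biases spanning the sigmoid
— for property tests and CLI smoke tests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from fracgate.errors import DomainError

__all__ = ["RunConfig", "SUBCOMMAND_SCHEMAS", "load_config", "fixture_sweep"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MLArgs(_StrictModel):
    alpha: float = Field(gt=0, le=2)
    beta: float = 1.0
    z: float


class SolveArgs(_StrictModel):
    landscape: Literal["quadratic", "double-well", "channel"] = "quadratic"
    gamma: float = Field(gt=0, le=1)
    Gamma_coef: float = Field(default=1.0, gt=0)
    beta: float = Field(default=1.0, gt=0)
    x0: float = 0.5
    dt: float = Field(default=0.01, gt=0)
    t_end: float = Field(default=10.0, gt=0)
    scheme: Literal["abm", "implicit_gl"] = "abm"


class ChannelArgs(_StrictModel):
    gamma: float = Field(gt=0, le=1)
    rate: float = Field(gt=0, description="composite rate Γ/n")
    beta: float = Field(default=1.0, gt=0)
    z: int = Field(default=1, ge=1)
    e0: float = Field(default=1.0, gt=0)
    n: int = Field(default=1, ge=1)
    V: float = 0.0
    V0: float = 0.0
    p0: float = Field(default=0.1, gt=0, lt=1)
    dt: float = Field(default=0.01, gt=0)
    t_end: float = Field(default=10.0, gt=0)


class GMEArgs(_StrictModel):
    landscape: Literal["flat", "quadratic", "double-well", "channel"] = "quadratic"
    gamma: float = Field(gt=0, le=1)
    beta: float = Field(default=1.0, gt=0)
    Delta: float = Field(default=1.0, gt=0)
    nx: int = Field(default=21, ge=3)
    x_min: float = -2.0
    x_max: float = 2.0
    dt: float = Field(default=0.01, gt=0)
    t_end: float = Field(default=10.0, gt=0)
    scheme: Literal["explicit", "implicit"] = "explicit"


SUBCOMMAND_SCHEMAS: dict[str, type[_StrictModel]] = {
    "ml": MLArgs,
    "solve": SolveArgs,
    "simulate-channel": ChannelArgs,
    "gme": GMEArgs,
}


class RunConfig(BaseModel):
    """A validated run: subcommand, its parameters, seed, output path."""

    model_config = ConfigDict(extra="forbid")

    subcommand: Literal["ml", "solve", "simulate-channel", "gme"]
    parameters: dict[str, Any]
    seed: int = 0
    output_path: str | None = None

    def validated_parameters(self) -> _StrictModel:
        return SUBCOMMAND_SCHEMAS[self.subcommand](**self.parameters)


def load_config(
    source, overrides: dict[str, Any] | None = None
) -> RunConfig:
    """Build a validated :class:`RunConfig` from a JSON file or a dict.

    ``overrides`` (e.g. CLI flags) take precedence over file values; keys
    set to None are ignored. Unknown keys are errors; every offending key
    is reported at once via pydantic's aggregated ValidationError.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise DomainError(f"config file not found: {path}")
        doc = json.loads(path.read_text())
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        raise DomainError(f"unsupported config source: {type(source)!r}")
    if overrides:
        params = dict(doc.get("parameters", {}))
        params.update({k: v for k, v in overrides.items() if v is not None})
        doc["parameters"] = params
    cfg = RunConfig(**doc)
    cfg.validated_parameters()  # raises with all offending keys listed
    return cfg


_LANDSCAPE_CYCLE = ("quadratic", "double-well", "channel")


def fixture_sweep(seed: int, n_cases: int) -> list[RunConfig]:
    """Deterministic parameter sweep for tests: n_cases validated configs.

    Draws anomalous exponents γ ∈ [0.3, 1.0], composite rates Γ/n ∈
    [0.1, 10] (log-uniform), voltage biases β z e₀(V−V₀) ∈ [−5, 5] and
    cycles through the built-in landscapes. The same seed always yields
    the same sweep.
    """
    if n_cases < 1:
        raise DomainError(f"n_cases must be >= 1, got {n_cases}")
    rng = np.random.default_rng(seed)
    out: list[RunConfig] = []
    for i in range(n_cases):
        gamma = float(rng.uniform(0.3, 1.0))
        rate = float(10.0 ** rng.uniform(-1.0, 1.0))
        bias = float(rng.uniform(-5.0, 5.0))
        kind = i % 2
        if kind == 0:
            cfg = RunConfig(
                subcommand="simulate-channel",
                parameters={
                    "gamma": gamma, "rate": rate, "beta": 1.0,
                    "V": bias, "V0": 0.0,
                    "p0": float(rng.uniform(0.05, 0.95)),
                    "dt": 0.01, "t_end": 5.0,
                },
                seed=seed,
            )
        else:
            cfg = RunConfig(
                subcommand="solve",
                parameters={
                    "landscape": _LANDSCAPE_CYCLE[i % len(_LANDSCAPE_CYCLE)],
                    "gamma": gamma, "Gamma_coef": rate, "beta": 1.0,
                    "x0": float(rng.uniform(0.1, 0.9)),
                    "dt": 0.01, "t_end": 5.0,
                },
                seed=seed,
            )
        cfg.validated_parameters()
        out.append(cfg)
    return out
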