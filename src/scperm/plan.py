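"""Constrained-tracer sampling design along the trans-bilayer axis.

A reaction coordinate of length ``rc_length`` is divided into equally spaced
windows.  Tracers are grouped into *configurations*: each configuration holds
several tracers spaced ``per_config_spacing`` apart so they cannot interact,
and the whole grid is covered ``coverage`` times.  With the reference design
(9 nm coordinate, 0.1 nm windows, 1.5 nm intra-configuration spacing,
coverage 4) this yields 90 windows sampled by 60 configurations of 6 tracers
each.

The fade-in coupling schedule used when tracers are inserted into a real
system is carried as plan metadata only; executing the insertion is an MD
engine's job, not this package's.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import PlanningError

__all__ = ["GridSpec", "ConfigAssignment", "SamplingPlan", "plan_insertions",
           "DEFAULT_LAMBDA_SCHEDULE"]

#: Coupling constants of the tracer fade-in schedule (metadata only).
DEFAULT_LAMBDA_SCHEDULE: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)

_REL_TOL = 1e-9


def _as_integer_ratio(num: float, den: float, what: str) -> int:
    ratio = num / den
    n = round(ratio)
    if n < 1 or abs(ratio - n) > _REL_TOL * max(abs(ratio), 1.0):
        raise PlanningError(f"{what}: {num} / {den} = {ratio} is not a positive integer")
    return int(n)


@dataclass(frozen=True)
class GridSpec:
    """Uniform window grid along the reaction coordinate.

    ``origin`` is the z of the first window relative to the bilayer center;
    by default the grid is centered so that windows pair exactly as z <-> -z.
    """

    rc_length: float
    window_spacing: float
    origin: float | None = None

    def __post_init__(self) -> None:
        if self.window_spacing <= 0:
            raise PlanningError("window_spacing must be positive")
        _as_integer_ratio(self.rc_length, self.window_spacing, "rc_length / window_spacing")
        if self.origin is None:
            object.__setattr__(
                self, "origin", -(self.rc_length - self.window_spacing) / 2.0
            )

    @property
    def n_windows(self) -> int:
        return _as_integer_ratio(self.rc_length, self.window_spacing, "rc_length / window_spacing")

    def windows(self) -> np.ndarray:
        """Window z positions (nm), first window at ``origin``."""
        return self.origin + self.window_spacing * np.arange(self.n_windows)

    def index_of(self, z0: float, tol: float = 1e-6) -> int:
        """Map a z position to its window index; raise if off-grid."""
        idx = round((z0 - self.origin) / self.window_spacing)
        if idx < 0 or idx >= self.n_windows:
            raise PlanningError(f"z0={z0} nm lies outside the grid")
        if abs(z0 - (self.origin + idx * self.window_spacing)) > tol:
            raise PlanningError(f"z0={z0} nm is not on the {self.window_spacing} nm grid")
        return int(idx)


@dataclass(frozen=True)
class ConfigAssignment:
    """One tracer configuration: its id, coverage repeat, and window z's."""

    config_id: int
    replicate: int
    z_positions: tuple[float, ...]


@dataclass(frozen=True)
class SamplingPlan:
    grid: GridSpec
    per_config_spacing: float
    coverage: int
    configs: tuple[ConfigAssignment, ...]
    lambda_schedule: tuple[float, ...] = DEFAULT_LAMBDA_SCHEDULE
    seed: int | None = None

    @property
    def n_configs(self) -> int:
        return len(self.configs)

    @property
    def molecules_per_config(self) -> int:
        return len(self.configs[0].z_positions)

    def window_assignments(self) -> Iterator[tuple[int, int, int, float]]:
        """Yield (window_id, config_id, replicate, z0) for every tracer."""
        for cfg in self.configs:
            for z0 in cfg.z_positions:
                yield self.grid.index_of(z0), cfg.config_id, cfg.replicate, z0

    def validate(self) -> None:
        """Check coverage conservation and intra-config spacing."""
        counts = np.zeros(self.grid.n_windows, dtype=int)
        for cfg in self.configs:
            z = np.asarray(cfg.z_positions)
            if len(z) > 1:
                gaps = np.diff(z)
                if np.abs(gaps - self.per_config_spacing).max() > 1e-9:
                    raise PlanningError(
                        f"config {cfg.config_id}: spacing deviates from "
                        f"{self.per_config_spacing} nm"
                    )
            for zi in z:
                counts[self.grid.index_of(zi)] += 1
        if not (counts == self.coverage).all():
            bad = np.flatnonzero(counts != self.coverage)
            raise PlanningError(f"coverage violated at windows {bad.tolist()}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "grid": {
                "rc_length": self.grid.rc_length,
                "window_spacing": self.grid.window_spacing,
                "origin": self.grid.origin,
            },
            "per_config_spacing": self.per_config_spacing,
            "coverage": self.coverage,
            "lambda_schedule": list(self.lambda_schedule),
            "seed": self.seed,
            "configs": [
                {
                    "config_id": c.config_id,
                    "replicate": c.replicate,
                    "z_positions": list(c.z_positions),
                }
                for c in self.configs
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingPlan":
        grid = GridSpec(**d["grid"])
        configs = tuple(
            ConfigAssignment(c["config_id"], c["replicate"], tuple(c["z_positions"]))
            for c in d["configs"]
        )
        return cls(
            grid=grid,
            per_config_spacing=d["per_config_spacing"],
            coverage=d["coverage"],
            configs=configs,
            lambda_schedule=tuple(d.get("lambda_schedule", DEFAULT_LAMBDA_SCHEDULE)),
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, path) -> "SamplingPlan":
        return cls.from_dict(json.loads(Path(path).read_text()))


def plan_insertions(
    grid: GridSpec,
    per_config_spacing: float,
    coverage: int,
    *,
    lambda_schedule: tuple[float, ...] = DEFAULT_LAMBDA_SCHEDULE,
    seed: int | None = None,
) -> SamplingPlan:
    """Assign every window to configurations of non-interacting tracers.

    Configurations enumerate the ``per_config_spacing / window_spacing``
    possible grid offsets deterministically (offset 0, w, 2w, ...), each
    repeated ``coverage`` times with a distinct replicate index, so that the
    multiset of all configuration z's equals the window grid repeated
    ``coverage`` times.
    """
    if coverage < 1:
        raise PlanningError("coverage must be >= 1")
    offsets = _as_integer_ratio(
        per_config_spacing, grid.window_spacing, "per_config_spacing / window_spacing"
    )
    molecules_per_config = _as_integer_ratio(
        grid.rc_length, per_config_spacing, "rc_length / per_config_spacing"
    )
    configs = []
    config_id = 0
    for replicate in range(coverage):
        for off in range(offsets):
            z0 = grid.origin + off * grid.window_spacing
            z = tuple(z0 + j * per_config_spacing for j in range(molecules_per_config))
            configs.append(ConfigAssignment(config_id, replicate, z))
            config_id += 1
    plan = SamplingPlan(
        grid=grid,
        per_config_spacing=per_config_spacing,
        coverage=coverage,
        configs=tuple(configs),
        lambda_schedule=lambda_schedule,
        seed=seed,
    )
    plan.validate()
    return plan
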