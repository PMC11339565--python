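"""YAML run configuration with schema validation and lossless round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .calibrate import (
    BASELINE_ANCHOR_DAYS,
    DEFAULT_C_GRID,
    DEFAULT_I0_GRID,
    DEFAULT_KAPPA_GRID,
    INTERVENTION_ANCHOR_DAY,
    INTERVENTION_ANCHOR_DAYS,
)
from .experiments import DEFAULT_BASE_SEED, DEFAULT_SCENARIO_DAYS
from .model import InterventionSpec, ModelParams

__all__ = [
    "RunConfig",
    "ConfigError",
    "UnknownConfigKeyError",
    "ConfigValidationError",
    "load_config",
    "write_config",
]


class ConfigError(ValueError):
    """Base class for configuration problems."""


class UnknownConfigKeyError(ConfigError):
    """A key in the config file is not part of the schema."""


class ConfigValidationError(ConfigError):
    """A config value violates its invariant; the message names the field."""


@dataclass
class RunConfig:
    """All knobs of a run, a sweep, or a calibration, with defaults.

    Model fields mirror :class:`~infodemic.model.ModelParams` and
    :class:`~infodemic.model.InterventionSpec`; experiment fields control
    the scenario list, the ensemble size, seeding, and the significance
    level; calibration fields hold the grids and anchors.
    """

    # model
    n: int = 6000
    beta: float = 0.05
    gamma: float = 0.05
    contacts: float = 1.5
    i0: int = 3
    max_days: int = 1000
    extinction_threshold: int = 0
    # intervention
    intervention_day: Optional[int] = None
    gamma_mult: float = 1.0
    beta_mult: float = 1.0
    # experiment
    scenario_days: list = field(default_factory=lambda: list(DEFAULT_SCENARIO_DAYS))
    n_reps: int = 100
    base_seed: int = DEFAULT_BASE_SEED
    alpha: float = 0.05
    out_dir: str = "out"
    # calibration
    c_grid: list = field(default_factory=lambda: [float(c) for c in DEFAULT_C_GRID])
    i0_grid: list = field(default_factory=lambda: list(DEFAULT_I0_GRID))
    kappa_grid: list = field(default_factory=lambda: list(DEFAULT_KAPPA_GRID))
    target_baseline_days: float = BASELINE_ANCHOR_DAYS
    target_intervention_days: float = INTERVENTION_ANCHOR_DAYS
    anchor_day: int = INTERVENTION_ANCHOR_DAY
    calibration_tolerance: float = 0.15

    def validate(self) -> "RunConfig":
        def check(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ConfigValidationError(f"{name}: {why}")

        check(self.n >= 1, "n", "population must be >= 1")
        check(0.0 <= self.beta <= 1.0, "beta", "must be a probability in [0, 1]")
        check(0.0 <= self.gamma <= 1.0, "gamma", "must be a probability in [0, 1]")
        check(self.contacts >= 0, "contacts", "must be >= 0")
        check(0 <= self.i0 <= self.n, "i0", "must be in [0, n]")
        check(self.max_days >= 1, "max_days", "must be >= 1")
        check(self.extinction_threshold >= 0, "extinction_threshold", "must be >= 0")
        check(
            self.intervention_day is None or self.intervention_day >= 0,
            "intervention_day",
            "must be >= 0 or null",
        )
        check(self.gamma_mult >= 0, "gamma_mult", "must be >= 0")
        check(self.beta_mult >= 0, "beta_mult", "must be >= 0")
        check(len(self.scenario_days) > 0, "scenario_days", "must be non-empty")
        check(
            all(d is None or (isinstance(d, int) and d >= 0) for d in self.scenario_days),
            "scenario_days",
            "entries must be null or non-negative integers",
        )
        check(self.n_reps >= 1, "n_reps", "must be >= 1")
        check(0.0 < self.alpha < 1.0, "alpha", "must be in (0, 1)")
        check(len(self.c_grid) > 0, "c_grid", "must be non-empty")
        check(len(self.i0_grid) > 0, "i0_grid", "must be non-empty")
        check(len(self.kappa_grid) > 0, "kappa_grid", "must be non-empty")
        check(all(k >= 1 for k in self.kappa_grid), "kappa_grid", "values must be >= 1")
        check(self.target_baseline_days >= 1, "target_baseline_days", "must be >= 1")
        check(
            self.target_intervention_days >= 1,
            "target_intervention_days",
            "must be >= 1",
        )
        check(self.anchor_day >= 0, "anchor_day", "must be >= 0")
        check(
            0 < self.calibration_tolerance < 1,
            "calibration_tolerance",
            "must be in (0, 1)",
        )
        return self

    def model_params(self) -> ModelParams:
        return ModelParams(
            n=self.n,
            beta=self.beta,
            gamma=self.gamma,
            contacts=self.contacts,
            i0=self.i0,
            max_days=self.max_days,
            extinction_threshold=self.extinction_threshold,
        )

    def intervention(self) -> Optional[InterventionSpec]:
        if self.intervention_day is None:
            return None
        return InterventionSpec(
            day=self.intervention_day,
            gamma_mult=self.gamma_mult,
            beta_mult=self.beta_mult,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected by name.

    An empty file yields the documented defaults.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise UnknownConfigKeyError(
            f"unknown config key(s): {', '.join(sorted(unknown))}"
        )
    return RunConfig(**raw).validate()


def write_config(cfg: RunConfig, path) -> None:
    """Write a config that :func:`load_config` reads back identically."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
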