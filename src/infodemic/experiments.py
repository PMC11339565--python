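"""Replicate ensembles, intervention-timing sweeps, and scenario comparison.

This layer reproduces the structure of the headline experiment: one
no-intervention baseline and a set of scenarios that differ only in the
day an official intervention occurs.  Each scenario is run as an ensemble
of seeded replicates, summarized by its mean extinction time, and pairs of
scenarios are compared with Welch's unequal-variance t test.

Scenarios in a sweep share replicate seeds (common random numbers): the
k-th replicate of every scenario uses ``base_seed + k``.  This removes
between-scenario sampling noise from the timing comparison; with a null
intervention the scenarios are then replicate-identical by construction.
It also doubles as the package's synthetic-data generator: every fixture
trajectory and duration sample used downstream comes from here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import InterventionSpec, ModelParams, Trajectory, duration, run

__all__ = [
    "DurationSample",
    "SweepTable",
    "ComparisonResult",
    "InsufficientDataError",
    "run_replicates",
    "sweep",
    "compare",
    "scenario_label",
    "DEFAULT_SCENARIO_DAYS",
    "DEFAULT_BASE_SEED",
]

#: Intervention days of the headline experiment; ``None`` is the baseline.
DEFAULT_SCENARIO_DAYS: tuple[Optional[int], ...] = (None, 100, 54, 16, 10, 5)

#: Date the fake-news video was first uploaded (2019-09-03), as an integer.
DEFAULT_BASE_SEED = 20190903


class InsufficientDataError(ValueError):
    """Raised when a comparison has fewer than two usable durations."""


def scenario_label(day: Optional[int]) -> str:
    return "none" if day is None else f"day-{day}"


@dataclass(frozen=True)
class DurationSample:
    """Extinction times of one scenario's replicate ensemble.

    ``censored`` marks replicates that hit the day cap with believers
    remaining (their duration is a lower bound); ``early_extinct`` marks
    replicates that died out before the intervention day and therefore
    never experienced the intervention.
    """

    label: str
    durations: np.ndarray
    seeds: np.ndarray
    censored: np.ndarray
    early_extinct: np.ndarray
    intervention_day: Optional[int] = None

    def __post_init__(self) -> None:
        k = len(self.durations)
        if not (len(self.seeds) == len(self.censored) == len(self.early_extinct) == k):
            raise ValueError("duration/seed/flag arrays must have equal length")
        if np.any(self.durations < 0):
            raise ValueError("durations must be >= 0")

    @property
    def n(self) -> int:
        return len(self.durations)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def n_early_extinct(self) -> int:
        return int(self.early_extinct.sum())

    @property
    def uncensored(self) -> np.ndarray:
        """Durations of replicates that reached extinction before the cap."""
        return self.durations[~self.censored]

    def mean(self) -> float:
        """Mean duration over uncensored replicates (NaN if all censored)."""
        d = self.uncensored
        return float(d.mean()) if d.size else float("nan")

    def sd(self) -> float:
        d = self.uncensored
        return float(d.std(ddof=1)) if d.size > 1 else float("nan")

    def ci95_halfwidth(self) -> float:
        d = self.uncensored
        if d.size < 2:
            return float("nan")
        return float(stats.t.ppf(0.975, d.size - 1) * d.std(ddof=1) / np.sqrt(d.size))

    def calibration_mean(self) -> float:
        """Mean over replicates that are neither censored nor early-extinct.

        Early extinctions never felt the intervention, so they carry no
        information about its strength; calibration excludes them.
        """
        keep = ~self.censored & ~self.early_extinct
        d = self.durations[keep]
        return float(d.mean()) if d.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": self.seeds,
                "duration": self.durations,
                "censored": self.censored.astype(int),
                "early_extinct": self.early_extinct.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_replicates(
    params: ModelParams,
    intervention: Optional[InterventionSpec] = None,
    n_reps: int = 100,
    base_seed: int = DEFAULT_BASE_SEED,
    label: Optional[str] = None,
    keep_trajectories: bool = False,
) -> DurationSample | tuple[DurationSample, list[Trajectory]]:
    """Run ``n_reps`` seeded replicates; replicate k uses ``base_seed + k``.

    Returns the per-replicate extinction times with censoring and
    early-extinction bookkeeping; with ``keep_trajectories`` also returns
    the full trajectories (memory permitting).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    day_t = intervention.day if intervention is not None else None
    seeds = np.arange(base_seed, base_seed + n_reps, dtype=np.int64)
    durs = np.empty(n_reps, dtype=np.int64)
    cens = np.zeros(n_reps, dtype=bool)
    early = np.zeros(n_reps, dtype=bool)
    trajs: list[Trajectory] = []
    for k, seed in enumerate(seeds):
        traj = run(params, intervention, int(seed))
        durs[k] = duration(traj)
        cens[k] = traj.censored
        early[k] = (not traj.censored) and day_t is not None and durs[k] < day_t
        if keep_trajectories:
            trajs.append(traj)
    sample = DurationSample(
        label=label if label is not None else scenario_label(day_t),
        durations=durs,
        seeds=seeds,
        censored=cens,
        early_extinct=early,
        intervention_day=day_t,
    )
    if keep_trajectories:
        return sample, trajs
    return sample


@dataclass(frozen=True)
class SweepTable:
    """Per-scenario summary of an intervention-timing sweep.

    ``table`` has one row per scenario in the order requested (the
    baseline conventionally first), with columns
    ``scenario, intervention_day, n, mean_days, sd_days, ci95, censored``.
    Summary statistics exclude censored replicates.
    """

    table: pd.DataFrame
    samples: tuple[DurationSample, ...] = field(default=())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)


def sweep(
    intervention_days: Sequence[Optional[int]],
    params: ModelParams,
    gamma_mult: float = 1.0,
    beta_mult: float = 1.0,
    n_reps: int = 100,
    base_seed: int = DEFAULT_BASE_SEED,
) -> SweepTable:
    """Run the intervention-timing experiment.

    One replicate ensemble per entry of ``intervention_days`` (``None`` for
    the baseline), all sharing the model parameters, the intervention
    strength, and the replicate seeds (common random numbers).
    """
    if len(intervention_days) == 0:
        raise ValueError("intervention_days must be non-empty")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for summary statistics")
    samples = []
    rows = []
    for day_t in intervention_days:
        interv = (
            None
            if day_t is None
            else InterventionSpec(day=day_t, gamma_mult=gamma_mult, beta_mult=beta_mult)
        )
        sample = run_replicates(params, interv, n_reps=n_reps, base_seed=base_seed)
        samples.append(sample)
        rows.append(
            {
                "scenario": sample.label,
                "intervention_day": np.nan if day_t is None else day_t,
                "n": sample.n,
                "mean_days": sample.mean(),
                "sd_days": sample.sd(),
                "ci95": sample.ci95_halfwidth(),
                "censored": sample.n_censored,
            }
        )
    return SweepTable(table=pd.DataFrame(rows), samples=tuple(samples))


@dataclass(frozen=True)
class ComparisonResult:
    """Welch test of mean extinction time between two scenarios."""

    label_a: str
    label_b: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool


def compare(a: DurationSample, b: DurationSample, alpha: float = 0.05) -> ComparisonResult:
    """Two-sided Welch unequal-variance t test on uncensored durations."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    da, db = a.uncensored, b.uncensored
    if da.size < 2 or db.size < 2:
        raise InsufficientDataError(
            "each sample needs >= 2 uncensored durations "
            f"(got {da.size} and {db.size})"
        )
    if da.std(ddof=1) == 0 and db.std(ddof=1) == 0:
        # Degenerate: Welch statistic undefined; equal means are trivially
        # indistinguishable, unequal means trivially distinct.
        if da.mean() == db.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = float("inf"), 0.0
    else:
        res = stats.ttest_ind(da, db, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        label_a=a.label,
        label_b=b.label,
        statistic=stat,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
    )
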