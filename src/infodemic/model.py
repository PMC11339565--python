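"""Discrete-time stochastic SIR dynamics for misinformation spread.

The population is divided into susceptibles (people who could come to
believe a piece of fake news), believers, and fact-checkers (people who
have checked the claim and are immune to it).  One tick is one day.  Each
day every susceptible makes ``contacts`` random contacts in a well-mixed
population; a contact with a believer transmits belief with probability
``beta``, so a susceptible becomes a believer with probability

    p_inf = 1 - (1 - beta * I / N) ** contacts

(the chain-binomial / Reed-Frost escape form), and every believer
fact-checks and recovers with probability ``gamma``.  Daily transitions are
binomial draws, which keeps the total population exactly constant.

An optional intervention (an official warning or statement published on
day ``day``) multiplies the recovery probability by ``gamma_mult`` and the
transmission probability by ``beta_mult`` from that day onward; effective
probabilities are clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "InterventionSpec",
    "Trajectory",
    "InvalidParametersError",
    "effective_rates",
    "step",
    "run",
    "duration",
]


class InvalidParametersError(ValueError):
    """Raised when model parameters violate their invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the daily chain-binomial update.

    Parameters
    ----------
    n
        Total population size (persons).  Constant over a run.
    beta
        Per-contact daily transmission probability, in [0, 1].
    gamma
        Per-day recovery (fact-checking) probability, in [0, 1].
    contacts
        Mean number of contacts per agent per day (non-negative real).
        With small ``beta`` the basic reproduction number is
        ``beta * contacts / gamma``.
    i0
        Initial number of believers (persons).
    max_days
        Hard cap on simulated days; runs that still have believers at the
        cap are flagged censored.
    extinction_threshold
        Believer count at or below which the spread counts as over.
    """

    n: int = 6000
    beta: float = 0.05
    gamma: float = 0.05
    contacts: float = 1.5
    i0: int = 3
    max_days: int = 1000
    extinction_threshold: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidParametersError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.beta <= 1.0:
            raise InvalidParametersError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 <= self.gamma <= 1.0:
            raise InvalidParametersError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.contacts < 0:
            raise InvalidParametersError(
                f"contacts must be >= 0, got {self.contacts}"
            )
        if not 0 <= self.i0 <= self.n:
            raise InvalidParametersError(
                f"i0 must be in [0, n={self.n}], got {self.i0}"
            )
        if self.max_days < 1:
            raise InvalidParametersError(f"max_days must be >= 1, got {self.max_days}")
        if self.extinction_threshold < 0:
            raise InvalidParametersError(
                "extinction_threshold must be >= 0, "
                f"got {self.extinction_threshold}"
            )

    @property
    def r0(self) -> float:
        """Basic reproduction number ``beta * contacts / gamma`` (inf if gamma=0)."""
        if self.gamma == 0:
            return float("inf")
        return self.beta * self.contacts / self.gamma

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InterventionSpec:
    """A step-change intervention at a fixed day.

    From ``day`` onward the effective recovery probability is
    ``gamma * gamma_mult`` and the effective transmission probability is
    ``beta * beta_mult``, both clamped to [0, 1].  ``day=None`` means no
    intervention ever occurs and the multipliers are never applied.
    """

    day: Optional[int] = None
    gamma_mult: float = 1.0
    beta_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.day is not None and self.day < 0:
            raise InvalidParametersError(f"intervention day must be >= 0, got {self.day}")
        if self.gamma_mult < 0 or self.beta_mult < 0:
            raise InvalidParametersError("intervention multipliers must be >= 0")

    @classmethod
    def none(cls) -> "InterventionSpec":
        return cls(day=None)

    def active(self, day: int) -> bool:
        return self.day is not None and day >= self.day


#: Sentinel "no intervention" instance used as a default.
NO_INTERVENTION = InterventionSpec.none()


def effective_rates(
    params: ModelParams,
    intervention: Optional[InterventionSpec],
    day: int,
) -> tuple[float, float]:
    """Transmission and recovery probabilities in force on a given day.

    Returns ``(beta_eff, gamma_eff)``; before the intervention day (or with
    no intervention) these are the baseline ``(beta, gamma)``.
    """
    if day < 0:
        raise InvalidParametersError(f"day must be >= 0, got {day}")
    if intervention is None or not intervention.active(day):
        return params.beta, params.gamma
    beta_eff = min(1.0, max(0.0, params.beta * intervention.beta_mult))
    gamma_eff = min(1.0, max(0.0, params.gamma * intervention.gamma_mult))
    return beta_eff, gamma_eff


def step(
    s: int,
    i: int,
    r: int,
    beta_eff: float,
    gamma_eff: float,
    contacts: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """One daily chain-binomial transition.

    New believers are drawn Binomial(S, p_inf) with
    ``p_inf = 1 - (1 - beta_eff * I / N) ** contacts``; recoveries are drawn
    Binomial(I, gamma_eff).  Returns the updated ``(S, I, R)``; the total is
    conserved by construction.
    """
    if i > 0 and s > 0:
        p_inf = 1.0 - (1.0 - beta_eff * i / n) ** contacts
        new_inf = int(rng.binomial(s, p_inf))
    else:
        new_inf = 0
    recoveries = int(rng.binomial(i, gamma_eff)) if i > 0 else 0
    return s - new_inf, i + new_inf - recoveries, r + recoveries


@dataclass(frozen=True)
class Trajectory:
    """Daily (S, I, R) counts of one simulated run.

    ``days`` are contiguous integers starting at 0.  ``extinct`` is True if
    the run ended because the believer count reached the extinction
    threshold, False if it hit the day cap (a censored run).
    """

    days: np.ndarray
    s: np.ndarray
    i: np.ndarray
    r: np.ndarray
    extinct: bool
    extinction_threshold: int = 0
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return int(self.s[0] + self.i[0] + self.r[0])

    @property
    def censored(self) -> bool:
        return not self.extinct

    def validate(self) -> None:
        """Assert conservation, monotonicity and contiguity of day indices."""
        n = self.n
        total = self.s + self.i + self.r
        if not np.all(total == n):
            raise AssertionError("population not conserved along trajectory")
        if np.any(self.s < 0) or np.any(self.i < 0) or np.any(self.r < 0):
            raise AssertionError("negative compartment count")
        if np.any(np.diff(self.s) > 0):
            raise AssertionError("S must be non-increasing")
        if np.any(np.diff(self.r) < 0):
            raise AssertionError("R must be non-decreasing")
        if not np.array_equal(self.days, np.arange(len(self.days))):
            raise AssertionError("day indices must be contiguous from 0")
        if self.extinct and self.i[-1] > self.extinction_threshold:
            raise AssertionError("extinct trajectory ends above threshold")

    def believer_percent(self) -> np.ndarray:
        """Believers as a percentage of the population, per day."""
        return 100.0 * self.i / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "S": self.s, "I": self.i, "R": self.r})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run(
    params: ModelParams,
    intervention: Optional[InterventionSpec] = None,
    seed: int = 0,
) -> Trajectory:
    """Simulate one stochastic run.

    Starts at ``(S, I, R) = (n - i0, i0, 0)`` on day 0 and iterates the
    daily chain-binomial step, switching to post-intervention rates from
    the intervention day onward.  Stops on the first day the believer count
    is at or below the extinction threshold (``extinct``), or at
    ``max_days`` (censored).  The same ``(params, intervention, seed)``
    always produces a bit-identical trajectory.
    """
    rng = np.random.default_rng(seed)
    intervention = intervention if intervention is not None else NO_INTERVENTION
    thr = params.extinction_threshold

    s, i, r = params.n - params.i0, params.i0, 0
    s_hist, i_hist, r_hist = [s], [i], [r]
    extinct = i <= thr
    day = 0
    while not extinct and day < params.max_days:
        beta_eff, gamma_eff = effective_rates(params, intervention, day)
        s, i, r = step(s, i, r, beta_eff, gamma_eff, params.contacts, params.n, rng)
        day += 1
        s_hist.append(s)
        i_hist.append(i)
        r_hist.append(r)
        extinct = i <= thr

    traj = Trajectory(
        days=np.arange(day + 1),
        s=np.asarray(s_hist, dtype=np.int64),
        i=np.asarray(i_hist, dtype=np.int64),
        r=np.asarray(r_hist, dtype=np.int64),
        extinct=bool(extinct),
        extinction_threshold=thr,
        seed=seed,
    )
    traj.validate()
    return traj


def duration(traj: Trajectory) -> int:
    """Extinction time: the first day the believer count is at/below threshold.

    For a censored trajectory (never reaching the threshold) this returns
    the last simulated day, a lower bound; check ``traj.censored``.
    """
    below = np.nonzero(traj.i <= traj.extinction_threshold)[0]
    if below.size:
        return int(traj.days[below[0]])
    return int(traj.days[-1])
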