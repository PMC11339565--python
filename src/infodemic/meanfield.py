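"""Deterministic mean-field references for the stochastic model.

Two deterministic companions to the chain-binomial simulator:

* :func:`solve_ode` integrates the classical continuous-time SIR system
  with transmission rate ``beta * contacts`` and recovery rate ``gamma``,
  including the same step-change intervention.
* :func:`iterate_mean` iterates the large-population expectation of the
  daily update itself (the exact deterministic limit of the discrete-time
  model).  For small per-day probabilities the two agree closely; the map
  is the right oracle for the simulator's ensemble mean at finite rates.

:func:`final_size` solves the classical final-size identity
``z = 1 - exp(-R0 * z)``, the attack fraction of a supercritical epidemic
in the mean-field limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import InterventionSpec, ModelParams, effective_rates

__all__ = ["OdeSolution", "solve_ode", "iterate_mean", "final_size", "ode_duration"]


@dataclass(frozen=True)
class OdeSolution:
    """Continuous-time SIR solution on a regular time grid (counts)."""

    t: np.ndarray
    s: np.ndarray
    i: np.ndarray
    r: np.ndarray
    n: float
    r0_basic: float

    def validate(self, tol: float = 1e-6) -> None:
        if np.max(np.abs(self.s + self.i + self.r - self.n)) > tol * self.n:
            raise AssertionError("ODE solution violates conservation")
        if np.any(np.diff(self.s) > 1e-9 * self.n):
            raise AssertionError("ODE S must be non-increasing")
        if np.any(np.diff(self.r) < -1e-9 * self.n):
            raise AssertionError("ODE R must be non-decreasing")

    def to_daily_frame(self) -> pd.DataFrame:
        """Interpolate onto integer days with the `day,S,I,R` schema."""
        days = np.arange(int(np.floor(self.t[-1])) + 1)
        return pd.DataFrame(
            {
                "day": days,
                "S": np.interp(days, self.t, self.s),
                "I": np.interp(days, self.t, self.i),
                "R": np.interp(days, self.t, self.r),
            }
        )


def solve_ode(
    params: ModelParams,
    intervention: Optional[InterventionSpec] = None,
    t_max: float = 1000.0,
    dt: float = 1.0,
) -> OdeSolution:
    """Integrate the mean-field SIR system with the intervention switch.

    dS/dt = -beta_eff * contacts * S * I / N
    dI/dt =  beta_eff * contacts * S * I / N - gamma_eff * I
    dR/dt =  gamma_eff * I

    The rate discontinuity at the intervention day is handled by
    integrating each constant-rate segment separately.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_max < dt:
        raise ValueError("t_max must be >= dt")

    def rhs_factory(beta_eff: float, gamma_eff: float):
        rate = beta_eff * params.contacts / params.n

        def rhs(_t, y):
            s, i, _r = y
            inf = rate * s * i
            return (-inf, inf - gamma_eff * i, gamma_eff * i)

        return rhs

    day_t = None
    if intervention is not None and intervention.day is not None:
        day_t = float(intervention.day)

    grid = np.arange(0.0, t_max + 0.5 * dt, dt)
    grid[-1] = min(grid[-1], t_max)
    y0 = (float(params.n - params.i0), float(params.i0), 0.0)

    # (t_start, t_end, post-intervention?) constant-rate segments
    if day_t is None or day_t >= t_max:
        segments = [(0.0, float(t_max), False)]
    elif day_t <= 0:
        segments = [(0.0, float(t_max), True)]
    else:
        segments = [(0.0, day_t, False), (day_t, float(t_max), True)]

    ts, ys = [], []
    y = y0
    for t0, t1, post in segments:
        if post:
            beta_eff, gamma_eff = effective_rates(
                params, intervention, intervention.day
            )
        else:
            beta_eff, gamma_eff = params.beta, params.gamma
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[0] > t0:
            t_eval = np.concatenate(([t0], t_eval))
        if t_eval[-1] < t1:
            t_eval = np.concatenate((t_eval, [t1]))
        sol = solve_ivp(
            rhs_factory(beta_eff, gamma_eff),
            (t0, t1),
            y,
            t_eval=t_eval,
            rtol=1e-9,
            atol=1e-9 * params.n,
            method="LSODA",
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise FloatingPointError("ODE integration produced non-finite state")
        ts.append(sol.t)
        ys.append(sol.y)
        y = sol.y[:, -1]

    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)
    t, idx = np.unique(t, return_index=True)
    y = y[:, idx]
    out = OdeSolution(
        t=t,
        s=y[0],
        i=y[1],
        r=y[2],
        n=float(params.n),
        r0_basic=params.r0,
    )
    out.validate()
    return out


def iterate_mean(
    params: ModelParams,
    intervention: Optional[InterventionSpec] = None,
    t_max: int = 1000,
) -> pd.DataFrame:
    """Deterministic limit of the daily update (real-valued compartments).

    Iterates the expectation of the chain-binomial step:
    ``S' = S (1 - p_inf)``, ``I' = I + S p_inf - gamma_eff I``,
    ``R' = R + gamma_eff I``.  This is what the stochastic ensemble mean
    converges to as the population grows, at the model's native one-day
    time step.
    """
    s = float(params.n - params.i0)
    i = float(params.i0)
    r = 0.0
    rows = [(0, s, i, r)]
    for day in range(t_max):
        beta_eff, gamma_eff = effective_rates(params, intervention, day)
        p_inf = 1.0 - (1.0 - beta_eff * i / params.n) ** params.contacts
        new_inf = s * p_inf
        rec = gamma_eff * i
        s, i, r = s - new_inf, i + new_inf - rec, r + rec
        rows.append((day + 1, s, i, r))
    return pd.DataFrame(rows, columns=["day", "S", "I", "R"])


def final_size(r0: float) -> float:
    """Largest root z of ``z = 1 - exp(-r0 * z)`` in [0, 1).

    Returns 0 for subcritical or critical ``r0`` (no epidemic in the
    mean-field limit); for ``r0 > 1`` the nontrivial root is found by
    Brent's method to absolute tolerance 1e-12.
    """
    if r0 < 0:
        raise ValueError("r0 must be >= 0")
    if r0 <= 1.0:
        return 0.0

    def f(z: float) -> float:
        return z - 1.0 + np.exp(-r0 * z)

    # f(0)=0 with negative slope for r0>1; f(1)=exp(-r0)>0 brackets the root.
    return float(brentq(f, 1e-12, 1.0, xtol=1e-12))


def ode_duration(sol: OdeSolution) -> float:
    """First time the mean-field believer count drops below one person.

    A qualitative analogue of the stochastic extinction time, not directly
    comparable to it (the deterministic I never reaches exactly zero).
    """
    below = np.nonzero(sol.i < 1.0)[0]
    if below.size == 0:
        return float(sol.t[-1])
    return float(sol.t[below[0]])
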