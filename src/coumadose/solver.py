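"""Heun (RK2) integration of the warfarin KPD system over a dosing regimen.

Doses are instantaneous bolus additions to the drug-amount compartment (the
PK model has first-order elimination and no explicit absorption phase). The
time grid is the union of uniform steps with every dose-event time and any
requested observation times, so events and read-outs land exactly on grid
points. When a dose coincides with a grid point the dose is applied first
and the state recorded after.

The stepping loop is compiled with numba; :func:`heun_step` is the generic
single-step method for arbitrary right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .model_core import IndividualParameters, ModelState, PopulationModel

__all__ = ["DoseEvent", "Regimen", "Trajectory", "heun_step", "integrate"]


@dataclass(frozen=True, order=True)
class DoseEvent:
    """A single oral dose: time since first dose (h) and amount (mg)."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events plus the nominal dosing interval."""

    events: tuple[DoseEvent, ...]
    dosing_interval: float = 24.0

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose-event times must be strictly increasing")
        if not self.dosing_interval > 0:
            raise ValueError("dosing interval must be > 0")

    @property
    def last_time(self) -> float:
        return self.events[-1].time if self.events else 0.0

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)


@dataclass
class Trajectory:
    """Dense simulation output: time grid, raw states and predicted INR.

    ``states`` has one row per grid point with columns
    (A, C1_1..C1_3, C2_1..C2_3).
    """

    times: np.ndarray
    states: np.ndarray
    inr: np.ndarray

    def inr_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of the INR curve (grid is dense)."""
        out = np.interp(t, self.times, self.inr)
        return float(out) if np.isscalar(t) else out

    def terminal_state(self) -> ModelState:
        return ModelState.from_vector(self.states[-1])

    def mean_inr(self, t0: float, t1: float) -> float:
        """Trapezoidal mean of INR over [t0, t1] using the stored grid."""
        mask = (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)
        t, y = self.times[mask], self.inr[mask]
        if len(t) < 2:
            raise ValueError("interval does not span at least two grid points")
        return float(np.trapezoid(y, t) / (t[-1] - t[0]))

    def to_frame(self):
        """Export as a DataFrame (time, A, C1_3, C2_3, INR)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "amount_mg": self.states[:, 0],
                "c1_3": self.states[:, 3],
                "c2_3": self.states[:, 6],
                "inr": self.inr,
            }
        )


def heun_step(
    y: np.ndarray,
    t: float,
    h: float,
    derivative_fn: Callable[[float, np.ndarray], np.ndarray],
) -> np.ndarray:
    """One Heun predictor-corrector step (local truncation error O(h^3)).

    y* = y + h f(t, y);  y_next = y + (h/2) (f(t, y) + f(t+h, y*)).
    """
    if not h > 0:
        raise ValueError("step size must be > 0")
    y = np.asarray(y, float)
    f0 = np.asarray(derivative_fn(t, y), float)
    y_pred = y + h * f0
    f1 = np.asarray(derivative_fn(t + h, y_pred), float)
    return y + 0.5 * h * (f0 + f1)


@njit(cache=True)
def _rhs(y, dy, k10, edk50, gamma, emax, k1, k2, forced_eff):  # pragma: no cover
    a = y[0]
    if forced_eff == forced_eff:  # not NaN -> override
        eff = forced_eff
    else:
        dr = k10 * a
        if dr <= 0.0:
            eff = 0.0
        else:
            drg = dr ** gamma
            eff = emax * drg / (edk50 ** gamma + drg)
    dy[0] = -k10 * a
    inflow = 1.0 - eff
    dy[1] = k1 * (inflow - y[1])
    dy[2] = k1 * (y[1] - y[2])
    dy[3] = k1 * (y[2] - y[3])
    dy[4] = k2 * (inflow - y[4])
    dy[5] = k2 * (y[4] - y[5])
    dy[6] = k2 * (y[5] - y[6])


@njit(cache=True)
def _heun_kernel(grid, dose_amt, y0, k10, edk50, gamma, emax, k1, k2, forced_eff):
    n = grid.shape[0]
    out = np.empty((n, 7))
    y = y0.copy()
    yp = np.empty(7)
    d0 = np.empty(7)
    d1 = np.empty(7)
    for i in range(n):
        y[0] += dose_amt[i]
        for j in range(7):
            out[i, j] = y[j]
        if i == n - 1:
            break
        h = grid[i + 1] - grid[i]
        _rhs(y, d0, k10, edk50, gamma, emax, k1, k2, forced_eff)
        for j in range(7):
            yp[j] = y[j] + h * d0[j]
        _rhs(yp, d1, k10, edk50, gamma, emax, k1, k2, forced_eff)
        for j in range(7):
            y[j] += 0.5 * h * (d0[j] + d1[j])
    return out


def _build_grid(
    event_times: np.ndarray, t_end: float, step: float,
    extra_times: Sequence[float] | None,
) -> np.ndarray:
    base = np.arange(0.0, t_end + 0.5 * step, step)
    if base[-1] < t_end:
        base = np.append(base, t_end)
    parts = [base, event_times]
    if extra_times is not None:
        extra = np.asarray(extra_times, float)
        if np.any(extra < 0) or np.any(extra > t_end + 1e-9):
            raise ValueError("extra times must lie within [0, t_end]")
        parts.append(extra)
    grid = np.unique(np.concatenate(parts))
    return grid[grid <= t_end + 1e-9]


def integrate(
    regimen: Regimen,
    indiv: IndividualParameters,
    pop: PopulationModel,
    baseline_inr: float,
    t_end: float,
    step: float = 0.1,
    *,
    initial_state: ModelState | None = None,
    extra_times: Sequence[float] | None = None,
    forced_eff: float | None = None,
) -> Trajectory:
    """Simulate a dosing regimen and return the dense INR trajectory.

    The state starts at the pre-treatment stationary point (A = 0, all
    activities 1) unless ``initial_state`` continues a previous simulation.
    ``forced_eff`` pins the inhibition to a constant (verification hook for
    the linear-cascade and pure-PK closed forms); ``extra_times`` forces
    specific read-out times onto the grid.
    """
    if not step > 0:
        raise ValueError("step size must be > 0")
    event_times = np.array([e.time for e in regimen.events], float)
    if event_times.size and t_end < event_times[-1]:
        raise ValueError("t_end must cover the last dose event")
    grid = _build_grid(event_times, t_end, step, extra_times)
    dose_amt = np.zeros_like(grid)
    if event_times.size:
        idx = np.searchsorted(grid, event_times)
        for i, e in zip(idx, regimen.events):
            if abs(grid[i] - e.time) > 1e-9:
                raise RuntimeError("event time not aligned to grid")  # defensive
            dose_amt[i] += e.amount

    y0 = (initial_state or ModelState()).to_vector()
    states = _heun_kernel(
        grid, dose_amt, y0,
        indiv.k10, indiv.edk50, pop.gamma, pop.emax,
        3.0 / pop.mtt1, 3.0 / pop.mtt2,
        np.nan if forced_eff is None else float(forced_eff),
    )
    inr = baseline_inr + pop.inr_max * (1.0 - (states[:, 3] + states[:, 6]) / 2.0)
    return Trajectory(times=grid, states=states, inr=inr)
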