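"""Direct per-time-point solution of the Jacobian linear systems.

For each node i and time interval k, the first-order Taylor expansion of the
rate function about (t_k, vehicle) yields an n x n linear system whose rows
are one time-difference relation from the vehicle course and n-1
perturbation-difference relations from the perturbations of nodes j != i
(data from perturbation i is never used to estimate row i). Solving each
system gives a per-time-point estimate of row i of the Jacobian; the
element-wise median across time points is the summary estimate.

This route is exact up to Taylor truncation on clean data but is fragile
under noise — it motivates the least-squares estimator and is retained as a
fast initializer and a demonstration of that fragility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import basal_from_initial_state, stimulus_from_steady_state
from .experiment import PerturbationDataset

__all__ = [
    "DifferenceTables",
    "JacobianSeries",
    "build_difference_tables",
    "solve_jacobian_series",
    "stimuli_from_series",
]

_COND_MAX = 1e12  # systems with condition number above this are flagged singular


@dataclass(frozen=True)
class DifferenceTables:
    """Finite-difference tables feeding the per-time-point linear systems.

    ``dt_x[k, i]`` = x_i(k+1) − x_i(k) on the vehicle course;
    ``dp_x[j][k, i]`` = x_i(k) under perturbation j minus vehicle;
    ``y_vehicle[k, i]`` = rate-estimate difference f̂_i(k+1) − f̂_i(k);
    ``y_pert[j][k, i]`` = f̂_{i,j}(k) − f̂_i(k). Rate estimates f̂ are forward
    differences (Δx/Δt), with a backward difference at the final point so
    every time index has an estimate.
    """

    times: np.ndarray
    dt_x: np.ndarray
    dp_x: dict[int, np.ndarray]
    y_vehicle: np.ndarray
    y_pert: dict[int, np.ndarray]


def _rate_estimates(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Forward-difference rate estimates per interval (N_t − 1 rows)."""
    return np.diff(values, axis=0) / np.diff(times)[:, None]


def _midpoint_states(values: np.ndarray) -> np.ndarray:
    """Interval-midpoint states (N_t − 1 rows).

    A forward difference estimates the average rate over its interval, which
    to second order is the rate at the interval midpoint; pairing it with
    the midpoint state keeps the linear relations consistent. Pairing with
    the left endpoint instead leaves an O(1) relative bias at coarse grids
    (for pure decay at unit spacing the recovered rate constant would be
    scaled by (1 − e^{−Δt})/Δt).
    """
    return 0.5 * (values[:-1] + values[1:])


def build_difference_tables(ds: PerturbationDataset) -> DifferenceTables:
    if ds.n_timepoints < 2:
        raise ValueError("difference tables need at least 2 time points")
    xv = ds.vehicle.values
    fv = _rate_estimates(ds.times, xv)
    mv = _midpoint_states(xv)
    dt_x = np.diff(mv, axis=0)  # rows k = 0..N_t-3
    y_vehicle = np.diff(fv, axis=0)
    dp_x, y_pert = {}, {}
    for j, tr in ds.perturbed.items():
        dp_x[j] = _midpoint_states(tr.values) - mv
        y_pert[j] = _rate_estimates(ds.times, tr.values) - fv
    return DifferenceTables(times=ds.times, dt_x=dt_x, dp_x=dp_x, y_vehicle=y_vehicle, y_pert=y_pert)


@dataclass(frozen=True)
class JacobianSeries:
    """Per-time-point Jacobian estimates F(t_k), k = 0..N_t−3.

    Each system combines a rate difference between consecutive intervals
    with the perturbation rows of one interval, so N_t sample points yield
    N_t − 2 estimates. ``estimates[k]`` is the n x n solve at interval k;
    flagged (singular) row-solves are NaN. ``median`` is the element-wise
    median over non-flagged estimates; ``spread`` the element-wise standard
    deviation; ``cond[k, i]`` the condition number of row i's system.
    """

    times: np.ndarray
    estimates: np.ndarray
    cond: np.ndarray
    flagged: np.ndarray

    @property
    def median(self) -> np.ndarray:
        return np.nanmedian(self.estimates, axis=0)

    @property
    def spread(self) -> np.ndarray:
        return np.nanstd(self.estimates, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = self.estimates.shape[1]
        for k in range(self.estimates.shape[0]):
            for i in range(n):
                for j in range(n):
                    rows.append(
                        (self.times[k], i + 1, j + 1, self.estimates[k, i, j], self.cond[k, i])
                    )
        return pd.DataFrame(rows, columns=["time", "i", "j", "estimate", "condition_number"])


def solve_jacobian_series(ds: PerturbationDataset) -> JacobianSeries:
    """Solve the per-interval n x n systems for every Jacobian row.

    Row i's system at interval k stacks the vehicle time-difference relation
    (y_i(k+1) vs Δ_t x(k+1)) with the perturbation relations for every j != i
    (y_{i,j}(k) vs Δ_{p,j} x(k)). Singular systems are flagged (NaN), not
    silently dropped; the median is taken over non-flagged solves.
    """
    tab = build_difference_tables(ds)
    n = ds.n
    n_sys = ds.n_timepoints - 2
    est = np.full((n_sys, n, n), np.nan)
    cond = np.full((n_sys, n), np.inf)
    flagged = np.zeros((n_sys, n), dtype=bool)
    others = {i: [j for j in range(1, n + 1) if j != i + 1] for i in range(n)}
    for k in range(n_sys):
        for i in range(n):
            A = np.empty((n, n))
            b = np.empty(n)
            A[0] = tab.dt_x[k]
            b[0] = tab.y_vehicle[k, i]
            for r, j in enumerate(others[i], start=1):
                A[r] = tab.dp_x[j][k]
                b[r] = tab.y_pert[j][k, i]
            c = np.linalg.cond(A)
            cond[k, i] = c
            if not np.isfinite(c) or c > _COND_MAX:
                flagged[k, i] = True
                continue
            est[k, i] = np.linalg.solve(A, b)
    for i in range(n):
        if flagged[:, i].all():
            raise np.linalg.LinAlgError(
                f"all per-time-point systems for node {i + 1} are singular"
            )
    return JacobianSeries(times=ds.times[:-1], estimates=est, cond=cond, flagged=flagged)


def stimuli_from_series(series: JacobianSeries, ds: PerturbationDataset) -> np.ndarray:
    """External stimulus estimate from the median Jacobian and the final state.

    The last sampled point is taken as near steady state, where the total
    forcing is −F·x; the basal component implied by the (pre-stimulus,
    steady) initial state is subtracted to leave the external stimulus.
    """
    F_med = series.median
    total = stimulus_from_steady_state(F_med, ds.vehicle.values[-1])
    basal = basal_from_initial_state(F_med, ds.vehicle.values[0])
    return total - basal
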