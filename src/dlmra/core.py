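"""Linear network ODE model, steady-state algebra and stability diagnostics.

The central object is :class:`LinearNetwork`, the model

.. math::

    dx_i/dt = S_{i,b} + S_{i,ex} + \\sum_j F_{ij} x_j,

where ``F`` is the (constant) Jacobian of the system — entry ``F[i, j]`` is
the direct, signed effect of node ``j``'s activity on node ``i``'s rate of
change — ``S_b`` is basal/constitutive production, and ``S_ex`` an external
stimulus that is switched on at t = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

__all__ = [
    "LinearNetwork",
    "Trajectory",
    "SteadyState",
    "rates",
    "simulate",
    "basal_steady_state",
    "stability_flags",
    "stimulus_from_steady_state",
    "basal_from_initial_state",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "UnstableNetworkError",
]

#: default integrator tolerances (stiff-capable adaptive solver)
RTOL = 1e-8
ATOL = 1e-10
#: |imag(eigenvalue)| above this counts as oscillatory
OSC_TOL = 1e-9
#: max |dx/dt| below this counts as a steady state
SS_TOL = 1e-9


class UnstableNetworkError(ValueError):
    """Raised when an operation requires a stable network but got an unstable one."""

    def __init__(self, msg: str, eigenvalues=None):
        super().__init__(msg)
        self.eigenvalues = eigenvalues


@dataclass(frozen=True)
class LinearNetwork:
    """A linear n-node network dx/dt = S_b + S_ex·1[stimulus] + F·x.

    Parameters
    ----------
    F : (n, n) array
        Edge-weight / Jacobian matrix (per unit time).
    S_b : (n,) array
        Basal production rates (activity / time).
    S_ex : (n,) array
        External stimulus strengths (activity / time), applied only while
        ``stimulus_active`` is true.
    stimulus_active : bool
        Whether the external stimulus currently drives the network.
    """

    F: np.ndarray
    S_b: np.ndarray
    S_ex: np.ndarray
    stimulus_active: bool = True

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        S_b = np.asarray(self.S_b, dtype=float).ravel()
        S_ex = np.asarray(self.S_ex, dtype=float).ravel()
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise ValueError(f"F must be square, got shape {F.shape}")
        n = F.shape[0]
        if S_b.shape != (n,) or S_ex.shape != (n,):
            raise ValueError(
                f"S_b and S_ex must have length {n}, got {S_b.shape} and {S_ex.shape}"
            )
        if not (np.all(np.isfinite(F)) and np.all(np.isfinite(S_b)) and np.all(np.isfinite(S_ex))):
            raise ValueError("network entries must be finite")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "S_b", S_b)
        object.__setattr__(self, "S_ex", S_ex)

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def forcing(self) -> np.ndarray:
        """Total constant forcing S_b (+ S_ex when the stimulus is active)."""
        return self.S_b + (self.S_ex if self.stimulus_active else 0.0)

    def with_stimulus(self, active: bool) -> "LinearNetwork":
        return replace(self, stimulus_active=active)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "F": self.F.ravel().tolist(),  # row-major
                "S_b": self.S_b.tolist(),
                "S_ex": self.S_ex.tolist(),
                "stimulus_active": self.stimulus_active,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "LinearNetwork":
        d = json.loads(doc)
        n = int(d["n"])
        return cls(
            F=np.asarray(d["F"], dtype=float).reshape(n, n),
            S_b=np.asarray(d["S_b"], dtype=float),
            S_ex=np.asarray(d["S_ex"], dtype=float),
            stimulus_active=bool(d.get("stimulus_active", True)),
        )


@dataclass(frozen=True)
class Trajectory:
    """Sampled node activities: ``values[k, i]`` is node i at ``times[k]``."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if v.shape[0] != t.size:
            raise ValueError("values row count must equal number of times")
        if not np.all(np.isfinite(v)):
            raise ValueError("trajectory values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[1]


def trajectory_to_csv(traj: Trajectory, path) -> None:
    """Write a trajectory as tidy CSV (columns: time, node, value; 1-based nodes)."""
    import pandas as pd

    rows = [
        (t, i + 1, traj.values[k, i])
        for k, t in enumerate(traj.times)
        for i in range(traj.n)
    ]
    pd.DataFrame(rows, columns=["time", "node", "value"]).to_csv(path, index=False)


def trajectory_from_csv(path) -> Trajectory:
    import pandas as pd

    wide = pd.read_csv(path).pivot(index="time", columns="node", values="value").sort_index()
    return Trajectory(times=wide.index.to_numpy(), values=wide.to_numpy())


@dataclass(frozen=True)
class SteadyState:
    x_ss: np.ndarray
    residual: float


def rates(net: LinearNetwork, x: np.ndarray) -> np.ndarray:
    """Rate vector dx/dt = S_b + S_ex·1[stimulus] + F·x."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (net.n,):
        raise ValueError(f"x must have length {net.n}, got {x.shape}")
    return net.forcing + net.F @ x


def simulate(
    net: LinearNetwork,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
    dense_output: bool = False,
):
    """Integrate the network from ``x0``; ``times[0]`` is the initial time.

    Uses a stiff-capable adaptive integrator (LSODA). Returns a
    :class:`Trajectory`; with ``dense_output=True`` returns
    ``(Trajectory, callable)`` where the callable evaluates the dense solution.
    """
    times = np.asarray(times, dtype=float).ravel()
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.shape != (net.n,):
        raise ValueError(f"x0 must have length {net.n}")
    F, s = net.F, net.forcing
    sol = solve_ivp(
        lambda t, x: s + F @ x,
        (times[0], times[-1]),
        x0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        dense_output=dense_output,
        jac=lambda t, x: F,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            f"integration failed: {sol.message}; eigenvalues of F: {np.linalg.eigvals(F)}"
        )
    values = sol.y.T.copy()
    values[0] = x0  # t_eval[0] is the initial condition, exactly
    traj = Trajectory(times=times, values=values)
    if dense_output:
        return traj, sol.sol
    return traj


def stability_flags(net: LinearNetwork, osc_tol: float = OSC_TOL) -> tuple[bool, bool]:
    """(stable, oscillatory): stable iff max Re(eig F) < 0; oscillatory iff
    any |Im(eig F)| exceeds ``osc_tol`` (damped oscillation potential)."""
    lam = np.linalg.eigvals(net.F)
    stable = bool(np.max(lam.real) < 0)
    oscillatory = bool(np.max(np.abs(lam.imag)) > osc_tol)
    return stable, oscillatory


def basal_steady_state(
    net: LinearNetwork, method: str = "solve", tol: float = SS_TOL, t_max: float = 1000.0
) -> SteadyState:
    """Steady state under basal production only (stimulus off).

    ``method='solve'`` solves F·x = −S_b directly (preferred for linear
    networks); ``method='integrate'`` integrates from zero until
    max |dx/dt| < ``tol`` or t > ``t_max``. Both routes agree for stable nets.
    """
    stable, _ = stability_flags(net)
    if not stable:
        raise UnstableNetworkError(
            "basal steady state requested for an unstable network",
            eigenvalues=np.linalg.eigvals(net.F),
        )
    quiet = net.with_stimulus(False)
    if method == "solve":
        x_ss = linalg.solve(net.F, -net.S_b)
    elif method == "integrate":
        x = np.zeros(net.n)
        t = 0.0
        while t < t_max:
            step = min(50.0, t_max - t)
            traj = simulate(quiet, x, np.array([t, t + step]))
            x = traj.values[-1]
            t += step
            if np.max(np.abs(rates(quiet, x))) < tol:
                break
        x_ss = x
    else:
        raise ValueError(f"unknown method {method!r}")
    residual = float(np.max(np.abs(rates(quiet, x_ss))))
    return SteadyState(x_ss=x_ss, residual=residual)


def stimulus_from_steady_state(F_hat: np.ndarray, x_ss: np.ndarray) -> np.ndarray:
    """Total per-node stimulus S_b + S_ex implied by a steady state: −F_hat·x_ss."""
    F_hat = np.asarray(F_hat, dtype=float)
    x_ss = np.asarray(x_ss, dtype=float).ravel()
    if F_hat.shape != (x_ss.size, x_ss.size):
        raise ValueError(f"shape mismatch: F_hat {F_hat.shape} vs x_ss {x_ss.shape}")
    return -(F_hat @ x_ss)


def basal_from_initial_state(F_hat: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Basal production implied by a pre-stimulus steady state: −F_hat·x0.

    Valid when t = 0 is a steady state reached without the external stimulus,
    so that basal production alone balances the network terms.
    """
    return stimulus_from_steady_state(F_hat, x0)
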