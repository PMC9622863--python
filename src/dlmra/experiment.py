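"""Perturbation time-course experiment designs.

The prescribed design for an n-node network is n + 1 time courses on a shared
grid: one vehicle (unperturbed control) course, plus one course per node in
which that node is perturbed. A perturbation retains a fraction ``p`` of the
node's unperturbed activity (p = 0: complete inhibition, p = 0.5: 50%
knockdown): the perturbed node's trace is the scaled copy of its vehicle
trace, and the remaining nodes are integrated with that trace as a forcing
input, so no mechanistic model of the perturbation is ever needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import LinearNetwork, Trajectory, basal_steady_state
from .models import FFLModelSpec, ffl_prestimulus_steady_state, hill_act, hill_rep, _ffl_gate
from .models import ACTIVATOR, MarkovTransitionModel, markov_to_continuous

__all__ = [
    "PerturbationSpec",
    "PerturbationDataset",
    "generate_design_data",
    "add_noise",
    "drop_node",
    "cellstate_design",
    "dataset_to_csv",
    "dataset_from_csv",
]

_RTOL = 1e-8
_ATOL = 1e-10


@dataclass(frozen=True)
class PerturbationSpec:
    """target: 1-based node index or 'vehicle'; strength p in [0, 1]."""

    target: int | str
    p: float = 0.0

    def __post_init__(self):
        if self.target != "vehicle" and not (isinstance(self.target, int) and self.target >= 1):
            raise ValueError(f"bad perturbation target {self.target!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"perturbation strength p must lie in [0, 1], got {self.p}")


@dataclass(frozen=True)
class PerturbationDataset:
    """Vehicle + per-node perturbation trajectories on one shared time grid.

    ``perturbed[j]`` (j = 1..n) is the condition in which node j was
    perturbed; its node-j column is the retained-fraction trace (synthetic
    data, before noise). ``kind`` records the generating model family
    ('linear', 'ffl' or 'cellstate' — cell-state conditions are
    initial-condition perturbations and carry p = nan).
    """

    n: int
    times: np.ndarray
    vehicle: Trajectory
    perturbed: dict[int, Trajectory]
    p: float
    kind: str = "linear"
    noise_d: float = 0.0
    seed: int | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        object.__setattr__(self, "times", t)
        if set(self.perturbed) != set(range(1, self.n + 1)):
            raise ValueError("perturbed map must have exactly one entry per node")
        for tr in [self.vehicle, *self.perturbed.values()]:
            if tr.values.shape != (t.size, self.n) or not np.allclose(tr.times, t):
                raise ValueError("all trajectories must share the dataset time grid")

    @property
    def n_timepoints(self) -> int:
        return self.times.size

    def condition(self, key) -> Trajectory:
        return self.vehicle if key == "vehicle" else self.perturbed[key]


def _integrate_forced(rate_others, x0_others, times):
    """Integrate the non-perturbed nodes under a forced perturbed-node trace."""
    sol = solve_ivp(
        rate_others,
        (times[0], times[-1]),
        x0_others,
        method="LSODA",
        t_eval=times,
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"forced integration failed: {sol.message}")
    return sol.y.T


def _ffl_forced_rates(spec: FFLModelSpec, x1, x2):
    """dx2/dt, dx3/dt of the FFL circuit given current (x1, x2) values."""
    x1 = max(float(x1), 0.0)
    x2 = max(float(x2), 0.0)
    f2 = hill_act(x1, spec.K_x1x2) if spec.sign_21 == ACTIVATOR else hill_rep(x1, spec.K_x1x2)
    g = _ffl_gate(spec, x1, x2)
    return f2, g


def generate_design_data(
    model: LinearNetwork | FFLModelSpec,
    times: np.ndarray,
    p: float = 0.0,
    check_responsiveness: bool = True,
) -> PerturbationDataset:
    """Generate the clean n+1-condition design dataset from a model.

    Two-step protocol: the model is first equilibrated without the external
    stimulus (basal steady state), then the stimulus is switched on at
    ``times[0]`` and the response sampled on ``times`` (vehicle). For each
    node j the perturbed course scales node j's vehicle trace by ``p`` and
    integrates the remaining nodes with the scaled dense trace as forcing.
    """
    times = np.asarray(times, dtype=float).ravel()
    PerturbationSpec(target=1, p=p)  # validate p
    if isinstance(model, LinearNetwork):
        return _linear_design(model, times, p, check_responsiveness)
    return _ffl_design(model, times, p, check_responsiveness)


def _linear_design(net, times, p, check):
    x0 = basal_steady_state(net).x_ss  # raises for unstable nets
    stim = net.with_stimulus(True)
    F, s = stim.F, stim.forcing
    sol = solve_ivp(
        lambda t, x: s + F @ x,
        (times[0], times[-1]),
        x0,
        method="LSODA",
        t_eval=times,
        rtol=_RTOL,
        atol=_ATOL,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"vehicle integration failed: {sol.message}")
    vehicle = Trajectory(times=times, values=sol.y.T)
    dense = sol.sol

    perturbed = {}
    for j in range(1, net.n + 1):
        ji = j - 1
        others = [i for i in range(net.n) if i != ji]

        def rate_others(t, xo, ji=ji, others=others):
            g = p * dense(t)[ji]
            full = np.empty(net.n)
            full[others] = xo
            full[ji] = g
            return (s + F @ full)[others]

        vals = np.empty((times.size, net.n))
        vals[:, others] = _integrate_forced(rate_others, x0[others], times)
        vals[:, ji] = p * vehicle.values[:, ji]
        perturbed[j] = Trajectory(times=times, values=vals)

    # responsiveness is a Hill-threshold (FFL) concern; linear nets with true
    # zero couplings would trip it spuriously
    return PerturbationDataset(
        n=net.n, times=times, vehicle=vehicle, perturbed=perturbed, p=p,
        kind="linear",
    )


def _ffl_design(spec, times, p, check):
    x0 = ffl_prestimulus_steady_state(spec)

    def full_rates(t, x):
        x1, x2, x3 = np.maximum(x, 0.0)
        f2, g = _ffl_forced_rates(spec, x1, x2)
        return [1.0 - x1, f2 - x2, g - x3]

    sol = solve_ivp(
        full_rates, (times[0], times[-1]), x0, method="LSODA",
        t_eval=times, rtol=_RTOL, atol=_ATOL, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"vehicle integration failed: {sol.message}")
    vehicle = Trajectory(times=times, values=sol.y.T)
    dense = sol.sol

    perturbed = {}
    for j in (1, 2, 3):
        ji = j - 1
        others = [i for i in range(3) if i != ji]

        def rate_others(t, xo, ji=ji, others=others):
            full = np.empty(3)
            full[others] = xo
            full[ji] = p * dense(t)[ji]
            full = np.maximum(full, 0.0)
            f2, g = _ffl_forced_rates(spec, full[0], full[1])
            all_rates = np.array([1.0 - full[0], f2 - full[1], g - full[2]])
            return all_rates[others]

        vals = np.empty((times.size, 3))
        vals[:, others] = _integrate_forced(rate_others, x0[others], times)
        vals[:, ji] = p * vehicle.values[:, ji]
        perturbed[j] = Trajectory(times=times, values=vals)

    warn = _responsiveness_warnings(vehicle, perturbed) if check else ()
    return PerturbationDataset(
        n=3, times=times, vehicle=vehicle, perturbed=perturbed, p=p,
        kind="ffl", warnings=warn,
    )


def _responsiveness_warnings(vehicle, perturbed, stim_frac=0.05, pert_frac=0.01):
    """Flag nodes unresponsive to the stimulus and perturbations with no
    detectable effect on any other node (relative to each node's scale)."""
    warn = []
    scale = np.maximum(np.max(np.abs(vehicle.values), axis=0), 1e-9)
    span = vehicle.values.max(axis=0) - vehicle.values.min(axis=0)
    for i, (sp, sc) in enumerate(zip(span, scale), start=1):
        if sp <= stim_frac * sc:
            warn.append(f"node {i} vehicle trajectory is unresponsive to the stimulus")
    for j, tr in perturbed.items():
        dev = np.abs(tr.values - vehicle.values)
        others = [i for i in range(vehicle.n) if i != j - 1]
        if all(dev[:, i].max() <= pert_frac * scale[i] for i in others):
            warn.append(f"perturbation of node {j} has no detectable effect on other nodes")
    return tuple(warn)


def add_noise(ds: PerturbationDataset, d: float, rng) -> PerturbationDataset:
    """Proportional Gaussian noise: each point x becomes x + N(0, sd = d·|x|).

    d = 0.1 / 0.2 / 0.5 correspond to 10:1 / 5:1 / 2:1 signal-to-noise.
    Points with x = 0 stay exactly 0. The input dataset is unmodified.
    """
    if d < 0:
        raise ValueError("noise level d must be non-negative")
    if d == 0:
        return ds
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    def noisy(tr: Trajectory) -> Trajectory:
        v = tr.values
        return Trajectory(times=tr.times, values=v + rng.normal(0.0, 1.0, v.shape) * d * np.abs(v))

    return replace(
        ds,
        vehicle=noisy(ds.vehicle),
        perturbed={j: noisy(tr) for j, tr in ds.perturbed.items()},
        noise_d=d,
        seed=seed,
    )


def drop_node(ds: PerturbationDataset, j: int) -> PerturbationDataset:
    """Remove node j's measurements and its perturbation condition.

    Emulates reconstructing a reduced (n−1)-node system when one node's data
    are unavailable. Remaining nodes are renumbered consecutively.
    """
    if not (1 <= j <= ds.n):
        raise ValueError(f"node index {j} out of range 1..{ds.n}")
    if ds.n < 2:
        raise ValueError("cannot drop a node from a 1-node dataset")
    keep = [i for i in range(ds.n) if i != j - 1]

    def reduced(tr: Trajectory) -> Trajectory:
        return Trajectory(times=tr.times, values=tr.values[:, keep])

    new_perturbed = {}
    for old in sorted(ds.perturbed):
        if old == j:
            continue
        new = old if old < j else old - 1
        new_perturbed[new] = reduced(ds.perturbed[old])
    return replace(
        ds, n=ds.n - 1, vehicle=reduced(ds.vehicle), perturbed=new_perturbed,
    )


def cellstate_design(m: MarkovTransitionModel, times: np.ndarray) -> PerturbationDataset:
    """Cell-state proportion time courses under initial-condition perturbations.

    Conditions do not clamp any node: the vehicle starts from equal
    proportions, and the condition labelled as perturbation j starts with
    state j's proportion set to zero and the removed mass redistributed
    proportionally over the remaining states. All trajectories conserve total
    proportion (the rate matrix has zero column sums).
    """
    times = np.asarray(times, dtype=float).ravel()
    net = markov_to_continuous(m)
    n = m.n

    def run(x0):
        sol = solve_ivp(
            lambda t, x: net.F @ x, (times[0], times[-1]), x0, method="LSODA",
            t_eval=times, rtol=_RTOL, atol=_ATOL,
        )
        if not sol.success:
            raise RuntimeError(f"cell-state integration failed: {sol.message}")
        return Trajectory(times=times, values=sol.y.T)

    vehicle = run(np.full(n, 1.0 / n))
    perturbed = {}
    for j in range(1, n + 1):
        x0 = np.full(n, 1.0 / n)
        x0[j - 1] = 0.0
        x0 /= x0.sum()
        perturbed[j] = run(x0)
    return PerturbationDataset(
        n=n, times=times, vehicle=vehicle, perturbed=perturbed, p=float("nan"),
        kind="cellstate",
    )


# ---------------------------------------------------------------------------
# Tidy-CSV serialization (columns: time, condition, node, value) + JSON sidecar
# ---------------------------------------------------------------------------


def dataset_to_csv(ds: PerturbationDataset, csv_path, meta_path=None) -> None:
    rows = []
    for cond_label, tr in [("vehicle", ds.vehicle)] + [
        (f"pert_{j}", ds.perturbed[j]) for j in sorted(ds.perturbed)
    ]:
        for k, t in enumerate(tr.times):
            for i in range(ds.n):
                rows.append((t, cond_label, i + 1, tr.values[k, i]))
    pd.DataFrame(rows, columns=["time", "condition", "node", "value"]).to_csv(
        csv_path, index=False
    )
    if meta_path is None:
        meta_path = Path(csv_path).with_suffix(".json")
    meta = {
        "n": ds.n,
        "p": None if np.isnan(ds.p) else ds.p,
        "kind": ds.kind,
        "noise_d": ds.noise_d,
        "seed": ds.seed,
        "times": ds.times.tolist(),
        "warnings": list(ds.warnings),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def dataset_from_csv(csv_path, meta_path=None) -> PerturbationDataset:
    df = pd.read_csv(csv_path)
    if meta_path is None:
        meta_path = Path(csv_path).with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    n = int(meta["n"])
    times = np.asarray(meta["times"], dtype=float)

    def extract(cond):
        sub = df[df["condition"] == cond].pivot(index="time", columns="node", values="value")
        sub = sub.sort_index()
        return Trajectory(times=sub.index.to_numpy(), values=sub.to_numpy())

    return PerturbationDataset(
        n=n,
        times=times,
        vehicle=extract("vehicle"),
        perturbed={j: extract(f"pert_{j}") for j in range(1, n + 1)},
        p=float("nan") if meta.get("p") is None else float(meta["p"]),
        kind=meta.get("kind", "linear"),
        noise_d=float(meta.get("noise_d", 0.0)),
        seed=meta.get("seed"),
        warnings=tuple(meta.get("warnings", ())),
    )
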