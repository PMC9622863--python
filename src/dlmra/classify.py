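"""Edge-sign classification and bootstrap percentile-window calling.

Classes are encoded as integers: +1 (positive edge), −1 (negative edge),
0 (null — no direct interaction). Two callers are provided:

* :func:`classify_point` for a single estimate vector, with a
  relative-magnitude null rule (below 1/100 of the largest parameter);
* :func:`classify_window` for a bootstrap ensemble of estimates, calling a
  parameter positive/negative only when a symmetric percentile window around
  the median excludes zero, and null when the window spans zero.

:func:`roc_over_windows` sweeps the window width to trade null-detection
against sensitivity, reports the ROC over null-vs-non-null calls, and picks
the operating window at a target false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimator import EstimationResult
from .models import ACTIVATOR, FFLModelSpec, ffl_prestimulus_steady_state

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "NULL",
    "BootstrapEnsemble",
    "ClassifierWindow",
    "classify_point",
    "classify_sign",
    "classify_window",
    "accuracy",
    "roc_over_windows",
    "RocResult",
    "multistart_cv",
    "linear_param_vector",
    "linear_truth_classes",
    "ffl_param_vector",
    "ffl_truth_classes",
    "cellstate_truth_classes",
]

POSITIVE, NEGATIVE, NULL = 1, -1, 0


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Per-parameter estimate distributions across B bootstrap datasets."""

    estimates: np.ndarray  # (B, n_params)
    seeds: tuple[int, ...] = ()
    model_id: int | str | None = None

    def __post_init__(self):
        est = np.atleast_2d(np.asarray(self.estimates, dtype=float))
        object.__setattr__(self, "estimates", est)
        if self.seeds and len(self.seeds) != est.shape[0]:
            raise ValueError("one seed per bootstrap dataset expected")

    @property
    def B(self) -> int:
        return self.estimates.shape[0]


@dataclass(frozen=True)
class ClassifierWindow:
    """Symmetric percentile window about the median: (lower, upper) = (100−w, w)."""

    w: float

    def __post_init__(self):
        if not (50.0 <= self.w <= 100.0):
            raise ValueError("window width w must lie in [50, 100]")

    @property
    def lower(self) -> float:
        return 100.0 - self.w

    @property
    def upper(self) -> float:
        return self.w


def classify_sign(values) -> np.ndarray:
    """Pure sign classes (exact zeros are null) — used for ground truth and
    for benchmarks where the truth is never exactly zero."""
    return np.sign(np.asarray(values, dtype=float)).astype(int)


def classify_point(values, truth_scale: float, frac: float = 0.01) -> np.ndarray:
    """Single-estimate classes: |value| below ``frac``·``truth_scale`` is
    null, otherwise the sign of the value."""
    if truth_scale <= 0:
        raise ValueError("truth_scale must be positive")
    values = np.asarray(values, dtype=float)
    cls = np.sign(values).astype(int)
    cls[np.abs(values) < frac * truth_scale] = NULL
    return cls


def classify_window(ens: BootstrapEnsemble, win: ClassifierWindow) -> np.ndarray:
    """Percentile-window classes for each parameter of an ensemble.

    Both window percentiles positive -> positive; both negative -> negative;
    window spanning zero -> null. At w = 50 the window collapses to the
    median, so the class is the median's sign and null requires an exactly
    zero median. Percentiles use linear interpolation between order
    statistics.
    """
    lo = np.percentile(ens.estimates, win.lower, axis=0)
    hi = np.percentile(ens.estimates, win.upper, axis=0)
    cls = np.zeros(ens.estimates.shape[1], dtype=int)
    cls[lo > 0] = POSITIVE
    cls[hi < 0] = NEGATIVE
    return cls


def accuracy(pred, truth) -> float:
    """Exact-match fraction of predicted vs true classes."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size != truth.size:
        raise ValueError(f"length mismatch: {pred.size} vs {truth.size}")
    if pred.size == 0:
        raise ValueError("empty classification")
    return float(np.mean(pred == truth))


@dataclass(frozen=True)
class RocResult:
    windows: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray  # non-null truths called non-null (any sign)
    sign_tpr: np.ndarray  # non-null truths called non-null with the correct sign
    auc: float
    selected_window: float
    target_fpr: float


def roc_over_windows(
    ensembles, truths, windows=None, target_fpr: float = 0.05
) -> RocResult:
    """ROC of the window classifier over a collection of models.

    The positive event is "called non-null": TPR is the fraction of
    truly-non-null parameters called non-null (a separate correct-sign rate
    is reported alongside), FPR the fraction of truly-null parameters called
    non-null. The sweep runs from the median-only window (w = 50) to the
    full range (w = 100); AUC is the trapezoidal area with the curve anchored
    at (0, 0) and (1, 1). The selected operating window is the narrowest w
    whose FPR does not exceed ``target_fpr`` (maximizing sensitivity under
    the FPR cap).
    """
    if windows is None:
        windows = np.arange(50.0, 100.0 + 1e-9, 0.5)
    windows = np.asarray(windows, dtype=float)
    truth_all = np.concatenate([np.asarray(t).ravel() for t in truths])
    nonnull = truth_all != NULL
    if not np.any(~nonnull):
        raise ValueError("no null truths: FPR undefined")
    tpr = np.empty(windows.size)
    fpr = np.empty(windows.size)
    sign_tpr = np.empty(windows.size)
    for k, w in enumerate(windows):
        win = ClassifierWindow(w)
        pred = np.concatenate([classify_window(e, win) for e in ensembles])
        called = pred != NULL
        fpr[k] = np.mean(called[~nonnull])
        tpr[k] = np.mean(called[nonnull]) if np.any(nonnull) else np.nan
        sign_tpr[k] = (
            np.mean(called[nonnull] & (pred[nonnull] == truth_all[nonnull]))
            if np.any(nonnull)
            else np.nan
        )
    order = np.argsort(fpr, kind="stable")
    fx = np.concatenate([[0.0], fpr[order], [1.0]])
    fy = np.concatenate([[0.0], tpr[order], [1.0]])
    auc = float(np.trapezoid(fy, fx))
    ok = np.where(fpr <= target_fpr)[0]
    selected = float(windows[ok[0]]) if ok.size else float(windows[-1])
    return RocResult(
        windows=windows, fpr=fpr, tpr=tpr, sign_tpr=sign_tpr, auc=auc,
        selected_window=selected, target_fpr=target_fpr,
    )


def multistart_cv(res: EstimationResult, mode: str = "twice_min") -> np.ndarray:
    """Per-parameter coefficient of variation across qualifying starts.

    ``mode='low_sse'`` keeps starts with Φ < 1e−4; ``mode='twice_min'`` keeps
    starts with Φ < 2·Φ_min. CV = sd/|mean| (population sd). Fewer than two
    qualifying starts yields an empty array (flagged, not an error).
    """
    phis = np.array([st["phi"] for st in res.starts])
    if mode == "low_sse":
        keep = phis < 1e-4
    elif mode == "twice_min":
        keep = phis < 2.0 * phis.min()
    else:
        raise ValueError("mode must be 'low_sse' or 'twice_min'")
    thetas = np.array([st["theta"] for st in res.starts])[keep]
    if thetas.shape[0] < 2:
        return np.empty((0,))
    mean = thetas.mean(axis=0)
    sd = thetas.std(axis=0)  # population sd
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(np.abs(mean) > 0, sd / np.abs(mean), np.inf)


# ---------------------------------------------------------------------------
# Parameter vectors and ground-truth class tables per model family
# ---------------------------------------------------------------------------


def linear_param_vector(res: EstimationResult) -> np.ndarray:
    """[F row-major, S_b, S_ex] — the n² + 2n reported parameters."""
    return np.concatenate([res.F_hat.ravel(), res.S_b_hat, res.S_ex_hat])


def linear_truth_classes(net) -> np.ndarray:
    """Sign classes of a linear network's true parameters."""
    return classify_sign(np.concatenate([net.F.ravel(), net.S_b, net.S_ex]))


def ffl_param_vector(res: EstimationResult) -> np.ndarray:
    """The 12 reported gene-circuit parameters: 9 edges, S_1,ex, S_2,b, S_3,b."""
    return np.concatenate(
        [res.F_hat.ravel(), [res.S_ex_hat[0], res.S_b_hat[1], res.S_b_hat[2]]]
    )


def ffl_effective_gain_32(spec: FFLModelSpec, tol: float = 1e-6) -> float:
    """Effective linear gain of the x2→x3 channel over the stimulus response.

    Secant slope of the gate output G with respect to x2 over the span x2
    traverses after the stimulus (from its pre-stimulus steady state to its
    stimulated steady state), with the gate's x1 input held at its
    stimulated level. This is the gain a linear surrogate of the circuit
    expresses over the experiment, and is what the derived basal term S_3,b
    inherits through the steady-state identity.
    """
    from .models import _ffl_gate, hill_act, hill_rep

    x0 = ffl_prestimulus_steady_state(spec)
    x1f = 1.0  # stimulated steady state of node 1
    f2 = hill_act if spec.sign_21 == ACTIVATOR else hill_rep
    x2f = float(f2(x1f, spec.K_x1x2))
    x2_0 = x0[1]
    if abs(x2f - x2_0) > tol:
        return float((_ffl_gate(spec, x1f, x2f) - _ffl_gate(spec, x1f, x2_0)) / (x2f - x2_0))
    h = 1e-5
    return float((_ffl_gate(spec, x1f, x2_0 + h) - _ffl_gate(spec, x1f, x2_0)) / h)


def ffl_truth_classes(spec: FFLModelSpec, tol: float = 1e-3) -> np.ndarray:
    """Ground-truth classes for the 12 reported FFL parameters.

    Edges: self-regulation is negative (first-order decay), absent edges
    (F12, F13, F23) are null, and the three circuit edges carry the
    activator/repressor sign. S_1,ex is positive. The basal terms are not
    free quantities of the circuit — they are what the steady-state identity
    S_b = −F·x(0) assigns to a linear surrogate — so their classes come from
    that identity with the circuit's effective gains: S_2,b = x2(0) (node 1
    starts at zero) and S_3,b = x3(0) − g32·x2(0) with g32 the effective
    x2→x3 gain of :func:`ffl_effective_gain_32`.
    """
    q = {ACTIVATOR: 1.0}
    s21 = q.get(spec.sign_21, -1.0)
    s31 = q.get(spec.sign_31, -1.0)
    s32 = q.get(spec.sign_32, -1.0)
    x0 = ffl_prestimulus_steady_state(spec)
    F_cls = np.array([[-1, 0, 0], [s21, -1, 0], [s31, s32, -1]], dtype=float).ravel()
    s2b = x0[1]
    s3b = x0[2] - ffl_effective_gain_32(spec) * x0[1]
    vals = np.concatenate([F_cls, [1.0, s2b, s3b]])
    cls = np.sign(vals).astype(int)
    cls[np.abs(vals) < tol] = NULL
    return cls


def cellstate_truth_classes(net) -> np.ndarray:
    """Sign classes of a continuous-time cell-state rate matrix (off-diagonal
    transition rates and diagonal outflow terms)."""
    return classify_sign(net.F.ravel())
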