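"""Constrained least-squares fitting of the pulse model to an observed beat.

The fit minimises, over the six pulse parameters p = (a1, a2, b1, b2,
theta1, theta2),

    J(p) = sum_n (z_p(n) - s(n))^2 + (1 - corr(z_p, s)),

the sum of squared errors between the model pulse z_p and the observed beat
s plus a Pearson-correlation penalty, subject to the feasible region

    0 <= a2 <= a1 <= 1,    0 <= b1 < b2 <= 3,    -pi <= theta1 < theta2 <= pi.

The systolic centre precedes the diastolic centre (theta1 < theta2), and
equal amplitudes are allowed (a2 <= a1 is non-strict) so that the default
templates — which include an equal-amplitude first beat — are feasible.

The minimisation uses a gradient-based interior-point-style local method
(scipy's trust-region constrained solver) with the strict inequalities
enforced through a small separation epsilon.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize
from scipy.signal import find_peaks

from ._exceptions import DegenerateInputError, InvalidArgumentError
from .pulse_model import PulseParams, PulseSpec, pulse_waveform

__all__ = [
    "ObservedBeat",
    "FitResult",
    "objective",
    "check_constraints",
    "fit_pulse",
    "read_beat",
]

logger = logging.getLogger(__name__)

#: Separation used where the feasible set's strict inequalities (b1 < b2,
#: theta1 < theta2) must be closed for the optimizer.
SEPARATION_EPS = 1e-6

#: Fallback / auto-init anchor: regular-template mean parameters.
_REGULAR_MEANS = PulseParams(0.997, 0.225, 0.641, 0.937, -1.471, 1.019)


@dataclass(frozen=True)
class ObservedBeat:
    """A single observed PPG beat: ``l = round(duration_T * fs)`` samples."""

    samples: np.ndarray
    fs: float
    duration_T: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 4:
            raise InvalidArgumentError(
                f"beat needs >= 4 samples in one dimension, got shape {samples.shape}"
            )
        expected = int(round(self.duration_T * self.fs))
        if samples.size != expected:
            raise InvalidArgumentError(
                f"beat length {samples.size} != round(T * fs) = {expected}"
            )
        if np.ptp(samples) == 0.0:
            raise DegenerateInputError(
                "beat samples are all identical; correlation is undefined"
            )

    @property
    def spec(self) -> PulseSpec:
        return PulseSpec(duration_T=self.duration_T, fs=self.fs)


@dataclass(frozen=True)
class FitResult:
    params: PulseParams
    objective_value: float
    converged: bool
    n_iterations: int

    def to_dict(self) -> dict:
        p = self.params
        return {
            "a1": p.a1, "a2": p.a2, "b1": p.b1, "b2": p.b2,
            "theta1": p.theta1, "theta2": p.theta2,
            "objective": self.objective_value,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def check_constraints(params: PulseParams) -> list[str]:
    """Return identifiers of all violated feasibility constraints.

    An empty list means *params* is feasible.  Total function: never raises.
    """
    violations: list[str] = []
    p = params
    if not (0.0 <= p.a2 <= p.a1 <= 1.0):
        violations.append("amplitude-bound: 0 <= a2 <= a1 <= 1")
    if not (0.0 <= p.b1 < p.b2 <= 3.0):
        violations.append("width-bound: 0 <= b1 < b2 <= 3")
    if not (-np.pi <= p.theta1 < p.theta2 <= np.pi):
        violations.append("phase-bound: -pi <= theta1 < theta2 <= pi")
    return violations


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise DegenerateInputError(
            "Pearson correlation undefined for a constant sequence"
        )
    return float((xc @ yc) / denom)


def objective(params: PulseParams, beat: ObservedBeat) -> float:
    """SSE + (1 - Pearson r) between the model pulse and the observed beat.

    The model pulse is generated on exactly the beat's sampling grid.  Zero
    if and only if the model reproduces the beat sample-wise.
    """
    z = pulse_waveform(params, beat.spec)
    s = beat.samples
    sse = float(np.sum((z - s) ** 2))
    return sse + (1.0 - _pearson(z, s))


def _auto_init(beat: ObservedBeat) -> PulseParams:
    """Heuristic feasible starting point for PPG-shaped beats.

    a1 from the beat maximum, a2 = a1/2; the two Gaussian centres from the
    phases of the two largest well-separated local maxima (falling back to
    the regular-template means when fewer than two are found); b1 = 0.6,
    b2 = 1.0.
    """
    s = beat.samples
    n = s.size
    a1 = float(np.clip(s.max(), 0.05, 1.0))
    a2 = a1 / 2.0
    # peaks at least an eighth of a cycle apart
    idx, props = find_peaks(s, distance=max(1, n // 8), prominence=1e-3 * np.ptp(s))
    phase_of = lambda k: (k / n) * 2.0 * np.pi - np.pi
    if idx.size >= 2:
        top2 = idx[np.argsort(props["prominences"])[-2:]]
        th1, th2 = sorted(phase_of(k) for k in top2)
        if th2 - th1 < 0.1:  # nearly coincident: fall back
            th1, th2 = _REGULAR_MEANS.theta1, _REGULAR_MEANS.theta2
    else:
        th1, th2 = _REGULAR_MEANS.theta1, _REGULAR_MEANS.theta2
    init = PulseParams(a1, a2, 0.6, 1.0, th1, th2)
    if check_constraints(init):  # pragma: no cover - defensive fallback
        init = _REGULAR_MEANS
    return init


def _repair(p: np.ndarray) -> PulseParams:
    """Project a near-feasible solver iterate exactly into the feasible set.

    The trust-region solver honours the constraints only to within its own
    tolerance; this clamps the at-most-epsilon residual violations.
    """
    a1, a2, b1, b2, th1, th2 = (float(v) for v in p)
    a1 = min(max(a1, 0.0), 1.0)
    a2 = min(max(a2, 0.0), a1)
    b1 = min(max(b1, 0.0), 3.0 - SEPARATION_EPS)
    b2 = min(max(b2, b1 + SEPARATION_EPS), 3.0)
    th1 = min(max(th1, -np.pi), np.pi - SEPARATION_EPS)
    th2 = min(max(th2, th1 + SEPARATION_EPS), np.pi)
    return PulseParams(a1, a2, b1, b2, th1, th2)


def fit_pulse(
    beat: ObservedBeat,
    init: PulseParams | str = "auto",
    *,
    obj_tol: float = 1e-9,
    step_tol: float = 1e-9,
    max_iter: int = 500,
) -> FitResult:
    """Fit the six pulse parameters to *beat* by constrained minimisation.

    Parameters
    ----------
    beat : ObservedBeat
        The observed single beat.
    init : PulseParams or "auto"
        Feasible starting point; ``"auto"`` derives one from the beat shape.
    obj_tol, step_tol : float
        Convergence tolerances on the objective gradient and on the trust
        region / variable step.
    max_iter : int
        Iteration cap; exceeding it returns ``converged=False`` rather than
        raising.

    Returns
    -------
    FitResult
        Always feasible; ``objective_value`` never exceeds the objective at
        the starting point.
    """
    if isinstance(init, str):
        if init != "auto":
            raise InvalidArgumentError(f"init must be PulseParams or 'auto', got {init!r}")
        init = _auto_init(beat)
    violations = check_constraints(init)
    if violations:
        raise InvalidArgumentError(f"infeasible initial point: {violations}")

    # p = (a1, a2, b1, b2, th1, th2); widths floored slightly above zero so
    # the Gaussian terms stay defined throughout the search.
    bounds = Bounds(
        lb=[0.0, 0.0, SEPARATION_EPS, 2 * SEPARATION_EPS, -np.pi, -np.pi + SEPARATION_EPS],
        ub=[1.0, 1.0, 3.0 - SEPARATION_EPS, 3.0, np.pi - SEPARATION_EPS, np.pi],
    )
    # a1 - a2 >= 0, b2 - b1 >= eps, th2 - th1 >= eps
    A = np.array(
        [
            [1.0, -1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, -1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, -1.0, 1.0],
        ]
    )
    linear = LinearConstraint(A, lb=[0.0, SEPARATION_EPS, SEPARATION_EPS], ub=np.inf)

    def fun(p: np.ndarray) -> float:
        return objective(PulseParams.from_array(p), beat)

    x0 = np.clip(init.as_array(), bounds.lb, bounds.ub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # solver chatter on tiny steps
        res = minimize(
            fun,
            x0,
            method="trust-constr",
            bounds=bounds,
            constraints=[linear],
            options={
                "gtol": obj_tol,
                "xtol": step_tol,
                "maxiter": max_iter,
                "verbose": 0,
            },
        )
    p_fit = _repair(np.clip(res.x, bounds.lb, bounds.ub))
    f_fit = objective(p_fit, beat)
    f_init = objective(init, beat)
    if f_init < f_fit:  # keep monotone improvement even if the solver wandered
        p_fit, f_fit = init, f_init
    converged = bool(res.status in (1, 2)) and not check_constraints(p_fit)
    return FitResult(
        params=p_fit,
        objective_value=float(f_fit),
        converged=converged,
        n_iterations=int(res.niter),
    )


def read_beat(path: str | Path, fs: float | None = None) -> ObservedBeat:
    """Read a single beat from two-column delimited text ``(time_s, amplitude)``.

    An optional single header line is skipped.  The sampling rate is taken
    from the median time step unless *fs* is given; the beat duration is the
    half-open span ``n / fs``.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise InvalidArgumentError(
                    f"{path}:{line_no}: expected two columns, got {line!r}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if line_no == 1:  # header
                    continue
                raise InvalidArgumentError(
                    f"{path}:{line_no}: non-numeric value in {line!r}"
                ) from None
    if len(rows) < 4:
        raise InvalidArgumentError(f"{path}: need >= 4 data rows, got {len(rows)}")
    t = np.array([r[0] for r in rows])
    s = np.array([r[1] for r in rows])
    if fs is None:
        dt = float(np.median(np.diff(t)))
        if dt <= 0:
            raise InvalidArgumentError(f"{path}: time column is not increasing")
        fs = 1.0 / dt
    return ObservedBeat(samples=s, fs=fs, duration_T=s.size / fs)
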