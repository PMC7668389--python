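"""Polar two-Gaussian model of a single PPG pulse.

One heartbeat is represented as a single revolution of a point on the unit
circle in the (x, y) plane; the PPG amplitude is the z-coordinate of that
trajectory, built from two Gaussian bumps in phase angle — one for the
systolic wave, one for the diastolic wave:

    x(t) = cos(w (t - t0) - pi)
    y(t) = sin(w (t - t0) - pi)
    z(t) = sum_i a_i exp(-(theta(t) - theta_i)^2 / (2 b_i^2)),   i = 1, 2

with angular velocity w = 2 pi / T for pulse duration T, and phase
theta(t) = atan2(y, x), which equals w (t - t0) - pi wrapped to [-pi, pi).
The -pi offset places the pulse onset (the valley of the waveform) at the
start of each revolution.

This module is pure computation: it holds no state and performs no I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import InvalidArgumentError

__all__ = [
    "PulseParams",
    "PulseSpec",
    "angular_velocity",
    "phase",
    "pulse_waveform",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PulseParams:
    """The six Gaussian parameters of one beat.

    Attributes
    ----------
    a1, a2 : float
        Peak amplitudes (dimensionless) of the systolic and diastolic
        waves.  Feasible region: ``0 <= a2 <= a1 <= 1``.
    b1, b2 : float
        Gaussian widths in radians.  Feasible region: ``0 <= b1 < b2 <= 3``.
    theta1, theta2 : float
        Gaussian centres (phase of the systolic and diastolic peaks) in
        radians.  Feasible region: ``-pi <= theta1 < theta2 <= pi``.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    theta1: float
    theta2: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a1, self.a2, self.b1, self.b2, self.theta1, self.theta2]
        )

    @classmethod
    def from_array(cls, p: np.ndarray) -> "PulseParams":
        a1, a2, b1, b2, t1, t2 = (float(v) for v in p)
        return cls(a1, a2, b1, b2, t1, t2)


@dataclass(frozen=True)
class PulseSpec:
    """Sampling layout of one pulse.

    The pulse occupies the half-open interval ``[t0, t0 + duration_T)``,
    sampled at ``t0 + k / fs`` for ``k = 0 .. n-1`` with
    ``n = round(duration_T * fs)``.  The half-open grid makes consecutive
    pulses concatenate without duplicated boundary samples.
    """

    duration_T: float
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_T <= 0:
            raise InvalidArgumentError(
                f"pulse duration must be positive, got {self.duration_T}"
            )
        if self.fs <= 0:
            raise InvalidArgumentError(
                f"sampling frequency must be positive, got {self.fs}"
            )
        if self.t0 < 0:
            raise InvalidArgumentError(f"start time must be >= 0, got {self.t0}")
        if self.n_samples < 2:
            raise InvalidArgumentError(
                "pulse must contain at least 2 samples; got "
                f"round({self.duration_T} * {self.fs}) = {self.n_samples}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_T * self.fs))

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + k/fs``, ``k = 0 .. n-1``."""
        return self.t0 + np.arange(self.n_samples) / self.fs


def angular_velocity(duration_T: float) -> float:
    """Angular velocity ``w = 2 pi / T`` in rad/s for pulse duration *T* (s)."""
    if duration_T <= 0:
        raise InvalidArgumentError(
            f"pulse duration must be positive, got {duration_T}"
        )
    return TWO_PI / duration_T


def phase(t, t0: float, duration_T: float):
    """Phase angle of the circular trajectory at time(s) *t*.

    Computed analytically as ``w (t - t0) - pi`` wrapped to ``[-pi, pi)``;
    equal to ``atan2(y(t), x(t))`` everywhere except at the onset, where the
    atan2 branch returns ``+pi`` and this form returns ``-pi``.  Strictly
    increasing in *t* over one pulse.

    Parameters
    ----------
    t : float or array_like
        Time(s) inside the pulse interval ``[t0, t0 + duration_T)``.
    t0 : float
        Pulse start time (s).
    duration_T : float
        Pulse duration (s).
    """
    t = np.asarray(t, dtype=float)
    w = angular_velocity(duration_T)
    if np.any(t < t0) or np.any(t >= t0 + duration_T):
        raise InvalidArgumentError(
            f"t must lie in [{t0}, {t0 + duration_T}); got values outside"
        )
    phi = w * (t - t0) - np.pi
    # already in [-pi, pi) for in-interval t; wrap guards float round-off
    phi = np.where(phi >= np.pi, phi - TWO_PI, phi)
    return phi if phi.ndim else float(phi)


def pulse_waveform(params: PulseParams, spec: PulseSpec) -> np.ndarray:
    """Sample one pulse's z-trajectory on the spec's half-open grid.

    Returns ``n = round(duration_T * fs)`` amplitudes; every sample lies in
    ``[0, a1 + a2]``.  Gaussian terms with zero amplitude are skipped, so
    ``a1 = a2 = 0`` yields an exactly-zero pulse regardless of the widths.
    """
    phi = phase(spec.times, spec.t0, spec.duration_T)
    z = np.zeros(spec.n_samples)
    for a, b, th in (
        (params.a1, params.b1, params.theta1),
        (params.a2, params.b2, params.theta2),
    ):
        if a == 0.0:
            continue
        if b <= 0.0:
            raise InvalidArgumentError(
                f"Gaussian width must be positive when amplitude is nonzero, got b={b}"
            )
        z += a * np.exp(-((phi - th) ** 2) / (2.0 * b * b))
    return z
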