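"""Noise injection: SNR-calibrated white Gaussian noise and deterministic
multi-frequency sinusoidal interference.

SNR convention: the reference power is the AC power of the clean signal —
its mean squared deviation from its own mean.  The synthetic PPG is
strictly non-negative with a substantial DC offset, and including that
offset in the signal power would let the nominal SNR be inflated
arbitrarily by shifting the baseline.  The white-noise variance is set from
this target analytically (sigma^2 = P_ac / 10^(SNR/10)); the realised
sample SNR therefore fluctuates around the request and converges to it as
the record grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._exceptions import DegenerateInputError, InvalidArgumentError
from .assembler import PPGRecord

__all__ = [
    "NoiseSpec",
    "white_gaussian_noise",
    "multifrequency_noise",
    "add_noise",
]


@dataclass(frozen=True)
class NoiseSpec:
    """What noise to add: a white-noise SNR (dB) and/or sinusoidal
    components, each an (amplitude, frequency Hz) pair."""

    snr_db: float | None = None
    components: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "components", tuple((float(a), float(f)) for a, f in self.components)
        )
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise InvalidArgumentError(f"snr_db must be finite, got {self.snr_db}")
        for a, f in self.components:
            if a < 0:
                raise InvalidArgumentError(f"noise amplitude must be >= 0, got {a}")
            if f <= 0:
                raise InvalidArgumentError(f"noise frequency must be > 0 Hz, got {f}")

    @property
    def is_empty(self) -> bool:
        return self.snr_db is None and not self.components

    @classmethod
    def from_lists(
        cls,
        snr_db: float | None = None,
        amplitudes: list[float] | None = None,
        frequencies: list[float] | None = None,
    ) -> "NoiseSpec":
        """Build from parallel amplitude/frequency lists (the CLI surface).

        The lists must have equal lengths.
        """
        amplitudes = amplitudes or []
        frequencies = frequencies or []
        if len(amplitudes) != len(frequencies):
            raise InvalidArgumentError(
                "the number of amplitude and frequency values must be the same "
                f"(got {len(amplitudes)} amplitudes, {len(frequencies)} frequencies)"
            )
        return cls(snr_db=snr_db, components=tuple(zip(amplitudes, frequencies)))


def white_gaussian_noise(
    signal: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. zero-mean Gaussian noise scaled for the requested SNR.

    The standard deviation is ``sqrt(P_ac / 10**(snr_db / 10))`` with
    ``P_ac`` the mean squared deviation of *signal* from its mean.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(snr_db):
        raise InvalidArgumentError(f"snr_db must be finite, got {snr_db}")
    p_ac = float(np.var(signal))
    if p_ac == 0.0:
        raise DegenerateInputError(
            "signal is constant (zero AC power); SNR is undefined"
        )
    sigma = np.sqrt(p_ac / 10.0 ** (snr_db / 10.0))
    return rng.normal(0.0, sigma, signal.size)


def multifrequency_noise(
    components, fs: float, n: int
) -> np.ndarray:
    """Sum of sinusoids ``A_i sin(2 pi f_i t)`` sampled at ``t = k / fs``.

    Deterministic (seed-independent).  Frequencies at or above the Nyquist
    rate ``fs / 2`` are rejected as aliasing.
    """
    components = list(components)
    if not components:
        raise InvalidArgumentError("component list must be non-empty")
    if fs <= 0 or n <= 0:
        raise InvalidArgumentError(f"need fs > 0 and n > 0, got fs={fs}, n={n}")
    t = np.arange(n) / fs
    out = np.zeros(n)
    for a, f in components:
        if f >= fs / 2.0:
            raise InvalidArgumentError(
                f"component frequency {f} Hz >= Nyquist rate {fs / 2.0} Hz (aliasing)"
            )
        if a < 0:
            raise InvalidArgumentError(f"noise amplitude must be >= 0, got {a}")
        out += a * np.sin(2.0 * np.pi * f * t)
    return out


def add_noise(
    record: PPGRecord, spec: NoiseSpec, rng: np.random.Generator
) -> PPGRecord:
    """Return *record* with the requested noise added to its samples.

    Onsets, labels and per-beat parameters are unchanged; the record's
    provenance notes the noise specification.  An empty spec is the
    identity on the samples.
    """
    samples = record.samples.copy()
    if spec.snr_db is not None:
        samples = samples + white_gaussian_noise(record.samples, spec.snr_db, rng)
    if spec.components:
        samples = samples + multifrequency_noise(
            spec.components, record.fs, record.samples.size
        )
    meta = dict(record.meta)
    meta["noise"] = {"snr_db": spec.snr_db, "components": list(spec.components)}
    return replace(record, samples=samples, meta=meta)
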