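"""Assemble a full PPG record from a beat schedule and a morphology template.

Each scheduled beat gets its own parameter draw (by role) from the
template's Gaussian distributions, is rendered by the pulse model on its
own half-open sampling grid, and the per-beat waveforms are concatenated.
Beat durations are quantised to whole sample counts by cumulative rounding,
so the sub-sample residuals never accumulate into drift.  Because each beat
is drawn independently, the last sample of one beat generally differs from
the first sample of the next; the junctions are smoothed afterwards by
replacing a short window around each interior onset with a natural cubic
spline fitted to the flanking samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from ._exceptions import InvalidArgumentError, UnsupportedRateError
from .pulse_model import PulseParams, PulseSpec, pulse_waveform
from .rhythm import BeatSchedule
from .template_fit import check_constraints
from .templates import ParamDistribution, TemplateSet

__all__ = ["PPGRecord", "sample_params", "assemble", "spline_smooth", "MIN_FS"]

logger = logging.getLogger(__name__)

#: Lowest supported sampling rate (Hz): below this the 0.05 s spline fit
#: windows would contain fewer than two samples.
MIN_FS = 30.0

#: Resampling cap when a parameter draw keeps violating the feasible set.
MAX_DRAW_ATTEMPTS = 100


@dataclass(frozen=True)
class PPGRecord:
    """A sampled PPG waveform with beat annotations and provenance.

    Attributes
    ----------
    samples : ndarray
        Dimensionless amplitude sequence.
    fs : float
        Sampling frequency (Hz).
    onsets : ndarray of int
        Sample index of each beat's first sample; strictly increasing,
        starting at 0.
    beat_labels : tuple of (role, group_type)
        One entry per beat, aligned with ``onsets``.
    beat_params : tuple of PulseParams
        The per-beat parameter draws actually used (provenance).
    meta : dict
        Configuration, seed and processing history.
    """

    samples: np.ndarray
    fs: float
    onsets: np.ndarray
    beat_labels: tuple[tuple[str, str | None], ...]
    beat_params: tuple[PulseParams, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        onsets = np.asarray(self.onsets, dtype=int)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "beat_labels", tuple(self.beat_labels))
        object.__setattr__(self, "beat_params", tuple(self.beat_params))
        if onsets.size:
            if onsets[0] != 0:
                raise InvalidArgumentError("first onset must be sample 0")
            if np.any(np.diff(onsets) <= 0):
                raise InvalidArgumentError("onsets must be strictly increasing")
        if len(self.beat_labels) != onsets.size:
            raise InvalidArgumentError("one label per onset required")

    @property
    def n_beats(self) -> int:
        return int(self.onsets.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def sample_params(
    template: TemplateSet, role: str, rng: np.random.Generator
) -> PulseParams:
    """Draw one feasible parameter set for *role* from the template.

    Each of the six parameters is an independent Gaussian draw; draws
    violating the feasible region are rejected and redrawn (up to 100
    attempts, after which the means are returned with a warning — the
    default templates reject only a tiny fraction of draws).
    """
    try:
        dist: ParamDistribution = template.roles[role]
    except KeyError:
        raise InvalidArgumentError(
            f"template {template.name!r} has no role {role!r}"
        ) from None
    means = np.asarray(dist.means)
    sds = np.asarray(dist.sds)
    mean_params = PulseParams.from_array(means)
    if check_constraints(mean_params):
        raise InvalidArgumentError(
            f"template {template.name!r} role {role!r} means are infeasible: "
            f"{check_constraints(mean_params)}"
        )
    for _ in range(MAX_DRAW_ATTEMPTS):
        draw = PulseParams.from_array(rng.normal(means, sds))
        if not check_constraints(draw):
            return draw
    logger.warning(
        "no feasible draw for template %r role %r after %d attempts; using means",
        template.name, role, MAX_DRAW_ATTEMPTS,
    )
    return mean_params


def assemble(
    schedule: BeatSchedule,
    template: TemplateSet,
    fs: float,
    rng: np.random.Generator,
    length_s: float | None = None,
) -> PPGRecord:
    """Render the scheduled beats into one concatenated record.

    Beat boundaries are placed by rounding the cumulative schedule time to
    the sample grid, so each beat's sample count is its exact share of the
    record without drift.  If *length_s* is given the record is truncated
    to ``round(length_s * fs)`` samples and trailing beats that start at or
    beyond the cut are dropped.
    """
    if fs < MIN_FS:
        raise UnsupportedRateError(
            f"sampling rates below {MIN_FS:g} Hz are unsupported, got {fs}"
        )
    if len(schedule) == 0:
        raise InvalidArgumentError("empty schedule")
    cum_ms = np.concatenate([[0.0], np.cumsum(schedule.durations_ms)])
    boundaries = np.round(cum_ms * fs / 1000.0).astype(int)

    pieces: list[np.ndarray] = []
    onsets: list[int] = []
    labels: list[tuple[str, str | None]] = []
    params_used: list[PulseParams] = []
    for k, beat in enumerate(schedule):
        n = int(boundaries[k + 1] - boundaries[k])
        if n < 2:
            raise InvalidArgumentError(
                f"beat {k} spans {n} samples at fs={fs}; increase fs or duration"
            )
        p = sample_params(template, beat.role, rng)
        z = pulse_waveform(p, PulseSpec(duration_T=n / fs, fs=fs))
        onsets.append(int(boundaries[k]))
        labels.append((beat.role, beat.group_type))
        params_used.append(p)
        pieces.append(z)
    samples = np.concatenate(pieces)

    if length_s is not None:
        n_keep = int(round(length_s * fs))
        samples = samples[:n_keep]
        keep = [i for i, o in enumerate(onsets) if o < n_keep]
        onsets = [onsets[i] for i in keep]
        labels = [labels[i] for i in keep]
        params_used = [params_used[i] for i in keep]

    return PPGRecord(
        samples=samples,
        fs=fs,
        onsets=np.array(onsets, dtype=int),
        beat_labels=tuple(labels),
        beat_params=tuple(params_used),
        meta={"template": template.name, "fs": fs, "smoothed": False},
    )


def spline_smooth(record: PPGRecord) -> PPGRecord:
    """Smooth beat junctions with natural cubic splines.

    Around every interior onset, a window of ``round(0.1 * fs)`` samples
    centred on the onset is replaced by a natural cubic spline fitted
    through the ``round(0.05 * fs)`` samples immediately before and after
    that window.  The first onset (record start) is untouched; an onset
    whose windows would run past the record ends or into a neighbouring
    onset's window is skipped with a warning.  All samples outside the
    replaced windows are bit-identical to the input.
    """
    fs = record.fs
    n_fit = int(round(0.05 * fs))  # flank samples on each side
    n_mid = int(round(0.1 * fs))  # replaced samples
    if n_fit < 2:
        raise UnsupportedRateError(
            f"spline smoothing needs >= 2 fit samples per flank; fs={fs} gives {n_fit}"
        )
    samples = record.samples.copy()
    n = samples.size
    half = n_mid // 2
    prev_end = -1  # last index touched by the previous onset's windows
    for onset in record.onsets[1:]:
        mid_lo = onset - half  # replaced: [mid_lo, mid_lo + n_mid)
        fit_lo = mid_lo - n_fit
        fit_hi = mid_lo + n_mid + n_fit  # exclusive
        if fit_lo <= prev_end or fit_lo < 0 or fit_hi > n:
            logger.warning(
                "skipping junction smoothing at onset %d: window [%d, %d) "
                "overlaps the record end or a neighbouring window",
                onset, fit_lo, fit_hi,
            )
            continue
        x_fit = np.concatenate(
            [np.arange(fit_lo, mid_lo), np.arange(mid_lo + n_mid, fit_hi)]
        )
        spline = CubicSpline(x_fit, samples[x_fit], bc_type="natural")
        x_mid = np.arange(mid_lo, mid_lo + n_mid)
        samples[x_mid] = spline(x_mid)
        prev_end = fit_hi - 1
    meta = dict(record.meta)
    meta["smoothed"] = True
    return replace(record, samples=samples, meta=meta)
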