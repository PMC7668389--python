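"""Beat-duration scheduling: regular rhythms and premature-group insertion.

A premature atrial contraction perturbs two consecutive beats — the
"premature group": a shortened *first* beat of duration d1 followed by a
*second* beat of duration d2, embedded among *reference* beats of duration
d0.  The supported group classes are distinguished by the combined duration:

    compensation:   d1 + d2 = 2 d0   (the pause fully compensates)
    reset:          d0 < d1 + d2 < 2 d0
    interpolation:  d1 + d2 = d0     (the pair fits in one reference beat)

Re-entry (d1 + d2 < d0) is recognised by the classifier but cannot be
generated: no morphology template exists for it.

Reference beat durations are drawn i.i.d. from a Gaussian around the mean
RR interval (60000 / heart-rate ms), truncated at three standard deviations
and floored at 250 ms to exclude non-physiological values.  Premature
groups replace pairs of reference beats at uniformly random, non-adjacent
positions; their durations are fixed multiples (r1, r2) of the local
reference duration, so the group class of the synthetic record is exact by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._exceptions import InvalidArgumentError, ValidationError

__all__ = [
    "Beat",
    "BeatSchedule",
    "RhythmConfig",
    "GROUP_TYPES",
    "regular_schedule",
    "insert_premature_groups",
    "classify_group",
    "implied_second_duration",
    "validate_config",
]

GROUP_TYPES = ("compensation", "reset", "interpolation")

#: Hard floor on any beat duration (ms); 250 ms corresponds to 240 bpm.
MIN_BEAT_MS = 250.0

#: Inclusive heart-rate limits (bpm).
HR_MIN, HR_MAX = 50.0, 180.0


@dataclass(frozen=True)
class Beat:
    duration_ms: float
    role: str = "reference"  # reference | first | second
    group_type: str | None = None  # None | compensation | reset | interpolation

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise InvalidArgumentError(f"beat duration must be > 0, got {self.duration_ms}")
        if self.role not in ("reference", "first", "second"):
            raise InvalidArgumentError(f"unknown beat role {self.role!r}")
        if self.group_type is not None and self.group_type not in GROUP_TYPES:
            raise InvalidArgumentError(f"unknown group type {self.group_type!r}")


@dataclass(frozen=True)
class BeatSchedule:
    """Ordered beat durations with role and premature-group labels."""

    beats: tuple[Beat, ...]

    def __post_init__(self) -> None:
        beats = tuple(self.beats)
        object.__setattr__(self, "beats", beats)
        for i, b in enumerate(beats):
            if b.role == "first":
                if i + 1 >= len(beats) or beats[i + 1].role != "second" or beats[
                    i + 1
                ].group_type != b.group_type:
                    raise InvalidArgumentError(
                        f"first beat at index {i} is not followed by its second beat"
                    )
            if b.role == "second":
                if i == 0 or beats[i - 1].role != "first":
                    raise InvalidArgumentError(
                        f"second beat at index {i} is not preceded by a first beat"
                    )

    def __len__(self) -> int:
        return len(self.beats)

    def __iter__(self):
        return iter(self.beats)

    @property
    def durations_ms(self) -> np.ndarray:
        return np.array([b.duration_ms for b in self.beats])

    @property
    def total_ms(self) -> float:
        return float(self.durations_ms.sum())

    @property
    def n_groups(self) -> int:
        return sum(1 for b in self.beats if b.role == "first")

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            [
                {"duration_ms": b.duration_ms, "role": b.role, "group_type": b.group_type}
                for b in self.beats
            ],
            **kwargs,
        )

    @classmethod
    def from_json(cls, text: str) -> "BeatSchedule":
        return cls(
            tuple(
                Beat(d["duration_ms"], d["role"], d["group_type"])
                for d in json.loads(text)
            )
        )


@dataclass(frozen=True)
class RhythmConfig:
    """User-facing rhythm settings.

    ``rr_sd`` applies to regular records only; ``irregular_times`` (the
    number of premature groups) to irregular ones.  ``duration_ratios``
    default to the template's fixed (r1, r2) when None.
    """

    signal_type: str = "regular"
    mean_hr: float = 60.0
    rr_sd: float = 0.0
    irregular_times: int = 0
    length: float = 10.0
    duration_ratios: tuple[float, float] | None = None


def regular_schedule(
    mean_hr: float,
    rr_sd: float,
    length: float,
    rng: np.random.Generator,
) -> BeatSchedule:
    """Draw reference beats until they cover *length* seconds.

    Durations are i.i.d. Normal(60000/mean_hr, rr_sd) ms, truncated to
    mean +/- 3 sd and floored at 250 ms.  The final record is trimmed to the
    exact length at assembly, not here.
    """
    if not (HR_MIN <= mean_hr <= HR_MAX):
        raise ValidationError(
            f"mean heart rate must be in [{HR_MIN:g}, {HR_MAX:g}] bpm, got {mean_hr}"
        )
    if rr_sd < 0:
        raise ValidationError(f"RR standard deviation must be >= 0, got {rr_sd}")
    if length <= 0:
        raise ValidationError(f"signal length must be > 0, got {length}")
    mean_ms = 60000.0 / mean_hr
    target_ms = length * 1000.0
    durations: list[float] = []
    total = 0.0
    while total < target_ms:
        d = float(rng.normal(mean_ms, rr_sd)) if rr_sd > 0 else mean_ms
        d = float(np.clip(d, mean_ms - 3 * rr_sd, mean_ms + 3 * rr_sd))
        d = max(d, MIN_BEAT_MS)
        durations.append(d)
        total += d
    return BeatSchedule(tuple(Beat(d) for d in durations))


def _eligible_positions(beats: list[Beat], used: set[int]) -> list[int]:
    """Indices i where beats i, i+1 are replaceable reference beats.

    Groups must keep >= 1 reference beat between each other and at both
    record ends; ``used`` holds indices already consumed by placed groups.
    """
    n = len(beats)
    blocked = set()
    for j in used:
        blocked.update(range(j - 2, j + 3))  # group at j occupies j, j+1 + 1-beat gap
    out = []
    for i in range(1, n - 2):
        if i in blocked or (i + 1) in blocked:
            continue
        if beats[i].role == "reference" and beats[i + 1].role == "reference":
            out.append(i)
    return out


def insert_premature_groups(
    schedule: BeatSchedule,
    group_type: str,
    ratios: tuple[float, float],
    count: int,
    rng: np.random.Generator,
) -> BeatSchedule:
    """Replace *count* reference-beat pairs with premature groups.

    Each group replaces two consecutive reference beats at a uniformly
    random eligible position; the group durations are d1 = r1 * d0 and
    d2 = r2 * d0, with d0 the duration of the first replaced reference
    beat.  Groups are never adjacent (>= 1 reference beat separates them
    and bounds the record at both ends).  Group types whose ratios sum to
    less than 2 shorten the record; reference beats drawn from the existing
    reference durations are appended to restore the scheduled length.
    """
    if group_type not in GROUP_TYPES:
        raise InvalidArgumentError(f"unknown group type {group_type!r}")
    r1, r2 = ratios
    if r1 <= 0 or r2 <= 0:
        raise InvalidArgumentError(f"duration ratios must be positive, got {ratios}")
    if count < 0:
        raise ValidationError(f"group count must be >= 0, got {count}")
    if count == 0:
        return schedule

    beats = list(schedule.beats)
    original_total = schedule.total_ms
    used: set[int] = set()
    placed: list[int] = []
    for _ in range(count):
        eligible = _eligible_positions(beats, used)
        if not eligible:
            raise ValidationError(
                f"cannot place {count} premature groups in a schedule of "
                f"{len(beats)} beats; decrease the count or lengthen the record"
            )
        i = int(rng.choice(eligible))
        used.add(i)
        placed.append(i)
    for i in placed:
        d0 = beats[i].duration_ms
        beats[i] = Beat(r1 * d0, role="first", group_type=group_type)
        beats[i + 1] = Beat(r2 * d0, role="second", group_type=group_type)

    # restore the covered length when the group shortened the record
    ref_durations = [b.duration_ms for b in beats if b.role == "reference"]
    total = sum(b.duration_ms for b in beats)
    while total < original_total:
        d = float(rng.choice(ref_durations))
        beats.append(Beat(d))
        total += d
    return BeatSchedule(tuple(beats))


def classify_group(
    d0: float, d1: float, d2: float, tol: float = 0.02
) -> str:
    """Classify the beat pair (d1, d2) against reference duration d0.

    Returns one of ``"regular"``, ``"compensation"``, ``"reset"``,
    ``"interpolation"`` or ``"re-entry (unsupported)"``; *tol* is the
    relative tolerance band (fraction of d0) for the equality-based classes.
    """
    if min(d0, d1, d2) <= 0:
        raise InvalidArgumentError("all durations must be > 0")
    band = tol * d0
    if abs(d1 - d0) <= band and abs(d2 - d0) <= band:
        return "regular"
    s = d1 + d2
    if abs(s - 2 * d0) <= band:
        return "compensation"
    if abs(s - d0) <= band:
        return "interpolation"
    if s < d0:
        return "re-entry (unsupported)"
    if s < 2 * d0:
        return "reset"
    # s beyond the compensation band on the long side: nearest class
    return "compensation"


def implied_second_duration(group_type: str, d0: float, d1: float) -> float:
    """Second-beat duration implied by the group-class identity.

    compensation: d2 = 2 d0 - d1; interpolation: d2 = d0 - d1.  Reset is
    under-determined (the identity is an inequality) and raises.
    """
    if group_type == "reset":
        raise InvalidArgumentError(
            "reset groups satisfy only d0 < d1 + d2 < 2*d0; d2 is under-determined"
        )
    if group_type not in ("compensation", "interpolation"):
        raise InvalidArgumentError(f"unknown group type {group_type!r}")
    if not (0 < d1 <= d0):
        raise InvalidArgumentError(
            f"first-beat duration must satisfy 0 < d1 <= d0, got d1={d1}, d0={d0}"
        )
    if group_type == "compensation":
        return 2 * d0 - d1
    return d0 - d1


def validate_config(config: RhythmConfig) -> list[str]:
    """Validate a rhythm configuration; returns human-readable messages
    (empty list = valid)."""
    messages: list[str] = []
    if not (HR_MIN <= config.mean_hr <= HR_MAX):
        messages.append(
            f"heart rate {config.mean_hr} bpm outside the supported range "
            f"[{HR_MIN:g}, {HR_MAX:g}]"
        )
    if config.length <= 0:
        messages.append(f"signal length must be > 0 s, got {config.length}")
    if config.rr_sd < 0:
        messages.append(f"RR standard deviation must be >= 0 ms, got {config.rr_sd}")
    if config.signal_type not in ("regular",) + GROUP_TYPES:
        messages.append(f"unknown signal type {config.signal_type!r}")
    if config.signal_type in GROUP_TYPES:
        if config.irregular_times < 0:
            messages.append("irregular times must be >= 0")
        elif config.irregular_times == 0:
            messages.append(
                "irregular signal type selected but irregular times is 0; "
                "the record will contain no premature groups"
            )
        elif config.mean_hr > 0 and config.length > 0:
            expected_beats = config.length * config.mean_hr / 60.0
            needed = 3 * config.irregular_times + 1  # 2 slots + 1 separator per group
            if needed > expected_beats:
                messages.append(
                    f"irregular times {config.irregular_times} too large for a "
                    f"{config.length:g} s record at {config.mean_hr:g} bpm "
                    f"(needs >= {needed} beats, ~{expected_beats:.0f} expected); "
                    "decrease irregular times or increase the length"
                )
    return messages
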