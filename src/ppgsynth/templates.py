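"""Morphology templates: per-role parameter distributions and duration ratios.

Each template carries, for every beat role it uses (reference, first,
second), the mean and standard deviation of the six pulse parameters.
Per-beat parameters are drawn independently from these Gaussians so the
waveform varies from beat to beat the way real PPG does.  The duration
ratios (r1, r2) of the premature group relative to the local reference beat
are fixed scalars — randomising them could silently change the group class.

The default numbers were estimated from real recordings (a regular
fingertip PPG trace for the reference morphology; a handful of compensation,
reset and interpolation premature groups for the irregular morphologies)
by fitting the two-Gaussian pulse model beat by beat.  The reference beats
of every irregular template reuse the regular-template distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from ._exceptions import InvalidArgumentError

__all__ = ["ParamDistribution", "TemplateSet", "DEFAULT_TEMPLATES", "get_template"]

PARAM_NAMES = ("a1", "a2", "b1", "b2", "theta1", "theta2")


@dataclass(frozen=True)
class ParamDistribution:
    """Independent Gaussian (mean, sd) per pulse parameter, in model order
    (a1, a2, b1, b2, theta1, theta2)."""

    means: tuple[float, float, float, float, float, float]
    sds: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.means) != 6 or len(self.sds) != 6:
            raise InvalidArgumentError("parameter distribution needs 6 (mean, sd) pairs")
        if any(sd < 0 for sd in self.sds):
            raise InvalidArgumentError(f"standard deviations must be >= 0: {self.sds}")


@dataclass(frozen=True)
class TemplateSet:
    """Per-role parameter distributions plus fixed duration ratios."""

    name: str  # regular | compensation | reset | interpolation
    roles: Mapping[str, ParamDistribution]
    duration_ratios: tuple[float, float] | None = None  # (r1, r2); None for regular

    def __post_init__(self) -> None:
        object.__setattr__(self, "roles", MappingProxyType(dict(self.roles)))
        if "reference" not in self.roles:
            raise InvalidArgumentError("template must define the reference role")
        if self.name != "regular":
            missing = {"first", "second"} - set(self.roles)
            if missing:
                raise InvalidArgumentError(
                    f"irregular template {self.name!r} lacks roles {sorted(missing)}"
                )
            if self.duration_ratios is None:
                raise InvalidArgumentError(
                    f"irregular template {self.name!r} needs duration ratios"
                )


_REGULAR = ParamDistribution(
    means=(0.997, 0.225, 0.641, 0.937, -1.471, 1.019),
    sds=(0.028, 0.030, 0.034, 0.161, 0.147, 0.102),
)

DEFAULT_TEMPLATES: Mapping[str, TemplateSet] = MappingProxyType(
    {
        "regular": TemplateSet(name="regular", roles={"reference": _REGULAR}),
        "compensation": TemplateSet(
            name="compensation",
            roles={
                "reference": _REGULAR,
                "first": ParamDistribution(
                    means=(0.829, 0.420, 0.732, 1.219, -1.008, 0.450),
                    sds=(0.010, 0.018, 0.033, 0.021, 0.147, 0.167),
                ),
                "second": ParamDistribution(
                    means=(0.785, 0.405, 0.678, 1.115, -1.792, -0.607),
                    sds=(0.034, 0.049, 0.036, 0.065, 0.080, 0.107),
                ),
            },
            duration_ratios=(0.830, 1.170),
        ),
        "reset": TemplateSet(
            name="reset",
            roles={
                "reference": _REGULAR,
                "first": ParamDistribution(
                    means=(0.774, 0.774, 0.647, 1.007, -1.378, 0.173),
                    sds=(0.012, 0.012, 0.041, 0.046, 0.180, 0.180),
                ),
                "second": ParamDistribution(
                    means=(0.995, 0.197, 0.778, 1.045, -1.809, 0.892),
                    sds=(0.002, 0.024, 0.055, 0.341, 0.203, 0.325),
                ),
            },
            duration_ratios=(0.607, 0.596),
        ),
        "interpolation": TemplateSet(
            name="interpolation",
            roles={
                "reference": _REGULAR,
                "first": ParamDistribution(
                    means=(0.668, 0.490, 0.893, 1.428, -0.627, 0.442),
                    sds=(0.151, 0.006, 0.034, 0.062, 0.292, 0.635),
                ),
                "second": ParamDistribution(
                    means=(0.595, 0.537, 0.889, 1.321, -1.049, -0.289),
                    sds=(0.084, 0.092, 0.170, 0.289, 0.207, 0.480),
                ),
            },
            duration_ratios=(0.561, 0.475),
        ),
    }
)


def get_template(name: str) -> TemplateSet:
    """Look up a built-in template by signal type name."""
    try:
        return DEFAULT_TEMPLATES[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown template {name!r}; available: {sorted(DEFAULT_TEMPLATES)}"
        ) from None
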