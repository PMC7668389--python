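"""Configuration, record serialization and the end-to-end synthesis driver.

A record is stored as a pair of files: a CSV waveform
(``time_s,ppg`` header, one row per sample) plus a JSON sidecar
``<stem>.annotations.json`` holding the beat onsets, beat labels, and the
full configuration and seed.  The sidecar alone suffices to regenerate the
record, making every saved pair self-describing.  Floats are written as
their shortest round-trip decimal representation, so identical
(config, seed) pairs produce byte-identical files and reading a pair back
reproduces the samples exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._exceptions import InvalidArgumentError, ValidationError
from .assembler import MIN_FS, PPGRecord, assemble, spline_smooth
from .noise import NoiseSpec, add_noise
from .rhythm import (
    GROUP_TYPES,
    RhythmConfig,
    insert_premature_groups,
    regular_schedule,
    validate_config,
)
from .templates import get_template

__all__ = [
    "SynthesisConfig",
    "run_synthesis",
    "write_record",
    "read_record",
    "validate_synthesis_config",
    "SIDECAR_SCHEMA_PATH",
    "validate_sidecar",
]

logger = logging.getLogger(__name__)

SIDECAR_SCHEMA_PATH = Path(__file__).parent / "annotations.schema.json"


@dataclass(frozen=True)
class SynthesisConfig:
    """Everything needed to synthesize one record reproducibly."""

    signal_type: str = "regular"
    fs: float = 125.0
    length: float = 10.0
    mean_hr: float = 60.0
    rr_sd: float = 50.0
    irregular_times: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    duration_ratios: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"] = {
            "snr_db": self.noise.snr_db,
            "components": [list(c) for c in self.noise.components],
        }
        if self.duration_ratios is not None:
            d["duration_ratios"] = list(self.duration_ratios)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthesisConfig":
        d = dict(d)
        noise = d.get("noise") or {}
        if not isinstance(noise, NoiseSpec):
            noise = NoiseSpec(
                snr_db=noise.get("snr_db"),
                components=tuple(tuple(c) for c in noise.get("components", [])),
            )
        d["noise"] = noise
        if d.get("duration_ratios") is not None:
            d["duration_ratios"] = tuple(d["duration_ratios"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d)

    def rhythm_config(self) -> RhythmConfig:
        return RhythmConfig(
            signal_type=self.signal_type,
            mean_hr=self.mean_hr,
            rr_sd=self.rr_sd,
            irregular_times=self.irregular_times,
            length=self.length,
            duration_ratios=self.duration_ratios,
        )


def validate_synthesis_config(config: SynthesisConfig) -> tuple[list[str], list[str]]:
    """Split validation findings into hard errors and advisory warnings."""
    messages = validate_config(config.rhythm_config())
    warnings = [m for m in messages if "irregular times is 0" in m]
    errors = [m for m in messages if m not in warnings]
    if config.fs < MIN_FS:
        errors.append(f"sampling frequency must be >= {MIN_FS:g} Hz, got {config.fs}")
    if config.noise.components:
        bad = [f for _, f in config.noise.components if f >= config.fs / 2.0]
        if bad:
            errors.append(
                f"noise frequencies {bad} Hz at or above the Nyquist rate "
                f"{config.fs / 2.0:g} Hz"
            )
    return errors, warnings


def run_synthesis(
    config: SynthesisConfig,
    out: str | Path | None = None,
    fmt: str = "csv",
) -> PPGRecord:
    """Schedule, assemble, smooth and add noise; optionally write the files.

    A single seeded random stream is threaded through scheduling, parameter
    sampling and noise generation in that fixed order, so results are
    bit-reproducible for a given (config, seed).
    """
    errors, warnings_ = validate_synthesis_config(config)
    if errors:
        raise ValidationError("; ".join(errors))
    for msg in warnings_:
        logger.warning("%s", msg)

    rng = np.random.default_rng(config.seed)
    # RR variability applies to regular records only; irregular records use
    # a fixed reference duration from the basic heart rate so the premature
    # groups' duration ratios stay exact.
    rr_sd = config.rr_sd if config.signal_type == "regular" else 0.0
    schedule = regular_schedule(config.mean_hr, rr_sd, config.length, rng)
    template = get_template(config.signal_type)
    if config.signal_type in GROUP_TYPES and config.irregular_times > 0:
        ratios = config.duration_ratios or template.duration_ratios
        schedule = insert_premature_groups(
            schedule, config.signal_type, ratios, config.irregular_times, rng
        )
    record = assemble(schedule, template, config.fs, rng, length_s=config.length)
    record = spline_smooth(record)
    if not config.noise.is_empty:
        record = add_noise(record, config.noise, rng)
    meta = dict(record.meta)
    meta["config"] = config.to_dict()
    meta["seed"] = config.seed
    record = dataclasses.replace(record, meta=meta)

    logger.info(
        "synthesized %s record: %d samples at %g Hz, %d beats, %d premature groups, seed=%d",
        config.signal_type, record.samples.size, config.fs, record.n_beats,
        sum(1 for r, _ in record.beat_labels if r == "first"), config.seed,
    )
    if out is not None:
        write_record(record, out, fmt=fmt)
    return record


def _fmt(v: float) -> str:
    """Shortest decimal that round-trips to the same float."""
    return repr(float(v))


def _sidecar_dict(record: PPGRecord) -> dict:
    return {
        "format_version": 1,
        "generator": f"ppgsynth {__version__}",
        "fs": record.fs,
        "n_samples": int(record.samples.size),
        "onsets": [int(o) for o in record.onsets],
        "beat_labels": [
            {"role": role, "group_type": gt} for role, gt in record.beat_labels
        ],
        "config": record.meta.get("config"),
        "seed": record.meta.get("seed"),
    }


def write_record(record: PPGRecord, path: str | Path, fmt: str = "csv") -> Path:
    """Write the waveform file and its JSON annotation sidecar.

    ``fmt="csv"`` (canonical): UTF-8, LF line endings, header
    ``time_s,ppg``.  ``fmt="xlsx"`` additionally requires openpyxl.
    Returns the waveform path; the sidecar lands at
    ``<stem>.annotations.json`` next to it.
    """
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        if fmt == "csv":
            lines = ["time_s,ppg"]
            fs = record.fs
            for k, v in enumerate(record.samples):
                lines.append(f"{_fmt(k / fs)},{_fmt(v)}")
            path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        elif fmt == "xlsx":
            _write_xlsx(record, path)
        else:
            raise InvalidArgumentError(f"unknown format {fmt!r}; use 'csv' or 'xlsx'")
        sidecar = path.with_suffix("").with_suffix(".annotations.json")
        sidecar.write_text(
            json.dumps(_sidecar_dict(record), indent=1) + "\n",
            encoding="utf-8",
            newline="\n",
        )
    except OSError as exc:
        raise OSError(f"cannot write record to {path}: {exc}") from exc
    return path


def _write_xlsx(record: PPGRecord, path: Path) -> None:
    try:
        from openpyxl import Workbook
    except ImportError as exc:  # pragma: no cover
        raise InvalidArgumentError(
            "xlsx export requires the optional openpyxl dependency"
        ) from exc
    wb = Workbook()
    ws = wb.active
    ws.title = "ppg"
    ws.append(["time_s", "ppg"])
    for k, v in enumerate(record.samples):
        ws.append([k / record.fs, float(v)])
    wb.save(path)


def read_record(path: str | Path) -> PPGRecord:
    """Read a CSV + sidecar pair back into a record.

    The inverse of :func:`write_record` for CSV output.  A missing sidecar
    yields a record with empty annotations and a warning; a malformed CSV
    cell raises with its line number.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != "time_s,ppg":
            raise InvalidArgumentError(
                f"{path}:1: expected header 'time_s,ppg', got {header!r}"
            )
        for line_no, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise InvalidArgumentError(
                    f"{path}:{line_no}: expected 2 comma-separated values, got {line!r}"
                )
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise InvalidArgumentError(
                    f"{path}:{line_no}: non-numeric cell in {line!r}"
                ) from None
    if len(values) < 2:
        raise InvalidArgumentError(f"{path}: fewer than 2 samples")

    sidecar_path = path.with_suffix("").with_suffix(".annotations.json")
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text(encoding="utf-8"))
        validate_sidecar(side)
        fs = float(side["fs"])
        onsets = np.array(side["onsets"], dtype=int)
        labels = tuple(
            (d["role"], d["group_type"]) for d in side["beat_labels"]
        )
        meta = {"config": side.get("config"), "seed": side.get("seed")}
    else:
        logger.warning("no annotation sidecar found at %s; annotations empty", sidecar_path)
        dt = float(np.median(np.diff(times)))
        fs = 1.0 / dt
        onsets = np.array([], dtype=int)
        labels = ()
        meta = {}
    return PPGRecord(
        samples=np.array(values),
        fs=fs,
        onsets=onsets,
        beat_labels=labels,
        meta=meta,
    )


def validate_sidecar(side: dict) -> None:
    """Structural validation of an annotation sidecar against the shipped
    schema contract (see ``annotations.schema.json``)."""
    required = {"format_version", "fs", "n_samples", "onsets", "beat_labels"}
    missing = required - set(side)
    if missing:
        raise ValidationError(f"sidecar missing required keys: {sorted(missing)}")
    if not isinstance(side["onsets"], list) or not all(
        isinstance(o, int) and o >= 0 for o in side["onsets"]
    ):
        raise ValidationError("sidecar 'onsets' must be a list of non-negative integers")
    labels = side["beat_labels"]
    if not isinstance(labels, list) or len(labels) != len(side["onsets"]):
        raise ValidationError("sidecar 'beat_labels' must parallel 'onsets'")
    for d in labels:
        if not isinstance(d, dict) or d.get("role") not in ("reference", "first", "second"):
            raise ValidationError(f"bad beat label entry: {d!r}")
        if d.get("group_type") not in (None, *GROUP_TYPES):
            raise ValidationError(f"bad group type in label: {d!r}")
    if not (isinstance(side["fs"], (int, float)) and side["fs"] > 0):
        raise ValidationError("sidecar 'fs' must be a positive number")
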