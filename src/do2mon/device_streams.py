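"""Read and write the two bedside-monitor line-stream dialects.

Two devices feed the DO2 pipeline over captured serial text:

* **MSPC** (pulse co-oximeter): one line per second, a leading ``HH:MM:SS``
  wall-clock timestamp followed by ``label=value`` tokens.  SpO2 is printed
  as a percent and SpHb in g/dL.
* **ECS** (pulse-wave-analysis cardiac-output monitor): one line every two
  seconds of unlabeled, whitespace-separated numeric tokens with no
  timestamp; cardiac output sits at a fixed, configurable position.

The true vendor formats are proprietary; this module defines a documented
stand-in dialect that preserves the two parsing strategies the pipeline
relies on — label-based extraction for the MSPC and positional extraction
for the ECS.  Malformed lines are never fatal: serial capture is lossy, so
bad lines are skipped, counted and logged.  A persistently unparseable CO
token is exactly how an undetectable CO signal manifests downstream.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "RawLine",
    "DeviceSample",
    "DialectConfig",
    "ParseError",
    "StreamFormatError",
    "parse_mspc_line",
    "parse_ecs_line",
    "read_stream",
    "write_stream",
]

#: printed precision of numeric values in both dialects (decimal places)
DIALECT_DECIMALS = 2

_TIMESTAMP_RE = re.compile(r"^(\d{1,2}):(\d{2}):(\d{2})$")


class Source(str, enum.Enum):
    """Which device emitted a line."""

    MSPC = "MSPC"
    ECS = "ECS"


class ParseError(ValueError):
    """A single line could not be parsed (recoverable: skip and count)."""


class StreamFormatError(ValueError):
    """The stream as a whole violates the dialect contract (fatal)."""


@dataclass(frozen=True)
class RawLine:
    """One captured line of device output.

    ``arrival_index`` is the 0-based position of the line within its own
    stream; for the timestampless ECS dialect it determines the sample time.
    """

    source: Source
    text: str
    arrival_index: int

    def __post_init__(self) -> None:
        if self.arrival_index < 0:
            raise ValueError("arrival_index must be non-negative")
        if "\n" in self.text or "\r" in self.text:
            raise ValueError("RawLine.text must not contain line terminators")


@dataclass(frozen=True)
class DeviceSample:
    """One parsed reading: source, seconds from session start, parameter map.

    MSPC samples carry ``SpO2`` (fraction in [0, 1]) and ``SpHb`` (g/dL);
    ECS samples carry ``CO`` (L/min) only.
    """

    source: Source
    timestamp: float
    params: dict

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")
        if self.source is Source.ECS:
            if set(self.params) != {"CO"}:
                raise ValueError("ECS samples carry CO and nothing else")
            if self.params["CO"] < 0:
                raise ValueError("CO must be non-negative")
        else:
            if "CO" in self.params:
                raise ValueError("MSPC samples never carry CO")
            spo2 = self.params.get("SpO2")
            if spo2 is not None and not (0.0 <= spo2 <= 1.0):
                raise ValueError("SpO2 must be a fraction in [0, 1]")
            sphb = self.params.get("SpHb")
            if sphb is not None and sphb < 0:
                raise ValueError("SpHb must be non-negative")


def _default_mspc_labels() -> dict:
    return {"SpO2": "SpO2", "SpHb": "SpHb"}


@dataclass
class DialectConfig:
    """Tunable knobs of the two dialects.

    ``ecs_co_field_index`` mirrors "positioning of the CO data value": the
    0-based token index at which CO appears on an ECS line.
    """

    ecs_co_field_index: int = 3
    ecs_cadence_s: float = 2.0
    mspc_cadence_s: float = 1.0
    mspc_labels: dict = field(default_factory=_default_mspc_labels)

    def __post_init__(self) -> None:
        if self.ecs_co_field_index < 0:
            raise ValueError("ecs_co_field_index must be non-negative")
        if self.ecs_cadence_s <= 0 or self.mspc_cadence_s <= 0:
            raise ValueError("cadences must be strictly positive")
        covered = set(self.mspc_labels.values())
        if not {"SpO2", "SpHb"} <= covered:
            raise ValueError("mspc_labels must cover SpO2 and SpHb")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "DialectConfig":
        """Load a config from a YAML key-value file; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _parse_clock(token: str) -> float:
    m = _TIMESTAMP_RE.match(token)
    if m is None:
        raise ParseError(f"malformed timestamp token: {token!r}")
    h, mnt, s = (int(g) for g in m.groups())
    if h > 23 or mnt > 59 or s > 59:
        raise ParseError(f"timestamp fields out of range: {token!r}")
    return h * 3600.0 + mnt * 60.0 + s


def parse_mspc_line(
    line: RawLine,
    cfg: DialectConfig,
    session_start_s: float | None = 0.0,
) -> DeviceSample:
    """Parse one MSPC line (``HH:MM:SS label=value ...``).

    ``session_start_s`` is the wall-clock offset (seconds) of the session
    start; within :func:`read_stream` the first accepted line defines it.
    Passing ``None`` makes this line itself the session start (t = 0); the
    standalone default of 0.0 reads the clock as seconds from midnight.
    Unknown labels are ignored; a bad timestamp or a line with no
    recognized label raises :class:`ParseError`.
    """
    if line.source is not Source.MSPC:
        raise ValueError("parse_mspc_line requires an MSPC line")
    tokens = line.text.split()
    if not tokens:
        raise ParseError("empty line")
    clock_s = _parse_clock(tokens[0])
    if session_start_s is None:
        session_start_s = clock_s
    t = clock_s - session_start_s
    # wall clock wrapped past midnight during an overnight session
    if t < -12 * 3600:
        t += 24 * 3600
    if t < 0:
        raise ParseError(f"timestamp precedes session start: {tokens[0]!r}")

    params: dict = {}
    for token in tokens[1:]:
        label, sep, value = token.partition("=")
        if not sep:
            continue
        name = cfg.mspc_labels.get(label)
        if name is None:
            continue
        try:
            x = float(value)
        except ValueError as exc:
            raise ParseError(f"non-numeric value for {label}: {value!r}") from exc
        if not math.isfinite(x):
            raise ParseError(f"non-finite value for {label}: {value!r}")
        if name == "SpO2":
            x /= 100.0  # dialect prints percent; internal unit is a fraction
        params[name] = x
    if not params:
        raise ParseError(f"no recognized label on line: {line.text!r}")
    return DeviceSample(source=Source.MSPC, timestamp=t, params=params)


def parse_ecs_line(line: RawLine, cfg: DialectConfig) -> DeviceSample:
    """Parse one ECS line of positional tokens; CO at ``ecs_co_field_index``.

    ECS lines carry no timestamp, so time is reconstructed from position:
    ``timestamp = arrival_index * ecs_cadence_s``.
    """
    if line.source is not Source.ECS:
        raise ValueError("parse_ecs_line requires an ECS line")
    tokens = line.text.split()
    if len(tokens) <= cfg.ecs_co_field_index:
        raise ParseError(
            f"too few tokens ({len(tokens)}) for CO at index {cfg.ecs_co_field_index}"
        )
    raw = tokens[cfg.ecs_co_field_index]
    try:
        co = float(raw)
    except ValueError as exc:
        raise ParseError(f"non-numeric CO token: {raw!r}") from exc
    if not math.isfinite(co) or co < 0:
        raise ParseError(f"CO token out of range: {raw!r}")
    return DeviceSample(
        source=Source.ECS,
        timestamp=line.arrival_index * cfg.ecs_cadence_s,
        params={"CO": co},
    )


def _iter_lines(source_obj: Union[str, Path, IO, Iterable[str]]) -> Iterable[str]:
    if isinstance(source_obj, (str, Path)):
        with open(source_obj, encoding="utf-8") as fh:
            yield from (ln.rstrip("\r\n") for ln in fh)
    else:
        yield from (ln.rstrip("\r\n") for ln in source_obj)


def read_stream(
    lines: Union[str, Path, IO, Iterable[str]],
    source: Source,
    cfg: DialectConfig | None = None,
) -> tuple[list[DeviceSample], int]:
    """Parse a whole stream; return ``(samples, n_rejected)``.

    ``lines`` may be a file path, an open text handle, or any iterable of
    strings.  Order is preserved; malformed lines are logged and counted,
    never fatal.  Accepted + rejected always equals the line total.
    """
    cfg = cfg or DialectConfig()
    samples: list[DeviceSample] = []
    rejected = 0
    session_start: float | None = None
    arrival = 0
    for text in _iter_lines(lines):
        raw = RawLine(source=source, text=text, arrival_index=arrival)
        arrival += 1
        try:
            if source is Source.MSPC:
                sample = parse_mspc_line(raw, cfg, session_start_s=session_start)
                if session_start is None:
                    session_start = _parse_clock(text.split()[0])
            else:
                sample = parse_ecs_line(raw, cfg)
        except ParseError as exc:
            rejected += 1
            logger.warning("%s line %d rejected: %s", source.value, raw.arrival_index, exc)
            continue
        samples.append(sample)
    return samples, rejected


def _fmt(x: float) -> str:
    return f"{x:.{DIALECT_DECIMALS}f}"


def _clock_str(t: float) -> str:
    s = int(round(t)) % (24 * 3600)
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


def write_stream(
    samples: Iterable[DeviceSample],
    source: Source,
    cfg: DialectConfig | None = None,
) -> list[str]:
    """Emit dialect lines such that ``read_stream`` reproduces the samples.

    Values round-trip to the dialect's printed precision (2 decimal places).
    MSPC session start is written as 00:00:00.  Mixed-source input is fatal.
    """
    cfg = cfg or DialectConfig()
    lines: list[str] = []
    for sample in samples:
        if sample.source is not source:
            raise StreamFormatError(
                f"mixed sources: expected {source.value}, got {sample.source.value}"
            )
        if source is Source.ECS:
            tokens = ["0.00"] * cfg.ecs_co_field_index + [_fmt(sample.params["CO"])]
            lines.append(" ".join(tokens))
        else:
            parts = [_clock_str(sample.timestamp)]
            label_for = {v: k for k, v in cfg.mspc_labels.items()}
            for name, value in sample.params.items():
                shown = value * 100.0 if name == "SpO2" else value
                parts.append(f"{label_for[name]}={_fmt(shown)}")
            lines.append(" ".join(parts))
    return lines
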