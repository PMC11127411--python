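"""Align the 1 Hz MSPC stream with the 0.5 Hz ECS stream on a 2-second grid.

The cardiac-output monitor (ECS) emits half as often as the co-oximeter
(MSPC), so DO2 cannot be derived line-by-line from either stream alone.
Each ECS sample defines one grid point; SpHb and SpO2 are filled from the
most recent MSPC sample at or before that point, provided it is no older
than a staleness bound (default one ECS period).  The rule is causal —
usable in real time — and deterministic.  Frames with a missing component
are kept as explicit gap markers and flagged invalid.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .device_streams import DeviceSample, Source

__all__ = ["SyncedFrame", "SyncConfig", "synchronize", "coverage", "frames_to_csv"]


@dataclass(frozen=True)
class SyncedFrame:
    """One co-registered grid point; ``valid`` iff co, sphb, spo2 all present."""

    t: float
    co: float | None
    sphb: float | None
    spo2: float | None
    valid: bool


@dataclass
class SyncConfig:
    grid_step_s: float = 2.0
    #: maximum age of an MSPC sample used at a grid point (seconds)
    staleness_s: float = 2.0

    def __post_init__(self) -> None:
        if self.grid_step_s <= 0 or self.staleness_s <= 0:
            raise ValueError("grid_step_s and staleness_s must be positive")


def synchronize(
    ecs_samples: Sequence[DeviceSample],
    mspc_samples: Sequence[DeviceSample],
    cfg: SyncConfig | None = None,
) -> list[SyncedFrame]:
    """Produce one frame per ECS sample on the ECS time grid.

    SpHb/SpO2 come from the most recent MSPC sample with timestamp <= t and
    age <= ``staleness_s`` (an exact tie counts, age 0); CO comes from the
    ECS sample itself.  Both inputs must be time-ordered.  Empty inputs are
    allowed and yield an empty (or all-invalid) frame list.
    """
    cfg = cfg or SyncConfig()
    if not ecs_samples:
        return []
    for s in ecs_samples:
        if s.source is not Source.ECS:
            raise ValueError("ecs_samples must all be ECS")
    for s in mspc_samples:
        if s.source is not Source.MSPC:
            raise ValueError("mspc_samples must all be MSPC")

    ecs = pd.DataFrame(
        {
            "t": np.array([s.timestamp for s in ecs_samples], dtype=float),
            "co": [s.params["CO"] for s in ecs_samples],
        }
    )
    if mspc_samples:
        mspc = pd.DataFrame(
            {
                "t": np.array([s.timestamp for s in mspc_samples], dtype=float),
                "sphb": [s.params.get("SpHb", np.nan) for s in mspc_samples],
                "spo2": [s.params.get("SpO2", np.nan) for s in mspc_samples],
            }
        )
        merged = pd.merge_asof(
            ecs, mspc, on="t", direction="backward", tolerance=cfg.staleness_s
        )
    else:
        merged = ecs.assign(sphb=np.nan, spo2=np.nan)

    frames = []
    for row in merged.itertuples(index=False):
        co = None if pd.isna(row.co) else float(row.co)
        sphb = None if pd.isna(row.sphb) else float(row.sphb)
        spo2 = None if pd.isna(row.spo2) else float(row.spo2)
        frames.append(
            SyncedFrame(
                t=float(row.t),
                co=co,
                sphb=sphb,
                spo2=spo2,
                valid=co is not None and sphb is not None and spo2 is not None,
            )
        )
    return frames


def coverage(frames: Iterable[SyncedFrame], cfg: SyncConfig | None = None) -> float:
    """Valid monitoring duration in seconds: n_valid_frames * grid_step."""
    cfg = cfg or SyncConfig()
    return sum(1 for f in frames if f.valid) * cfg.grid_step_s


def frames_to_csv(
    frames: Iterable[SyncedFrame], path: Union[str, Path, None] = None
) -> str:
    """Write frames as CSV (t_s, co_lpm, sphb_gdl, spo2_frac, valid).

    Missing values become empty fields.  Returns the CSV text; also writes
    it to ``path`` when given.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["t_s", "co_lpm", "sphb_gdl", "spo2_frac", "valid"])
    for f in frames:
        writer.writerow(
            [
                f"{f.t:g}",
                "" if f.co is None else f"{f.co:g}",
                "" if f.sphb is None else f"{f.sphb:g}",
                "" if f.spo2 is None else f"{f.spo2:g}",
                str(f.valid).lower(),
            ]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
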