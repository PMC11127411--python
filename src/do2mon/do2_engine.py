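"""Oxygen-delivery derivation, 20-second trend aggregation, session summaries.

Global oxygen delivery is the product of cardiac output and arterial oxygen
content.  With dissolved oxygen neglected,

    DO2 [mL O2/min] = CO [L/min] x Hb [g/dL] x SpO2 x 1.34 [mL O2/g] x 10,

where 1.34 mL/g is hemoglobin's maximal oxygen-carrying capacity and the
factor 10 converts g/dL to g/L.  Dividing by body surface area (m^2) gives
the indexed value used for between-patient comparison; BSA is optional
here, so both absolute and indexed series are available.

Session-level statistics follow the monitoring report conventions: the mean
DO2, the 10th centile of DO2 (a lower-tail summary of impaired delivery,
linear interpolation between closest ranks), and valid monitoring duration.
A session fails when the CO signal is essentially undetectable.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .sync_engine import SyncedFrame

__all__ = [
    "O2_CAPACITY_ML_PER_G",
    "DO2Frame",
    "DO2TrendPoint",
    "SessionSummary",
    "FailureReason",
    "compute_do2",
    "derive_series",
    "bucket_trend",
    "summarize_session",
    "detect_failure",
    "trend_to_csv",
    "series_to_csv",
    "plot_trend",
]

#: maximal O2-binding capacity of hemoglobin, mL O2 per g Hb
O2_CAPACITY_ML_PER_G = 1.34
#: g/dL -> g/L
_DL_PER_L = 10.0


@dataclass(frozen=True)
class DO2Frame:
    """Per-grid-point DO2; ``do2`` missing (None) when the source frame was invalid."""

    t: float
    do2: float | None
    do2_indexed: float | None = None


@dataclass(frozen=True)
class DO2TrendPoint:
    """Mean DO2 over one 20-s display bucket."""

    bucket_start_s: float
    mean_do2: float
    n_frames: int


@dataclass(frozen=True)
class SessionSummary:
    mean_do2: float | None
    p10_do2: float | None
    valid_duration_min: float
    n_valid_frames: int
    failed: bool


class FailureReason(str, enum.Enum):
    OK = "OK"
    NO_CO_SIGNAL = "NO_CO_SIGNAL"
    NO_VALID_FRAMES = "NO_VALID_FRAMES"


def compute_do2(
    co: float, sphb: float, spo2: float, bsa_m2: float | None = None
) -> tuple[float | None, float | None]:
    """DO2 in mL O2/min (and per m^2 when ``bsa_m2`` given) from one reading.

    Non-finite inputs yield ``(None, None)`` rather than propagating NaN.
    """
    if not all(math.isfinite(x) for x in (co, sphb, spo2)):
        return None, None
    if co < 0 or sphb < 0 or not (0.0 <= spo2 <= 1.0):
        raise ValueError("inputs out of physiological domain")
    do2 = co * sphb * spo2 * O2_CAPACITY_ML_PER_G * _DL_PER_L
    indexed = None
    if bsa_m2 is not None:
        if not (math.isfinite(bsa_m2) and bsa_m2 > 0):
            return do2, None
        indexed = do2 / bsa_m2
    return do2, indexed


def derive_series(
    frames: Sequence[SyncedFrame], bsa_m2: float | None = None
) -> list[DO2Frame]:
    """Element-wise DO2 over synchronized frames; invalid frames stay missing."""
    out = []
    for f in frames:
        if f.valid:
            do2, indexed = compute_do2(f.co, f.sphb, f.spo2, bsa_m2)
        else:
            do2, indexed = None, None
        out.append(DO2Frame(t=f.t, do2=do2, do2_indexed=indexed))
    return out


def bucket_trend(
    do2_frames: Sequence[DO2Frame], bucket_s: float = 20.0, indexed: bool = False
) -> list[DO2TrendPoint]:
    """Aggregate frames into half-open windows [k*bucket_s, (k+1)*bucket_s).

    Each bucket with at least one non-missing DO2 emits the mean of its
    non-missing values; empty buckets are omitted.  A trailing partial
    bucket is emitted like any other.
    """
    if bucket_s <= 0:
        raise ValueError("bucket_s must be positive")
    sums: dict[int, list[float]] = {}
    for f in do2_frames:
        v = f.do2_indexed if indexed else f.do2
        if v is None:
            continue
        sums.setdefault(int(f.t // bucket_s), []).append(v)
    return [
        DO2TrendPoint(bucket_start_s=k * bucket_s, mean_do2=float(np.mean(vs)), n_frames=len(vs))
        for k, vs in sorted(sums.items())
    ]


def summarize_session(
    do2_frames: Sequence[DO2Frame],
    grid_step_s: float = 2.0,
    indexed: bool = False,
) -> SessionSummary:
    """Session mean, 10th-centile DO2 and valid duration.

    The 10th centile uses linear interpolation between closest ranks
    (rank h = (n-1)*0.10 + 1 on the sorted values).  An empty session gives
    a failed summary with missing statistics.
    """
    values = np.array(
        [
            (f.do2_indexed if indexed else f.do2)
            for f in do2_frames
            if (f.do2_indexed if indexed else f.do2) is not None
        ],
        dtype=float,
    )
    n = values.size
    if n == 0:
        return SessionSummary(
            mean_do2=None,
            p10_do2=None,
            valid_duration_min=0.0,
            n_valid_frames=0,
            failed=True,
        )
    return SessionSummary(
        mean_do2=float(values.mean()),
        p10_do2=float(np.percentile(values, 10.0)),
        valid_duration_min=n * grid_step_s / 60.0,
        n_valid_frames=int(n),
        failed=False,
    )


def detect_failure(
    frames: Sequence[SyncedFrame],
    n_ecs_lines: int,
    n_ecs_rejected: int,
    min_co_fraction: float = 0.10,
) -> tuple[bool, FailureReason]:
    """Flag a session whose CO signal was essentially undetectable.

    Failure when the fraction of ECS lines that yielded a parseable CO falls
    below ``min_co_fraction`` (default 10%), or when no valid frames exist.
    """
    if n_ecs_lines > 0:
        co_fraction = (n_ecs_lines - n_ecs_rejected) / n_ecs_lines
    else:
        co_fraction = 0.0
    if co_fraction < min_co_fraction:
        return True, FailureReason.NO_CO_SIGNAL
    if not any(f.valid for f in frames):
        return True, FailureReason.NO_VALID_FRAMES
    return False, FailureReason.OK


def series_to_csv(
    do2_frames: Iterable[DO2Frame], path: Union[str, Path, None] = None
) -> str:
    """DO2 series as CSV (t_s, do2); missing values as empty fields."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["t_s", "do2"])
    for f in do2_frames:
        w.writerow([f"{f.t:g}", "" if f.do2 is None else f"{f.do2:g}"])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def trend_to_csv(
    points: Iterable[DO2TrendPoint], path: Union[str, Path, None] = None
) -> str:
    """Trend points as CSV (bucket_start_s, mean_do2, n_frames)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["bucket_start_s", "mean_do2", "n_frames"])
    for p in points:
        w.writerow([f"{p.bucket_start_s:g}", f"{p.mean_do2:g}", p.n_frames])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def plot_trend(points: Sequence[DO2TrendPoint], path: Union[str, Path]) -> None:
    """Static trend chart to PNG (presentation only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.step(
        [p.bucket_start_s / 60.0 for p in points],
        [p.mean_do2 for p in points],
        where="post",
    )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("DO2 (mL/min)")
    ax.set_title("DO2 trend (20-s buckets)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
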