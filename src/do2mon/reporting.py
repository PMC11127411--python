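"""Cohort-level reporting and the sensor-wear safety monitor.

The primary outcome of a monitoring study like this one is feasibility: the
percentage of sessions in which the pipeline produced a usable DO2 trend.
The cohort report also tabulates AKI incidence, compares session DO2
metrics between AKI and non-AKI patients (Welch t-test), and lists safety
alerts for sessions whose finger-cuff wear time exceeded the recommended
maximum of 480 minutes (strictly: 480 itself is compliant).

Printed precisions follow clinical-report convention: success rate to the
nearest whole percent, AKI incidence to one decimal; raw values are kept
alongside.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .agreement import GroupComparison, unpaired_t
from .do2_engine import SessionSummary
from .simulate import SessionRecord

__all__ = [
    "SAFETY_LIMIT_MIN",
    "CohortReport",
    "cohort_report",
    "safety_monitor",
    "registry_to_csv",
    "registry_from_csv",
    "format_cohort_report",
]

#: recommended maximum continuous finger-cuff wear, minutes
SAFETY_LIMIT_MIN = 480.0


@dataclass(frozen=True)
class CohortReport:
    n_total: int
    n_success: int
    success_pct: float
    success_pct_printed: str
    n_aki: int
    aki_pct: float
    aki_pct_printed: str
    #: Welch comparisons of per-session metrics, AKI (a) vs non-AKI (b)
    group_stats: dict
    safety_alerts: list


def cohort_report(
    registry: Sequence[SessionRecord],
    summaries: Mapping[str, SessionSummary],
    limit_min: float = SAFETY_LIMIT_MIN,
) -> CohortReport:
    """Aggregate a session registry into the cohort feasibility report.

    ``summaries`` maps session_id to its DO2 summary (required for
    successful sessions).  Group comparisons of mean and 10th-centile DO2
    between AKI and non-AKI successful sessions are included when both
    groups have n >= 2, else recorded as None.
    """
    if not registry:
        raise ValueError("empty registry")
    ids = [r.session_id for r in registry]
    if len(set(ids)) != len(ids):
        raise ValueError("session_id values must be unique")
    n_total = len(registry)
    n_success = sum(1 for r in registry if r.success)
    n_aki = sum(1 for r in registry if r.aki)
    success_pct = 100.0 * n_success / n_total
    aki_pct = 100.0 * n_aki / n_total

    group_stats: dict[str, GroupComparison | None] = {}
    for metric in ("mean_do2", "p10_do2"):
        aki_vals, ctrl_vals = [], []
        for r in registry:
            if not r.success:
                continue
            s = summaries.get(r.session_id)
            if s is None or s.failed:
                continue
            v = getattr(s, metric)
            if v is None:
                continue
            (aki_vals if r.aki else ctrl_vals).append(v)
        if len(aki_vals) >= 2 and len(ctrl_vals) >= 2:
            group_stats[metric] = unpaired_t(aki_vals, ctrl_vals)
        else:
            group_stats[metric] = None

    return CohortReport(
        n_total=n_total,
        n_success=n_success,
        success_pct=success_pct,
        success_pct_printed=f"{success_pct:.0f}%",
        n_aki=n_aki,
        aki_pct=aki_pct,
        aki_pct_printed=f"{aki_pct:.1f}%",
        group_stats=group_stats,
        safety_alerts=safety_monitor(registry, limit_min),
    )


def safety_monitor(
    registry: Iterable[SessionRecord], limit_min: float = SAFETY_LIMIT_MIN
) -> list[str]:
    """Session ids whose wear time strictly exceeds the recommended limit."""
    return [r.session_id for r in registry if r.wear_min > limit_min]


def registry_to_csv(
    registry: Iterable[SessionRecord], path: Union[str, Path, None] = None
) -> str:
    """Registry as CSV (session_id, profile, success, aki, wear_min)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["session_id", "profile", "success", "aki", "wear_min"])
    for r in registry:
        w.writerow(
            [r.session_id, r.profile.value, str(r.success).lower(), str(r.aki).lower(), f"{r.wear_min:.1f}"]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def registry_from_csv(path: Union[str, Path]) -> list[SessionRecord]:
    from .simulate import Profile

    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return [
        SessionRecord(
            session_id=r["session_id"],
            profile=Profile(r["profile"]),
            success=r["success"].strip().lower() in ("true", "1", "yes"),
            aki=r["aki"].strip().lower() in ("true", "1", "yes"),
            wear_min=float(r["wear_min"]),
        )
        for r in rows
    ]


def format_cohort_report(report: CohortReport) -> str:
    """Human-readable text rendering of a cohort report."""
    lines = [
        "Cohort report",
        "=============",
        f"sessions:            {report.n_total}",
        f"successful:          {report.n_success} ({report.success_pct_printed};"
        f" raw {report.success_pct:.4f}%)",
        f"AKI:                 {report.n_aki} ({report.aki_pct_printed};"
        f" raw {report.aki_pct:.4f}%)",
    ]
    for metric, gc in report.group_stats.items():
        if gc is None:
            lines.append(f"{metric}: group comparison not available")
        else:
            lines.append(
                f"{metric} AKI vs non-AKI: {gc.mean_a:.1f}±{gc.sd_a:.1f} (n={gc.n_a})"
                f" vs {gc.mean_b:.1f}±{gc.sd_b:.1f} (n={gc.n_b}),"
                f" t={gc.t_stat:.3f}, p={gc.p_value:.3f}"
            )
    if report.safety_alerts:
        lines.append("safety alerts (> %g min wear): %s" % (SAFETY_LIMIT_MIN, ", ".join(report.safety_alerts)))
    else:
        lines.append("safety alerts: none")
    return "\n".join(lines) + "\n"
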