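"""Method-agreement and group-comparison statistics.

Sensor hemoglobin (SpHb, pulse co-oximetry) is validated against laboratory
Hb by Bland-Altman analysis: for paired readings the differences d_i =
SpHb_i - labHb_i are summarized by their mean (the bias), the sample SD of
the differences, and the 95% limits of agreement bias +/- 1.96 SD.  The
significance of the bias is assessed by a one-sample t-test of d against 0;
the paired two-sample t-test of the two columns is algebraically the same
test and is reported alongside as a consistency check.

The between-group comparison of session DO2 metrics (e.g. patients with vs
without postoperative acute kidney injury) uses an unpaired two-sample
t-test, Welch's by default.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "LOA_MULTIPLIER",
    "PairedReading",
    "AgreementResult",
    "GroupComparison",
    "pair_readings",
    "bland_altman",
    "unpaired_t",
    "bland_altman_plot_data",
    "pairs_from_csv",
    "agreement_report",
]

#: classic Bland-Altman limits-of-agreement multiplier (95% normal quantile)
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedReading:
    """One matched sensor/laboratory hemoglobin pair (both g/dL)."""

    t: float
    sphb: float
    lab_hb: float

    def __post_init__(self) -> None:
        for v in (self.sphb, self.lab_hb):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("hemoglobin values must be positive and finite")


@dataclass(frozen=True)
class AgreementResult:
    n: int
    bias: float
    sd_diff: float
    loa_upper: float
    loa_lower: float
    t_paired_p: float
    t_bias_p: float


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    p_value: float


def pair_readings(
    sphb_series: Sequence[tuple[float, float]],
    lab_records: Sequence[tuple[float, float]],
    window_s: float = 300.0,
) -> list[PairedReading]:
    """Match each lab draw with the nearest-in-time SpHb value.

    Lab records with no SpHb within ``window_s`` are dropped; one SpHb value
    may serve several lab records.  Both inputs are (t, value) sequences,
    time-ordered.
    """
    if not sphb_series:
        return []
    times = np.array([t for t, _ in sphb_series], dtype=float)
    vals = np.array([v for _, v in sphb_series], dtype=float)
    pairs = []
    for t_lab, hb in lab_records:
        i = int(np.argmin(np.abs(times - t_lab)))
        if abs(times[i] - t_lab) > window_s:
            continue
        pairs.append(PairedReading(t=float(t_lab), sphb=float(vals[i]), lab_hb=float(hb)))
    return pairs


def bland_altman(pairs: Sequence[PairedReading]) -> AgreementResult:
    """Bias, SD of differences, 95% limits of agreement and t-tests.

    Differences are sensor minus laboratory.  Requires n >= 2 (the SD is
    undefined below that).  With zero-variance differences the t-tests are
    degenerate: p = 1 when the bias is exactly 0, else p = 0.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 pairs")
    sphb = np.array([p.sphb for p in pairs], dtype=float)
    lab = np.array([p.lab_hb for p in pairs], dtype=float)
    d = sphb - lab
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        p1 = p2 = 1.0 if bias == 0.0 else 0.0
    else:
        p1 = float(stats.ttest_1samp(d, 0.0).pvalue)
        p2 = float(stats.ttest_rel(sphb, lab).pvalue)
    return AgreementResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        t_paired_p=p2,
        t_bias_p=p1,
    )


def unpaired_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sided unpaired t-test between two groups (Welch's by default).

    Degenerate case fixed by convention: when both groups have zero variance,
    equal means give t=0, p=1 and unequal means give t=+/-inf, p=0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    sd_a, sd_b = float(a.std(ddof=1)), float(b.std(ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        delta = float(a.mean() - b.mean())
        t_stat = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
        p = 1.0 if delta == 0.0 else 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=sd_a,
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=sd_b,
        n_b=int(b.size),
        t_stat=t_stat,
        p_value=p,
    )


def bland_altman_plot_data(
    pairs: Sequence[PairedReading],
) -> tuple[list[tuple[float, float]], dict]:
    """Per-pair (mean, difference) points plus the three reference lines.

    Returns ``(points, lines)`` where lines holds ``bias``, ``loa_upper``
    and ``loa_lower``; rendering is up to the caller.  An empty input gives
    empty points and no lines.
    """
    points = [((p.sphb + p.lab_hb) / 2.0, p.sphb - p.lab_hb) for p in pairs]
    if len(pairs) >= 2:
        res = bland_altman(pairs)
        lines = {"bias": res.bias, "loa_upper": res.loa_upper, "loa_lower": res.loa_lower}
    else:
        lines = {}
    return points, lines


def pairs_from_csv(path: Union[str, Path]) -> list[PairedReading]:
    """Read pairs from CSV with columns t_s, sphb_gdl, lab_hb_gdl."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return [
        PairedReading(
            t=float(r["t_s"]), sphb=float(r["sphb_gdl"]), lab_hb=float(r["lab_hb_gdl"])
        )
        for r in rows
    ]


def agreement_report(result: AgreementResult) -> dict:
    """Flat key-value view of an AgreementResult for text/CSV emission."""
    return {
        "n_pairs": result.n,
        "bias_gdl": result.bias,
        "sd_diff_gdl": result.sd_diff,
        "loa_upper_gdl": result.loa_upper,
        "loa_lower_gdl": result.loa_lower,
        "t_bias_p": result.t_bias_p,
        "t_paired_p": result.t_paired_p,
    }
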