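"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (explicit loops and sums) so they
stay independent of the vectorized implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from do2mon.device_streams import DeviceSample, Source
from do2mon.sync_engine import SyncConfig, SyncedFrame


def brute_force_synchronize(ecs_samples, mspc_samples, cfg: SyncConfig):
    """O(n*m) reference alignment: most recent MSPC at-or-before each grid point."""
    frames = []
    for e in ecs_samples:
        t = e.timestamp
        best = None
        for m in mspc_samples:  # exhaustive scan, no ordering assumptions
            if m.timestamp <= t and t - m.timestamp <= cfg.staleness_s:
                if best is None or m.timestamp >= best.timestamp:
                    best = m
        sphb = best.params.get("SpHb") if best is not None else None
        spo2 = best.params.get("SpO2") if best is not None else None
        co = e.params["CO"]
        frames.append(
            SyncedFrame(
                t=t,
                co=co,
                sphb=sphb,
                spo2=spo2,
                valid=co is not None and sphb is not None and spo2 is not None,
            )
        )
    return frames


def first_principles_bland_altman(sphb, lab):
    """Bias, SD of differences and the one-sample t statistic via explicit sums."""
    d = [s - l for s, l in zip(sphb, lab)]
    n = len(d)
    mean = sum(d) / n
    ss = sum((x - mean) ** 2 for x in d)
    sd = math.sqrt(ss / (n - 1))
    t = mean / (sd / math.sqrt(n)) if sd > 0 else float("nan")
    return mean, sd, t


def first_principles_welch(a, b):
    """Welch t statistic and degrees of freedom via explicit sums."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def random_streams(rng: np.random.Generator, n_ecs_max=40, n_mspc_max=80):
    """Small random (ECS, MSPC) sample lists with irregular MSPC timing."""
    n_ecs = int(rng.integers(0, n_ecs_max))
    n_mspc = int(rng.integers(0, n_mspc_max))
    ecs = [
        DeviceSample(Source.ECS, timestamp=i * 2.0, params={"CO": float(rng.uniform(3, 9))})
        for i in range(n_ecs)
    ]
    times = np.sort(rng.uniform(0, max(2.0 * n_ecs, 1.0), size=n_mspc))
    mspc = [
        DeviceSample(
            Source.MSPC,
            timestamp=float(t),
            params={"SpHb": float(rng.uniform(8, 14)), "SpO2": float(rng.uniform(0.9, 1.0))},
        )
        for t in times
    ]
    return ecs, mspc


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
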