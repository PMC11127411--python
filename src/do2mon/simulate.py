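"""Scenario simulator: seeded vital-sign trajectories emitted as device text.

Stands in for the two bedside monitors during development and testing, the
same way a randomized-parameter simulator was used to exercise the pipeline
before patient use.  Baselines for cardiac output, sensor hemoglobin and
oxygen saturation are drawn uniformly within textbook adult normal ranges
(CO 4-8 L/min, post-cardiac-surgery SpHb 8-14 g/dL, SpO2 95-100%) and then
shaped:

* ``RANDOM_NORMAL_RANGE`` — flat baselines plus multiplicative noise;
* ``UPTREND`` / ``DOWNTREND`` — a linear drift of the session's DO2 (a
  signed fraction of baseline per hour), the qualitative shapes seen in
  recovering vs deteriorating patients; superimposed dips multiply CO down
  over an interval (transient low-output episodes);
* monitoring gaps (bypass, transfer) suppress all lines in an interval;
* a CO malfunction replaces every ECS CO token with a non-numeric sentinel,
  reproducing an undetectable CO signal end to end.

Each session records its ground truth per grid point so that recovery of
DO2 through write -> parse -> synchronize -> derive can be checked exactly.
Identical seed and config give byte-identical streams.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .device_streams import DeviceSample, DialectConfig, Source, write_stream
from .do2_engine import O2_CAPACITY_ML_PER_G

__all__ = [
    "Profile",
    "ScenarioConfig",
    "SimulatedSession",
    "SessionRecord",
    "simulate",
    "simulate_cohort",
]

#: non-numeric token standing in for an undetectable CO value
CO_SENTINEL = "--"

#: default |DO2 drift| per hour for trending profiles (fraction of baseline);
#: sustained over a ~6 h session this is a pronounced trend that never clips
#: DO2 to zero
DEFAULT_TREND_PER_HOUR = 0.1

#: cohort monitoring-wear distribution, minutes (mean, SD)
WEAR_MIN_MEAN = 378.0
WEAR_MIN_SD = 93.0


class Profile(str, enum.Enum):
    RANDOM_NORMAL_RANGE = "RANDOM_NORMAL_RANGE"
    UPTREND = "UPTREND"
    DOWNTREND = "DOWNTREND"


@dataclass
class ScenarioConfig:
    """Full description of one simulated monitoring session."""

    duration_s: float = 3600.0
    seed: int = 0
    co_range: tuple[float, float] = (4.0, 8.0)
    sphb_range: tuple[float, float] = (8.0, 14.0)
    spo2_range: tuple[float, float] = (0.95, 1.00)
    profile: Profile = Profile.RANDOM_NORMAL_RANGE
    #: signed DO2 drift per hour as a fraction of baseline; None picks the
    #: profile default (+/-0.1 for trends, 0 for the flat profile)
    drift_per_hour: float | None = None
    #: (start_s, duration_s, depth_fraction) CO dips
    dips: list = field(default_factory=list)
    #: (start_s, duration_s) monitoring gaps with no lines at all
    gaps: list = field(default_factory=list)
    co_malfunction: bool = False
    noise_sd_fraction: float = 0.02

    def __post_init__(self) -> None:
        self.profile = Profile(self.profile)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for lo, hi in (self.co_range, self.sphb_range, self.spo2_range):
            if lo > hi:
                raise ValueError("ranges must be ordered lo <= hi")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be non-negative")
        for start, dur, depth in self.dips:
            if not (0 <= start and start + dur <= self.duration_s):
                raise ValueError("dips must lie within [0, duration_s]")
            if not (0 <= depth < 1):
                raise ValueError("dip depth_fraction must be in [0, 1)")
        for start, dur in self.gaps:
            if not (0 <= start and start + dur <= self.duration_s):
                raise ValueError("gaps must lie within [0, duration_s]")

    @property
    def effective_drift(self) -> float:
        if self.drift_per_hour is not None:
            return self.drift_per_hour
        if self.profile is Profile.UPTREND:
            return DEFAULT_TREND_PER_HOUR
        if self.profile is Profile.DOWNTREND:
            return -DEFAULT_TREND_PER_HOUR
        return 0.0


@dataclass
class SimulatedSession:
    config: ScenarioConfig
    ecs_lines: list[str]
    mspc_lines: list[str]
    #: per-ECS-grid-point ground truth: t_s (capture-relative grid time),
    #: t_real_s (real session time), co, sphb, spo2, do2
    truth: pd.DataFrame


@dataclass(frozen=True)
class SessionRecord:
    """One cohort-registry row."""

    session_id: str
    profile: Profile
    success: bool
    aki: bool
    wear_min: float


def _in_any(t: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return any(start <= t < start + dur for start, dur in intervals)


def _dip_factor(t: float, dips: Sequence[tuple[float, float, float]]) -> float:
    f = 1.0
    for start, dur, depth in dips:
        if start <= t < start + dur:
            f *= 1.0 - depth
    return f


def simulate(config: ScenarioConfig) -> SimulatedSession:
    """Generate one session: truth table plus both device line streams.

    The DO2 drift factor ``1 + drift * t/3600`` is split evenly (square
    root) between CO and SpHb so that noise-free DO2 drifts by exactly the
    configured fraction.  Noise is multiplicative Gaussian per emitted
    sample; CO/SpHb clip at 0 and SpO2 at [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    co0 = rng.uniform(*config.co_range)
    sphb0 = rng.uniform(*config.sphb_range)
    spo2_0 = rng.uniform(*config.spo2_range)
    drift = config.effective_drift
    sd = config.noise_sd_fraction
    dialect = DialectConfig()

    def noisy(x: float) -> float:
        return x * (1.0 + sd * rng.standard_normal()) if sd > 0 else x

    def base_at(t: float) -> tuple[float, float, float]:
        f = max(0.0, 1.0 + drift * t / 3600.0)
        g = math.sqrt(f)
        co = co0 * g * _dip_factor(t, config.dips)
        return co, sphb0 * g, spo2_0

    # Gaps (bypass, transfer) suspend capture on BOTH streams, so emitted
    # timestamps run on a capture-relative clock: the j-th emitted MSPC line
    # is stamped j seconds, matching the arrival-index timing the ECS dialect
    # forces.  Parameter values are still evaluated at real session time.
    mspc_samples = []
    n_mspc = int(config.duration_s // dialect.mspc_cadence_s)
    emitted = 0
    for i in range(n_mspc):
        t = i * dialect.mspc_cadence_s
        if _in_any(t, config.gaps):
            continue
        _, sphb, spo2 = base_at(t)
        sphb = max(0.0, noisy(sphb))
        spo2 = min(1.0, max(0.0, noisy(spo2)))
        mspc_samples.append(
            DeviceSample(
                source=Source.MSPC,
                timestamp=emitted * dialect.mspc_cadence_s,
                params={"SpO2": spo2, "SpHb": sphb},
            )
        )
        emitted += 1
    mspc_lines = write_stream(mspc_samples, Source.MSPC, dialect)

    # ECS at 2 s cadence; truth rows only for emitted (non-gap) points,
    # keyed by the capture-relative grid time the pipeline will reconstruct
    ecs_lines: list[str] = []
    truth_rows = []
    n_ecs = int(config.duration_s // dialect.ecs_cadence_s)
    for i in range(n_ecs):
        t = i * dialect.ecs_cadence_s
        if _in_any(t, config.gaps):
            continue
        co, sphb, spo2 = base_at(t)
        co_obs = max(0.0, noisy(co))
        t_grid = len(ecs_lines) * dialect.ecs_cadence_s
        sample = DeviceSample(source=Source.ECS, timestamp=t_grid, params={"CO": co_obs})
        (line,) = write_stream([sample], Source.ECS, dialect)
        if config.co_malfunction:
            tokens = line.split()
            tokens[dialect.ecs_co_field_index] = CO_SENTINEL
            line = " ".join(tokens)
        ecs_lines.append(line)
        truth_rows.append(
            {
                "t_s": t_grid,
                "t_real_s": t,
                "co": co,
                "sphb": sphb,
                "spo2": spo2,
                "do2": co * sphb * spo2 * O2_CAPACITY_ML_PER_G * 10.0,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["t_s", "t_real_s", "co", "sphb", "spo2", "do2"]
    )
    return SimulatedSession(config=config, ecs_lines=ecs_lines, mspc_lines=mspc_lines, truth=truth)


def simulate_cohort(
    n_sessions: int,
    profile_mix: dict | None = None,
    seed: int = 0,
    n_malfunction: int = 0,
    duration_s: float = 600.0,
    base_config: ScenarioConfig | None = None,
) -> tuple[list[SessionRecord], list[SimulatedSession]]:
    """Simulate a cohort: registry rows plus per-session streams.

    ``profile_mix`` maps profiles to fractions summing to 1; exact session
    counts are assigned by largest remainder and shuffled (seeded).  The
    first ``n_malfunction`` sessions after shuffling get a CO malfunction
    and are recorded as unsuccessful.  AKI labels attach to DOWNTREND
    sessions.  Wear minutes are drawn Normal(378, 93), clipped at 0.
    Per-session seeds derive deterministically from the master seed.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if not (0 <= n_malfunction <= n_sessions):
        raise ValueError("n_malfunction out of range")
    profile_mix = profile_mix or {Profile.RANDOM_NORMAL_RANGE: 1.0}
    mix = {Profile(k): float(v) for k, v in profile_mix.items()}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("profile_mix fractions must sum to 1")

    # largest-remainder apportionment of profiles to sessions
    items = sorted(mix.items(), key=lambda kv: kv[0].value)
    floors = {p: int(frac * n_sessions) for p, frac in items}
    rem = n_sessions - sum(floors.values())
    by_remainder = sorted(items, key=lambda kv: kv[1] * n_sessions - floors[kv[0]], reverse=True)
    for p, _ in by_remainder[:rem]:
        floors[p] += 1
    profiles: list[Profile] = []
    for p, _ in items:
        profiles.extend([p] * floors[p])

    rng = np.random.default_rng(seed)
    rng.shuffle(profiles)

    registry: list[SessionRecord] = []
    sessions: list[SimulatedSession] = []
    base = base_config or ScenarioConfig(duration_s=duration_s)
    seeds = rng.integers(0, 2**31 - 1, size=n_sessions)
    wear = np.clip(rng.normal(WEAR_MIN_MEAN, WEAR_MIN_SD, size=n_sessions), 0.0, None)
    for i, profile in enumerate(profiles):
        cfg = replace(
            base,
            seed=int(seeds[i]),
            profile=profile,
            duration_s=duration_s,
            co_malfunction=i < n_malfunction,
        )
        session = simulate(cfg)
        registry.append(
            SessionRecord(
                session_id=f"S{i + 1:03d}",
                profile=profile,
                success=not cfg.co_malfunction,
                aki=profile is Profile.DOWNTREND,
                wear_min=float(wear[i]),
            )
        )
        sessions.append(session)
    return registry, sessions
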