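"""End-to-end session pipeline: parse -> synchronize -> derive -> report.

Mirrors the bedside flow: two captured device streams go in, and the
artifacts a clinician-facing report needs come out — synchronized frames,
the DO2 series, the 20-s trend, and a session summary with the failure
verdict.  Inputs may be files on disk or a simulation scenario described in
the same YAML config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Union

import yaml

from . import device_streams as ds
from . import do2_engine as de
from . import sync_engine as se
from .simulate import ScenarioConfig, simulate

logger = logging.getLogger(__name__)

__all__ = ["SessionResult", "run_session", "run_pipeline"]


class PipelineError(RuntimeError):
    """Fatal pipeline problem (missing inputs, unwritable output)."""


class SessionResult:
    """Bundle of everything one session run produced."""

    def __init__(self, frames, do2_frames, trend, summary, failed, reason, n_rejected):
        self.frames = frames
        self.do2_frames = do2_frames
        self.trend = trend
        self.summary = summary
        self.failed = failed
        self.reason = reason
        self.n_rejected = n_rejected


def run_session(
    ecs_lines,
    mspc_lines,
    dialect: ds.DialectConfig | None = None,
    sync_cfg: se.SyncConfig | None = None,
    bsa_m2: float | None = None,
    bucket_s: float = 20.0,
) -> SessionResult:
    """Run the full per-session chain on two line streams (paths or iterables)."""
    dialect = dialect or ds.DialectConfig()
    sync_cfg = sync_cfg or se.SyncConfig()
    ecs_samples, ecs_rej = ds.read_stream(ecs_lines, ds.Source.ECS, dialect)
    mspc_samples, mspc_rej = ds.read_stream(mspc_lines, ds.Source.MSPC, dialect)
    n_ecs_lines = len(ecs_samples) + ecs_rej
    frames = se.synchronize(ecs_samples, mspc_samples, sync_cfg)
    do2_frames = de.derive_series(frames, bsa_m2)
    trend = de.bucket_trend(do2_frames, bucket_s)
    summary = de.summarize_session(do2_frames, sync_cfg.grid_step_s)
    failed, reason = de.detect_failure(frames, n_ecs_lines, ecs_rej)
    if failed:
        logger.warning("session failed: %s", reason.value)
        summary = de.SessionSummary(
            mean_do2=summary.mean_do2,
            p10_do2=summary.p10_do2,
            valid_duration_min=summary.valid_duration_min,
            n_valid_frames=summary.n_valid_frames,
            failed=True,
        )
    return SessionResult(
        frames, do2_frames, trend, summary, failed, reason, ecs_rej + mspc_rej
    )


def run_pipeline(config: Union[str, Path, dict], out_dir: Union[str, Path, None] = None) -> Path:
    """Execute a session described by a YAML config and write its artifacts.

    The config holds either a ``scenario`` block (ScenarioConfig fields) or
    an ``inputs`` block (``ecs``/``mspc`` file paths), plus optional
    ``bsa_m2``, ``dialect``, ``sync`` and ``out_dir``.  Artifacts written:
    frames.csv, do2.csv, trend.csv, summary.json, session.log (plus the
    emitted streams for simulated sessions).  Returns the output directory.
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise PipelineError(f"config not found: {cfg_path}")
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh) or {}
    out = Path(out_dir or config.get("out_dir", "do2mon_out"))
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError(f"cannot create output directory {out}: {exc}") from exc

    log_path = out / "session.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("do2mon")
    root.addHandler(handler)
    try:
        dialect = ds.DialectConfig(**config.get("dialect", {}))
        sync_cfg = se.SyncConfig(**config.get("sync", {}))
        if "scenario" in config:
            scenario = ScenarioConfig(**config["scenario"])
            session = simulate(scenario)
            ecs_lines, mspc_lines = session.ecs_lines, session.mspc_lines
            (out / "ecs.txt").write_text("\n".join(ecs_lines) + ("\n" if ecs_lines else ""))
            (out / "mspc.txt").write_text("\n".join(mspc_lines) + ("\n" if mspc_lines else ""))
        elif "inputs" in config:
            ecs_path = Path(config["inputs"]["ecs"])
            mspc_path = Path(config["inputs"]["mspc"])
            for p in (ecs_path, mspc_path):
                if not p.exists():
                    raise PipelineError(f"input stream not found: {p}")
            ecs_lines, mspc_lines = ecs_path, mspc_path
        else:
            raise PipelineError("config must contain a 'scenario' or 'inputs' block")

        result = run_session(
            ecs_lines,
            mspc_lines,
            dialect=dialect,
            sync_cfg=sync_cfg,
            bsa_m2=config.get("bsa_m2"),
        )
        se.frames_to_csv(result.frames, out / "frames.csv")
        de.series_to_csv(result.do2_frames, out / "do2.csv")
        de.trend_to_csv(result.trend, out / "trend.csv")
        summary = asdict(result.summary)
        summary["failure_reason"] = result.reason.value
        summary["n_rejected_lines"] = result.n_rejected
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        logger.info("session complete: %s", summary["failure_reason"])
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
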