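"""End-to-end pipeline runner behind the command line.

Wires the stages together for batches of sessions: simulate (optional) ->
segment -> condition -> detect -> summarise -> score -> associate, with a
manifest recording inputs, parameter values, package version and seed so a
run can be reproduced exactly.  A session failing at any stage is
quarantined (recorded with its stage and error) and the batch continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import leashwalk
from leashwalk.errors import LeashwalkError, StageError
from leashwalk.pull_events import DetectionConfig, detect_pull_events, summarize_walk
from leashwalk.signal_prep import interpolate_uniform, smooth, tare
from leashwalk.trace_io import RawTrace, find_sync_pulses, read_trace

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "trace_io": {"strict": True, "sync": {"min_force": 5.0, "min_duration": 2.0,
                                          "guard_gap": 1.0}},
    "signal": {"rate_hz": 10.0, "smooth_window": 3},
    "detection": {"threshold_fraction": 0.001, "direction_margin": 0.1},
    "ethogram": {"kappa_bin_s": 1.0},
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config over the documented defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict):
                cfg.setdefault(section, {}).update(values)
            else:
                cfg[section] = values
    return cfg


def process_trace(trace: RawTrace, body_weight: float, cfg: dict | None = None,
                  has_protocol: bool = False):
    """Run one trace through segmentation, conditioning and detection.

    Returns (metrics, events, conditioned trace).  When ``has_protocol`` is
    set the pre-walk calibration hold and sync pulls are located first and
    only the walk segment is analysed.
    """
    cfg = cfg or load_config()
    if has_protocol:
        seg = find_sync_pulses(trace, **cfg["trace_io"]["sync"])
        if seg.calibration[1] > seg.calibration[0]:
            cal = trace.force[seg.calibration[0]:seg.calibration[1]]
            # taring is authoritative; the hold median is a diagnostic only
            logger.info("session %s: calibration-hold median %.3f kgf "
                        "(device offset diagnostic)",
                        trace.session_id, float(np.median(cal)))
        walk = trace.slice(*seg.walk)
    else:
        walk = trace
    uni = interpolate_uniform(walk, rate=cfg["signal"]["rate_hz"])
    uni = smooth(tare(uni), window=cfg["signal"]["smooth_window"])
    det = DetectionConfig(body_weight=body_weight,
                          threshold_fraction=cfg["detection"]["threshold_fraction"],
                          direction_margin=cfg["detection"]["direction_margin"])
    events = detect_pull_events(uni, det)
    metrics = summarize_walk(events, uni)
    return metrics, events, uni


@dataclass
class RunResult:
    """Outcome of a batch run: per-session metric rows and quarantined failures."""

    metrics: pd.DataFrame
    failures: list = field(default_factory=list)  # (session_id, stage, message)

    @property
    def ok(self) -> bool:
        return not self.failures


def run_sessions(sessions: list[dict], cfg: dict | None = None,
                 out_dir: str | Path | None = None, seed: int | None = None) -> RunResult:
    """Process a batch of sessions, each ``{"path": ..., "body_weight": ...,
    "has_protocol": bool}``; failures are quarantined, not fatal."""
    cfg = cfg or load_config()
    rows, failures = [], []
    for sess in sessions:
        sid = sess.get("session_id") or Path(sess["path"]).stem
        try:
            trace = read_trace(sess["path"], session_id=sid,
                               strict=cfg["trace_io"]["strict"])
        except LeashwalkError as exc:
            failures.append((sid, "read", str(exc)))
            continue
        try:
            if "body_weight" not in sess:
                raise StageError("detection", sid,
                                 LeashwalkError("dog body weight missing"))
            metrics, events, _ = process_trace(
                trace, sess["body_weight"], cfg,
                has_protocol=sess.get("has_protocol", False))
        except LeashwalkError as exc:
            stage = exc.stage if isinstance(exc, StageError) else "process"
            failures.append((sid, stage, str(exc)))
            continue
        rows.append({"session_id": sid, **metrics.as_dict()})

    metrics_df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out_dir / "metrics.csv", index=False)
        manifest = {
            "version": leashwalk.__version__,
            "seed": seed,
            "config": cfg,
            "sessions": [s.get("session_id") or Path(s["path"]).stem for s in sessions],
            "failures": failures,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    for sid, stage, msg in failures:
        logger.warning("session %s quarantined at stage %s: %s", sid, stage, msg)
    return RunResult(metrics=metrics_df, failures=failures)
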