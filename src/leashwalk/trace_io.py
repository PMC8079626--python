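"""Reading, writing and protocol segmentation of device trace logs.

A trace log is the raw output of the leash tension meter: per-sample time
(seconds), tension force (kgf) and a signed direction scalar in [-1, +1]
derived from the device's 3-axis accelerometer (+1 = dog-ward pull,
-1 = handler-ward).  The on-disk dialect is a plain CSV with header
``time_s,force_kgf,dir``.

A complete recording follows a fixed pre-walk protocol: a ~10 s calibration
hold (device dangling, not connected to the dog), then three ~3 s
synchronisation pulls performed by the handler, then the walk itself.
:func:`find_sync_pulses` locates the three pulls and returns a
:class:`SegmentMap` partitioning the recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from leashwalk.errors import (
    EmptyInputError,
    FormatError,
    ParameterError,
    RangeError,
    SyncFailureError,
)

logger = logging.getLogger(__name__)

#: Device specification: nominal sampling rate (Hz), measuring range (kgf)
#: and force resolution (kgf).
DEVICE_SPEC = {"rate_hz": 10.0, "range_kgf": (0.0, 100.0), "resolution_kgf": 0.1}

TRACE_COLUMNS = ("time_s", "force_kgf", "dir")


@dataclass
class RawTrace:
    """A raw (possibly unevenly sampled) force/direction recording.

    Attributes
    ----------
    session_id : str
        Identifier of the recording session.
    t : ndarray
        Sample times in seconds since recording start; strictly increasing.
    force : ndarray
        Leash tension in kgf, within the device range [0, 100].
    dir : ndarray
        Signed direction scalar per sample, in [-1, +1].
    meta : dict
        Device specification (nominal rate, range, resolution).
    """

    session_id: str
    t: np.ndarray
    force: np.ndarray
    dir: np.ndarray
    meta: dict = field(default_factory=lambda: dict(DEVICE_SPEC))

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.dir = np.asarray(self.dir, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (len(self.t) == len(self.force) == len(self.dir)):
            raise FormatError("t, force and dir must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise FormatError("sample times must be strictly increasing")
        lo, hi = self.meta.get("range_kgf", (0.0, 100.0))
        if len(self.force) and (self.force.min() < lo or self.force.max() > hi):
            raise RangeError(
                f"force outside device range [{lo}, {hi}] kgf "
                f"(observed [{self.force.min():.3g}, {self.force.max():.3g}])"
            )
        if self.meta.get("resolution_kgf", 0.1) <= 0:
            raise ParameterError("device resolution must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, start: int, end: int) -> "RawTrace":
        """Return the half-open sample window [start, end) as a new trace."""
        return replace(
            self,
            t=self.t[start:end].copy(),
            force=self.force[start:end].copy(),
            dir=self.dir[start:end].copy(),
        )


@dataclass(frozen=True)
class SegmentMap:
    """Half-open index intervals for the protocol phases of a recording."""

    calibration: tuple[int, int]
    sync_pulses: tuple[tuple[int, int], ...]
    walk: tuple[int, int]

    def __post_init__(self):
        if len(self.sync_pulses) != 3:
            raise SyncFailureError(
                f"expected 3 sync pulses, got {len(self.sync_pulses)}",
                candidates=self.sync_pulses,
            )
        intervals = [self.calibration, *self.sync_pulses, self.walk]
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if a1 > b0:
                raise FormatError("segment intervals must be ordered and non-overlapping")
        if self.walk[0] >= self.walk[1]:
            raise FormatError("walk segment must be non-empty")


def read_trace(
    path: str | Path,
    session_id: str | None = None,
    strict: bool = True,
    meta: dict | None = None,
) -> RawTrace:
    """Read a device trace CSV (``time_s,force_kgf,dir``) into a RawTrace.

    Parameters
    ----------
    strict : bool
        In strict mode any non-monotone timestamp or malformed row raises a
        :class:`FormatError`.  In lenient mode offending rows are dropped and
        a count is logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; expected header "
                          f"{','.join(TRACE_COLUMNS)}")
    if df.empty:
        raise EmptyInputError(f"{path} contains a header but no samples")

    bad = df[list(TRACE_COLUMNS)].isna().any(axis=1)
    if bad.any():
        if strict:
            raise FormatError(f"{path}: {int(bad.sum())} malformed row(s)")
        logger.warning("%s: dropping %d malformed row(s)", path, int(bad.sum()))
        df = df[~bad]

    t = df["time_s"].to_numpy(float)
    nonmono = np.zeros(len(t), dtype=bool)
    nonmono[1:] = np.diff(t) <= 0
    if nonmono.any():
        if strict:
            i = int(np.flatnonzero(nonmono)[0])
            raise FormatError(f"{path}: non-monotone timestamp at row {i} (t={t[i]})")
        logger.warning("%s: dropping %d non-monotone row(s)", path, int(nonmono.sum()))
        # drop iteratively: keep rows forming a strictly increasing sequence
        keep = []
        last = -np.inf
        for i, ti in enumerate(t):
            if ti > last:
                keep.append(i)
                last = ti
        df = df.iloc[keep]

    return RawTrace(
        session_id=session_id or path.stem,
        t=df["time_s"].to_numpy(float),
        force=df["force_kgf"].to_numpy(float),
        dir=df["dir"].to_numpy(float),
        meta=dict(meta) if meta else dict(DEVICE_SPEC),
    )


def write_trace(trace: RawTrace, path: str | Path) -> None:
    """Write a RawTrace as CSV, quantising force to the device resolution.

    Re-reading the file yields a trace equal to the original up to the
    resolution rounding of the force channel.
    """
    res = trace.meta.get("resolution_kgf", DEVICE_SPEC["resolution_kgf"])
    force = np.round(trace.force / res) * res
    df = pd.DataFrame({"time_s": trace.t, "force_kgf": force, "dir": trace.dir})
    df.to_csv(path, index=False, float_format="%.6g")


def find_sync_pulses(
    trace: RawTrace,
    min_force: float = 5.0,
    min_duration: float = 2.0,
    guard_gap: float = 1.0,
) -> SegmentMap:
    """Locate the three synchronisation pulls and partition the recording.

    A candidate pulse is a maximal run of samples with force >= ``min_force``
    whose time span is at least ``min_duration`` seconds.  Exactly three
    qualifying pulses are required; otherwise a :class:`SyncFailureError`
    listing the candidates is raised.  The calibration segment is everything
    before the first pulse; the walk starts ``guard_gap`` seconds after the
    end of the third pulse.
    """
    if min_force <= 0 or min_duration <= 0 or guard_gap < 0:
        raise ParameterError("min_force and min_duration must be positive, guard_gap >= 0")
    above = trace.force >= min_force
    if not above.any():
        raise SyncFailureError("no samples reach the sync pulse force", candidates=[])

    # maximal runs of above-threshold samples
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))

    candidates = [
        (int(s), int(e))
        for s, e in zip(starts, ends)
        if trace.t[e - 1] - trace.t[s] >= min_duration
    ]
    if len(candidates) != 3:
        raise SyncFailureError(
            f"expected 3 sync pulses of >= {min_force} kgf lasting >= {min_duration} s, "
            f"found {len(candidates)}",
            candidates=candidates,
        )

    last_end = candidates[2][1]
    walk_t0 = trace.t[last_end - 1] + guard_gap
    walk_start = int(np.searchsorted(trace.t, walk_t0, side="left"))
    if walk_start >= len(trace):
        raise SyncFailureError("no walk samples after the final sync pulse", candidates=candidates)

    seg = SegmentMap(
        calibration=(0, candidates[0][0]),
        sync_pulses=tuple(candidates),
        walk=(walk_start, len(trace)),
    )
    logger.info(
        "session %s: calibration [%d,%d), pulses %s, walk [%d,%d)",
        trace.session_id, *seg.calibration, seg.sync_pulses, *seg.walk,
    )
    return seg
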