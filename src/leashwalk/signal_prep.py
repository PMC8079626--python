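"""Walk-segment conditioning: uniform resampling, taring, smoothing.

The device samples nominally at 10 Hz but real logs can carry timestamp
jitter, so force and direction are first linearly interpolated onto an even
grid.  Tension is then *tarred* — the trace minimum, which corresponds to
the unloaded baseline, is subtracted so that slack leash reads zero — and
smoothed with a short centred moving average before event detection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from leashwalk.errors import EmptyInputError, InsufficientDataError, ParameterError
from leashwalk.trace_io import RawTrace


@dataclass
class UniformTrace:
    """An evenly sampled tension/direction series.

    ``tarred`` records whether the baseline has been subtracted;
    ``smoothed`` is the moving-average window length in samples (0 = raw).
    """

    t0: float
    rate: float
    force: np.ndarray
    dir: np.ndarray
    tarred: bool = False
    smoothed: int = 0
    session_id: str = ""

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        self.dir = np.asarray(self.dir, dtype=float)
        if self.rate <= 0:
            raise ParameterError("sampling rate must be positive")
        if len(self.force) != len(self.dir):
            raise ParameterError("force and dir must have equal length")
        # smoothing after taring may lift the minimum slightly off zero,
        # so the zero-minimum contract is enforced on unsmoothed traces only
        if (
            self.tarred
            and self.smoothed == 0
            and len(self.force)
            and abs(self.force.min()) > 1e-12
        ):
            raise ParameterError("trace flagged tarred but min(force) != 0")

    def __len__(self) -> int:
        return len(self.force)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.force)) / self.rate

    @property
    def duration(self) -> float:
        """Walk time covered, in seconds (one sample interval per sample)."""
        return len(self.force) / self.rate


def interpolate_uniform(raw: RawTrace, rate: float = 10.0) -> UniformTrace:
    """Resample a raw segment onto the grid ``t[0] + k/rate`` by linear
    interpolation of force and direction.

    The grid covers the segment span without extrapolating beyond either
    endpoint, so the first output sample equals the first input sample.
    """
    if rate <= 0:
        raise ParameterError("rate must be positive")
    if len(raw) < 2:
        raise InsufficientDataError("need at least 2 samples to interpolate")
    span = raw.t[-1] - raw.t[0]
    n = int(np.floor(span * rate)) + 1
    grid = raw.t[0] + np.arange(n) / rate
    return UniformTrace(
        t0=float(raw.t[0]),
        rate=float(rate),
        force=np.interp(grid, raw.t, raw.force),
        dir=np.interp(grid, raw.t, raw.dir),
        session_id=raw.session_id,
    )


def tare(trace: UniformTrace) -> UniformTrace:
    """Subtract the trace minimum so the unloaded baseline reads zero.

    Idempotent and invariant to constant offsets; the direction channel is
    untouched.
    """
    if len(trace) == 0:
        raise EmptyInputError("cannot tare an empty trace")
    return replace(trace, force=trace.force - trace.force.min(), tarred=True)


def smooth(trace: UniformTrace, window: int = 3) -> UniformTrace:
    """Centred moving average with edge truncation.

    ``window`` must be odd and >= 1; a window of 1 is the identity.  Near
    the edges the average runs over the in-bounds part of the window only,
    so output length equals input length and no value leaves the input's
    [min, max] range.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd and >= 1, got {window}")
    if window == 1:
        return replace(trace, smoothed=1)
    sm = (
        pd.Series(trace.force)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(trace, force=sm, smoothed=window)
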