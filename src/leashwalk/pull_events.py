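"""Pull-event detection, direction attribution and walk-level metrics.

A *pull event* is a burst of leash tension above a body-weight-scaled
threshold (0.1% of the dog's body weight force by default).  On the tarred,
smoothed tension series an event

* **starts** at the first sample strictly above the threshold following a
  sample at or below it (or following a previous event's end), and
* **ends** at the first sample where either the tension drops strictly
  below the threshold, or the discrete gradient flips from negative to
  positive — a rising valley marks the onset of a new pull, so that sample
  begins the next candidate event.

Ties at the threshold extend an event; a zero gradient is not a sign
change.  Each event's initiator (dog, handler, or both pulling at once) is
read from the signed accelerometer direction channel in the sample
immediately before event onset.

Walk-level metrics follow the NT/DT/HT naming convention: *net* metrics
pool every event, *dog* and *handler* metrics the events attributed to each
party.  Mean tension is the mean of event peak forces.  Dog and handler
pulling frequencies (DPF, HPF) are attributed event counts divided by the
walking duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from leashwalk.errors import ContractError, ParameterError
from leashwalk.signal_prep import UniformTrace

logger = logging.getLogger(__name__)

DOG = "dog"
HANDLER = "handler"
BOTH = "both"


@dataclass(frozen=True)
class DetectionConfig:
    """Detection parameters.

    threshold_fraction
        Fraction of body weight (in kgf) defining the event threshold;
        the default 0.001 corresponds to 0.1% of body weight force.
    direction_margin
        Half-width of the dead band on the direction channel inside which
        a pull is attributed to both parties at once.
    """

    body_weight: float
    threshold_fraction: float = 0.001
    direction_margin: float = 0.1

    def __post_init__(self):
        if self.body_weight <= 0:
            raise ParameterError("body weight must be positive")
        if not (0 < self.threshold_fraction < 1):
            raise ParameterError("threshold_fraction must be in (0, 1)")
        if not (0 <= self.direction_margin < 1):
            raise ParameterError("direction_margin must be in [0, 1)")


@dataclass
class PullEvent:
    """One detected tension burst, as a half-open sample window."""

    start: int
    end: int
    peak_force: float
    peak_index: int
    direction: str = ""
    truncated: bool = False

    def __post_init__(self):
        if not (self.start < self.end):
            raise ContractError("event start must precede end")
        if not (self.start <= self.peak_index < self.end):
            raise ContractError("peak index must lie within the event")


@dataclass
class WalkMetrics:
    """The eight walk-level tension outcomes plus bookkeeping counts."""

    nt_max: float
    nt_mean: float
    dt_max: float
    dt_mean: float
    ht_max: float
    ht_mean: float
    dpf: float
    hpf: float
    duration: float
    n_events: int
    n_dog: int
    n_handler: int
    n_both: int
    #: samplewise mean of the tarred tension — auxiliary diagnostic, not
    #: one of the eight peak-based outcomes
    samplewise_mean: float = 0.0

    def as_dict(self) -> dict:
        return {
            "nt_max": self.nt_max, "nt_mean": self.nt_mean,
            "dt_max": self.dt_max, "dt_mean": self.dt_mean,
            "ht_max": self.ht_max, "ht_mean": self.ht_mean,
            "dpf": self.dpf, "hpf": self.hpf,
            "duration": self.duration, "n_events": self.n_events,
            "n_dog": self.n_dog, "n_handler": self.n_handler,
            "n_both": self.n_both, "samplewise_mean": self.samplewise_mean,
        }


def compute_threshold(cfg: DetectionConfig) -> float:
    """Event threshold in kgf: threshold_fraction x body weight."""
    return cfg.threshold_fraction * cfg.body_weight


def detect_pull_events(trace: UniformTrace, cfg: DetectionConfig) -> list[PullEvent]:
    """Segment the tarred, smoothed tension series into pull events.

    Returns disjoint, ordered events with peak force/index populated and
    direction attributed from the pre-onset accelerometer sample.  An event
    still open at the final sample is closed there and flagged truncated.
    """
    if not trace.tarred:
        raise ContractError("detect_pull_events requires a tarred trace")
    thr = compute_threshold(cfg)
    f = trace.force
    n = len(f)
    events: list[PullEvent] = []

    i = 0
    start = None  # index of the current open event, None if no event open
    last_sign = 0  # sign of the last nonzero gradient inside the open event
    while i < n:
        if start is None:
            if f[i] > thr:
                start = i
                last_sign = 0
            i += 1
            continue
        # event open; decide whether sample i closes it
        if f[i] < thr:
            events.append(_close(f, start, i))
            start = None
            i += 1
            continue
        d = f[i] - f[i - 1]
        if d > 0 and last_sign < 0:
            # rising after a fall: sample i starts a new pull
            events.append(_close(f, start, i))
            start = i
            last_sign = 0
            i += 1
            continue
        if d != 0:
            last_sign = 1 if d > 0 else -1
        i += 1
    if start is not None:
        ev = _close(f, start, n)
        ev.truncated = True
        events.append(ev)

    for ev in events:
        ev.direction = attribute_direction(ev, trace, cfg.direction_margin)
    return events


def _close(f: np.ndarray, start: int, end: int) -> PullEvent:
    peak_index = start + int(np.argmax(f[start:end]))
    return PullEvent(start=start, end=end, peak_force=float(f[peak_index]),
                     peak_index=peak_index)


def attribute_direction(event: PullEvent, trace: UniformTrace, margin: float = 0.1) -> str:
    """Attribute a pull to the dog, the handler or both.

    Reads the signed direction channel in the sample immediately before
    event onset: positive beyond the margin = dog, negative beyond the
    margin = handler, within the dead band = both.  An event starting at
    sample 0 has no prior sample; the onset sample itself is used and a
    warning logged.
    """
    if event.start >= 1:
        d = trace.dir[event.start - 1]
    else:
        d = trace.dir[0]
        logger.warning("event starts at sample 0; using onset-sample direction")
    if d > margin:
        return DOG
    if d < -margin:
        return HANDLER
    return BOTH


def summarize_walk(events: list[PullEvent], trace: UniformTrace) -> WalkMetrics:
    """Compute the eight walk-level tension metrics from detected events.

    Net metrics pool every event; dog/handler metrics cover the events
    attributed to each party ("both" events count toward net metrics and
    the event total only).  Mean tensions average event peak forces; an
    event-free walk yields all-zero tensions and frequencies.
    """
    duration = trace.duration
    if duration <= 0:
        raise ContractError("walk duration must be positive")

    peaks = np.array([e.peak_force for e in events])
    dog_peaks = np.array([e.peak_force for e in events if e.direction == DOG])
    hand_peaks = np.array([e.peak_force for e in events if e.direction == HANDLER])
    n_both = sum(1 for e in events if e.direction == BOTH)

    def _mx(x):
        return float(x.max()) if len(x) else 0.0

    def _mn(x):
        return float(x.mean()) if len(x) else 0.0

    return WalkMetrics(
        nt_max=_mx(peaks), nt_mean=_mn(peaks),
        dt_max=_mx(dog_peaks), dt_mean=_mn(dog_peaks),
        ht_max=_mx(hand_peaks), ht_mean=_mn(hand_peaks),
        dpf=len(dog_peaks) / duration,
        hpf=len(hand_peaks) / duration,
        duration=duration,
        n_events=len(events),
        n_dog=len(dog_peaks),
        n_handler=len(hand_peaks),
        n_both=n_both,
        samplewise_mean=float(trace.force.mean()) if len(trace) else 0.0,
    )
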