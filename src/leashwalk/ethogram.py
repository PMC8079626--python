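"""Coded behaviour logs: catalogs, summaries and coder agreement.

Behaviour observations exported from video coding come in two flavours:
*point events* (instantaneous, counted) and *state events* (intervals,
timed).  The legal vocabulary lives in an :class:`EthogramCatalog`; the
default catalog covers nine canine behaviours, seven human verbal cues and
three human body-language behaviours.

Summaries follow the study conventions: point behaviours are reported as
rates (events per second of walk), state behaviours as percent of walk time
(overlapping same-behaviour intervals merged first), plus grouped totals
for verbal cues and body language.  Agreement between two codings of the
same video is quantified by Cohen's kappa on fixed-width time bins.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from leashwalk.errors import CatalogError, FormatError, ParameterError

POINT = "point"
STATE = "state"
CATEGORIES = ("canine", "human_verbal", "human_body")


@dataclass(frozen=True)
class EthogramCatalog:
    """Behaviour name -> {category, type} vocabulary."""

    entries: dict  # name -> {"category": str, "type": str}

    def __post_init__(self):
        for name, info in self.entries.items():
            if info["category"] not in CATEGORIES:
                raise CatalogError(f"{name}: unknown category {info['category']!r}")
            if info["type"] not in (POINT, STATE):
                raise CatalogError(f"{name}: unknown event type {info['type']!r}")

    def names(self, category: str | None = None) -> list[str]:
        """Behaviour names in catalog order, optionally one category only."""
        return [
            n for n, info in self.entries.items()
            if category is None or info["category"] == category
        ]

    def type_of(self, behavior: str) -> str:
        try:
            return self.entries[behavior]["type"]
        except KeyError:
            raise CatalogError(f"behaviour {behavior!r} not in catalog") from None

    def __contains__(self, behavior: str) -> bool:
        return behavior in self.entries


def default_catalog() -> EthogramCatalog:
    """Load the packaged default catalog."""
    text = resources.files("leashwalk").joinpath("data/ethogram.yml").read_text()
    raw = yaml.safe_load(text)
    entries: dict = {}
    for category in CATEGORIES:
        for name, etype in raw.get(category, {}).items():
            entries[name] = {"category": category, "type": etype}
    return EthogramCatalog(entries)


@dataclass
class BehaviorLog:
    """All coded events of one walk session."""

    session_id: str
    duration: float
    point_events: list  # (behavior, time_s)
    state_events: list  # (behavior, start_s, end_s)

    def validate(self, catalog: EthogramCatalog) -> None:
        if self.duration <= 0:
            raise ParameterError("log duration must be positive")
        for b, t in self.point_events:
            if catalog.type_of(b) != POINT:
                raise CatalogError(f"{b!r} coded as point but catalog says state")
            if not (0 <= t <= self.duration):
                raise FormatError(f"point event {b!r} at {t} s outside [0, {self.duration}]")
        for b, s, e in self.state_events:
            if catalog.type_of(b) != STATE:
                raise CatalogError(f"{b!r} coded as state but catalog says point")
            if not (0 <= s < e <= self.duration):
                raise FormatError(f"state event {b!r} [{s}, {e}) invalid for duration "
                                  f"{self.duration}")


@dataclass
class BehaviorSummary:
    """Per-behaviour rates/fractions and grouped totals for one walk."""

    rates: dict = field(default_factory=dict)      # point behavior -> events/s
    fractions: dict = field(default_factory=dict)  # state behavior -> % of walk time
    totals: dict = field(default_factory=dict)     # group name -> summed rate


def read_behavior_log(path: str | Path, duration: float,
                      session_id: str | None = None) -> BehaviorLog:
    """Read a behaviour CSV ``behavior,type,start_s,end_s`` (end empty for
    point events)."""
    path = Path(path)
    points, states = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"behavior", "type", "start_s", "end_s"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: expected header behavior,type,start_s,end_s")
        for row in reader:
            if row["type"] == POINT:
                points.append((row["behavior"], float(row["start_s"])))
            elif row["type"] == STATE:
                states.append((row["behavior"], float(row["start_s"]), float(row["end_s"])))
            else:
                raise FormatError(f"{path}: unknown event type {row['type']!r}")
    return BehaviorLog(session_id=session_id or path.stem, duration=duration,
                       point_events=points, state_events=states)


def write_behavior_log(log: BehaviorLog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["behavior", "type", "start_s", "end_s"])
        for b, t in log.point_events:
            w.writerow([b, POINT, f"{t:.6g}", ""])
        for b, s, e in log.state_events:
            w.writerow([b, STATE, f"{s:.6g}", f"{e:.6g}"])


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping [start, end) intervals; total time never grows."""
    merged: list[list[float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def summarize_behaviors(log: BehaviorLog, catalog: EthogramCatalog) -> BehaviorSummary:
    """Point rates (events/s), state fractions (% of walk time) and grouped
    totals (total verbal cue, total body language) for one session."""
    log.validate(catalog)
    summary = BehaviorSummary()

    for name in catalog.names():
        if catalog.type_of(name) == POINT:
            count = sum(1 for b, _ in log.point_events if b == name)
            summary.rates[name] = count / log.duration
        else:
            spans = _merge_intervals([(s, e) for b, s, e in log.state_events if b == name])
            total = sum(e - s for s, e in spans)
            summary.fractions[name] = 100.0 * total / log.duration

    for group, category in (("total_verbal_cue", "human_verbal"),
                            ("total_body_language", "human_body")):
        members = catalog.names(category)
        summary.totals[group] = sum(summary.rates.get(m, 0.0) for m in members)
    return summary


def bin_timeline(log: BehaviorLog, bin_width: float, behaviors: list[str],
                 catalog: EthogramCatalog) -> list[str]:
    """Discretise a log into one label per fixed-width time bin.

    Bins are half-open [k*w, (k+1)*w); a point event on a boundary falls in
    the later bin (an event at exactly the walk end goes to the last bin).
    Within a bin, the label is the state behaviour with the largest overlap,
    falling back to the first point behaviour present, else ``"none"``;
    ties break by catalog order.
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")
    if bin_width > log.duration:
        raise ParameterError("bin width exceeds the walk duration")
    order = [b for b in catalog.names() if b in behaviors]
    unknown = set(behaviors) - set(order)
    if unknown:
        raise CatalogError(f"behaviour(s) not in catalog: {sorted(unknown)}")

    n_bins = int(np.ceil(log.duration / bin_width))
    labels = ["none"] * n_bins

    state_overlap = [dict() for _ in range(n_bins)]
    point_hits = [set() for _ in range(n_bins)]
    for b, s, e in log.state_events:
        if b not in order:
            continue
        first = int(s // bin_width)
        last = min(n_bins - 1, int(np.ceil(e / bin_width)) - 1)
        for k in range(first, last + 1):
            lo, hi = k * bin_width, (k + 1) * bin_width
            ov = min(e, hi) - max(s, lo)
            if ov > 0:
                state_overlap[k][b] = state_overlap[k].get(b, 0.0) + ov
    for b, t in log.point_events:
        if b not in order:
            continue
        k = min(n_bins - 1, int(t // bin_width))
        point_hits[k].add(b)

    for k in range(n_bins):
        if state_overlap[k]:
            best = max(state_overlap[k].values())
            labels[k] = next(b for b in order
                             if state_overlap[k].get(b, -1.0) >= best - 1e-12)
        elif point_hits[k]:
            labels[k] = next(b for b in order if b in point_hits[k])
    return labels


def cohens_kappa(seq_a, seq_b) -> float:
    """Cohen's kappa between two equal-length categorical sequences.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e computed
    from the two coders' marginal label frequencies.  When both sequences
    are the same constant label, p_e = 1 and kappa is returned as 1.0 by
    convention (perfect, if vacuous, agreement).
    """
    a = list(seq_a)
    b = list(seq_b)
    if len(a) != len(b):
        raise ParameterError("sequences must have equal length")
    if not a:
        raise ParameterError("sequences must be non-empty")
    n = len(a)
    labels = sorted(set(a) | set(b))
    idx = {lab: i for i, lab in enumerate(labels)}
    pa = np.zeros(len(labels))
    pb = np.zeros(len(labels))
    p_o = 0.0
    for x, y in zip(a, b):
        pa[idx[x]] += 1
        pb[idx[y]] += 1
        if x == y:
            p_o += 1
    pa /= n
    pb /= n
    p_o /= n
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
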