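"""Synthetic inputs with ground truth for every pipeline stage.

The study's raw recordings are not public, so every input the pipeline
consumes can be generated here under a stated scenario:

* **Device traces** (:func:`simulate_walk`) — 10 Hz force/direction logs
  with a baseline offset, Gaussian sensor noise, planted pull bursts of
  parametric shape (triangle, hump, double-hump), and optionally the full
  pre-walk protocol: a 10 s calibration hold followed by three 3 s
  synchronisation pulls.  The double-hump shape exists specifically to
  exercise the gradient-sign event-split rule.
* **Behaviour logs** (:func:`simulate_behavior_log`) — point events from a
  homogeneous Poisson process, state events as alternating on/off
  exponential intervals matching a target percent-of-time in expectation.
* **Questionnaires** (:func:`simulate_questionnaire`) — 13 Likert items
  from a discretised 2-factor latent model with negatively worded items
  anti-correlated with their factor.
* **Cohorts** (:func:`simulate_cohort`) — volunteers x dogs with
  level-compatible assignment, five-factor personality scores drawn from a
  realistic volunteer distribution, and outcomes built on the transformed
  scale from planted fixed effects + crossed volunteer/dog random
  intercepts + residual noise, then back-transformed.

All generators are deterministic under a fixed seed and return the ground
truth needed for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from leashwalk.errors import ParameterError, ScenarioError
from leashwalk.ethogram import POINT, STATE, BehaviorLog, EthogramCatalog, default_catalog
from leashwalk.association import TransformSpec
from leashwalk.trace_io import DEVICE_SPEC, RawTrace

#: Five-factor domain score means and SDs typical of a volunteer cohort;
#: used as the default personality distribution.
PERSONALITY_DISTRIBUTION = {
    "neuroticism": (24.97, 8.80),
    "extraversion": (27.24, 7.77),
    "openness": (29.59, 6.41),
    "agreeableness": (34.35, 5.97),
    "conscientiousness": (30.54, 7.23),
}

SHAPES = ("triangle", "hump", "double-hump")

#: seconds of direction-channel lead before a planted onset, so that the
#: pre-onset sample read by direction attribution carries the right sign
#: even after smoothing shifts the detected onset slightly earlier
DIR_LEAD_S = 0.5


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one planted pull burst."""

    start: float           # s, walk-relative
    duration: float        # s
    peak: float            # kgf above baseline
    direction: str         # "dog" | "handler" | "both"
    shape: str = "triangle"

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ScenarioError(f"unknown burst shape {self.shape!r}")
        if self.duration <= 0 or self.peak <= 0:
            raise ScenarioError("event duration and peak must be positive")

    @property
    def n_pulls(self) -> int:
        """How many detectable events this burst contributes (a double-hump
        splits at the rising valley)."""
        return 2 if self.shape == "double-hump" else 1


@dataclass
class WalkScenario:
    """A fully specified synthetic walk recording."""

    duration: float = 300.0          # s of walk
    dog_weight: float = 20.0         # kg
    events: list = field(default_factory=list)   # list[PlantedEvent]
    baseline: float = 0.3            # kgf offset when leash slack
    noise_sd: float = 0.0            # kgf
    include_protocol: bool = False   # prepend calibration hold + sync pulls
    calibration_s: float = 10.0
    sync_pull_s: float = 3.0
    sync_force: float = 8.0          # kgf
    rate: float = 10.0               # Hz
    jitter: float = 0.0              # timestamp jitter, fraction of interval
    seed: int = 0
    session_id: str = "synthetic"

    def __post_init__(self):
        if self.noise_sd < 0 or self.duration <= 0 or self.dog_weight <= 0:
            raise ScenarioError("duration and weight must be positive, noise_sd >= 0")
        evs = sorted(self.events, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if a.start + a.duration > b.start:
                raise ScenarioError(
                    f"planted events overlap: [{a.start}, {a.start + a.duration}) and "
                    f"[{b.start}, ...)")
        for e in evs:
            if e.start < 0 or e.start + e.duration > self.duration:
                raise ScenarioError(f"event at {e.start} s outside the walk")


def _burst_profile(shape: str, n: int, peak: float) -> np.ndarray:
    """Force profile of one burst over n samples, peaking at `peak`."""
    x = np.linspace(0.0, 1.0, n)
    if shape == "triangle":
        return peak * (1.0 - np.abs(2.0 * x - 1.0))
    if shape == "hump":
        return peak * np.sin(np.pi * x) ** 2
    # double-hump: two humps of unequal height, valley well above zero
    return peak * (0.55 + 0.45 * np.cos(4 * np.pi * (x - 0.25))) * np.sin(np.pi * x) ** 0.25


def simulate_walk(sc: WalkScenario) -> tuple[RawTrace, list[PlantedEvent]]:
    """Generate a raw device trace and return it with its ground truth.

    The direction channel is 0 at baseline and takes the planted event's
    sign (+1 dog, -1 handler, 0 both) from ``DIR_LEAD_S`` seconds before
    the burst onset through its end, so attribution from the pre-onset
    sample matches the truth even when smoothing advances the detected
    onset by a sample or two.
    """
    rng = np.random.default_rng(sc.seed)
    dt = 1.0 / sc.rate

    segments = []  # (force array, dir array) per protocol phase
    if sc.include_protocol:
        n_cal = int(round(sc.calibration_s * sc.rate))
        # device dangling: reads its own weight, distinct from the walk baseline
        segments.append((np.full(n_cal, 0.5), np.zeros(n_cal)))
        n_pull = int(round(sc.sync_pull_s * sc.rate))
        n_gap = int(round(1.5 * sc.rate))
        for _ in range(3):
            segments.append((np.zeros(n_gap), np.zeros(n_gap)))
            segments.append((np.full(n_pull, sc.sync_force), np.zeros(n_pull)))
        segments.append((np.zeros(n_gap), np.zeros(n_gap)))

    n_walk = int(round(sc.duration * sc.rate))
    walk_f = np.zeros(n_walk)
    walk_d = np.zeros(n_walk)
    dir_value = {"dog": 1.0, "handler": -1.0, "both": 0.0}
    for ev in sorted(sc.events, key=lambda e: e.start):
        i0 = int(round(ev.start * sc.rate))
        n_ev = max(3, int(round(ev.duration * sc.rate)))
        i1 = min(n_walk, i0 + n_ev)
        walk_f[i0:i1] += _burst_profile(ev.shape, i1 - i0, ev.peak)
        d0 = max(0, i0 - int(round(DIR_LEAD_S * sc.rate)))
        walk_d[d0:i1] = dir_value[ev.direction]
    segments.append((walk_f, walk_d))

    force = np.concatenate([f for f, _ in segments]) + sc.baseline
    dirc = np.concatenate([d for _, d in segments])
    if sc.noise_sd > 0:
        force = force + rng.normal(0.0, sc.noise_sd, len(force))
    lo, hi = DEVICE_SPEC["range_kgf"]
    force = np.clip(force, lo, hi)

    t = np.arange(len(force)) * dt
    if sc.jitter > 0:
        t = t + rng.uniform(-sc.jitter * dt, sc.jitter * dt, len(t))
        t = np.maximum.accumulate(t + np.arange(len(t)) * 1e-9)  # keep strictly increasing
        t -= t[0]

    trace = RawTrace(session_id=sc.session_id, t=t, force=force, dir=dirc)
    return trace, sorted(sc.events, key=lambda e: e.start)


def simulate_behavior_log(
    point_rates: dict | None = None,
    state_fractions: dict | None = None,
    duration: float = 300.0,
    seed: int = 0,
    catalog: EthogramCatalog | None = None,
    session_id: str = "synthetic",
) -> BehaviorLog:
    """Generate a behaviour log with stated point rates (events/s) and
    state percent-of-time targets.

    Point events follow a homogeneous Poisson process; state behaviours
    alternate exponential on/off intervals whose mean lengths give the
    target fraction in expectation (mean bout 10 s on the "on" side).
    """
    catalog = catalog or default_catalog()
    point_rates = point_rates or {}
    state_fractions = state_fractions or {}
    rng = np.random.default_rng(seed)

    points, states = [], []
    for b, rate in point_rates.items():
        if rate < 0:
            raise ParameterError(f"rate for {b!r} must be >= 0")
        if catalog.type_of(b) != POINT:
            raise ParameterError(f"{b!r} is not a point behaviour")
        n = rng.poisson(rate * duration)
        for t in np.sort(rng.uniform(0.0, duration, n)):
            points.append((b, float(t)))
    for b, frac in state_fractions.items():
        if not (0 <= frac <= 100):
            raise ParameterError(f"fraction for {b!r} must be in [0, 100]")
        if catalog.type_of(b) != STATE:
            raise ParameterError(f"{b!r} is not a state behaviour")
        if frac == 0:
            continue
        p = frac / 100.0
        mean_on = 10.0
        mean_off = mean_on * (1.0 - p) / p if p < 1 else 0.0
        t = float(rng.exponential(mean_off)) if mean_off > 0 else 0.0
        while t < duration:
            end = min(duration, t + float(rng.exponential(mean_on)))
            if end > t:
                states.append((b, t, end))
            t = end + (float(rng.exponential(mean_off)) if mean_off > 0 else 0.0)
            if mean_off == 0:
                break
    return BehaviorLog(session_id=session_id, duration=duration,
                       point_events=points, state_events=states)


def simulate_questionnaire(
    n: int,
    factor_means: tuple[float, float] = (4.0, 3.5),
    loading: float = 0.8,
    reversed_items: tuple = (2, 4, 6, 7, 8, 10, 12),
    h_members: tuple = (2, 3, 4, 5, 6, 10, 11),
    d_members: tuple = (1, 7, 8, 9, 12, 13),
    seed: int = 0,
) -> np.ndarray:
    """Generate an n x 13 matrix of Likert responses from a 2-factor model.

    Each item is ``loading * factor + sqrt(1 - loading^2) * noise`` on a
    latent scale centred at its factor's mean, discretised to 1..5.
    Negatively worded items are generated anti-correlated with their
    factor (their latent value is reflected about the scale midpoint).
    """
    if not (0 <= loading <= 1):
        raise ParameterError("loading must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fh = rng.normal(0.0, 1.0, n)
    fd = rng.normal(0.0, 1.0, n)
    out = np.empty((n, 13))
    resid = np.sqrt(1.0 - loading ** 2)
    for j in range(1, 14):
        factor, mean = (fh, factor_means[0]) if j in h_members else (fd, factor_means[1])
        latent = mean + 0.8 * (loading * factor + resid * rng.normal(0.0, 1.0, n))
        if j in reversed_items:
            latent = 6.0 - latent  # reflect: item disagrees when the factor is high
        out[:, j - 1] = np.clip(np.round(latent), 1, 5)
    return out


@dataclass
class CohortScenario:
    """A synthetic study cohort with planted personality effects."""

    n_volunteers: int = 74
    n_dogs: int = 111
    n_walks: int = 370
    #: predictor -> (outcome -> beta on the *transformed* scale)
    effects: dict = field(default_factory=dict)
    #: outcome -> TransformSpec used when planting and back-transforming
    transforms: dict = field(default_factory=dict)
    #: outcome -> intercept on the transformed scale
    intercepts: dict = field(default_factory=dict)
    outcomes: tuple = ("nt_max",)
    volunteer_sd: float = 0.05       # random-intercept SD, transformed scale
    dog_sd: float = 0.05
    residual_sd: float = 0.15
    n_levels: int = 3                # walking levels 1..n_levels
    personality: dict = field(default_factory=lambda: dict(PERSONALITY_DISTRIBUTION))
    seed: int = 0

    def __post_init__(self):
        if self.n_walks < self.n_volunteers:
            raise ScenarioError("need at least one walk per volunteer")
        if min(self.n_volunteers, self.n_dogs) < 2:
            raise ScenarioError("cohort needs >= 2 volunteers and dogs")


@dataclass
class CohortTruth:
    """Planted parameters of a simulated cohort."""

    effects: dict
    intercepts: dict
    volunteer_sd: float
    dog_sd: float
    residual_sd: float
    volunteer_intercepts: dict = field(default_factory=dict)  # outcome -> array
    dog_intercepts: dict = field(default_factory=dict)


def simulate_cohort(sc: CohortScenario) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a tidy one-row-per-walk analysis table plus ground truth.

    Volunteers carry a training level and five personality scores; dogs a
    behavioural level and body weight.  Each walk pairs a volunteer with a
    dog of the same or lower level.  Outcomes are built on the transformed
    scale as intercept + planted fixed effects (on standardised predictors
    where the effect map says so) + volunteer and dog random intercepts +
    residual noise, then back-transformed to the measurement scale.
    """
    rng = np.random.default_rng(sc.seed)

    vol_level = rng.integers(1, sc.n_levels + 1, sc.n_volunteers)
    # ensure at least one volunteer can walk every dog
    vol_level[0] = sc.n_levels
    dog_level = rng.integers(1, sc.n_levels + 1, sc.n_dogs)
    dog_weight = np.clip(rng.normal(20.0, 8.0, sc.n_dogs), 4.0, 60.0)

    personality = {
        d: np.clip(rng.normal(m, s, sc.n_volunteers), 0.0, 48.0)
        for d, (m, s) in sc.personality.items()
    }

    rows = []
    for w in range(sc.n_walks):
        v = w % sc.n_volunteers  # every volunteer walks; remaining walks cycle
        eligible = np.flatnonzero(dog_level <= vol_level[v])
        if len(eligible) == 0:
            raise ScenarioError(f"no dog at or below volunteer level {vol_level[v]}")
        d = int(rng.choice(eligible))
        rows.append({"session_id": f"walk{w:04d}", "volunteer_id": f"V{v:03d}",
                     "dog_id": f"D{d:03d}", "dog_weight": dog_weight[d],
                     "dog_level": int(dog_level[d]), "volunteer_level": int(vol_level[v]),
                     **{k: personality[k][v] for k in personality}})
    df = pd.DataFrame(rows)
    v_idx = df["volunteer_id"].str.slice(1).astype(int).to_numpy()
    d_idx = df["dog_id"].str.slice(1).astype(int).to_numpy()

    truth = CohortTruth(effects={k: dict(v) for k, v in sc.effects.items()},
                        intercepts=dict(sc.intercepts),
                        volunteer_sd=sc.volunteer_sd, dog_sd=sc.dog_sd,
                        residual_sd=sc.residual_sd)

    # standardised predictors so planted betas are per-point of the raw score
    for outcome in sc.outcomes:
        tr = sc.transforms.get(outcome, TransformSpec("log10"))
        u_vol = rng.normal(0.0, sc.volunteer_sd, sc.n_volunteers)
        u_dog = rng.normal(0.0, sc.dog_sd, sc.n_dogs)
        y = np.full(len(df), sc.intercepts.get(outcome, 0.0))
        for pred, outmap in sc.effects.items():
            beta = outmap.get(outcome, 0.0)
            if beta:
                y = y + beta * df[pred].to_numpy(float)
        y = y + u_vol[v_idx] + u_dog[d_idx] + rng.normal(0.0, sc.residual_sd, len(df))
        df[outcome] = tr.invert(y)
        truth.volunteer_intercepts[outcome] = u_vol
        truth.dog_intercepts[outcome] = u_dog

    return df, truth
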