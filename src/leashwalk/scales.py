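"""Questionnaire factor scoring and personality profile validation.

The exit questionnaire is a 13-item instrument on a 1-5 Likert scale.  Half
of the items are negatively worded and must be reverse-scored before
averaging into two factors: a human-satisfaction factor (H) describing how
the handler felt about the walk, and a perception-of-dog factor (D)
describing how well-behaved the handler judged the dog.

.. note::
    The shipped item->factor mapping and reversal sets are a documented
    working default, not an authoritative published key: H covers the
    handler-experience items {2,3,4,5,6,10,11} (2,4,6,10 reversed) and D
    the dog-perception items {1,7,8,9,12,13} (7,8,12 reversed).  Both are
    configurable via :class:`FactorSpec`.

Handler personality enters the pipeline as NEO five-factor domain scores
(neuroticism, extraversion, openness, agreeableness, conscientiousness);
item-level scoring of the proprietary inventory is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from leashwalk.errors import ParameterError, RangeError, UndefinedStatisticError

N_ITEMS = 13
SCALE_MAX = 5

#: Observed envelope of domain scores in a typical volunteer cohort;
#: values outside it are flagged (not rejected) by validate_personality.
OBSERVED_DOMAIN_RANGE = (3.0, 48.0)
DOMAIN_RANGE = (0.0, 48.0)

DOMAINS = ("neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One handler's 13 Likert responses (each 1..5)."""

    items: tuple

    def __post_init__(self):
        if len(self.items) != N_ITEMS:
            raise ParameterError(f"expected {N_ITEMS} items, got {len(self.items)}")
        for i, x in enumerate(self.items, start=1):
            if not (1 <= x <= SCALE_MAX):
                raise RangeError(f"item {i} value {x} outside [1, {SCALE_MAX}]")


@dataclass(frozen=True)
class FactorSpec:
    """Which (1-based) items form a factor and which of them are reversed."""

    name: str
    members: tuple
    reversed_items: tuple = ()

    def __post_init__(self):
        if not self.members:
            raise ParameterError("a factor needs at least one member item")
        if not set(self.reversed_items) <= set(self.members):
            raise ParameterError("reversed items must be a subset of members")
        for i in self.members:
            if not (1 <= i <= N_ITEMS):
                raise ParameterError(f"item index {i} outside 1..{N_ITEMS}")


DEFAULT_FACTOR_H = FactorSpec("H", members=(2, 3, 4, 5, 6, 10, 11),
                              reversed_items=(2, 4, 6, 10))
DEFAULT_FACTOR_D = FactorSpec("D", members=(1, 7, 8, 9, 12, 13),
                              reversed_items=(7, 8, 12))


@dataclass(frozen=True)
class FactorScores:
    factor_h: float
    factor_d: float

    def __post_init__(self):
        for v in (self.factor_h, self.factor_d):
            if not (1 <= v <= SCALE_MAX):
                raise RangeError(f"factor score {v} outside [1, {SCALE_MAX}]")


@dataclass(frozen=True)
class PersonalityProfile:
    """NEO five-factor domain scores."""

    neuroticism: float
    extraversion: float
    openness: float
    agreeableness: float
    conscientiousness: float

    def as_dict(self) -> dict:
        return {d: getattr(self, d) for d in DOMAINS}


def reverse_score(x: float, scale_max: int = SCALE_MAX) -> float:
    """Reverse-code a Likert item: x -> scale_max + 1 - x (an involution)."""
    if not (1 <= x <= scale_max):
        raise RangeError(f"item value {x} outside [1, {scale_max}]")
    return scale_max + 1 - x


def score_factor(resp: QuestionnaireResponse, spec: FactorSpec) -> float:
    """Mean of the factor's member items after reverse-coding the listed
    negatively worded ones; always in [1, 5]."""
    vals = []
    for i in spec.members:
        x = resp.items[i - 1]
        vals.append(reverse_score(x) if i in spec.reversed_items else x)
    return float(np.mean(vals))


def score_questionnaire(
    resp: QuestionnaireResponse,
    spec_h: FactorSpec = DEFAULT_FACTOR_H,
    spec_d: FactorSpec = DEFAULT_FACTOR_D,
) -> FactorScores:
    return FactorScores(factor_h=score_factor(resp, spec_h),
                        factor_d=score_factor(resp, spec_d))


def cronbach_alpha(responses: np.ndarray, reversed_items: tuple = ()) -> float:
    """Cronbach's alpha of an n x k item matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with sample (ddof=1) variances.  Items listed in ``reversed_items``
    (1-based column indices) are reverse-coded first.
    """
    x = np.asarray(responses, dtype=float)
    if x.ndim != 2:
        raise ParameterError("responses must be a 2-D n x k matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ParameterError("need at least 2 respondents and 2 items")
    x = x.copy()
    for i in reversed_items:
        x[:, i - 1] = SCALE_MAX + 1 - x[:, i - 1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


def validate_personality(p: PersonalityProfile) -> dict:
    """Range-check a profile against the instrument's 0-48 domain range.

    Returns per-domain flags: ``ok`` within the typically observed
    envelope, ``outside_observed_envelope`` if legal but beyond it.
    Values outside 0-48 raise a :class:`RangeError`.
    """
    flags = {}
    lo, hi = DOMAIN_RANGE
    obs_lo, obs_hi = OBSERVED_DOMAIN_RANGE
    for domain, value in p.as_dict().items():
        try:
            v = float(value)
        except (TypeError, ValueError):
            raise ParameterError(f"{domain} score must be numeric, got {value!r}") from None
        if not np.isfinite(v) or not (lo <= v <= hi):
            raise RangeError(f"{domain} score {v} outside instrument range [{lo}, {hi}]")
        flags[domain] = "ok" if obs_lo < v < obs_hi else "outside_observed_envelope"
    return flags
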