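"""Generators: determinism, invariant compliance, and end-to-end recovery of
planted ground truth."""

import numpy as np
import pytest

from leashwalk.errors import ParameterError, ScenarioError
from leashwalk.ethogram import summarize_behaviors
from leashwalk.pull_events import DetectionConfig, detect_pull_events
from leashwalk.scales import cronbach_alpha
from leashwalk.signal_prep import interpolate_uniform, smooth, tare
from leashwalk.synthetic import (
    CohortScenario,
    PlantedEvent,
    WalkScenario,
    simulate_behavior_log,
    simulate_cohort,
    simulate_questionnaire,
    simulate_walk,
)
from leashwalk.trace_io import find_sync_pulses


def _detect(trace, weight, rate=10.0):
    uni = smooth(tare(interpolate_uniform(trace, rate)), window=3)
    return detect_pull_events(uni, DetectionConfig(weight)), uni


class TestSimulateWalk:
    def test_deterministic_under_seed(self):
        sc = WalkScenario(duration=60.0, noise_sd=0.1, seed=42,
                          events=[PlantedEvent(10.0, 2.0, 3.0, "dog")])
        a, _ = simulate_walk(sc)
        b, _ = simulate_walk(sc)
        np.testing.assert_array_equal(a.force, b.force)
        np.testing.assert_array_equal(a.t, b.t)

    def test_null_walk_end_to_end(self):
        trace, truth = simulate_walk(WalkScenario(duration=60.0, noise_sd=0.0))
        assert truth == []
        events, _ = _detect(trace, 20.0)
        assert events == []

    def test_planted_events_recovered_with_directions(self):
        events_in = [
            PlantedEvent(10.0, 2.0, 2.5, "dog", "triangle"),
            PlantedEvent(30.0, 1.5, 1.0, "handler", "hump"),
            PlantedEvent(50.0, 2.5, 3.5, "dog", "hump"),
            PlantedEvent(70.0, 1.0, 0.8, "handler", "triangle"),
            PlantedEvent(90.0, 2.0, 1.5, "dog", "triangle"),
        ]
        sc = WalkScenario(duration=120.0, dog_weight=20.0, events=events_in,
                          noise_sd=0.0)
        trace, truth = simulate_walk(sc)
        detected, _ = _detect(trace, sc.dog_weight)
        assert len(detected) == len(truth)
        for det, tru in zip(detected, truth):
            assert det.direction == tru.direction
            assert det.peak_index / 10.0 == pytest.approx(
                tru.start + tru.duration / 2, abs=0.5)

    def test_double_hump_yields_two_events(self):
        sc = WalkScenario(duration=30.0, events=[
            PlantedEvent(10.0, 3.0, 2.0, "dog", "double-hump")], noise_sd=0.0)
        trace, truth = simulate_walk(sc)
        assert truth[0].n_pulls == 2
        detected, _ = _detect(trace, 20.0)
        assert len(detected) == 2
        assert all(e.direction == "dog" for e in detected)

    def test_protocol_segmentation(self):
        sc = WalkScenario(duration=60.0, include_protocol=True, noise_sd=0.0,
                          events=[PlantedEvent(20.0, 2.0, 2.0, "dog")])
        trace, _ = simulate_walk(sc)
        seg = find_sync_pulses(trace)
        assert len(seg.sync_pulses) == 3
        # calibration hold covers the first ~10 s
        assert seg.calibration[0] == 0 and seg.calibration[1] >= 95

    def test_overlapping_events_rejected(self):
        with pytest.raises(ScenarioError):
            WalkScenario(duration=60.0, events=[
                PlantedEvent(10.0, 5.0, 1.0, "dog"),
                PlantedEvent(12.0, 5.0, 1.0, "handler")])

    def test_jitter_still_monotone(self):
        sc = WalkScenario(duration=30.0, jitter=0.2, seed=3,
                          events=[PlantedEvent(10.0, 2.0, 2.0, "dog")])
        trace, _ = simulate_walk(sc)
        assert np.all(np.diff(trace.t) > 0)


class TestSimulateBehaviorLog:
    def test_zero_rate_no_events(self, catalog):
        log = simulate_behavior_log({"gaze": 0.0}, {}, duration=100.0, seed=1)
        assert log.point_events == []

    def test_poisson_rate_recovered(self, catalog):
        log = simulate_behavior_log({"gaze": 0.04}, {}, duration=10_000.0, seed=2)
        s = summarize_behaviors(log, catalog)
        assert s.rates["gaze"] == pytest.approx(0.04, rel=0.05)

    def test_state_fraction_recovered(self, catalog):
        log = simulate_behavior_log({}, {"sniff": 20.0}, duration=50_000.0, seed=3)
        s = summarize_behaviors(log, catalog)
        assert s.fractions["sniff"] == pytest.approx(20.0, abs=2.0)

    def test_log_valid_against_catalog(self, catalog):
        log = simulate_behavior_log({"gaze": 0.05, "praise": 0.01},
                                    {"pant": 30.0}, duration=300.0, seed=4)
        log.validate(catalog)  # raises on any violation

    def test_fraction_above_100_rejected(self):
        with pytest.raises(ParameterError):
            simulate_behavior_log({}, {"sniff": 120.0}, duration=100.0)


class TestSimulateQuestionnaire:
    def test_full_loading_perfect_alpha(self):
        x = simulate_questionnaire(500, loading=1.0, seed=5)
        h_cols = [i - 1 for i in (2, 3, 4, 5, 6, 10, 11)]
        rev = tuple(k + 1 for k, i in enumerate((2, 3, 4, 5, 6, 10, 11))
                    if i in (2, 4, 6, 10))
        a = cronbach_alpha(x[:, h_cols], reversed_items=rev)
        assert a > 0.9  # discretisation keeps it just below 1

    def test_zero_loading_alpha_near_zero(self):
        x = simulate_questionnaire(20_000, loading=0.0, seed=6)
        h_cols = [i - 1 for i in (2, 3, 4, 5, 6, 10, 11)]
        a = cronbach_alpha(x[:, h_cols])
        assert abs(a) < 0.05

    def test_reversed_items_anticorrelated(self):
        x = simulate_questionnaire(20_000, loading=0.9, seed=7)
        # item 3 (positive) and item 4 (reversed) load on the same factor
        r = np.corrcoef(x[:, 2], x[:, 3])[0, 1]
        assert r < -0.3

    def test_values_are_likert(self):
        x = simulate_questionnaire(1000, seed=8)
        assert x.min() >= 1 and x.max() <= 5
        assert np.array_equal(x, np.round(x))


class TestSimulateCohort:
    def test_null_cohort_constant_outcome(self):
        from leashwalk.association import TransformSpec
        sc = CohortScenario(n_volunteers=10, n_dogs=12, n_walks=40,
                            volunteer_sd=0.0, dog_sd=0.0, residual_sd=0.0,
                            intercepts={"nt_max": 0.3},
                            transforms={"nt_max": TransformSpec("log10")},
                            seed=9)
        df, _ = simulate_cohort(sc)
        np.testing.assert_allclose(df["nt_max"], 10 ** 0.3, rtol=1e-12)

    def test_level_compatibility(self):
        df, _ = simulate_cohort(CohortScenario(seed=10))
        assert (df["dog_level"] <= df["volunteer_level"]).all()

    def test_determinism(self):
        a, _ = simulate_cohort(CohortScenario(seed=11))
        b, _ = simulate_cohort(CohortScenario(seed=11))
        assert a.equals(b)

    def test_intraclass_correlation_matches_variance_ratio(self):
        """Null outcome: the volunteer variance share matches the configured
        variance components within Monte-Carlo error."""
        from leashwalk.association import TransformSpec, fit_mixed, ModelSpec
        sc = CohortScenario(n_volunteers=40, n_dogs=50, n_walks=800,
                            volunteer_sd=0.2, dog_sd=0.1, residual_sd=0.1,
                            transforms={"nt_max": TransformSpec("identity")},
                            seed=12)
        df, _ = simulate_cohort(sc)
        res = fit_mixed(df, ModelSpec("nt_max", TransformSpec("identity"),
                                      forced=()))
        total = sum(res.vc_variances.values()) + res.residual_variance
        icc_vol = res.vc_variances["volunteer_id"] / total
        expected = 0.04 / (0.04 + 0.01 + 0.01)
        assert icc_vol == pytest.approx(expected, abs=0.15)
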