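"""Outcome transforms, screening, mixed-model fitting, backward elimination
and VIF checks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from leashwalk.association import (
    ModelSpec,
    TransformSpec,
    WalkAssociationModel,
    backward_eliminate,
    bivariate_screen,
    fit_mixed,
    transform_outcome,
    vif_check,
)
from leashwalk.errors import ParameterError, RangeError
from leashwalk.synthetic import CohortScenario, simulate_cohort

FORCED = ("neuroticism", "extraversion", "openness", "agreeableness",
          "conscientiousness", "dog_level")


def _null_cohort(seed=0, **kw):
    sc = CohortScenario(n_volunteers=30, n_dogs=40, n_walks=150,
                        outcomes=("nt_max",), seed=seed, **kw)
    df, _ = simulate_cohort(sc)
    return df


class TestTransform:
    def test_power_half(self):
        assert transform_outcome([0.04], TransformSpec("power", 0.5))[0] == pytest.approx(0.2)

    def test_log10(self):
        assert transform_outcome([1.0], TransformSpec("log10"))[0] == 0.0

    def test_power_round_trip(self):
        spec = TransformSpec("power", 10.0)
        x = np.array([0.3, 1.2, 2.0])
        np.testing.assert_allclose(spec.invert(spec.apply(x)), x, rtol=1e-12)

    def test_log10_of_nonpositive_names_row(self):
        with pytest.raises(RangeError, match=r"row\(s\): \[2\]"):
            transform_outcome([1.0, 2.0, 0.0], TransformSpec("log10"))

    def test_bad_specs(self):
        with pytest.raises(ParameterError):
            TransformSpec("power", 0.0)
        with pytest.raises(ParameterError):
            TransformSpec("boxcox")


class TestScreen:
    def test_rule_p_boundaries(self, rng):
        n = 400
        df = _null_cohort(seed=3)
        df["strong"] = 0.5 * np.log10(df["nt_max"]) + rng.normal(0, 0.01, len(df))
        df["noise"] = rng.normal(size=len(df))
        kept = bivariate_screen(df, "nt_max", ["strong", "noise"], forced=FORCED,
                                transform=TransformSpec("log10"))
        assert "strong" in kept
        assert set(FORCED) <= set(kept)  # forced retained regardless of p

    def test_constant_candidate_excluded_with_warning(self):
        df = _null_cohort(seed=4)
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            kept = bivariate_screen(df, "nt_max", ["flat"], forced=FORCED,
                                    transform=TransformSpec("log10"))
        assert "flat" not in kept

    def test_true_predictor_usually_passes(self):
        """A planted effect at study scale passes the p<0.2 screen nearly always."""
        passes = 0
        reps = 25
        for s in range(reps):
            sc = CohortScenario(
                n_volunteers=74, n_dogs=111, n_walks=370,
                effects={"neuroticism": {"nt_max": 0.01}},
                transforms={"nt_max": TransformSpec("log10")},
                volunteer_sd=0.05, dog_sd=0.05, residual_sd=0.15, seed=100 + s)
            df, _ = simulate_cohort(sc)
            model = WalkAssociationModel(
                df, ModelSpec("nt_max", TransformSpec("log10"), forced=(),
                              screened=("neuroticism",)))
            passes += "neuroticism" in model.screen()
        assert passes >= int(0.9 * reps)


class TestFitMixed:
    def test_zero_variance_matches_ols(self, rng):
        """With both variance components estimated at the zero boundary the
        mixed fit reduces to ordinary least squares."""
        n = 200
        df = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            "volunteer_id": [f"V{i%20}" for i in range(n)],
            "dog_id": [f"D{i%30}" for i in range(n)],
        })
        # residuals orthogonal to both grouping factors: no between-group
        # variance, so the ML variance components collapse to zero
        e = rng.normal(0, 0.2, n)
        D = np.column_stack([pd.get_dummies(df.volunteer_id).to_numpy(float),
                             pd.get_dummies(df.dog_id).to_numpy(float)])
        e = e - D @ np.linalg.lstsq(D, e, rcond=None)[0]
        df["y"] = 1.0 + 0.5 * df.x1 - 0.3 * df.x2 + e
        spec = ModelSpec("y", forced=("x1", "x2"))
        res = fit_mixed(df, spec)
        assert max(res.vc_variances.values()) < 1e-6
        ols = sm.OLS(df.y, sm.add_constant(df[["x1", "x2"]])).fit()
        assert res.params["x1"] == pytest.approx(ols.params["x1"], abs=1e-6)
        assert res.params["x2"] == pytest.approx(ols.params["x2"], abs=1e-6)

    def test_recovers_variance_components(self):
        sc = CohortScenario(n_volunteers=60, n_dogs=80, n_walks=600,
                            volunteer_sd=0.3, dog_sd=0.2, residual_sd=0.1,
                            transforms={"nt_max": TransformSpec("identity")},
                            seed=11)
        df, truth = simulate_cohort(sc)
        res = fit_mixed(df, ModelSpec("nt_max", TransformSpec("identity"),
                                      forced=("neuroticism",)))
        assert res.vc_variances["volunteer_id"] == pytest.approx(0.09, rel=0.6)
        assert res.vc_variances["dog_id"] == pytest.approx(0.04, rel=0.8)
        assert res.residual_variance == pytest.approx(0.01, rel=0.5)

    def test_singular_design_lists_aliased(self):
        df = _null_cohort(seed=5)
        df["dup"] = df["neuroticism"]
        spec = ModelSpec("nt_max", TransformSpec("log10"),
                         forced=("neuroticism", "dup"))
        with pytest.raises(ParameterError, match="dup"):
            fit_mixed(df, spec)

    def test_missing_column(self):
        df = _null_cohort(seed=6).drop(columns=["dog_level"])
        with pytest.raises(ParameterError, match="dog_level"):
            fit_mixed(df, ModelSpec("nt_max", TransformSpec("log10")))

    def test_summary_renders(self):
        df = _null_cohort(seed=7)
        res = fit_mixed(df, ModelSpec("nt_max", TransformSpec("log10")))
        text = res.summary()
        assert "BIC" in text and "neuroticism" in text and "(forced)" in text


class TestBackwardElimination:
    def test_trace_is_deterministic(self):
        df = _null_cohort(seed=8)
        df["junk1"] = np.random.default_rng(1).normal(size=len(df))
        df["junk2"] = np.random.default_rng(2).normal(size=len(df))
        spec = ModelSpec("nt_max", TransformSpec("log10"),
                         screened=("junk1", "junk2"))
        a = backward_eliminate(df, spec, screen=False)
        b = backward_eliminate(df, spec, screen=False)
        assert a.elimination_trace == b.elimination_trace
        assert a.bic_path == b.bic_path

    def test_forced_never_removed(self):
        df = _null_cohort(seed=9)
        df["junk"] = np.random.default_rng(3).normal(size=len(df))
        res = backward_eliminate(
            df, ModelSpec("nt_max", TransformSpec("log10"), screened=("junk",)),
            screen=False)
        removed = {name for name, _, _ in res.elimination_trace}
        assert not (removed & set(FORCED))
        assert set(FORCED) <= set(res.predictors)

    def test_final_nonforced_all_significant(self):
        df = _null_cohort(seed=10)
        rng = np.random.default_rng(4)
        for j in range(3):
            df[f"junk{j}"] = rng.normal(size=len(df))
        res = backward_eliminate(
            df, ModelSpec("nt_max", TransformSpec("log10"),
                          screened=("junk0", "junk1", "junk2")), screen=False)
        for p in res.predictors:
            if p not in FORCED and p != "Intercept":
                assert res.pvalues[p] < 0.05
        assert len(res.bic_path) == len(res.elimination_trace) + 1

    def test_pure_noise_removed_before_signal(self):
        """A noise candidate is eliminated while a strong one survives."""
        sc = CohortScenario(n_volunteers=40, n_dogs=60, n_walks=300,
                            effects={"neuroticism": {"nt_max": 0.02}},
                            transforms={"nt_max": TransformSpec("log10")},
                            residual_sd=0.1, seed=12)
        df, _ = simulate_cohort(sc)
        df["junk"] = np.random.default_rng(5).normal(size=len(df))
        res = backward_eliminate(
            df, ModelSpec("nt_max", TransformSpec("log10"), forced=(),
                          screened=("neuroticism", "junk")), screen=False)
        assert "neuroticism" in res.predictors
        assert "junk" not in res.predictors


class TestVIF:
    def test_orthogonal_predictors_unity(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({"a": np.sin(2 * np.pi * t / n),
                          "b": np.cos(2 * np.pi * t / n)})
        v = vif_check(X)
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-10)

    def test_correlated_pair_closed_form(self, rng):
        # two predictors with sample correlation exactly 0.6
        g = rng.normal(size=2000)
        h = rng.normal(size=2000)
        g = (g - g.mean()) / g.std()
        h -= h @ g / (g @ g) * g
        h = (h - h.mean()) / h.std()
        x2 = 0.6 * g + np.sqrt(1 - 0.36) * h
        v = vif_check(pd.DataFrame({"a": g, "b": x2}))
        assert v["a"] == pytest.approx(1.5625, abs=1e-6)
        assert v["b"] == pytest.approx(1.5625, abs=1e-6)

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.normal(size=100)
        v = vif_check(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_too_few_predictors(self, rng):
        with pytest.raises(ParameterError):
            vif_check(pd.DataFrame({"a": rng.normal(size=10)}))
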