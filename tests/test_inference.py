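"""Inference tests: AIC bookkeeping against hand computation, closed-form
OLS special cases, the 2-unit selection rule, backward elimination with
marginality, the random-intercept LRT and marginal-mean post hocs."""

import numpy as np
import pandas as pd
import pytest

from chromashift.inference import (
    ModelFit,
    ModelSpec,
    compare_models,
    default_ladder,
    fit_model,
    posthoc_means,
    prepare_model_frame,
    simplify_model,
    test_random_effect as random_effect_lrt,
)
from chromashift.synthetic_data import (
    EffectModel,
    generate_shift_dataset,
    infection_design,
    social_design,
)

MAINS = (("line",), ("treatment",), ("time",))
FULL = MAINS + (("line", "treatment"), ("line", "time"), ("treatment", "time"),
                ("line", "treatment", "time"))


def _frame(design, model, seed, response="L"):
    shifts = generate_shift_dataset(design, model, seed=seed, attribute=response)
    return prepare_model_frame(shifts, response)


def _manual_frame(deltas, times=None):
    n = len(deltas)
    return pd.DataFrame(
        {
            "individual_id": [f"f{i}" for i in range(n)],
            "line": ["DAN", "R"] * (n // 2) + ["DAN"] * (n % 2),
            "treatment": ["control"] * n,
            "time": times if times is not None else [24.0] * n,
            "delta": deltas,
        }
    )


class TestModelSpec:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec(response="L", fixed=(("line",), ("line", "treatment")))

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            ModelSpec(response="L", fixed=(("colour",),))

    def test_default_ladder_is_the_four_candidates(self):
        ladder = default_ladder("L")
        assert len(ladder) == 4
        assert {s.random_intercept for s in ladder} == {True, False}
        assert {s.n_interactions for s in ladder} == {0, 4}


class TestFitModel:
    def test_aic_identity_against_hand_computation(self):
        # 10-row fixture, intercept-only OLS: logLik and AIC from first principles
        deltas = np.array([1.2, -0.5, 0.3, 2.1, -1.7, 0.8, 0.0, 1.1, -0.9, 0.4])
        fit = fit_model(
            _manual_frame(deltas), ModelSpec("L", fixed=(), random_intercept=False)
        )
        n = len(deltas)
        sigma2 = np.sum((deltas - deltas.mean()) ** 2) / n  # ML variance
        llf_hand = -n / 2.0 * (np.log(2 * np.pi * sigma2) + 1.0)
        assert fit.loglik == pytest.approx(llf_hand, abs=1e-9)
        assert fit.k_params == 2  # intercept + residual variance
        assert fit.aic == pytest.approx(2 * 2 - 2 * llf_hand, abs=1e-9)

    def test_ols_closed_form_on_five_points(self):
        times = np.array([0.0, 12.0, 24.0, 36.0, 48.0])
        deltas = np.array([0.5, 1.9, 2.2, 4.1, 4.6])
        fit = fit_model(
            _manual_frame(deltas, times=times),
            ModelSpec("L", fixed=(("time",),), random_intercept=False),
        )
        slope = np.sum((times - times.mean()) * (deltas - deltas.mean())) / np.sum(
            (times - times.mean()) ** 2
        )
        intercept = deltas.mean() - slope * times.mean()
        assert fit.params.loc["time", "estimate"] == pytest.approx(slope, abs=1e-12)
        assert fit.params.loc["Intercept", "estimate"] == pytest.approx(intercept, abs=1e-12)

    def test_intercept_only_estimate_is_sample_mean(self):
        deltas = np.array([3.0, 5.0, 4.0, 6.0, 2.0, 4.0])
        fit = fit_model(_manual_frame(deltas), ModelSpec("L", fixed=(), random_intercept=False))
        assert fit.params.loc["Intercept", "estimate"] == pytest.approx(deltas.mean())

    def test_near_zero_noise_recovers_generating_coefficients(self):
        beta = {"line[R]": -1.5, "treatment[infected]": 2.25, "time": 0.08}
        model = EffectModel(intercept=0.7, effects=beta, sd_individual=0.0, sd_residual=1e-8)
        frame = _frame(infection_design(), model, seed=1)
        fit = fit_model(frame, ModelSpec("L", fixed=MAINS, random_intercept=True))
        assert fit.params.loc["Intercept", "estimate"] == pytest.approx(0.7, abs=1e-4)
        for term, value in beta.items():
            assert fit.params.loc[term, "estimate"] == pytest.approx(value, abs=1e-4)

    def test_coefficient_table_layout(self):
        frame = _frame(infection_design(), EffectModel(effects={"time": 0.05}), seed=2)
        fit = fit_model(frame, ModelSpec("L", fixed=MAINS, random_intercept=True))
        assert list(fit.params.columns) == ["estimate", "std_error", "df", "t_value", "p_value"]
        assert fit.sigma_u is not None and fit.sigma_u >= 0

    def test_non_finite_response_rejected(self):
        frame = _manual_frame(np.array([1.0, np.nan, 2.0, 1.0]))
        with pytest.raises(ValueError, match="non-finite"):
            fit_model(frame, ModelSpec("L", fixed=(), random_intercept=False))


def _stub(aic, k, fixed=(), random_intercept=False, n_obs=240):
    spec = ModelSpec("L", fixed=fixed, random_intercept=random_intercept)
    return ModelFit(
        spec=spec,
        method="ML",
        formula="delta ~ 1",
        params=pd.DataFrame(),
        loglik=(2.0 * k - aic) / 2.0,
        k_params=k,
        aic=aic,
        n_obs=n_obs,
        sigma_resid=1.0,
    )


class TestCompareModels:
    def test_identical_models_pick_either_deterministically(self):
        comp = compare_models([_stub(100.0, 5), _stub(100.0, 5)])
        assert comp.chosen.aic == 100.0
        assert comp.equivalence[(0, 1)]

    @pytest.mark.parametrize("delta", [0.0, 0.5, 1.0, 1.9, 1.999])
    def test_within_two_units_simplest_wins(self, delta):
        big = _stub(100.0, 8, fixed=MAINS)
        small = _stub(100.0 + delta, 4)
        comp = compare_models([big, small])
        assert comp.chosen is small

    @pytest.mark.parametrize("delta", [2.0, 2.1, 3.0, 10.0])
    def test_beyond_two_units_lower_aic_wins(self, delta):
        big = _stub(100.0, 8, fixed=MAINS)
        small = _stub(100.0 + delta, 4)
        comp = compare_models([big, small])
        assert comp.chosen is big

    def test_tie_break_prefers_no_random_intercept(self):
        with_re = _stub(100.0, 5, fixed=MAINS, random_intercept=True)
        without = _stub(101.0, 5, fixed=MAINS, random_intercept=False)
        assert compare_models([with_re, without]).chosen is without

    def test_mixed_ml_reml_input_rejected(self):
        reml = pd.DataFrame()
        good = _stub(100.0, 4)
        bad = ModelFit(
            spec=good.spec, method="REML", formula="", params=reml, loglik=0.0,
            k_params=4, aic=8.0, n_obs=240, sigma_resid=1.0,
        )
        with pytest.raises(ValueError, match="ML"):
            compare_models([good, bad])

    def test_different_observation_counts_rejected(self):
        with pytest.raises(ValueError, match="identical observations"):
            compare_models([_stub(100.0, 4, n_obs=240), _stub(99.0, 4, n_obs=156)])

    def test_row_order_invariance_of_ml_comparison(self):
        model = EffectModel(effects={"treatment[infected]": 3.0}, sd_individual=2.0)
        frame = _frame(infection_design(), model, seed=5)
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        for spec in default_ladder("L"):
            a = fit_model(frame, spec)
            b = fit_model(shuffled, spec)
            assert a.aic == pytest.approx(b.aic, abs=1e-6)


class TestSimplify:
    def test_strong_treatment_effect_always_retained(self):
        model = EffectModel(
            intercept=0.0, effects={"treatment[infected]": 6.0}, sd_individual=1.0,
            sd_residual=3.0,
        )
        for seed in range(6):
            frame = _frame(infection_design(), model, seed=seed)
            start = fit_model(frame, ModelSpec("L", fixed=MAINS, random_intercept=True))
            final = simplify_model(start, frame)
            assert ("treatment",) in final.spec.fixed

    def test_interaction_retained_with_its_main_effects(self):
        model = EffectModel(
            intercept=0.0,
            effects={
                "line[R]": 1.0,
                "treatment[infected]": 1.0,
                "time": 0.0,
                "line[R]:treatment[infected]": 6.0,
            },
            sd_individual=1.0,
            sd_residual=2.0,
        )
        frame = _frame(infection_design(), model, seed=11)
        start = fit_model(frame, ModelSpec("L", fixed=FULL, random_intercept=True))
        final = simplify_model(start, frame)
        assert ("line", "treatment") in final.spec.fixed
        assert ("line",) in final.spec.fixed and ("treatment",) in final.spec.fixed

    def test_elimination_path_recorded_and_aic_monotone(self):
        model = EffectModel(effects={"treatment[infected]": 4.0}, sd_individual=1.0)
        frame = _frame(infection_design(), model, seed=21)
        start = fit_model(frame, ModelSpec("L", fixed=FULL, random_intercept=True))
        final = simplify_model(start, frame)
        aics = [start.aic] + [after for _, _, after in final.elimination_path]
        assert all(b < a for a, b in zip(aics, aics[1:]))


class TestRandomEffectTest:
    def test_chi_square_zero_for_identical_likelihoods(self):
        frame = _frame(infection_design(), EffectModel(sd_individual=2.0), seed=3)
        fit = fit_model(frame, ModelSpec("L", fixed=MAINS, random_intercept=True))
        assert 2.0 * (fit.loglik - fit.loglik) == 0.0

    def test_null_individual_effect_gives_small_statistic(self):
        model = EffectModel(intercept=1.0, sd_individual=0.0, sd_residual=4.0)
        frame = _frame(infection_design(), model, seed=8)
        res = random_effect_lrt(
            frame,
            ModelSpec("L", fixed=MAINS, random_intercept=True),
            ModelSpec("L", fixed=MAINS, random_intercept=False),
        )
        assert res.statistic >= 0.0
        assert res.df == 1
        assert res.p_value > 0.05

    def test_high_icc_strongly_significant(self):
        model = EffectModel(intercept=1.0, sd_individual=4.0, sd_residual=4.0)
        frame = _frame(infection_design(), model, seed=13)
        res = random_effect_lrt(
            frame,
            ModelSpec("L", fixed=MAINS, random_intercept=True),
            ModelSpec("L", fixed=MAINS, random_intercept=False),
        )
        assert res.p_value < 0.001

    def test_specs_must_differ_only_in_random_intercept(self):
        frame = _frame(infection_design(), EffectModel(), seed=1)
        with pytest.raises(ValueError, match="identical apart"):
            random_effect_lrt(
                frame,
                ModelSpec("L", fixed=MAINS, random_intercept=True),
                ModelSpec("L", fixed=MAINS[:2], random_intercept=False),
            )


class TestPosthocMeans:
    def test_two_level_factor_adjusted_equals_raw(self):
        model = EffectModel(effects={"treatment[infected]": 3.0}, sd_individual=1.0)
        frame = _frame(infection_design(), model, seed=4)
        fit = fit_model(frame, ModelSpec("L", fixed=MAINS, random_intercept=True))
        comps = posthoc_means(fit, "treatment")
        assert len(comps) == 1
        assert comps[0].p_adjusted == pytest.approx(comps[0].p_raw, rel=1e-6)

    def test_balanced_one_factor_marginal_means_equal_cell_means(self):
        model = EffectModel(effects={"treatment[infected]": 3.0}, sd_individual=0.0)
        frame = _frame(infection_design(), model, seed=6)
        fit = fit_model(
            frame, ModelSpec("L", fixed=(("treatment",),), random_intercept=False)
        )
        (comp,) = posthoc_means(fit, "treatment")
        cell_diff = (
            frame.loc[frame.treatment == "control", "delta"].mean()
            - frame.loc[frame.treatment == "infected", "delta"].mean()
        )
        assert comp.estimate == pytest.approx(cell_diff, abs=1e-9)

    def test_three_level_ordered_means_sign_pattern(self):
        # high-power social simulation: control < single < group
        model = EffectModel(
            effects={"treatment[single]": 4.0, "treatment[group]": 8.0},
            sd_individual=1.0,
            sd_residual=2.0,
        )
        frame = _frame(social_design(), model, seed=15)
        fit = fit_model(frame, ModelSpec("L", fixed=MAINS, random_intercept=True))
        comps = {(c.level_a, c.level_b): c for c in posthoc_means(fit, "treatment")}
        assert len(comps) == 3
        assert comps[("control", "single")].estimate < 0
        assert comps[("control", "group")].estimate < 0
        assert comps[("group", "single")].estimate > 0
        assert all(c.p_adjusted >= c.p_raw - 1e-12 for c in comps.values())

    def test_absent_factor_rejected(self):
        frame = _frame(infection_design(), EffectModel(), seed=2)
        fit = fit_model(frame, ModelSpec("L", fixed=(("time",),), random_intercept=False))
        with pytest.raises(ValueError, match="not in the fitted model"):
            posthoc_means(fit, "treatment")

    def test_continuous_factor_rejected(self):
        frame = _frame(infection_design(), EffectModel(), seed=2)
        fit = fit_model(frame, ModelSpec("L", fixed=MAINS, random_intercept=False))
        with pytest.raises(ValueError, match="continuous"):
            posthoc_means(fit, "time")
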