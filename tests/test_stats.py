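"""Tests for the mixed-model analysis and its Monte-Carlo validators."""

import numpy as np
import pandas as pd
import pytest

from cortiquant import (
    ConfigError,
    DataError,
    DensityMixedModel,
    FitError,
    ModelSpec,
    StudyGenConfig,
    fit_mixed_model,
    log_transform_outcomes,
    simulate_observations,
    type1_error_check,
)


def one_arm_config(effects, punches=20, sections=4, seed=0, **kw):
    arms = tuple({a for a, _ in effects})
    conds = tuple(dict.fromkeys(c for _, c in effects))
    return StudyGenConfig(
        arms=arms, conditions=conds,
        punches_per_condition=punches,
        density_sections_per_punch=sections,
        proliferation_sections_per_punch=0,
        arm_condition_effects=effects,
        seed=seed, **kw,
    )


class TestLogTransform:
    def test_examples(self):
        df = pd.DataFrame({"raw_per_mm2": [0.0, 9.0, 99.0]})
        out = log_transform_outcomes(df)
        assert out["log_value"].tolist() == pytest.approx([0.0, 1.0, 2.0])

    def test_elementwise_matches_recomputation(self, rng):
        raw = rng.uniform(0, 50, size=200)
        out = log_transform_outcomes(pd.DataFrame({"raw_per_mm2": raw}))
        assert np.allclose(out["log_value"], np.log10(raw + 1.0))

    def test_idempotent(self):
        df = pd.DataFrame({"raw_per_mm2": [3.0], "log_value": [0.60206]})
        out = log_transform_outcomes(log_transform_outcomes(df))
        assert out["log_value"].iloc[0] == pytest.approx(0.60206)

    def test_negative_raw_rejected(self):
        with pytest.raises(DataError):
            log_transform_outcomes(pd.DataFrame({"raw_per_mm2": [-1.0]}))


class TestMixedModelFit:
    def test_single_cell_intercept_is_sample_mean(self):
        cfg = one_arm_config({("S1P", "F"): 1.2}, punches=15, sections=4,
                             fragment_sd=0.0, residual_sd=0.1)
        obs = simulate_observations(cfg)
        fit = fit_mixed_model(obs, ModelSpec())
        assert fit.fixed_effects["estimate"].iloc[0] == pytest.approx(
            obs["log_value"].mean(), abs=1e-8
        )
        assert fit.contrasts == []

    def test_matches_ols_when_no_fragment_variance(self):
        """With fragment_sd = 0 and a balanced design, the REML cell means
        coincide with the ordinary least-squares (group mean) oracle."""
        effects = {("S1P", "F"): 1.2, ("S1P", "F-T"): 1.0,
                   ("S1P", "D2"): 0.4, ("S1P", "D6"): 0.6}
        cfg = one_arm_config(effects, punches=25, sections=6,
                             fragment_sd=0.0, residual_sd=0.1, seed=5)
        obs = simulate_observations(cfg)
        fit = fit_mixed_model(obs, ModelSpec())
        ols = obs.groupby(["arm", "condition"])["log_value"].mean()
        for row in fit.fixed_effects.itertuples(index=False):
            assert row.estimate == pytest.approx(
                ols[(row.arm, row.condition)], abs=1e-6
            )

    def test_recovers_known_effects(self):
        effects = {("S1P", "F"): 1.2, ("S1P", "F-T"): 1.0,
                   ("S1P", "D2"): 0.4, ("S1P", "D6"): 0.6}
        cfg = one_arm_config(effects, punches=50, sections=12,
                             fragment_sd=0.2, residual_sd=0.1, seed=1)
        fit = fit_mixed_model(simulate_observations(cfg), ModelSpec())
        for row in fit.fixed_effects.itertuples(index=False):
            true = effects[(row.arm, row.condition)]
            assert row.estimate == pytest.approx(true, abs=4 * row.se)
        assert fit.fragment_var == pytest.approx(0.04, rel=0.5)
        assert fit.residual_var == pytest.approx(0.01, rel=0.3)

    def test_contrast_families_full_design(self):
        cfg = StudyGenConfig(punches_per_condition=2,
                             density_sections_per_punch=2,
                             proliferation_sections_per_punch=0, seed=3)
        fit = fit_mixed_model(simulate_observations(cfg), ModelSpec())
        within = [c for c in fit.contrasts if c.family == "within_arm"]
        between = [c for c in fit.contrasts if c.family == "between_arm"]
        assert len(within) == 4 * 3  # per arm: F~F-T, F-T~D2, D2~D6
        assert len(between) == 2 * 4  # drug vs vehicle, at each condition
        pairs = {c.pair for c in between}
        assert ("CT_NaOH:F", "S1P:F") in pairs
        assert ("CT_DMSO:D6", "ZVAD:D6") in pairs

    def test_alpha_reflag_without_refit(self):
        cfg = StudyGenConfig(punches_per_condition=2,
                             density_sections_per_punch=2,
                             proliferation_sections_per_punch=0, seed=3)
        fit = fit_mixed_model(simulate_observations(cfg), ModelSpec(alpha=0.01))
        for c in fit.contrasts:
            assert c.significant == (c.p_value < 0.01)
        refl = fit.with_alpha(0.5)
        for c in refl.contrasts:
            assert c.significant == (c.p_value < 0.5)
        assert [c.p_value for c in refl.contrasts] == [
            c.p_value for c in fit.contrasts
        ]

    def test_empty_cell_dropped_with_warning(self, caplog):
        effects = {("S1P", "F"): 1.0, ("S1P", "F-T"): 1.0,
                   ("CT_NaOH", "F"): 1.0, ("CT_NaOH", "F-T"): 1.0}
        cfg = StudyGenConfig(arms=("S1P", "CT_NaOH"), conditions=("F", "F-T"),
                             punches_per_condition=4,
                             density_sections_per_punch=2,
                             proliferation_sections_per_punch=0,
                             arm_condition_effects=effects, seed=0)
        obs = simulate_observations(cfg)
        obs = obs[~((obs.arm == "S1P") & (obs.condition == "F-T"))]
        import logging

        with caplog.at_level(logging.WARNING, logger="cortiquant.stats"):
            fit = fit_mixed_model(obs, ModelSpec())
        assert len(fit.fixed_effects) == 3
        assert any("empty design cell" in r.message for r in caplog.records)
        with pytest.raises(FitError):
            fit_mixed_model(obs, ModelSpec(drop_empty_cells=False))

    def test_estimator_api(self):
        from sklearn.base import clone

        cfg = StudyGenConfig(punches_per_condition=2,
                             density_sections_per_punch=2,
                             proliferation_sections_per_punch=0, seed=3)
        obs = simulate_observations(cfg)
        est = DensityMixedModel(alpha=0.01)
        assert clone(est).get_params() == est.get_params()
        est.fit(obs)
        assert est.fixed_effects_.shape[0] == 16
        assert est.fragment_var_ >= 0 and est.residual_var_ >= 0
        preds = est.predict(obs.head(5))
        assert len(preds) == 5


class TestType1Check:
    @staticmethod
    def null_config(**kw):
        effects = {(a, c): 1.2 for a in ("S1P", "CT_NaOH") for c in ("F", "F-T")}
        base = dict(
            arms=("S1P", "CT_NaOH"), conditions=("F", "F-T"),
            punches_per_condition=6, density_sections_per_punch=2,
            proliferation_sections_per_punch=0,
            arm_condition_effects=effects,
        )
        base.update(kw)
        return StudyGenConfig(**base)

    def test_alpha_zero_never_rejects(self):
        res = type1_error_check(self.null_config(), ModelSpec(alpha=0.0),
                                n_reps=3, seed=0)
        assert res.rejection_rate == 0.0

    def test_seed_reproducible(self):
        r1 = type1_error_check(self.null_config(), ModelSpec(), n_reps=3, seed=5)
        r2 = type1_error_check(self.null_config(), ModelSpec(), n_reps=3, seed=5)
        assert r1 == r2

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            type1_error_check(self.null_config(), ModelSpec(), n_reps=0, seed=0)
        effects = {(a, c): 0.5 for a in ("S1P",) for c in ("F", "F-T")}
        effects[("S1P", "F-T")] = 0.9  # not a null configuration
        cfg = StudyGenConfig(arms=("S1P",), conditions=("F", "F-T"),
                             arm_condition_effects=effects,
                             proliferation_sections_per_punch=0)
        with pytest.raises(ConfigError):
            type1_error_check(cfg, ModelSpec(), n_reps=2, seed=0)
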