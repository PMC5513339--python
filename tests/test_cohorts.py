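"""Synthetic cohort generation: predictors, risks, allocation, effects, outcomes."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from treatval import (
    Cohort,
    RngState,
    allocate_treatment,
    apply_treatment_effect,
    builtin_scenario,
    compute_untreated_risk,
    draw_outcomes,
    draw_predictors,
    generate_cohort,
    generate_validation_pair,
)
from treatval.cohorts import allocation_probability, treatment_odds_ratio

SEED = 20170714


class TestPredictors:
    def test_sample_variance_matches_spec(self):
        x1, x2, u = draw_predictors(100_000, np.sqrt(0.2), RngState(SEED, "var"))
        for v in (x1, x2, u):
            assert 0.19 <= v.var() <= 0.21
            assert abs(v.mean()) < 0.01

    def test_boundary_n_one(self):
        x1, x2, u = draw_predictors(1, 0.5, RngState(SEED, "one"))
        assert x1.shape == x2.shape == u.shape == (1,)

    def test_deterministic_given_seed_and_label(self):
        a = draw_predictors(50, 0.4, RngState(SEED, "det"))
        b = draw_predictors(50, 0.4, RngState(SEED, "det"))
        c = draw_predictors(50, 0.4, RngState(SEED, "other"))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert not np.array_equal(a[0], c[0])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            draw_predictors(0, 0.4, RngState(SEED))
        with pytest.raises(ValueError):
            draw_predictors(10, -1.0, RngState(SEED))


class TestUntreatedRisk:
    def test_closed_form_at_origin(self, sc1):
        z = np.zeros(1)
        risk = compute_untreated_risk(z, z, z, sc1.outcome_model)
        assert risk[0] == pytest.approx(0.18243, abs=5e-6)

    def test_null_model_gives_half(self):
        from treatval import OutcomeModelSpec

        m = OutcomeModelSpec(0.0, 0.0, 0.0, 0.0)
        x = np.linspace(-3, 3, 11)
        assert np.allclose(compute_untreated_risk(x, x, x, m), 0.5)

    def test_population_incidence_near_twenty_percent(self, sc1):
        """Mean untreated risk under the default generating model is ~20%."""
        x1, x2, u = draw_predictors(1_000_000, sc1.predictor_sd, RngState(SEED, "inc"))
        risk = compute_untreated_risk(x1, x2, u, sc1.outcome_model)
        assert risk.mean() == pytest.approx(0.20, abs=0.005)


class TestAllocation:
    def test_default_model_crosses_half_at_its_threshold(self, sc1):
        p = allocation_probability(np.array([0.195]), sc1.allocation)
        assert p[0] == pytest.approx(0.5)

    def test_threshold_model_closed_form(self):
        alloc = builtin_scenario("scenario_4").allocation
        p = allocation_probability(np.array([0.18, 0.21]), alloc)
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(expit(100 * 0.21 - 18), abs=1e-12)
        assert p[1] == pytest.approx(0.9526, abs=5e-5)

    def test_threshold_model_treats_most_high_risk(self):
        """Nearly all individuals above the 18% risk threshold get treated."""
        cfg = builtin_scenario("scenario_4")
        x1, x2, u = draw_predictors(1_000_000, cfg.predictor_sd, RngState(SEED, "s4"))
        risk = compute_untreated_risk(x1, x2, u, cfg.outcome_model)
        tr = allocate_treatment(risk, cfg.allocation, RngState(SEED, "s4a"))
        assert tr[risk > 0.18].mean() == pytest.approx(0.95, abs=0.01)

    def test_random_mode_ignores_risk(self):
        alloc = builtin_scenario("scenario_2").allocation
        p = allocation_probability(np.array([0.01, 0.5, 0.99]), alloc)
        assert np.allclose(p, 0.5)


class TestTreatmentEffect:
    def test_constant_or_on_odds_scale(self, sc1):
        out = apply_treatment_effect(np.array([0.2]), np.array([1]), sc1.effect)
        assert out[0] == pytest.approx(0.125 / 1.125, abs=1e-10)  # odds 0.25*0.5

    def test_or_one_is_identity(self):
        from treatval import TreatmentEffectSpec

        eff = TreatmentEffectSpec(mode="constant", or_constant=1.0)
        risk = np.array([0.1, 0.5, 0.9])
        out = apply_treatment_effect(risk, np.ones(3, dtype=int), eff)
        assert np.allclose(out, risk)

    def test_untreated_rows_unchanged(self, sc1):
        risk = np.array([0.2, 0.4])
        out = apply_treatment_effect(risk, np.array([0, 1]), sc1.effect)
        assert out[0] == risk[0] and out[1] < risk[1]

    def test_risk_dependent_or_closed_form(self):
        eff = builtin_scenario("scenario_3").effect
        orr = treatment_odds_ratio(np.array([0.2]), eff)
        assert orr[0] == pytest.approx(1 / (1 + np.exp(-1 + 5 * 0.2)), abs=1e-12)
        out = apply_treatment_effect(np.array([0.2]), np.array([1]), eff)
        assert out[0] == pytest.approx(0.25 * 0.5 / (1 + 0.25 * 0.5), abs=1e-10)

    def test_invalid_risks_rejected(self, sc1):
        with pytest.raises(ValueError):
            apply_treatment_effect(np.array([0.0]), np.array([1]), sc1.effect)


class TestOutcomes:
    def test_untreated_outcomes_coincide(self, sc1):
        coh = generate_cohort(sc1, RngState(SEED, "out1"), treated=True)
        unt = coh.treated == 0
        assert np.array_equal(coh.y_observed[unt], coh.y_untreated[unt])
        assert np.array_equal(coh.risk_observed[unt], coh.risk_untreated[unt])

    def test_coupling_is_monotone_under_protective_or(self, sc1):
        coh = generate_cohort(sc1, RngState(SEED, "out2"), treated=True, n=20_000)
        assert np.all(coh.y_observed <= coh.y_untreated)

    def test_observed_marginal_matches_risk(self, sc1):
        """Shared-uniform coupling leaves the marginal outcome law intact."""
        n = 100_000
        coh = generate_cohort(sc1, RngState(SEED, "out3"), treated=True, n=n)
        expected = coh.risk_observed.sum()
        observed = coh.y_observed.sum()
        var = (coh.risk_observed * (1 - coh.risk_observed)).sum()
        chi2 = (observed - expected) ** 2 / var
        assert stats.chi2.sf(chi2, df=1) > 0.001

    def test_treatment_lowers_observed_incidence(self, sc1):
        coh = generate_cohort(sc1, RngState(SEED, "out4"), treated=True, n=1_000_000)
        assert coh.y_untreated.mean() == pytest.approx(0.20, abs=0.005)
        assert coh.y_observed.mean() < coh.y_untreated.mean()

    def test_uncoupled_outcomes_keep_marginals(self, sc1):
        coh = generate_cohort(sc1, RngState(SEED, "out5"), treated=True, n=200_000, couple_outcomes=False)
        assert coh.y_observed.mean() == pytest.approx(coh.risk_observed.mean(), abs=0.005)
        # independence: some treated individuals flip 0 -> 1
        tr = coh.treated == 1
        assert np.any(coh.y_observed[tr] > coh.y_untreated[tr])


class TestValidationPair:
    def test_development_cohort_is_untreated(self, sc1_pair):
        dev, val = sc1_pair
        assert dev.n_treated == 0
        assert val.n_treated > 0

    def test_treated_fraction_sc1_and_sc10(self):
        for name, lo, hi in (("scenario_1", 0.48, 0.52), ("scenario_10", 0.73, 0.77)):
            cfg = builtin_scenario(name)
            coh = generate_cohort(cfg, RngState(SEED, f"frac/{name}"), treated=True, n=1_000_000)
            assert lo <= coh.treated.mean() <= hi

    @pytest.mark.parametrize("name, frac", [("scenario_2", 0.50), ("scenario_5", 0.25)])
    def test_treated_fraction_over_replicates(self, name, frac):
        cfg = builtin_scenario(name)
        fracs = [
            generate_validation_pair(cfg, RngState(SEED, f"tf/{name}/{r}"))[1].treated.mean()
            for r in range(30)
        ]
        assert np.mean(fracs) == pytest.approx(frac, abs=0.02)

    def test_risk_distributions_by_allocation_mode(self):
        """Risk-based allocation treats riskier individuals; random does not."""
        nonrandom = generate_cohort(
            builtin_scenario("scenario_1"), RngState(SEED, "ks1"), treated=True, n=50_000
        )
        tr = nonrandom.treated == 1
        assert nonrandom.risk_untreated[tr].mean() > nonrandom.risk_untreated[~tr].mean()
        # stochastic dominance of the treated risk distribution
        qs = np.linspace(0.05, 0.95, 19)
        assert np.all(
            np.quantile(nonrandom.risk_untreated[tr], qs)
            >= np.quantile(nonrandom.risk_untreated[~tr], qs)
        )
        random = generate_cohort(
            builtin_scenario("scenario_2"), RngState(SEED, "ks2"), treated=True, n=50_000
        )
        tr = random.treated == 1
        ks = stats.ks_2samp(random.risk_untreated[tr], random.risk_untreated[~tr])
        assert ks.pvalue > 0.001

    def test_pair_is_deterministic(self, sc1):
        a = generate_validation_pair(sc1, RngState(SEED, "det"))
        b = generate_validation_pair(sc1, RngState(SEED, "det"))
        assert np.array_equal(a[1].y_observed, b[1].y_observed)
        assert np.array_equal(a[0].x1, b[0].x1)

    def test_invalid_sizes_rejected(self, sc1):
        from dataclasses import replace

        from treatval import ConfigError

        with pytest.raises(ConfigError, match="n_dev"):
            replace(sc1, n_dev=0)

    def test_export_roundtrip(self, tmp_path, sc1_pair):
        import pandas as pd

        _, val = sc1_pair
        path = tmp_path / "val.csv"
        val.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "id", "x1", "x2", "u", "risk_untreated", "treated",
            "risk_observed", "y_untreated", "y_observed",
        ]
        back = Cohort.from_frame(df)
        assert np.allclose(back.risk_untreated, val.risk_untreated)
        assert np.array_equal(back.y_observed, val.y_observed)
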