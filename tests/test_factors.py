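"""Tests of the exposure-factor registry and the two survey estimators."""

import math

import numpy as np
import pytest

from fecalflow.factors import (
    AGE_GROUPS,
    CUP_ML,
    NEIGHBORHOODS,
    SACHET_ML,
    BetaPosterior,
    FactorRegistry,
    FactorSpec,
    IntervalObservation,
    beta_posterior,
    default_registry,
    fit_interval_lognormal,
    sample_factor,
    wash_fraction_remaining,
)


class TestFactorSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown distribution family"):
            FactorSpec("x", "cauchy", {"a": 1})

    @pytest.mark.parametrize("family,params", [
        ("triangle", {"a": 1.0, "c": 0.5, "b": 2.0}),
        ("beta", {"alpha": 0.0, "beta": 1.0}),
        ("gamma", {"shape": -1.0, "scale": 1.0}),
        ("lognormal", {"mu": 0.0, "sigma": 0.0}),
        ("uniform", {"a": 2.0, "b": 2.0}),
        ("constant_by_age", {"values": {"0-1": 0.1}}),
    ])
    def test_invalid_parameters_rejected(self, family, params):
        with pytest.raises(ValueError):
            FactorSpec("x", family, params)

    def test_dict_roundtrip(self):
        spec = FactorSpec("f", "beta", {"alpha": 2.0, "beta": 3.0},
                          source="note", context={"age_group": "1-2"})
        back = FactorSpec.from_dict(spec.to_dict())
        assert back.name == spec.name and back.family == spec.family
        assert back.params == spec.params and back.context == spec.context


class TestSampleFactor:
    def test_families_respect_their_supports(self, rng):
        checks = [
            (FactorSpec("t", "triangle", {"a": 0.1, "c": 0.3, "b": 0.5}),
             lambda x: 0.1 <= x <= 0.5),
            (FactorSpec("b", "beta", {"alpha": 2.0, "beta": 5.0}),
             lambda x: 0.0 < x < 1.0),
            (FactorSpec("g", "gamma_offset", {"shape": 2.0, "scale": 3.0, "offset": 10.0}),
             lambda x: x > 10.0),
            (FactorSpec("u", "uniform", {"a": 1.0, "b": 10.0}),
             lambda x: 1.0 <= x <= 10.0),
            (FactorSpec("n", "normal", {"mu": 0.5, "sigma": 2.0}),
             lambda x: x > 0.0),  # redrawn until positive
            (FactorSpec("w", "weibull", {"shape": 2.0, "scale": 4.0}),
             lambda x: x > 0.0),
            (FactorSpec("l", "lognormal", {"mu": 0.0, "sigma": 1.0}),
             lambda x: x > 0.0),
        ]
        for spec, ok in checks:
            for _ in range(200):
                assert ok(sample_factor(spec, rng)), spec.name

    def test_lognormal_moments(self, rng):
        spec = FactorSpec("l", "lognormal", {"mu": 1.2, "sigma": 0.4})
        draws = np.array([sample_factor(spec, rng) for _ in range(20_000)])
        assert np.log(draws).mean() == pytest.approx(1.2, abs=0.02)
        assert np.log(draws).std() == pytest.approx(0.4, abs=0.02)

    def test_degenerate_triangle_is_constant(self, rng):
        spec = FactorSpec("t", "triangle", {"a": 0.2, "c": 0.2, "b": 0.2})
        assert sample_factor(spec, rng) == 0.2

    def test_constant_by_age_requires_age_group(self, rng):
        spec = FactorSpec("c", "constant_by_age",
                          {"values": {g: 0.1 for g in AGE_GROUPS}})
        with pytest.raises(ValueError, match="age_group"):
            sample_factor(spec, rng)
        assert sample_factor(spec, rng, age_group="1-2") == 0.1

    def test_linlog_requires_duration(self, rng):
        spec = FactorSpec("w", "linlog", {"b0": 0.68, "b1": -0.80})
        with pytest.raises(ValueError, match="duration"):
            sample_factor(spec, rng)
        got = sample_factor(spec, rng, duration=30.0)
        assert got == pytest.approx(min(1.0, 10 ** (0.68 - 0.80 * math.log(30.0))))


class TestWashFraction:
    def test_monotone_decreasing_in_duration(self):
        durations = [15.0, 30.0, 60.0, 120.0, 300.0]
        for soap in (True, False):
            fracs = [wash_fraction_remaining(d, soap) for d in durations]
            assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_soap_removes_more_for_long_washes(self):
        assert wash_fraction_remaining(120.0, True) < wash_fraction_remaining(120.0, False)

    def test_clamped_to_unit_interval(self):
        assert wash_fraction_remaining(1.0, True) == 1.0  # 10**2.18 clamped
        assert 0.0 <= wash_fraction_remaining(10_000.0, True) <= 1.0

    def test_base10_variant_and_validation(self):
        nat = wash_fraction_remaining(60.0, False)
        b10 = wash_fraction_remaining(60.0, False, log_base="10")
        assert nat == pytest.approx(10 ** (0.68 - 0.80 * math.log(60.0)))
        assert b10 == pytest.approx(10 ** (0.68 - 0.80 * math.log10(60.0)))
        with pytest.raises(ValueError):
            wash_fraction_remaining(0.0, True)
        with pytest.raises(ValueError):
            wash_fraction_remaining(60.0, True, log_base="2")


class TestBetaPosterior:
    def test_uniform_prior_update(self):
        post = beta_posterior(7, 20)
        assert (post.alpha, post.beta) == (8.0, 14.0)
        assert post.mean == pytest.approx(8.0 / 22.0)

    def test_sequential_updates_equal_single_batch(self):
        # conjugacy: Beta(1,1) + (y1,n1) + (y2,n2) == Beta(1,1) + (y1+y2,n1+n2)
        first = beta_posterior(4, 10)
        combined = BetaPosterior(first.alpha + 3, first.beta + (15 - 3))
        batch = beta_posterior(4 + 3, 10 + 15)
        assert (combined.alpha, combined.beta) == (batch.alpha, batch.beta)

    def test_validation(self):
        with pytest.raises(ValueError):
            beta_posterior(5, 4)
        with pytest.raises(ValueError):
            beta_posterior(-1, 4)
        with pytest.raises(ValueError):
            beta_posterior(1.5, 4)

    def test_posterior_concentrates_on_truth(self, rng):
        y = int(rng.binomial(5000, 0.3))
        post = beta_posterior(y, 5000)
        assert post.mean == pytest.approx(0.3, abs=0.03)
        draws = [post.sample(rng) for _ in range(1000)]
        assert np.std(draws) < 0.02


class TestIntervalLognormal:
    def test_recovers_parameters_from_censored_data(self, rng):
        mu, sigma = 0.9, 0.6
        x = rng.lognormal(mu, sigma, 500)
        obs = [IntervalObservation(float(max(math.ceil(v) - 1, 0)), float(math.ceil(max(v, 1e-9))))
               for v in x]
        mu_hat, sigma_hat = fit_interval_lognormal(obs)
        assert mu_hat == pytest.approx(mu, abs=0.1)
        assert sigma_hat == pytest.approx(sigma, abs=0.1)

    def test_open_top_interval_supported(self, rng):
        x = rng.lognormal(1.5, 0.5, 400)
        obs = []
        for v in x:
            n = max(math.ceil(v), 1)
            if n >= 10:
                obs.append(IntervalObservation(9.0, math.inf))
            else:
                obs.append(IntervalObservation(float(n - 1), float(n)))
        mu_hat, sigma_hat = fit_interval_lognormal(obs)
        assert mu_hat == pytest.approx(1.5, abs=0.15)
        assert sigma_hat == pytest.approx(0.5, abs=0.15)

    def test_identical_intervals_hit_the_boundary(self):
        obs = [IntervalObservation(1.0, 2.0)] * 10
        with pytest.warns(RuntimeWarning, match="boundary"):
            mu_hat, sigma_hat = fit_interval_lognormal(obs)
        assert sigma_hat == 0.0
        assert mu_hat == pytest.approx(0.5 * (math.log(1.0) + math.log(2.0)))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_interval_lognormal([IntervalObservation(0.0, 1.0)])

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            IntervalObservation(-1.0, 2.0)
        with pytest.raises(ValueError):
            IntervalObservation(2.0, 2.0)


class TestRegistry:
    def test_default_registry_is_complete(self):
        reg = default_registry()
        names = {s.name for s in reg}
        required = {
            "hand_contact_area_cm2", "hand_fraction_in_mouth",
            "attachment_coefficient", "detachment_coefficient",
            "handwash_duration_s", "bathing_duration_s",
            "wash_log10_remaining_soap", "wash_log10_remaining_nosoap",
            "mouthing_removal_fraction", "prob_handwash_soap",
            "prob_bathing_soap", "soil_adherence_mg_cm2",
            "water_adherence_ul_cm2", "surface_contact_per_hour",
            "mouthing_per_hour_indoor", "mouthing_per_hour_outdoor",
            "prob_touch_own_feces", "prob_surface_contact_defecation",
            "surface_contacts_defecation_per_hour",
            "prob_exclusive_breastfeeding", "prob_breastfeeding",
            "prob_raw_or_bought_food", "prob_eat_with_hands",
            "raw_produce_serving_g", "prepared_food_serving_g",
            "prob_sachet_water", "tap_water_daily_cups",
            "sachet_water_daily_sachets", "behavior_duration_min",
        }
        assert required <= names

    def test_age_and_neighborhood_contexts_resolve(self):
        reg = default_registry()
        for ag in AGE_GROUPS:
            assert reg.get("prob_breastfeeding", age_group=ag).context["age_group"] == ag
            reg.get("tap_water_daily_cups", age_group=ag)
            reg.get("sachet_water_daily_sachets", age_group=ag)
        for nb in NEIGHBORHOODS:
            assert reg.get("prob_sachet_water", neighborhood=nb).context["neighborhood"] == nb

    def test_specific_context_beats_wildcard(self):
        reg = FactorRegistry([
            FactorSpec("f", "uniform", {"a": 0.0, "b": 1.0}),
            FactorSpec("f", "uniform", {"a": 5.0, "b": 6.0}, context={"age_group": "1-2"}),
        ])
        assert reg.get("f").params["a"] == 0.0
        assert reg.get("f", age_group="1-2").params["a"] == 5.0
        assert reg.get("f", age_group="2-5").params["a"] == 0.0  # falls back

    def test_missing_factor_raises(self):
        with pytest.raises(KeyError):
            default_registry().get("no_such_factor")

    def test_list_roundtrip(self):
        reg = default_registry()
        back = FactorRegistry.from_list(reg.to_list())
        assert len(back) == len(reg)
        for a, b in zip(reg, back):
            assert a.to_dict() == b.to_dict()

    def test_exclusive_breastfeeding_declines_with_age(self):
        reg = default_registry()
        spec = reg.get("prob_exclusive_breastfeeding")
        vals = [spec.params["values"][g] for g in AGE_GROUPS]
        assert vals[0] > vals[1] > vals[2] == 0.0

    def test_drinking_unit_volumes(self):
        assert CUP_ML == 237.0
        assert SACHET_ML == 500.0
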