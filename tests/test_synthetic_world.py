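"""Generator mechanics: world construction, the value/choice/rating models,
streams, and the laboratory-experiment emulation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contextchoice.synthetic_world import (
    ExperimentHeterogeneity,
    WorldConfig,
    choice_probabilities,
    generate_world,
    normalized_value,
    normalized_values,
    simulate_checkins,
    simulate_choice_stream,
    simulate_experiment,
    simulate_orders,
    simulate_rating,
)
from tests.conftest import tiny_config


class TestGenerateWorld:
    def test_counts_follow_configuration(self):
        cfg = WorldConfig(
            n_cities=1,
            clusters_per_city=2,
            restaurants_per_cluster=4,
            restaurants_per_cluster_range=None,
            categories=("Pizza",),
            n_users=5,
            events_per_user=5,
            init_reviews_per_restaurant=3,
            init_reviews_range=None,
            seed=0,
        )
        world = generate_world(cfg)
        assert len(world.restaurants) == 8
        assert all("Pizza" in r.assigned_terms for r in world.restaurants)
        assert all(len(w.assigned_terms) >= 1 for w in world.restaurants)
        assert len(world.init_reviews) == 8 * 3

    def test_same_seed_same_world(self):
        a = generate_world(tiny_config())
        b = generate_world(tiny_config())
        assert [dataclasses.astuple(r) for r in a.restaurants] == [
            dataclasses.astuple(r) for r in b.restaurants
        ]
        assert [dataclasses.astuple(r) for r in a.init_reviews] == [
            dataclasses.astuple(r) for r in b.init_reviews
        ]

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(n_users=0).validate()
        with pytest.raises(ValueError):
            WorldConfig(price_probs=(0.5, 0.5, 0.1, 0.0)).validate()
        with pytest.raises(ValueError):
            WorldConfig(sigma_norm=0.0).validate()

    def test_quality_and_price_invariants(self, tiny_world):
        for r in tiny_world.restaurants:
            assert 1.0 <= r.latent_quality <= 5.0
            assert r.price in (1, 2, 3, 4)
            assert r.true_primary_term in r.assigned_terms
            assert "Restaurants" not in r.assigned_terms

    def test_init_review_means_converge_on_latent_quality(self):
        # 400 whole-star reviews at sigma_u=0.5: empirical mean within 0.15
        # of latent quality for >= 95% of restaurants (mid-range qualities,
        # where the clamp-and-round bias is below the Monte-Carlo bound)
        cfg = WorldConfig(
            clusters_per_city=40,
            restaurants_per_cluster=2,
            restaurants_per_cluster_range=None,
            categories=("Pizza",),
            init_reviews_per_restaurant=400,
            init_reviews_range=None,
            quality_mean=3.3,
            quality_sd=0.5,
            cluster_quality_sd=0.4,
            sigma_u=0.5,
            n_users=5,
            events_per_user=5,
            seed=3,
        )
        world = generate_world(cfg)
        means = {}
        for r in world.init_reviews:
            means.setdefault(r.business_id, []).append(r.stars)
        hits = [
            abs(np.mean(means[r.id]) - r.latent_quality) <= 0.15
            for r in world.restaurants
        ]
        assert np.mean(hits) >= 0.95


class TestNormalizedValue:
    def test_divisive_normalization_formula(self):
        assert normalized_value(4, [4, 4, 2], sigma=1, omega=1) == pytest.approx(4 / 11)

    def test_zero_context_weight_reduces_to_ratio(self):
        assert normalized_value(4, [4, 4, 2], sigma=1, omega=0) == 4.0

    def test_membership_and_domain_errors(self):
        with pytest.raises(ValueError):
            normalized_value(3, [4, 4, 2], sigma=1, omega=1)
        with pytest.raises(ValueError):
            normalized_value(4, [4, 4, 2], sigma=0, omega=1)
        with pytest.raises(ValueError):
            normalized_values([4, 2], sigma=1, omega=-0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r_other=st.floats(1, 5),
        bump=st.floats(0.01, 2),
        omega=st.floats(0.01, 2),
    )
    def test_value_strictly_decreases_as_any_competitor_improves(self, r_other, bump, omega):
        low = normalized_value(4.0, [4.0, r_other], sigma=1.0, omega=omega)
        high = normalized_value(4.0, [4.0, min(5.0, r_other + bump)], sigma=1.0, omega=omega)
        if r_other + bump <= 5.0:
            assert high < low


class TestChoiceProbabilities:
    def test_equal_values_give_uniform(self):
        p = choice_probabilities([2.0, 2.0, 2.0], tau=0.7)
        assert np.allclose(p, 1 / 3)

    def test_two_option_closed_form(self):
        p = choice_probabilities([1.0, 0.0], tau=1.0)
        e = math.e
        assert p == pytest.approx([e / (1 + e), 1 / (1 + e)])

    def test_sharp_temperature_concentrates_on_the_max(self):
        p = choice_probabilities([0.3, 0.31, 0.29], tau=0.001)
        assert p[1] > 0.999

    def test_simplex_and_overflow_safety(self):
        p = choice_probabilities([1e6, -1e6, 0.0], tau=0.01)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            choice_probabilities([], tau=1.0)
        with pytest.raises(ValueError):
            choice_probabilities([1.0, np.inf], tau=1.0)
        with pytest.raises(ValueError):
            choice_probabilities([1.0], tau=0.0)


class TestSimulateRating:
    def test_degenerate_noise_free_context_free_case(self):
        cfg = WorldConfig(kappa=0.0, sigma_u=0.0, discretize=False)
        rng = np.random.default_rng(0)
        assert simulate_rating(3.5, 4.5, cfg, rng) == 3.5

    def test_expectation_shift_arithmetic(self):
        cfg = WorldConfig(kappa=0.4, sigma_u=0.0, discretize=False)
        rng = np.random.default_rng(0)
        assert simulate_rating(3.5, 4.5, cfg, rng) == pytest.approx(3.5 + 0.4 * 1.5)

    def test_monte_carlo_deviation_slope_matches_closed_form(self):
        cfg = WorldConfig(kappa=0.4, sigma_u=0.5, discretize=False)
        rng = np.random.default_rng(1)
        draws = np.array([simulate_rating(3.0, 4.0, cfg, rng) for _ in range(10_000)])
        dev = draws - 3.0
        se = 0.5 / math.sqrt(len(draws))
        assert abs(dev.mean() - 0.4 * 1.0) <= 3 * se

    def test_out_of_scale_inputs_rejected(self):
        cfg = WorldConfig()
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_rating(0.5, 3.0, cfg, rng)

    def test_clamping_attenuates_but_never_flips_the_deviation_slope(self):
        # discretize mode, prior near the ceiling: the measured deviation
        # slope shrinks but stays positive across a grid of context means
        cfg = WorldConfig(kappa=0.4, sigma_u=0.5, discretize=True)
        for prior in [4.6, 4.8]:
            means = []
            for m in [2.5, 3.5, 4.5]:
                rng = np.random.default_rng(7)
                draws = [simulate_rating(prior, m, cfg, rng) for _ in range(4000)]
                means.append(np.mean(draws) - prior)
            slope = (means[-1] - means[0]) / 2.0
            assert 0 < slope < 0.4


class TestStreams:
    def test_context_free_sharp_choices_maximize_ratings(self):
        cfg = tiny_config(omega=0.0, tau=0.005)
        world = generate_world(cfg)
        records, _ = simulate_choice_stream(world, cfg)
        assert np.mean([r["is_target"] for r in records]) > 0.95

    def test_richer_contexts_reduce_target_probability_analytically(self):
        # matched top-two gap, different set means: enumerate probabilities
        lo = np.array([3.5, 3.0, 2.5])
        hi = np.array([5.0, 4.5, 4.0])
        p_lo = choice_probabilities(normalized_values(lo, 1.0, 0.5), 0.05)[0]
        p_hi = choice_probabilities(normalized_values(hi, 1.0, 0.5), 0.05)[0]
        assert p_hi < p_lo

    def test_same_seed_identical_event_streams(self, tiny_world):
        cfg = tiny_world.config
        r1, v1 = simulate_choice_stream(tiny_world, cfg)
        r2, v2 = simulate_choice_stream(tiny_world, cfg)
        assert [dataclasses.astuple(x) for x in v1] == [dataclasses.astuple(x) for x in v2]
        assert len(r1) == len(r2)

    def test_checkins_carry_no_user_identity(self, tiny_world):
        events = simulate_checkins(tiny_world, tiny_world.config)
        assert events
        assert not hasattr(events[0], "user_id")

    def test_orders_cover_only_rated_restaurants_and_round_trip_sets(self, tiny_world):
        orders, options = simulate_orders(tiny_world, tiny_world.config)
        ids = {o["restaurant_id"] for o in options}
        assert all(o.restaurant_id in ids for o in orders)
        assert all((o.city, o.cuisine) for o in orders)

    def test_iia_holds_exactly_without_context_weight(self):
        # ratio p(top)/p(second) invariant to the distractor grid at omega=0
        ratios = []
        for d in np.linspace(1.0, 4.0, 13):
            p = choice_probabilities(normalized_values([4.5, 4.0, d], 1.0, 0.0), 0.1)
            ratios.append(p[0] / p[1])
        assert max(ratios) - min(ratios) < 1e-12

    def test_iia_violated_with_context_weight(self):
        # p(top | top-two) strictly decreasing in the distractor rating
        conds = []
        for d in np.linspace(1.0, 3.9, 10):
            p = choice_probabilities(normalized_values([4.5, 4.0, d], 1.0, 0.5), 0.05)
            conds.append(p[0] / (p[0] + p[1]))
        assert all(a > b for a, b in zip(conds, conds[1:]))


class TestSimulateExperiment:
    def _pool(self):
        from contextchoice.rating_state import DisplayedOption, SetSnapshot

        rng = np.random.default_rng(0)
        pool = []
        for i in range(60):
            n = rng.integers(3, 8)
            disp = rng.choice(np.arange(4, 11) / 2, size=n)
            while len(set(disp)) < 3:
                disp = rng.choice(np.arange(4, 11) / 2, size=n)
            options = tuple(
                DisplayedOption(
                    business_id=f"s{i}b{j}",
                    displayed_rating=float(d),
                    raw_prior_mean=float(d),
                    n_reviews=int(rng.integers(5, 200)),
                    price=int(rng.integers(1, 5)),
                )
                for j, d in enumerate(disp)
            )
            pool.append(SetSnapshot(set_id=("c", i, "Pizza"), timestamp=0.0, options=options))
        return pool

    def test_trial_counts_are_135_135_5_per_participant(self):
        with pytest.warns(UserWarning):
            trials, _ = simulate_experiment(self._pool(), 3, WorldConfig(), seed=1)
        from collections import Counter

        for p in ("p0000", "p0001", "p0002"):
            c = Counter(t.trial_type for t in trials if t.participant_id == p)
            assert c == {"choice": 135, "rating": 135, "catch": 5}

    def test_lapse_rate_half_yields_half_catch_accuracy(self):
        from contextchoice.inference import catch_trial_exclusion

        het = ExperimentHeterogeneity(lapse_rate=0.5)
        with pytest.warns(UserWarning):
            trials, _ = simulate_experiment(self._pool(), 40, WorldConfig(), het, seed=2)
        _, accuracy = catch_trial_exclusion(trials)
        assert np.mean(list(accuracy.values())) == pytest.approx(0.5, abs=0.12)

    def test_rating_trials_recover_participant_context_slopes(self):
        # subject-level expectation-rating effects track the drawn c_p
        from contextchoice import context_measures as cm
        from contextchoice import inference as inf

        het = ExperimentHeterogeneity(correlation=0.0, c_sd=3.0)
        with pytest.warns(UserWarning):
            trials, truth = simulate_experiment(self._pool(), 40, WorldConfig(), het, seed=3)
        _, rating = cm.build_experiment_tables(trials)
        fit = inf.expectation_rating_model(rating)
        eff = inf.subject_effects(fit, "mean_set_excl_highlighted")
        c_p = np.array([truth[p][1] for p in eff.index])
        # effect is -c_p, so the correlation must be clearly negative
        assert np.corrcoef(eff, c_p)[0, 1] < -0.3

    def test_participant_count_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_experiment(self._pool(), 0, WorldConfig())

    def test_satisfaction_bounded_and_exactly_one_response(self):
        with pytest.warns(UserWarning):
            trials, _ = simulate_experiment(self._pool(), 2, WorldConfig(), seed=4)
        for t in trials:
            if t.trial_type == "rating":
                assert 0.0 <= t.response_satisfaction <= 100.0
                assert t.response_choice is None
            else:
                assert t.response_satisfaction is None
                assert t.response_choice is not None
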