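"""Genetic-algorithm fitter: mutation, selection, fitness, full loop."""

import numpy as np
import pandas as pd
import pytest

import gnrherk as gk
from gnrherk.fitting import ObjectiveSet, rank_probabilities
from gnrherk.synth import standard_fit_objectives


@pytest.fixture(scope="module")
def small_objectives(params):
    """A compact objective set: one 1-min-pulse N:C trace."""
    from gnrherk.synth import generate_nc_traces, make_objectives

    protocol = gk.single_pulse(1e-7, 1.0, 30.0, "washout")
    table = generate_nc_traces(
        params, protocol, sample_interval=3.0, noise_sd=0.0, n_cells=1, seed=0
    )
    return make_objectives(trace_entries=[("p1", protocol, table)])


class TestMutate:
    def test_zero_scale_is_identity(self, params):
        rng = np.random.default_rng(0)
        assert gk.mutate(params, scale=0.0, rng=rng) == params

    def test_unflagged_parameters_never_change(self, params):
        rng = np.random.default_rng(1)
        unflagged = [n for n in gk.PARAM_NAMES if n not in gk.FITTED_PARAMS]
        current = params
        for _ in range(200):
            current = gk.mutate(current, rng=rng)
        for name in unflagged:
            assert getattr(current, name) == getattr(params, name)

    def test_perturbation_statistics(self, params):
        # theta_new/theta_current = 1 + 0.1*eps: mean 1, sd 0.1
        rng = np.random.default_rng(2)
        ratios = []
        for _ in range(10_000):
            mutated = gk.mutate(params, rng=rng)
            ratios.append(mutated.fitted_values() / params.fitted_values())
        ratios = np.concatenate(ratios)  # 1e5 draws
        assert ratios.mean() == pytest.approx(1.0, abs=0.001)
        assert ratios.std() == pytest.approx(0.1, abs=0.002)

    def test_positivity_floor(self, params):
        tiny = params.with_fitted_values(np.full(10, 1e-12))
        rng = np.random.default_rng(3)
        for _ in range(50):
            mutated = gk.mutate(tiny, scale=5.0, rng=rng)
            assert np.all(mutated.fitted_values() >= 1e-12)


class TestSelection:
    def test_rank_probabilities_two_vectors(self):
        # best of two gets rank 2 -> probability 2/3
        probs = rank_probabilities([0.1, 0.9])
        np.testing.assert_allclose(probs, [2 / 3, 1 / 3])

    def test_ties_broken_by_stable_input_order(self):
        probs = rank_probabilities([0.5, 0.5, 0.1])
        # best is index 2 (rank 3); tied pair keeps input order (ranks 2, 1)
        np.testing.assert_allclose(probs, [2 / 6, 1 / 6, 3 / 6])

    def test_population_of_one_unchanged(self, params):
        rng = np.random.default_rng(0)
        assert gk.select([params], [0.5], rng) == [params]

    def test_selection_frequencies_match_probabilities(self, params):
        pop = [params.replace(R0=0.1 * (i + 1)) for i in range(3)]
        fits = [0.9, 0.1, 0.5]  # ranks: 1, 3, 2 -> probs 1/6, 3/6, 2/6
        rng = np.random.default_rng(12345)
        counts = np.zeros(3)
        for _ in range(1000):
            for chosen in gk.select(pop, fits, rng):
                counts[pop.index(chosen)] += 1
        freqs = counts / counts.sum()
        np.testing.assert_allclose(freqs, [1 / 6, 3 / 6, 2 / 6], atol=0.04)


class TestFitness:
    def test_zero_at_generating_parameters(self, params, small_objectives):
        assert gk.fitness(params, small_objectives) < 1e-8

    def test_single_record_squared_error(self, params):
        # zero-amplitude protocol leaves N:C at its resting value of 0.8
        protocol = gk.build_pulse_train(0.0, 5.0, 30.0, 30.0)
        records = pd.DataFrame(
            [
                {
                    "protocol_id": "ctrl",
                    "observable": "nc_erk",
                    "time_min": 10.0,
                    "value": 1.3,
                    "weight": 1.0,
                }
            ]
        )
        objectives = ObjectiveSet({"ctrl": protocol}, records)
        assert gk.fitness(params, objectives) == pytest.approx(0.25, abs=1e-6)

    def test_weight_scaling_invariance(self, params, small_objectives):
        doubled = ObjectiveSet(
            small_objectives.protocols,
            small_objectives.records.assign(
                weight=small_objectives.records["weight"] * 2
            ),
        )
        candidate = params.replace(MEK_tot=0.9)
        assert gk.fitness(candidate, small_objectives) == pytest.approx(
            gk.fitness(candidate, doubled), rel=1e-12
        )

    def test_failed_evaluation_returns_inf(self, small_objectives, params):
        broken = params.replace(k_exp=0.0)  # no resting state exists
        assert gk.fitness(broken, small_objectives) == np.inf

    def test_reference_and_fast_integrators_agree(self, params, small_objectives):
        candidate = params.with_fitted_values(params.fitted_values() * 1.3)
        fast = gk.fitness(candidate, small_objectives, integrator="fast")
        ref = gk.fitness(candidate, small_objectives, integrator="reference", dt=0.5)
        assert fast == pytest.approx(ref, rel=2e-2, abs=1e-9)


class TestObjectiveValidation:
    def test_unknown_protocol_id_rejected(self, params):
        records = pd.DataFrame(
            [{"protocol_id": "ghost", "observable": "nc_erk", "time_min": 1.0,
              "value": 1.0, "weight": 1.0}]
        )
        with pytest.raises(ValueError):
            ObjectiveSet({}, records)

    def test_time_outside_horizon_rejected(self, params):
        protocol = gk.single_pulse(1e-7, 1.0, 30.0, "washout")
        records = pd.DataFrame(
            [{"protocol_id": "p", "observable": "nc_erk", "time_min": 31.0,
              "value": 1.0, "weight": 1.0}]
        )
        with pytest.raises(ValueError):
            ObjectiveSet({"p": protocol}, records)

    def test_nonpositive_weight_rejected(self, params):
        protocol = gk.single_pulse(1e-7, 1.0, 30.0, "washout")
        records = pd.DataFrame(
            [{"protocol_id": "p", "observable": "nc_erk", "time_min": 1.0,
              "value": 1.0, "weight": 0.0}]
        )
        with pytest.raises(ValueError):
            ObjectiveSet({"p": protocol}, records)


class TestFit:
    def test_true_init_is_immediately_optimal(self, params, small_objectives):
        result = gk.fit(small_objectives, params, generations=2, pop_size=4, seed=0)
        assert result.best_fitness < 1e-8

    def test_same_seed_reproducible(self, params, small_objectives):
        init = params.with_fitted_values(params.fitted_values() * 1.5)
        a = gk.fit(small_objectives, init, generations=3, pop_size=4, seed=7)
        b = gk.fit(small_objectives, init, generations=3, pop_size=4, seed=7)
        assert a == b

    def test_best_so_far_non_increasing(self, params, small_objectives):
        init = params.with_fitted_values(params.fitted_values() * 1.5)
        result = gk.fit(small_objectives, init, generations=10, pop_size=6, seed=1)
        assert np.all(np.diff(result.history) <= 0)

    def test_zero_mutation_scale_keeps_population(self, params, small_objectives):
        init = params.with_fitted_values(params.fitted_values() * 1.5)
        result = gk.fit(
            small_objectives, init, generations=3, pop_size=4, seed=0,
            mutation_scale=0.0,
        )
        assert result.best_params == init

    def test_fitness_improves_from_perturbed_start(self, params, small_objectives):
        init = params.with_fitted_values(params.fitted_values() * 1.5)
        start = gk.fitness(init, small_objectives)
        result = gk.fit(small_objectives, init, generations=15, pop_size=10, seed=4)
        assert result.best_fitness < start

    def test_invalid_sizes_rejected(self, params, small_objectives):
        with pytest.raises(ValueError):
            gk.fit(small_objectives, params, generations=0, pop_size=4)
        with pytest.raises(ValueError):
            gk.fit(small_objectives, params, generations=1, pop_size=1)


class TestStandardObjectives:
    def test_covers_three_regimes_and_dose_response(self, params):
        objectives = standard_fit_objectives(params)
        ids = set(objectives.protocols)
        assert {"pulse_1min", "pulse_10min", "constant"} <= ids
        assert sum(1 for i in ids if i.startswith("dose_response")) == 5
        assert gk.fitness(params, objectives) < 1e-8
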