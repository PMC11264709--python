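"""Fitness map, Kimura fixation, mutation proposals, generation loop."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathway_evolver.evolution import (
    ConfigurationError,
    MutationModel,
    SelectionTarget,
    apply_haldane_update,
    fixation_probability,
    flux_fitness,
    generation_step,
    initialize_population,
    population_fitness,
    propose_mutations,
    raw_logistic,
    sample_effect,
    simulate_generations,
)
from pathway_evolver.model import ROLE_BINDING, ROLE_FORWARD_VMAX
from pathway_evolver.fixtures import make_linear_chain


class TestLogisticFitness:
    def test_inflection_point(self):
        assert raw_logistic(0.5) == 0.5

    def test_tail_values_match_closed_form(self):
        assert raw_logistic(0.0) == pytest.approx(1.0 / (1.0 + math.e**5),
                                                  rel=1e-12)
        assert raw_logistic(1.0) == pytest.approx(1.0 / (1.0 + math.e**-5),
                                                  rel=1e-12)

    def test_anchors_zero_and_start_flux(self):
        t = SelectionTarget("R", 1.0)
        assert flux_fitness(0.0, t, start_flux=2.5) == 0.0
        assert flux_fitness(2.5, t, start_flux=2.5) == pytest.approx(1.0)

    def test_asymptote_is_the_normalized_ceiling(self):
        t = SelectionTarget("R", 1.0)
        l0 = 1.0 / (1.0 + math.e**5)
        l1 = 1.0 / (1.0 + math.e**-5)
        ceiling = (1.0 - l0) / (l1 - l0)
        assert flux_fitness(1e9, t, start_flux=1.0) == pytest.approx(
            ceiling, rel=1e-9)
        assert ceiling == pytest.approx(1.006783, abs=1e-6)

    def test_zero_start_flux_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            flux_fitness(1.0, SelectionTarget("R", 1.0), start_flux=0.0)

    def test_multiplier_shifts_the_optimum(self):
        # with multiplier 2 the starting flux still scores exactly 1,
        # but the ceiling doubles its distance: positive-selection mode
        t = SelectionTarget("R", 1.0, multiplier=2.0)
        assert flux_fitness(1.0, t, start_flux=1.0) == pytest.approx(1.0)
        assert flux_fitness(2.0, t, start_flux=1.0) > 1.5


class TestPopulationFitness:
    def test_identity_and_absorbing_zero(self):
        assert population_fitness([1.0, 1.0], [0.5, 0.5]) == 1.0
        assert population_fitness([0.0, 1.1], [0.5, 0.5]) == 0.0

    def test_weighted_geometric_mean(self):
        assert population_fitness([0.9, 1.1], [0.5, 0.5]) == pytest.approx(
            math.sqrt(0.99), rel=1e-12)


class TestFixationProbability:
    def test_neutral_returns_initial_frequency(self):
        assert fixation_probability(0.0, ne=1000, c=2, p=0.5) == 0.5
        assert fixation_probability(0.0, ne=10, c=1, p=0.3) == 0.3

    def test_closed_form_case(self):
        expected = (1.0 - math.exp(-2.0)) / (1.0 - math.exp(-4.0))
        assert fixation_probability(0.001, ne=1000, c=2, p=0.5) \
            == pytest.approx(expected, abs=1e-12)

    def test_strongly_deleterious_underflows_gracefully(self):
        p = fixation_probability(-0.01, ne=10**6, c=2, p=0.5)
        assert 0.0 <= p < 1e-300

    @given(st.floats(-0.5, 0.5), st.integers(1, 10**7),
           st.sampled_from([1, 2]),
           st.floats(0.01, 0.99))
    @settings(max_examples=200, derandomize=True)
    def test_probability_bounds(self, s, ne, c, p):
        out = fixation_probability(s, ne, c, p)
        assert 0.0 <= out <= 1.0

    def test_monotone_nondecreasing_in_s(self):
        grid = np.linspace(-0.05, 0.05, 201)
        vals = [fixation_probability(s, ne=1000, c=2, p=0.5) for s in grid]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))


class TestSampleEffect:
    def test_means_recover_the_stated_shifts(self, rng):
        n = 100_000
        vmax = [sample_effect(ROLE_FORWARD_VMAX, rng) for _ in range(n)]
        binding = [sample_effect(ROLE_BINDING, rng) for _ in range(n)]
        se = 0.01 / math.sqrt(n)
        assert abs(np.mean(vmax) - (-0.01)) < 3 * se
        assert abs(np.mean(binding) - 0.01) < 3 * se

    def test_degenerate_sigma_returns_the_mean(self, rng):
        mm = MutationModel(sigma=0.0)
        assert sample_effect(ROLE_BINDING, rng, mm) == 0.01
        assert sample_effect(ROLE_FORWARD_VMAX, rng, mm) == -0.01


class TestHaldaneUpdate:
    def _group(self):
        from pathway_evolver.model import HaldaneGroup
        return HaldaneGroup("R1", "Vf", "Vr", "Keq", ["KmS"], ["KmP"])

    def test_identity_recovery(self):
        vals = {"Vf": 10.0, "Vr": 999.0, "Keq": 2.0, "KmS": 1.0, "KmP": 4.0}
        assert apply_haldane_update(self._group(), "KmS", vals) == 20.0

    def test_km_mutation_shifts_vr(self):
        vals = {"Vf": 10.0, "Vr": 20.0, "Keq": 2.0, "KmS": 1.01, "KmP": 4.0}
        assert apply_haldane_update(self._group(), "KmS", vals) \
            == pytest.approx(40.0 / 2.02, rel=1e-12)

    def test_residual_restored_after_update(self):
        g = self._group()
        vals = {"Vf": 10.0, "Vr": 20.0, "Keq": 2.0, "KmS": 1.0, "KmP": 4.4}
        vals["Vr"] = apply_haldane_update(g, "KmP", vals)
        assert g.residual(vals) <= 1e-9

    def test_non_member_rejected(self):
        with pytest.raises(ValueError, match="member"):
            apply_haldane_update(self._group(), "Kother",
                                 {"Vf": 1.0, "Keq": 1.0, "KmS": 1, "KmP": 1,
                                  "Vr": 1.0, "Kother": 1.0})


class TestProposals:
    def test_empirical_rate_matches_lambda(self, rng):
        model, _ = make_linear_chain(n=5, enzyme_conc=True)
        state = initialize_population(model, [SelectionTarget("R1", 1.0)],
                                      ne=100, ploidy=2, rng=rng)
        gens = 60_000
        lam = MutationModel().rate
        n_func = 10  # kcat + Km per step
        total = 0
        for _ in range(gens):
            props = propose_mutations(state, model, rng)
            total += sum(1 for p in props if not p.parameter_id.startswith("E_"))
        observed = total / (gens * n_func)
        se = math.sqrt(lam / (gens * n_func))
        assert abs(observed - lam) < 3 * se

    def test_enzyme_to_functional_ratio_is_one(self, rng):
        model, _ = make_linear_chain(n=5, enzyme_conc=True)
        state = initialize_population(model, [SelectionTarget("R1", 1.0)],
                                      ne=100, ploidy=2, rng=rng)
        e = f = 0
        for _ in range(60_000):
            for p in propose_mutations(state, model, rng):
                if p.parameter_id.startswith("E_"):
                    e += 1
                else:
                    f += 1
        ratio = e / f
        se = ratio * math.sqrt(1 / e + 1 / f)
        assert abs(ratio - 1.0) < 3 * se

    def test_no_events_leaves_state_untouched(self, rng):
        model, _ = make_linear_chain(n=2)
        state = initialize_population(model, [SelectionTarget("R1", 1.0)],
                                      ne=100, ploidy=2, rng=rng)

        class ZeroPoisson:
            def poisson(self, lam):
                return np.zeros_like(np.asarray(lam), dtype=int)

        before = dict(state.parameter_values)
        assert propose_mutations(state, model, ZeroPoisson()) == []
        assert state.parameter_values == before

    def test_proposals_attach_haldane_updates(self, reversible_chain, rng):
        state = initialize_population(reversible_chain,
                                      [SelectionTarget("Rdrain", 1.0)],
                                      ne=100, ploidy=2, rng=rng)
        seen = False
        for _ in range(20_000):
            for p in propose_mutations(state, reversible_chain, rng):
                if p.parameter_id.startswith(("KmS", "KmP", "kcatf")):
                    seen = True
                    assert p.haldane_update is not None
        assert seen


class TestGenerationLoop:
    def test_zero_generations_is_identity(self, reversible_chain, rng):
        state = initialize_population(reversible_chain,
                                      [SelectionTarget("Rdrain", 1.0)],
                                      ne=100, ploidy=2, rng=rng)
        out, events, trace = simulate_generations(state, reversible_chain, 0,
                                                  rng)
        assert out is state and events == [] and trace == []

    def test_no_mutable_parameters_no_events(self, rng):
        model, _ = make_linear_chain(n=2)
        for p in model.all_parameters():
            p.mutable = False
        model._proposal_engine = None  # rebuilt with frozen parameters
        state = initialize_population(model, [SelectionTarget("R1", 1.0)],
                                      ne=100, ploidy=2, rng=rng)
        _, events, _ = simulate_generations(state, model, 2000, rng)
        assert events == []

    def test_rejection_reverts_bit_identically(self, reversible_chain, rng):
        class NeverFix:
            """Delegate draws but force every accept/reject draw to reject."""

            def __init__(self, inner):
                self._inner = inner

            def __getattr__(self, name):
                return getattr(self._inner, name)

            def random(self):
                return 1.0  # >= any fixation probability

        state = initialize_population(reversible_chain,
                                      [SelectionTarget("Rdrain", 1.0)],
                                      ne=100, ploidy=2, rng=rng)
        before = dict(state.parameter_values)
        conc_before = state.concentrations.copy()
        never = NeverFix(rng)
        rejected = 0
        for g in range(10_000):
            state, event = generation_step(state, reversible_chain, never,
                                           generation=g)
            if event is not None:
                assert not event.fixed
                rejected += 1
        assert rejected > 50
        assert state.parameter_values == before
        assert np.array_equal(state.concentrations, conc_before)

    def test_flux_neutral_mutations_fix_at_half(self, rng):
        # constant source: downstream parameters cannot move the selected
        # flux, so every proposal is neutral and ~50% of them fix
        model, _ = make_linear_chain(n=3)
        state = initialize_population(model, [SelectionTarget("R3", 1.0)],
                                      ne=1000, ploidy=2, rng=rng)
        _, events, _ = simulate_generations(state, model, 30_000, rng)
        assert len(events) > 100
        assert all(abs(e.fixation_probability - 0.5) < 1e-6 for e in events)
        frac_fixed = np.mean([e.fixed for e in events])
        se = math.sqrt(0.25 / len(events))
        assert abs(frac_fixed - 0.5) < 3.5 * se

    def test_lethal_when_solver_fails(self, rng):
        # an extreme mutation pushing Vmax below the source rate has no
        # steady state; the event must be recorded as lethal (fitness 0)
        model, _ = make_linear_chain(n=1, v0=1.0, vmax=1.05, km=1.0)
        state = initialize_population(model, [SelectionTarget("R1", 1.0)],
                                      ne=1000, ploidy=2, rng=rng)
        mm = MutationModel(rate=0.5, mean_shift=-0.2, sigma=0.05)
        from pathway_evolver.evolution import SolverOptions
        saw_lethal = False
        for g in range(400):
            state, event = generation_step(
                state, model, rng, mm,
                SolverOptions(time_cap=200.0), generation=g)
            if event is not None and event.fitness_after == 0.0:
                saw_lethal = True
                assert event.s == -1.0
                assert event.fixation_probability < 1e-300
                break
        assert saw_lethal
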