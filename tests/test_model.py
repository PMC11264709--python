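"""Model parsing, role classification, Haldane-group construction."""
import math

import pytest

from pathway_evolver.model import (
    ROLE_BINDING,
    ROLE_ENZYME_CONC,
    ROLE_FORWARD_VMAX,
    ROLE_KEQ,
    ROLE_OTHER,
    ModelError,
    ModelSyntaxError,
    RateEvaluationError,
    UndeclaredIdentifierError,
    UnsupportedFeatureError,
    build_haldane_groups,
    classify_parameters,
    evaluate_rate,
    parse_native_model,
    parse_sbml,
    serialize_native_model,
    serialize_sbml,
)

MINIMAL = """
species:
  Xin  init=1.0  boundary
  S1   init=0.5
parameters:
  Vmax = 2.0
  Km = 1.0
reactions:
  R1: Xin -> S1  rate = Vmax * Xin / (Km + Xin)
"""


class TestNativeFormat:
    def test_minimal_document(self):
        model = parse_native_model(MINIMAL)
        assert len(model.species) == 2
        assert len(model.reactions) == 1
        assert model.species[0].is_boundary
        assert model.parameter_values() == {"Vmax": 2.0, "Km": 1.0}

    def test_undeclared_identifier_is_named(self):
        bad = MINIMAL.replace("Km + Xin", "Kfoo + Xin")
        with pytest.raises(UndeclaredIdentifierError, match="Kfoo"):
            parse_native_model(bad)

    def test_syntax_error_carries_line_number(self):
        with pytest.raises(ModelSyntaxError, match="line 4"):
            parse_native_model("species:\n  A init=1.0\nparameters:\n  ???\n")

    def test_round_trip_preserves_values_and_stoichiometry(self, linear_chain):
        model, _ = linear_chain
        text = serialize_native_model(model)
        again = parse_native_model(text)
        assert again.parameter_values() == model.parameter_values()
        assert [(r.id, r.substrates, r.products) for r in again.reactions] \
            == [(r.id, r.substrates, r.products) for r in model.reactions]
        # a second round trip is a fixed point
        assert serialize_native_model(again) == text

    def test_stoichiometric_coefficients(self):
        text = MINIMAL.replace("R1: Xin -> S1", "R1: 2 Xin -> 3 S1")
        model = parse_native_model(text)
        assert model.reactions[0].substrates == [("Xin", 2)]
        assert model.reactions[0].products == [("S1", 3)]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            parse_native_model(MINIMAL + "\nparameters:\n  Vmax = 3.0\n")


class TestSBML:
    def test_minimal_mm_reaction_round_trip(self, linear_chain):
        model, _ = linear_chain
        doc = serialize_sbml(model)
        again = parse_sbml(doc)
        assert again.parameter_values() == model.parameter_values()
        assert [s.id for s in again.species] == [s.id for s in model.species]
        assert [s.is_boundary for s in again.species] \
            == [s.is_boundary for s in model.species]

    def test_boundary_condition_maps_to_flag(self, linear_chain):
        model, _ = linear_chain
        again = parse_sbml(serialize_sbml(model))
        assert again.species_by_id()["Xin"].is_boundary
        assert not again.species_by_id()["S1"].is_boundary

    def test_event_element_is_unsupported(self, linear_chain):
        model, _ = linear_chain
        doc = serialize_sbml(model)
        event = ('<listOfEvents><event id="ev" useValuesFromTriggerTime='
                 '"true"><trigger initialValue="false" persistent="true">'
                 "<math xmlns=\"http://www.w3.org/1998/Math/MathML\">"
                 "<true/></math></trigger></event></listOfEvents>")
        doc = doc.replace("</model>", event + "</model>")
        with pytest.raises(UnsupportedFeatureError, match="event"):
            parse_sbml(doc)


class TestClassification:
    @pytest.mark.parametrize("name,role", [
        ("KmATP", ROLE_BINDING),
        ("parameter__12", ROLE_OTHER),
        ("Vmax_HK", ROLE_FORWARD_VMAX),
        ("Keq_PGI", ROLE_KEQ),
        ("E_1", ROLE_ENZYME_CONC),
        ("KiGlc", ROLE_BINDING),
    ])
    def test_name_heuristics(self, name, role):
        text = MINIMAL.replace("  Km = 1.0", f"  Km = 1.0\n  {name} = 1.0")
        model = parse_native_model(text)
        assert classify_parameters(model)[name] == role

    def test_override_precedence_and_unknown_id(self):
        text = MINIMAL.replace("  Km = 1.0", "  Km = 1.0\n  parameter__12 = 1.0")
        model = parse_native_model(text)
        roles = classify_parameters(model,
                                    {"parameter__12": ROLE_BINDING})
        assert roles["parameter__12"] == ROLE_BINDING
        with pytest.raises(ModelError, match="nosuch"):
            classify_parameters(model, {"nosuch": ROLE_BINDING})

    def test_classification_is_pure(self, reversible_chain):
        a = classify_parameters(reversible_chain)
        b = classify_parameters(reversible_chain)
        assert a == b


REVERSIBLE_UNI_UNI = """
species:
  S  init=1.0
  P  init=1.0
parameters:
  Vf_1 = 10.0
  Vr_1 = 20.0
  Keq_1 = 2.0
  KmS_1 = 1.0
  KmP_1 = 4.0
reactions:
  R1: S -> P  rate = (Vf_1 * S / KmS_1 - Vr_1 * P / KmP_1) / (1 + S / KmS_1 + P / KmP_1)
"""


class TestHaldaneGroups:
    def test_uni_uni_group_satisfies_identity(self):
        model = parse_native_model(REVERSIBLE_UNI_UNI)
        groups = build_haldane_groups(model, classify_parameters(model))
        assert len(groups) == 1
        g = groups[0]
        assert (g.vf, g.vr, g.keq) == ("Vf_1", "Vr_1", "Keq_1")
        values = model.parameter_values()
        # Keq = (Vf * KmP) / (Vr * KmS) -> 10*4/(20*1) = 2
        assert g.residual(values) <= 1e-9

    def test_bi_uni_reaction_yields_no_group(self):
        text = REVERSIBLE_UNI_UNI.replace("R1: S -> P", "R1: S + P -> S")
        model = parse_native_model(text)
        assert build_haldane_groups(model, classify_parameters(model)) == []

    def test_irreversible_reaction_yields_no_group(self):
        text = REVERSIBLE_UNI_UNI.replace("  Vr_1 = 20.0\n", "")
        text = text.replace(" - Vr_1 * P / KmP_1", "")
        model = parse_native_model(text)
        assert build_haldane_groups(model, classify_parameters(model)) == []

    def test_inconsistent_group_is_skipped(self):
        text = REVERSIBLE_UNI_UNI.replace("Vr_1 = 20.0", "Vr_1 = 19.0")
        model = parse_native_model(text)
        assert build_haldane_groups(model, classify_parameters(model)) == []

    def test_fixture_chain_builds_one_group_per_step(self, reversible_chain):
        assert len(reversible_chain.haldane_groups) == 2
        values = reversible_chain.parameter_values()
        assert all(g.residual(values) <= 1e-9
                   for g in reversible_chain.haldane_groups)


class TestRateEvaluation:
    def test_irreversible_mm_value(self):
        text = """
species:
  S  init=1.0
  E  init=1.0  boundary
parameters:
  kcat = 2.0
  Km = 1.0
reactions:
  R1: S -> S  rate = kcat * E * S / (Km + S)
"""
        model = parse_native_model(text)
        r = model.reactions[0]
        rate = evaluate_rate(r, {"S": 1.0, "E": 1.0}, model.parameter_values())
        assert rate == pytest.approx(1.0)
        assert evaluate_rate(r, {"S": 0.0, "E": 1.0},
                             model.parameter_values()) == 0.0

    def test_reversible_mm_nulls_at_equilibrium(self):
        model = parse_native_model(REVERSIBLE_UNI_UNI)
        r = model.reactions[0]
        # P/S = Keq nulls the net rate
        rate = evaluate_rate(r, {"S": 1.0, "P": 2.0}, model.parameter_values())
        assert math.isclose(rate, 0.0, abs_tol=1e-12)

    def test_division_by_zero_names_reaction(self):
        text = MINIMAL.replace("rate = Vmax * Xin / (Km + Xin)",
                               "rate = Vmax / (Xin - 1)")
        model = parse_native_model(text)
        with pytest.raises(RateEvaluationError, match="R1"):
            evaluate_rate(model.reactions[0], {"Xin": 1.0, "S1": 0.5},
                          model.parameter_values())
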