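"""SBML and chain-notation round trips, subset boundaries, parse errors."""

import numpy as np
import pytest

from kinsim import (compile_model, fixtures, read_chain_notation, read_sbml,
                    write_chain_notation, write_sbml)
from kinsim import expr as ex
from kinsim.errors import (InvalidModelError, ParseError,
                           UnsupportedConstructError)
from kinsim.model_ir import ModelIR


def model_with_rules_and_events():
    m = ModelIR(id="rules_events")
    m.add_compartment("cell", 2.0)
    m.add_species("A", "cell", 4.0)
    m.add_species("B", "cell", 1.0, is_concentration=False)
    m.add_parameter("k", 0.5)
    m.add_parameter("total", 0.0, constant=False)
    m.add_reaction("J", ["A"], ["B"], "k*A")
    m.add_rule("assignment", "total", "A + B")
    m.add_rule("rate", "B", "0.1*A")
    m.add_event("flush", "time >= 2", [("A", "0.5")])
    m.add_initial_assignment("A", "2*k")
    return m


@pytest.mark.parametrize("make", [
    fixtures.two_step_chain,
    fixtures.closed_pair,
    fixtures.michaelis_menten,
    fixtures.bistable_switch,
    model_with_rules_and_events,
])
def test_write_read_round_trip_is_structural_identity(make):
    m = make()
    doc = write_sbml(m)
    assert m.structurally_equal(read_sbml(doc))


def test_chain_document_has_three_reactions(chain2):
    xml = write_sbml(chain2).xml_text
    assert xml.count("<reaction ") == 3


def test_empty_model_writes_minimal_document():
    doc = write_sbml(ModelIR(id="empty"))
    m = read_sbml(doc)
    assert m.id == "empty" and not m.species and not m.reactions


def test_invalid_model_is_rejected_on_write():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.add_species("A", "c", 1.0)
    m.compartments[0].size = 0.0
    with pytest.raises(InvalidModelError):
        write_sbml(m)


def test_distribution_draw_survives_round_trip():
    m = ModelIR(id="distrib")
    m.add_compartment("cell", 1.0)
    m.add_species("A", "cell", 1.0)
    m.add_initial_assignment("A", "normal(0, 1)")
    m2 = read_sbml(write_sbml(m))
    e = m2.initial_assignments[0].math
    assert e.kind == ex.DRAW and e.value == "normal"


def test_delay_is_unsupported():
    xml = write_sbml(fixtures.two_step_chain()).xml_text
    delayed = xml.replace(
        "<ci> X0 </ci>",
        '<apply><csymbol definitionURL="http://www.sbml.org/sbml/symbols/delay">'
        "delay</csymbol><ci> X0 </ci><cn>1</cn></apply>", 1)
    with pytest.raises(UnsupportedConstructError, match="delay"):
        read_sbml(delayed)


def test_algebraic_rule_is_unsupported():
    xml = write_sbml(model_with_rules_and_events()).xml_text
    broken = xml.replace('<assignmentRule variable="total">',
                         "<algebraicRule>", 1).replace(
        "</assignmentRule>", "</algebraicRule>", 1)
    with pytest.raises(UnsupportedConstructError, match="algebraicRule"):
        read_sbml(broken)


def test_malformed_xml_reports_parse_error():
    with pytest.raises(ParseError):
        read_sbml("<sbml><model>")


class TestChainNotation:
    def test_full_caption_string(self):
        m = read_chain_notation(fixtures.two_step_chain_text)
        assert [s.id for s in m.species] == ["X0", "S1", "S2"]
        assert m.species_by_id("X0").boundary
        assert m.species_by_id("X0").initial_value == 10.0
        assert not m.species_by_id("S1").boundary
        assert len(m.reactions) == 3
        assert {p.id: p.value for p in m.parameters} == \
            {"k1": 0.1, "k2": 0.3, "k3": 0.14}

    def test_literal_published_variant_parses_as_written(self):
        """The literal text (first rate k1*S1, spelling Xo) must parse; the
        spelling normalizes onto the declared species X0."""
        m = read_chain_notation(fixtures.two_step_chain_literal_text)
        assert m.species_by_id("X0").initial_value == 10.0
        law = m.reactions[0].kinetic_law
        assert law.free_symbols() == {"k1", "S1"}

    def test_minimal_reaction_defaults(self):
        m = read_chain_notation("A -> B; 1")
        assert len(m.reactions) == 1
        assert [s.initial_value for s in m.species] == [0.0, 0.0]
        assert not any(s.boundary for s in m.species)

    def test_missing_rate_is_a_parse_error(self):
        with pytest.raises(ParseError):
            read_chain_notation("A -> ; ")

    def test_explicit_boundary_marker(self):
        m = read_chain_notation("$X -> S; k*X; k = 1")
        assert m.species_by_id("X").boundary

    def test_stoichiometric_coefficients(self):
        m = read_chain_notation("2 A -> B; k*A*A; k = 1; A = 3")
        r = m.reactions[0]
        assert r.reactants[0].stoichiometry == 2.0

    def test_chain_round_trip_through_writer(self):
        m = fixtures.two_step_chain()
        m2 = read_chain_notation(write_chain_notation(m))
        xa, xb = compile_model(m), compile_model(m2)
        state = np.array([1.7, 2.9])
        assert xa.rhs(0.0, state) == pytest.approx(xb.rhs(0.0, state), abs=1e-12)


def test_chain_and_sbml_routes_agree_pointwise(rng):
    """The two input routes must compile to evaluators with identical RHS."""
    via_chain = compile_model(read_chain_notation(fixtures.two_step_chain_text))
    via_sbml = compile_model(read_sbml(write_sbml(fixtures.two_step_chain())))
    for _ in range(20):
        state = rng.uniform(0, 10, size=2)
        assert via_chain.rhs(0.0, state) == pytest.approx(
            via_sbml.rhs(0.0, state), abs=1e-12)
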