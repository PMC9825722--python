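"""Compiled evaluator: stoichiometry, rates, RHS, cache, events, draws."""

import numpy as np
import pytest

from kinsim import compile_model, fixtures, handle_events
from kinsim import engine
from kinsim.errors import (CyclicAssignmentError, DomainError,
                           InvalidModelError, StaleModelError,
                           UnsupportedConstructError)
from kinsim.model_ir import ModelIR


def test_chain_stoichiometry_matrix(chain2_exec):
    # chain topology: J1 produces S1, J2 converts S1->S2, J3 consumes S2
    assert np.array_equal(chain2_exec.stoichiometry_matrix,
                          [[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])


def test_chain_rates_at_unit_state(chain2_exec):
    v = chain2_exec.evaluate_rates(0.0, [1.0, 1.0])
    assert v == pytest.approx([1.0, 0.3, 0.14])


def test_chain_rhs_at_origin_and_steady_state(chain2_exec):
    assert chain2_exec.rhs(0.0, [0.0, 0.0]) == pytest.approx([1.0, 0.0])
    assert np.max(np.abs(chain2_exec.rhs(0.0, [10 / 3, 50 / 7]))) < 1e-12


def test_zero_state_zeroes_mass_action_rates(closed_pair_exec):
    assert closed_pair_exec.evaluate_rates(0.0, [0.0, 0.0]) == pytest.approx([0, 0])


def test_rhs_is_linear_in_rates(mm_exec, rng):
    """rhs(x) = N v(x) exactly for pure reaction-governed models."""
    N = mm_exec.stoichiometry_matrix
    for _ in range(20):
        x = rng.uniform(0.01, 5.0, size=2)
        assert mm_exec.rhs(0.0, x) == pytest.approx(
            N @ mm_exec.evaluate_rates(0.0, x), abs=1e-14)


def test_left_null_vectors_annihilate_rhs(closed_pair_exec, rng):
    """Conservation holds at the RHS level: c^T N = 0 implies c^T f(x) = 0."""
    c = np.array([1.0, 1.0])
    assert np.allclose(c @ closed_pair_exec.stoichiometry_matrix, 0.0)
    for _ in range(20):
        x = rng.uniform(0, 10, size=2)
        assert abs(c @ closed_pair_exec.rhs(0.0, x)) < 1e-12


def test_cache_consistency(chain2, rng):
    """A cache-served artifact and a fresh compile agree pointwise."""
    cached = compile_model(chain2)
    fresh = compile_model(chain2, force_regenerate=True)
    for _ in range(100):
        x = rng.uniform(0, 20, size=2)
        assert cached.rhs(0.0, x) == pytest.approx(fresh.rhs(0.0, x), abs=1e-12)
        assert cached.evaluate_rates(0.0, x) == pytest.approx(
            fresh.evaluate_rates(0.0, x), abs=1e-12)


def test_repeated_compile_hits_artifact_cache(chain2):
    compile_model(chain2)
    before = engine.artifact_cache_info()
    compile_model(chain2)
    after = engine.artifact_cache_info()
    assert after["hits"] == before["hits"] + 1
    assert after["compiles"] == before["compiles"]


def test_cyclic_assignment_rules_rejected():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.add_parameter("a", 0.0, constant=False)
    m.add_parameter("b", 0.0, constant=False)
    m.add_rule("assignment", "a", "b")
    m.add_rule("assignment", "b", "a")
    with pytest.raises(CyclicAssignmentError):
        compile_model(m)


def test_invalid_model_rejected_at_compile():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.compartments[0].size = -1.0
    with pytest.raises(InvalidModelError):
        compile_model(m)


def test_stale_model_refuses_to_evaluate(chain2):
    xm = compile_model(chain2)
    chain2.add_parameter("k_new", 1.0)
    assert xm.stale
    with pytest.raises(StaleModelError):
        xm.evaluate_rates(0.0, [1.0, 1.0])
    with pytest.raises(StaleModelError):
        xm.rhs(0.0, [1.0, 1.0])


def test_domain_error_names_the_reaction():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.add_species("S", "c", 0.0)
    m.add_reaction("Jlog", ["S"], [], "ln(S)")
    xm = compile_model(m)
    with pytest.raises(DomainError, match="Jlog"):
        xm.evaluate_rates(0.0, [0.0])


def test_rate_rule_contributes_constant_derivative():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.add_parameter("P", 0.0, constant=False)
    m.add_rule("rate", "P", "1")
    xm = compile_model(m)
    assert xm.rhs(0.0, [3.0]) == pytest.approx([1.0])
    assert xm.rhs(7.0, [100.0]) == pytest.approx([1.0])


def test_assignment_rules_feed_kinetic_laws():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.add_species("S", "c", 2.0)
    m.add_parameter("scaled", 0.0, constant=False)
    m.add_parameter("k", 3.0)
    m.add_rule("assignment", "scaled", "2*S")
    m.add_reaction("J", ["S"], [], "k*scaled")
    xm = compile_model(m)
    assert xm.evaluate_rates(0.0, [2.0]) == pytest.approx([12.0])


def test_draws_restricted_to_initial_context():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.add_species("S", "c", 1.0)
    m.add_reaction("J", ["S"], [], "normal(0, 1)*S")
    with pytest.raises(UnsupportedConstructError):
        compile_model(m)


def test_seeded_draw_determinism():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.add_species("S", "c", 0.0)
    m.add_initial_assignment("S", "normal(5, 1)")
    a = compile_model(m, seed=42)
    b = compile_model(m, seed=42)
    other = compile_model(m, seed=43)
    assert a.state[0] == b.state[0]
    assert a.state[0] != other.state[0]
    assert a.state[0] != 5.0  # a draw happened, not the declared value


class TestEvents:
    def make(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_species("S1", "c", 1.0)
        m.add_rule("rate", "S1", "0")
        m.add_event("reset", "time >= 5", [("S1", "0")])
        return compile_model(m)

    def test_bisection_finds_linear_trigger_time(self):
        xm = self.make()
        res = handle_events(xm, 4.9, 5.1, np.array([1.0]), np.array([1.0]))
        assert res is not None
        t_fire, post = res
        assert t_fire == pytest.approx(5.0, abs=1e-9)
        assert post[0] == 0.0

    def test_no_transition_returns_none(self):
        xm = self.make()
        assert handle_events(xm, 0.0, 1.0, np.array([1.0]), np.array([1.0])) is None

    def test_simultaneous_events_apply_in_document_order(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_species("S", "c", 1.0)
        m.add_rule("rate", "S", "0")
        m.add_event("first", "time >= 2", [("S", "10")])
        m.add_event("second", "time >= 2", [("S", "20")])
        xm = compile_model(m)
        _, post = handle_events(xm, 1.9, 2.1, np.array([1.0]), np.array([1.0]))
        assert post[0] == 20.0  # the later event's write wins

    def test_assignments_are_simultaneous(self):
        """All RHS evaluate against the pre-event state before any write."""
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_species("A", "c", 2.0)
        m.add_species("B", "c", 3.0)
        m.add_rule("rate", "A", "0")
        m.add_rule("rate", "B", "0")
        m.add_event("swap", "time >= 1", [("A", "B"), ("B", "A")])
        xm = compile_model(m)
        _, post = handle_events(xm, 0.5, 1.5, np.array([2.0, 3.0]),
                                np.array([2.0, 3.0]))
        assert post == pytest.approx([3.0, 2.0])
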