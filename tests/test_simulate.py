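"""Time-course integration: accuracy, grids, events, stochastic runs."""

import numpy as np
import pytest

from kinsim import (IntegratorOptions, compile_model, fixtures, gillespie,
                    simulate)
from kinsim.errors import KinsimError
from kinsim.model_ir import ModelIR
from kinsim.simulate import step_euler, step_rk45

from conftest import deterministic_fixture_models


def decay_model(rate=1.0, s0=1.0):
    m = ModelIR(id="decay")
    m.add_compartment("c", 1.0)
    m.add_species("S", "c", s0)
    m.add_parameter("k", rate)
    m.add_reaction("J", ["S"], [], "k*S")
    return m


def test_rk45_reproduces_exponential_decay():
    xm = compile_model(decay_model())
    tc = simulate(xm, 0, 1, 11, IntegratorOptions(rel_tol=1e-8))
    assert tc["S"][-1] == pytest.approx(np.exp(-1.0), abs=1e-6)


def test_grid_semantics_points_includes_both_endpoints(chain2_exec):
    tc = simulate(chain2_exec, 0, 10, 11)
    assert tc.values.shape[0] == 11
    assert tc.times[0] == 0.0 and tc.times[-1] == 10.0
    assert np.all(np.diff(tc.times) > 0)
    # row 0 is the initial condition
    assert tc.values[0, 1:] == pytest.approx([0.0, 0.0])


def test_degenerate_window_rejected(chain2_exec):
    with pytest.raises(ValueError):
        simulate(chain2_exec, 5.0, 5.0, 11)
    with pytest.raises(ValueError):
        simulate(chain2_exec, 0.0, 10.0, 1)


class TestEulerStep:
    def test_single_explicit_step(self):
        xm = compile_model(decay_model())
        assert step_euler(xm, 0.0, [1.0], 0.1) == pytest.approx([0.9])

    def test_zero_rhs_leaves_state(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_species("S", "c", 4.0)
        xm = compile_model(m)
        assert step_euler(xm, 0.0, [4.0], 0.5) == pytest.approx([4.0])

    def test_chain_first_step_from_origin(self, chain2_exec):
        out = step_euler(chain2_exec, 0.0, [0.0, 0.0], 0.01)
        assert out[0] == pytest.approx(0.01)  # h * k1 * X0


class TestRk45Step:
    def test_constant_rhs_is_exact(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_parameter("P", 0.0, constant=False)
        m.add_rule("rate", "P", "3")
        xm = compile_model(m)
        state, err, h_next = step_rk45(xm, 0.0, [1.0], 0.25)
        assert state == pytest.approx([1.75], abs=1e-15)
        assert err < 1e-14

    def test_error_estimate_vanishes_on_quadratic_solution(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_parameter("P", 0.0, constant=False)
        m.add_rule("rate", "P", "2*time")
        xm = compile_model(m)
        state, err, _ = step_rk45(xm, 1.0, [1.0], 0.5)
        assert state == pytest.approx([1.0 + (1.5**2 - 1.0)], abs=1e-13)
        assert err < 1e-12

    def test_observed_convergence_order(self):
        """The 5th-order solution should show order >= 4.8 under h-halving."""
        xm = compile_model(decay_model())
        errors = []
        hs = [0.4 / 2**i for i in range(4)]
        for h in hs:
            state, _, _ = step_rk45(xm, 0.0, [1.0], h)
            errors.append(abs(state[0] - np.exp(-h)))
        orders = [np.log2(errors[i] / errors[i + 1]) - 1  # minus dt scaling
                  for i in range(len(errors) - 1)]
        # local error order p+1 = 6 for a 5th-order method; subtracting the
        # one order lost per halving of the interval leaves >= 4.8
        assert min(orders) >= 4.8


def test_cross_integrator_agreement():
    """Euler at small fixed step double-checks the adaptive solution."""
    for ir in deterministic_fixture_models():
        a = simulate(compile_model(ir), 0, 10, 11,
                     IntegratorOptions(name="euler", fixed_step=1e-4))
        b = simulate(compile_model(ir), 0, 10, 11,
                     IntegratorOptions(name="rk45", rel_tol=1e-8))
        ref = np.maximum(np.abs(b.values[-1, 1:]), 1e-9)
        rel = np.max(np.abs(a.values[-1, 1:] - b.values[-1, 1:]) / ref)
        assert rel < 1e-3, ir.id


def test_closed_system_conserves_mass_along_trajectory(closed_pair_exec):
    tc = simulate(closed_pair_exec, 0, 10, 201, IntegratorOptions(rel_tol=1e-8))
    total = tc["S1"] + tc["S2"]
    assert np.max(np.abs(total - total[0])) / total[0] < 1e-9


def test_bdf_backend_matches_rk45(mm_exec):
    a = simulate(mm_exec, 0, 20, 21, IntegratorOptions(name="bdf", rel_tol=1e-8))
    b = simulate(compile_model(fixtures.michaelis_menten()), 0, 20, 21,
                 IntegratorOptions(name="rk45", rel_tol=1e-8))
    assert a.values[-1, 1:] == pytest.approx(b.values[-1, 1:], rel=1e-5)


class TestEventsInSimulation:
    def make_ir(self):
        m = decay_model(rate=0.0, s0=0.0)
        m.add_parameter("growth", 1.0)
        m.add_reaction("Jin", [], ["S"], "growth")
        m.add_event("reset", "time >= 5", [("S", "0")])
        return m

    def test_event_fires_and_resets_species(self):
        xm = compile_model(self.make_ir())
        tc = simulate(xm, 0, 10, 101, IntegratorOptions(rel_tol=1e-10))
        t = tc.times
        # S grows linearly, resets to 0 at t=5, then grows again
        assert tc["S"][np.isclose(t, 4.9)][0] == pytest.approx(4.9, abs=1e-6)
        assert tc["S"][np.isclose(t, 5.1)][0] == pytest.approx(0.1, abs=1e-6)
        assert tc["S"][-1] == pytest.approx(5.0, abs=1e-6)

    def test_split_call_equals_single_call(self):
        """Simulating through the event window in one call equals splitting
        the call at a grid point (state continuity)."""
        one = simulate(compile_model(self.make_ir()), 0, 10, 21,
                       IntegratorOptions(rel_tol=1e-10))
        xm = compile_model(self.make_ir())
        first = simulate(xm, 0, 4, 9, IntegratorOptions(rel_tol=1e-10))
        second = simulate(xm, 4, 10, 13, IntegratorOptions(rel_tol=1e-10))
        stitched = np.vstack([first.values, second.values[1:]])
        assert stitched[:, 1] == pytest.approx(one.values[:, 1], abs=1e-9)


class TestGillespie:
    def test_same_seed_bit_identical(self):
        opts = IntegratorOptions(name="gillespie", seed=11)
        a = gillespie(compile_model(fixtures.immigration_death()), 0, 50, 501, opts)
        b = gillespie(compile_model(fixtures.immigration_death()), 0, 50, 501, opts)
        assert np.array_equal(a.values, b.values)
        assert a.seed_used == 11

    def test_different_seeds_differ(self):
        a = gillespie(compile_model(fixtures.immigration_death()), 0, 50, 501,
                      IntegratorOptions(name="gillespie", seed=1))
        b = gillespie(compile_model(fixtures.immigration_death()), 0, 50, 501,
                      IntegratorOptions(name="gillespie", seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_zero_propensities_freeze_trajectory(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_species("S", "c", 5.0, is_concentration=False)
        m.add_parameter("k", 0.0)
        m.add_reaction("J", ["S"], [], "k*S")
        tc = gillespie(compile_model(m), 0, 10, 11,
                       IntegratorOptions(name="gillespie", seed=0))
        assert np.all(tc["S"] == 5.0)

    def test_non_integer_start_rejected(self):
        m = fixtures.immigration_death(s_init=0.5)
        with pytest.raises(KinsimError):
            gillespie(compile_model(m), 0, 1, 11,
                      IntegratorOptions(name="gillespie", seed=0))

    def test_stationary_mean_and_fano_factor(self):
        """Immigration-death stationary law is Poisson(k/gamma): mean 10,
        variance/mean 1."""
        samples = []
        for seed in range(6):
            xm = compile_model(fixtures.immigration_death())
            tc = gillespie(xm, 0, 150, 751,
                           IntegratorOptions(name="gillespie", seed=seed))
            samples.append(tc["S"][tc.times >= 50.0])
        pool = np.concatenate(samples)
        assert pool.mean() == pytest.approx(10.0, abs=0.5)
        assert 0.9 <= pool.var() / pool.mean() <= 1.1


def test_timecourse_csv_round_trip(tmp_path, chain2_exec):
    tc = simulate(chain2_exec, 0, 5, 6)
    path = tmp_path / "tc.csv"
    tc.to_csv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "time,S1,S2"
    back = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
    assert np.array_equal(back, tc.values)  # 17 significant digits: lossless
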