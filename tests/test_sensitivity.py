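"""Forward, staggered and finite-difference sensitivities; steady-state
sensitivities and their closed forms on the linear chain."""

import numpy as np
import pytest

from kinsim import (SensitivityOptions, compile_model,
                    finite_difference_sensitivities, fixtures,
                    forward_sensitivities, newton_steady_state,
                    steady_state_sensitivities)
from kinsim.errors import KinsimError


def test_initial_sensitivities_vanish(chain2_exec):
    res = forward_sensitivities(chain2_exec, 0, 10, 11)
    assert np.max(np.abs(res.values[0])) == 0.0


def test_chain_closed_form_limits(chain2):
    """At large t the trajectories' sensitivities approach the steady-state
    closed forms of the chain: dS1/dk1 -> X0/k2, dS1/dk3 = 0 identically."""
    res = forward_sensitivities(compile_model(chain2), 0, 400, 81)
    assert res.get("k1", "S1")[-1] == pytest.approx(10.0 / 0.3, abs=1e-3)
    assert np.max(np.abs(res.get("k3", "S1"))) == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("make", [fixtures.two_step_chain, fixtures.michaelis_menten,
                                  lambda: fixtures.linear_chain(3, seed=11)])
def test_forward_methods_are_interchangeable(make):
    sim = forward_sensitivities(compile_model(make()), 0, 40, 81)
    stag = forward_sensitivities(compile_model(make()), 0, 40, 81,
                                 SensitivityOptions(method="staggered"))
    assert np.max(np.abs(sim.values - stag.values)) < 1e-6


def test_forward_methods_match_finite_differences(chain2):
    sim = forward_sensitivities(compile_model(chain2), 0, 40, 101)
    stag = forward_sensitivities(compile_model(chain2), 0, 40, 101,
                                 SensitivityOptions(method="staggered"))
    fd = finite_difference_sensitivities(compile_model(chain2), 0, 40, 101)
    assert np.max(np.abs(sim.values - fd.values)) < 1e-4
    assert np.max(np.abs(stag.values - fd.values)) < 1e-4


def test_parameter_subset_equals_slice_of_full_result(chain2):
    # adaptive step control couples the augmented system, so the forward
    # route agrees to integration accuracy; the FD route slices exactly
    full = forward_sensitivities(compile_model(chain2), 0, 20, 21)
    sub = forward_sensitivities(compile_model(chain2), 0, 20, 21,
                                SensitivityOptions(parameters=["k2"]))
    j = full.parameter_ids.index("k2")
    assert sub.values[:, 0, :] == pytest.approx(full.values[:, j, :], abs=1e-6)

    full_fd = finite_difference_sensitivities(compile_model(chain2), 0, 20, 21)
    sub_fd = finite_difference_sensitivities(
        compile_model(chain2), 0, 20, 21,
        SensitivityOptions(method="finite-difference", parameters=["k2"]))
    assert np.array_equal(sub_fd.values[:, 0, :], full_fd.values[:, j, :])


def test_initial_value_sensitivity_identity_at_t0(chain2):
    res = forward_sensitivities(compile_model(chain2), 0, 5, 6,
                                SensitivityOptions(parameters=["S1"]))
    assert res.values[0, 0, :] == pytest.approx([1.0, 0.0])
    # dS1(t)/dS1(0) decays like exp(-k2 t)
    assert res.get("S1", "S1")[-1] == pytest.approx(np.exp(-0.3 * 5), abs=1e-6)


def test_unknown_parameter_rejected_by_forward(chain2_exec):
    with pytest.raises(KinsimError):
        forward_sensitivities(chain2_exec, 0, 1, 3,
                              SensitivityOptions(parameters=["nope"]))


def test_unknown_parameter_gives_zero_column_in_fd(chain2_exec):
    res = finite_difference_sensitivities(
        chain2_exec, 0, 5, 6, SensitivityOptions(method="finite-difference",
                                               parameters=["k1", "ghost"]))
    assert np.max(np.abs(res.values[:, 1, :])) == 0.0
    assert np.max(np.abs(res.values[:, 0, :])) > 0.0


def test_zero_fd_step_rejected():
    with pytest.raises(ValueError):
        SensitivityOptions(method="finite-difference", fd_step=0.0)


class TestSteadyStateSensitivities:
    @pytest.fixture
    def solved(self, chain2):
        xm = compile_model(chain2)
        newton_steady_state(xm)
        return xm

    def test_chain_closed_forms(self, solved):
        S = steady_state_sensitivities(solved, ["k1", "k2", "k3"])
        i_s1, i_s2 = 0, 1
        # S1* = k1 X0 / k2, S2* = k1 X0 / k3
        assert S[0, i_s1] == pytest.approx(10.0 / 0.3, abs=1e-6)       # dS1/dk1
        assert S[1, i_s1] == pytest.approx(-0.1 * 10 / 0.3**2, abs=1e-6)
        assert S[1, i_s2] == pytest.approx(0.0, abs=1e-9)              # dS2/dk2
        assert S[2, i_s2] == pytest.approx(-0.1 * 10 / 0.14**2, abs=1e-4)

    def test_fully_scaled_gives_power_law_exponent(self, solved):
        S = steady_state_sensitivities(solved, ["k3"], "fully-scaled")
        assert S[0, 1] == pytest.approx(-1.0, abs=1e-9)   # S2* ~ k3^-1

    def test_limit_consistency_with_time_dependent(self, chain2):
        """Sensitivities at t >> the slowest timescale match the steady-state
        linear solve.  The sensitivity transients carry secular t*exp(-t/tau)
        terms (tau = 1/k3 ~ 7), so the limit is taken at 10 doubled
        timescales, t = 10 * (2/k3) ~ 143."""
        td = forward_sensitivities(compile_model(chain2), 0, 150, 16)
        xm = compile_model(chain2)
        newton_steady_state(xm)
        ss = steady_state_sensitivities(xm, td.parameter_ids)
        assert np.max(np.abs(td.values[-1] - ss)) < 1e-4


def test_normalization_modes(chain2):
    raw = forward_sensitivities(compile_model(chain2), 0, 40, 5)
    pscaled = forward_sensitivities(
        compile_model(chain2), 0, 40, 5,
        SensitivityOptions(normalization="parameter-scaled"))
    j = raw.parameter_ids.index("k2")
    assert pscaled.values[:, j, :] == pytest.approx(0.3 * raw.values[:, j, :],
                                                    rel=1e-12)
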