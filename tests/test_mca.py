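"""Jacobian, stability verdicts, elasticities and control coefficients."""

import numpy as np
import pytest

from kinsim import (IntegratorOptions, compile_model, control_coefficients,
                    elasticities, fixtures, newton_steady_state,
                    reduced_jacobian, simulate, stability)
from kinsim.errors import NotAtSteadyStateError, ZeroFluxScalingError
from kinsim.mca import perturb_reaction_activity
from kinsim.model_ir import ModelIR


def test_chain_jacobian_is_constant_and_triangular(chain2_exec):
    J = chain2_exec.jacobian(0.0, np.array([1.0, 1.0]))
    assert J == pytest.approx(np.array([[-0.3, 0.0], [0.3, -0.14]]))
    J2 = chain2_exec.jacobian(0.0, np.array([7.0, 2.0]))
    assert J2 == pytest.approx(J)  # linear model: state-independent


def test_zero_rate_model_has_zero_jacobian():
    m = ModelIR()
    m.add_compartment("c", 1.0)
    m.add_species("S", "c", 1.0)
    m.add_parameter("k", 0.0)
    m.add_reaction("J", ["S"], [], "k*S")
    xm = compile_model(m)
    assert np.max(np.abs(xm.jacobian(0.0, np.array([1.0])))) == 0.0


def test_jacobian_matches_finite_differences(mm_exec):
    x = np.array([0.7, 1.3])
    J = mm_exec.jacobian(0.0, x)
    h = 1e-7
    fd = np.empty_like(J)
    for j in range(2):
        xp, xmn = x.copy(), x.copy()
        xp[j] += h
        xmn[j] -= h
        fd[:, j] = (mm_exec.rhs(0.0, xp) - mm_exec.rhs(0.0, xmn)) / (2 * h)
    assert J == pytest.approx(fd, abs=1e-6)


class TestStability:
    def test_chain_is_stable_with_triangular_spectrum(self, chain2):
        xm = compile_model(chain2)
        newton_steady_state(xm)
        rep = stability(xm)
        assert sorted(rep.eigenvalues.real) == pytest.approx([-0.3, -0.14])
        assert rep.verdict == "stable"

    def test_pure_growth_is_unstable(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_species("S", "c", 0.0)
        m.add_reaction("J", [], ["S"], "S", modifiers=["S"])
        xm = compile_model(m)
        rep = stability(xm, steady_state=np.array([0.0]))
        assert rep.max_real_part == pytest.approx(1.0)
        assert rep.verdict == "unstable"

    def test_closed_pair_reduces_to_single_eigenvalue(self):
        xm = compile_model(fixtures.closed_pair(1.0, 1.0))
        newton_steady_state(xm)
        rep = stability(xm)
        assert rep.jacobian.shape == (1, 1)
        assert rep.eigenvalues == pytest.approx([-2.0])
        assert rep.verdict == "stable"

    def test_non_stationary_point_rejected(self, chain2_exec):
        with pytest.raises(NotAtSteadyStateError):
            stability(chain2_exec, steady_state=np.array([100.0, 100.0]))

    def test_verdict_agrees_with_perturbed_integration(self):
        """1%-perturbed trajectories return to stable roots and leave the
        unstable one."""
        ir = fixtures.bistable_switch()
        low, mid, high = ir.metadata["roots"]

        xm = compile_model(ir)
        xm.state = np.array([high])
        assert stability(xm).verdict == "stable"
        xm.state = np.array([high * 1.01])
        tc = simulate(xm, 0, 200, 3)
        assert tc.values[-1, 1] == pytest.approx(high, abs=1e-6)

        xm2 = compile_model(ir)
        xm2.state = np.array([mid])
        assert stability(xm2, residual_tol=1e-8).verdict == "unstable"
        xm2.state = np.array([mid * 1.01])
        tc2 = simulate(xm2, 0, 200, 3)
        assert abs(tc2.values[-1, 1] - mid) > 0.5  # driven away to `high`


class TestElasticities:
    def test_first_order_mass_action_scaled_elasticity_is_one(self, chain2):
        xm = compile_model(chain2)
        newton_steady_state(xm)
        E = elasticities(xm, scaled=True)
        assert E[1, 0] == pytest.approx(1.0)   # v2 = k2*S1 w.r.t. S1
        assert E[0, 0] == pytest.approx(0.0)   # v1 = k1*X0: no S1 dependence
        assert E[0, 1] == pytest.approx(0.0)

    def test_power_law_exponent(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_species("S", "c", 3.0)
        m.add_parameter("k", 0.7)
        m.add_reaction("J", ["S"], [], "k*S^2")
        xm = compile_model(m)
        E = elasticities(xm, state=np.array([3.0]), scaled=True)
        assert E[0, 0] == pytest.approx(2.0)

    def test_zero_rate_scaling_rejected(self):
        m = ModelIR()
        m.add_compartment("c", 1.0)
        m.add_species("S", "c", 1.0)
        m.add_parameter("k", 0.0)
        m.add_reaction("J", ["S"], [], "k*S")
        with pytest.raises(ZeroFluxScalingError):
            elasticities(compile_model(m), scaled=True)


def mca_fixture_models():
    return [fixtures.two_step_chain(), fixtures.michaelis_menten(),
            fixtures.linear_chain(4, seed=5), fixtures.closed_pair(1.3, 0.6)]


class TestControlCoefficients:
    def solved(self, ir):
        xm = compile_model(ir)
        newton_steady_state(xm)
        return xm

    def test_chain_flux_control_is_all_in_the_supply_step(self, chain2):
        rep = control_coefficients(self.solved(chain2))
        assert rep.flux_control[0] == pytest.approx([1.0, 0.0, 0.0], abs=1e-9)

    def test_chain_concentration_control_of_s2_by_consumption(self, chain2):
        rep = control_coefficients(self.solved(chain2))
        i, j = rep.species_ids.index("S2"), rep.reaction_ids.index("J3")
        assert rep.concentration_control[i, j] == pytest.approx(-1.0, abs=1e-9)

    @pytest.mark.parametrize("ir", mca_fixture_models(), ids=lambda m: m.id)
    def test_summation_theorems(self, ir):
        rep = control_coefficients(self.solved(ir))
        assert rep.flux_control.sum(axis=1) == pytest.approx(
            np.ones(len(rep.reaction_ids)), abs=1e-6)
        assert rep.concentration_control.sum(axis=1) == pytest.approx(
            np.zeros(len(rep.species_ids)), abs=1e-6)

    @pytest.mark.parametrize("ir", [fixtures.two_step_chain(),
                                    fixtures.michaelis_menten(),
                                    fixtures.linear_chain(4, seed=5)],
                             ids=lambda m: m.id)
    def test_connectivity_theorem(self, ir):
        """C^J . scaled elasticities = 0 species-wise (no conservation)."""
        xm = self.solved(ir)
        rep = control_coefficients(xm)
        prod = rep.flux_control @ rep.scaled_elasticities
        assert np.max(np.abs(prod)) < 1e-6

    def test_perturbation_oracle(self, chain2):
        """Scaled C^J matches Delta(ln J)/Delta(ln e) from re-solving after
        scaling one reaction's activity by 1.001."""
        rep = control_coefficients(self.solved(chain2))
        factor = 1.001
        for j, rid in enumerate(rep.reaction_ids):
            pert = perturb_reaction_activity(chain2, rid, factor)
            xm = compile_model(pert)
            newton_steady_state(xm)
            flux_p = xm.evaluate_rates(0.0, xm.state)
            measured = np.log(flux_p / rep.flux) / np.log(factor)
            assert measured == pytest.approx(rep.flux_control[:, j],
                                             abs=0.02, rel=0.02)

    def test_zero_flux_makes_scaled_coefficients_an_error(self):
        m = fixtures.closed_pair(k_forward=1.0, k_backward=1.0,
                                 s1_init=0.0, s2_init=0.0)
        xm = compile_model(m)
        newton_steady_state(xm)
        with pytest.raises(ZeroFluxScalingError):
            control_coefficients(xm)


def test_reduced_jacobian_of_closed_pair():
    xm = compile_model(fixtures.closed_pair(1.0, 1.0))
    assert reduced_jacobian(xm).shape == (1, 1)
    assert reduced_jacobian(xm)[0, 0] == pytest.approx(-2.0)
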