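"""Jacobian, stability, elasticities and metabolic control analysis.

Control coefficients follow the standard summation/connectivity framework
(Kacser-Burns scaling): with N = L N_R the moiety-reduced stoichiometry,
E = dv/dx the unscaled elasticity matrix and J_R = N_R E L the reduced
Jacobian,

    C^S = -L J_R^{-1} N_R            (species x reactions, unscaled)
    C^J = E C^S + I                  (reactions x reactions, unscaled)

scaled by v_j / x_i and v_j / J_i respectively.  The link-matrix formula is
exact at a steady state; numeric perturbation of reaction activities is kept
as an independent oracle in the test-suite, not as the implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import expr as ex
from .engine import ExecutableModel
from .errors import (
    KinsimError,
    NotAtSteadyStateError,
    SingularJacobianError,
    ZeroFluxScalingError,
)
from .model_ir import ModelIR
from .steady_state import Reduction

__all__ = ["MCAReport", "StabilityReport", "reduced_jacobian", "stability",
           "elasticities", "control_coefficients", "perturb_reaction_activity"]

_STABILITY_TOL = 1e-9


@dataclass
class StabilityReport:
    jacobian: np.ndarray            # reduced r x r
    eigenvalues: np.ndarray
    max_real_part: float
    verdict: str                    # stable | unstable | marginal


@dataclass
class MCAReport:
    species_ids: list[str]
    reaction_ids: list[str]
    unscaled_elasticities: np.ndarray       # reactions x species
    scaled_elasticities: np.ndarray
    concentration_control: np.ndarray       # species x reactions, scaled
    flux_control: np.ndarray                # reactions x reactions, scaled
    unscaled_concentration_control: np.ndarray
    unscaled_flux_control: np.ndarray
    steady_state: np.ndarray
    flux: np.ndarray

    def to_dict(self) -> dict:
        return {
            "species": self.species_ids,
            "reactions": self.reaction_ids,
            "unscaled_elasticities": self.unscaled_elasticities.tolist(),
            "scaled_elasticities": self.scaled_elasticities.tolist(),
            "concentration_control": self.concentration_control.tolist(),
            "flux_control": self.flux_control.tolist(),
            "steady_state": self.steady_state.tolist(),
            "flux": self.flux.tolist(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def flux_control_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flux_control, index=self.reaction_ids,
                            columns=self.reaction_ids)

    def concentration_control_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.concentration_control, index=self.species_ids,
                            columns=self.reaction_ids)


def _require_reaction_model(exec_model: ExecutableModel):
    if exec_model.layout.rate_rule_order:
        raise KinsimError("control analysis requires a pure reaction network "
                          "(no rate rules)")


def reduced_jacobian(exec_model: ExecutableModel, state=None) -> np.ndarray:
    """J_R = N_R (dv/dx) L at the given (default current) state."""
    exec_model._check_fresh()
    x = exec_model.state if state is None else np.asarray(state, dtype=float)
    red = Reduction(exec_model, x)
    return red.jacobian(exec_model.time, x[red.ind])


def stability(exec_model: ExecutableModel, steady_state=None,
              residual_tol: float = 1e-6) -> StabilityReport:
    """Eigenvalue stability verdict of a steady state.

    ``stable`` iff every eigenvalue of the reduced Jacobian has real part
    below -1e-9, ``marginal`` if the largest real part sits within that
    tolerance of zero.
    """
    exec_model._check_fresh()
    x = exec_model.state if steady_state is None \
        else np.asarray(steady_state, dtype=float)
    resid = float(np.max(np.abs(exec_model.rhs(exec_model.time, x)))) \
        if exec_model.layout.n_state else 0.0
    if resid > residual_tol:
        raise NotAtSteadyStateError(
            f"residual {resid:.3g} exceeds {residual_tol:.3g}")
    J = reduced_jacobian(exec_model, x)
    eig = np.linalg.eigvals(J) if J.size else np.array([], dtype=complex)
    max_re = float(np.max(eig.real)) if eig.size else 0.0
    if max_re < -_STABILITY_TOL:
        verdict = "stable"
    elif abs(max_re) <= _STABILITY_TOL:
        verdict = "marginal"
    else:
        verdict = "unstable"
    return StabilityReport(J, eig, max_re, verdict)


def elasticities(exec_model: ExecutableModel, state=None,
                 scaled: bool = False) -> np.ndarray:
    """Unscaled dv_i/dx_j, or scaled (x_j/v_i) dv_i/dx_j (reactions x species)."""
    exec_model._check_fresh()
    x = exec_model.state if state is None else np.asarray(state, dtype=float)
    E = exec_model.rate_jacobian_species(exec_model.time, x)
    if not scaled:
        return E
    v = exec_model.evaluate_rates(exec_model.time, x)
    if np.any(v == 0):
        raise ZeroFluxScalingError("scaled elasticities undefined: zero rate")
    if np.any(x == 0):
        raise ZeroFluxScalingError("scaled elasticities undefined: zero amount")
    return E * (x[None, :] / v[:, None])


def control_coefficients(exec_model: ExecutableModel,
                         residual_tol: float = 1e-6) -> MCAReport:
    """Full metabolic control analysis report at the current steady state."""
    exec_model._check_fresh()
    _require_reaction_model(exec_model)
    x = exec_model.state.copy()
    t = exec_model.time
    resid = float(np.max(np.abs(exec_model.rhs(t, x))))
    if resid > residual_tol:
        raise NotAtSteadyStateError(
            f"residual {resid:.3g}: solve for the steady state first")
    v = exec_model.evaluate_rates(t, x)
    if np.any(v == 0):
        raise ZeroFluxScalingError("scaled control coefficients undefined: "
                                   "a steady-state flux is zero")
    E = exec_model.rate_jacobian_species(t, x)   # reactions x species
    red = Reduction(exec_model, x)
    n = exec_model.layout.n_state
    r = len(red.ind)
    L = np.zeros((n, r))
    for k, i in enumerate(red.ind):
        L[i, k] = 1.0
    if red.dep:
        L[red.dep, :] = red.L0
    N = exec_model.stoichiometry_matrix
    N_R = N[red.ind, :]
    J_R = N_R @ E @ L
    try:
        CS = -L @ np.linalg.solve(J_R, N_R)       # species x reactions
    except np.linalg.LinAlgError as err:
        raise SingularJacobianError(str(err)) from err
    CJ = E @ CS + np.eye(len(v))                  # reactions x reactions

    if np.any(x == 0):
        raise ZeroFluxScalingError("scaled control coefficients undefined: "
                                   "a steady-state amount is zero")
    CS_scaled = CS * (v[None, :] / x[:, None])
    CJ_scaled = CJ * (v[None, :] / v[:, None])

    E_scaled = E * (x[None, :] / v[:, None])
    return MCAReport(
        species_ids=exec_model.state_ids,
        reaction_ids=exec_model.reaction_ids,
        unscaled_elasticities=E,
        scaled_elasticities=E_scaled,
        concentration_control=CS_scaled,
        flux_control=CJ_scaled,
        unscaled_concentration_control=CS,
        unscaled_flux_control=CJ,
        steady_state=x,
        flux=v,
    )


def perturb_reaction_activity(ir: ModelIR, reaction_id: str,
                              factor: float) -> ModelIR:
    """Copy of the model with one reaction's rate scaled by ``factor``.

    Scaling a reaction's activity this way is the operational definition of
    a control coefficient and is used as the numerical oracle for the
    link-matrix formula.
    """
    out = ir.copy()
    rxn = out.reaction_by_id(reaction_id)
    rxn.kinetic_law = ex.mul(ex.num(factor), rxn.kinetic_law)
    out._touch()
    return out
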