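"""Time-dependent and steady-state parameter sensitivities.

Forward sensitivities integrate the linearized equations

    s_j' = J(x, t) s_j + df/dp_j,     s_j(0) = dx0/dp_j

with J and df/dp built symbolically from the compiled model.  Two forward
strategies are provided and must be interchangeable:

``simultaneous``
    one augmented system of dimension n (1 + m) stepped by the adaptive
    Dormand-Prince pair, error-controlled over states and sensitivities
    jointly.
``staggered``
    the state is stepped first; each accepted step is then traversed again
    for the sensitivities with the same tableau, evaluating J and df/dp on
    the state's cubic-Hermite dense output.

``finite-difference`` re-simulates with centrally perturbed parameters and
serves as an independent oracle.

Sensitivities with respect to species initial amounts are supported via
s(0) = e_i.  Initial assignments that depend on a selected parameter are not
differentiated (s(0) = 0 is used); models with events are rejected because a
trigger crossing makes the forward equations discontinuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import ExecutableModel
from .errors import KinsimError, SingularJacobianError, StepFailureError
from .simulate import (IntegratorOptions, _dp_step, _error_norm, _hermite,
                       _step_factor, simulate)
from .steady_state import Reduction

__all__ = ["SensitivityOptions", "SensitivityResult", "forward_sensitivities",
           "finite_difference_sensitivities", "steady_state_sensitivities"]

NORMALIZATIONS = ("none", "parameter-scaled", "fully-scaled")


@dataclass
class SensitivityOptions:
    method: str = "simultaneous"    # simultaneous | staggered | finite-difference
    parameters: Optional[Sequence[str]] = None   # None: all constant parameters
    rel_tol: float = 1e-10
    abs_tol: float = 1e-12
    fd_step: float = 1e-6
    normalization: str = "none"

    def __post_init__(self):
        if self.method not in ("simultaneous", "staggered", "finite-difference"):
            raise ValueError(f"unknown sensitivity method {self.method!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.fd_step <= 0:
            raise ValueError("fd_step must be positive")


@dataclass
class SensitivityResult:
    times: np.ndarray
    parameter_ids: list[str]
    species_ids: list[str]
    values: np.ndarray              # [time, parameter, species]
    normalization: str = "none"
    method: str = "simultaneous"

    def get(self, parameter: str, species: str) -> np.ndarray:
        return self.values[:, self.parameter_ids.index(parameter),
                           self.species_ids.index(species)]

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for pi, p in enumerate(self.parameter_ids):
            for si, s in enumerate(self.species_ids):
                for ti, t in enumerate(self.times):
                    rows.append((t, p, s, self.values[ti, pi, si]))
        return pd.DataFrame(rows, columns=["time", "parameter", "species", "value"])

    def to_csv(self, path) -> None:
        self.to_long_dataframe().to_csv(path, index=False)


def _split_parameters(exec_model: ExecutableModel, parameters):
    """Partition the selection into globals-vector parameters and
    initial-value (state id) parameters; validate existence."""
    if parameters is None:
        parameters = exec_model.constant_parameter_ids
    parameters = list(parameters)
    g_params, init_params = [], []
    const = set(exec_model.constant_parameter_ids)
    states = set(exec_model.state_ids)
    for p in parameters:
        if p in const:
            g_params.append(p)
        elif p in states:
            init_params.append(p)
        else:
            raise KinsimError(
                f"{p!r} is not a constant parameter or floating-species id")
    return parameters, g_params, init_params


def _normalize(values, traj, p_vals, norm):
    """values[t, p, s]; traj[t, s] are the state trajectories."""
    if norm == "none":
        return values
    out = values * p_vals[None, :, None]
    if norm == "fully-scaled":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = out / traj[:, None, :]
    return out


def forward_sensitivities(exec_model: ExecutableModel, start, end, points,
                          opts: SensitivityOptions | None = None) -> SensitivityResult:
    """Solve the forward sensitivity equations on a uniform output grid."""
    if opts is None:
        opts = SensitivityOptions()
    if opts.method == "finite-difference":
        return finite_difference_sensitivities(exec_model, start, end, points, opts)
    if exec_model.ir.events:
        raise KinsimError("forward sensitivities do not support models with events")
    if end <= start:
        raise ValueError("end must be greater than start")
    exec_model._check_fresh()

    parameters, g_params, init_params = _split_parameters(exec_model, opts.parameters)
    species_ids = exec_model.state_ids
    n = len(species_ids)
    m = len(parameters)
    grid = np.linspace(start, end, points)

    x0 = exec_model.state.copy()
    S0 = np.zeros((n, m))
    for j, p in enumerate(parameters):
        if p in init_params:
            S0[species_ids.index(p), j] = 1.0

    g_tuple = tuple(g_params)
    g_cols = [parameters.index(p) for p in g_params]

    def Fp(t, x):
        out = np.zeros((n, m))
        if g_tuple:
            out[:, g_cols] = exec_model.rhs_param_jacobian(t, x, g_tuple)
        return out

    if opts.method == "simultaneous":
        traj, sens = _simultaneous(exec_model, x0, S0, Fp, grid, opts)
    else:
        traj, sens = _staggered(exec_model, x0, S0, Fp, grid, opts)

    exec_model.state = traj[-1].copy()
    exec_model.time = grid[-1]
    p_vals = np.array([exec_model.g[exec_model.layout.g_index[p]]
                       if p in g_params else x0[species_ids.index(p)]
                       for p in parameters])
    values = _normalize(sens, traj, p_vals, opts.normalization)
    return SensitivityResult(grid, parameters, list(species_ids), values,
                             opts.normalization, opts.method)


def _simultaneous(exec_model, x0, S0, Fp, grid, opts):
    n, m = S0.shape

    def fun(t, z):
        x = z[:n]
        S = z[n:].reshape(n, m)
        f = exec_model.rhs(t, x)
        dS = exec_model.jacobian(t, x) @ S + Fp(t, x)
        return np.concatenate([f, dS.ravel()])

    z = np.concatenate([x0, S0.ravel()])
    traj = np.empty((len(grid), n))
    sens = np.empty((len(grid), m, n))
    traj[0] = x0
    sens[0] = S0.T

    def record(gi, zt):
        traj[gi] = zt[:n]
        sens[gi] = zt[n:].reshape(n, m).T

    _adaptive_drive(fun, z, grid, record, opts)
    return traj, sens


def _adaptive_drive(fun, z, grid, record, opts):
    start, end = grid[0], grid[-1]
    eps = 1e-12 * max(1.0, abs(end))
    t = start
    f = fun(t, z)
    h = (end - start) / 100.0
    gi = 1
    while t < end - eps:
        h = min(h, end - t)
        if h < 1e-14 * max(1.0, abs(t)):
            raise StepFailureError(t)
        z5, z4, _, f_new = _dp_step(fun, t, z, h, f0=f)
        err = _error_norm(z5 - z4, z, z5, opts.rel_tol, opts.abs_tol)
        if err > 1.0:
            h = h * _step_factor(err)
            continue
        t1 = t + h
        interp = _hermite(t, z, f, t1, z5, f_new)
        while gi < len(grid) and grid[gi] <= t1 + eps:
            record(gi, interp(grid[gi]))
            gi += 1
        t, z, f = t1, z5, f_new
        h = h * _step_factor(err)
    while gi < len(grid):
        record(gi, z)
        gi += 1


def _staggered(exec_model, x0, S0, Fp, grid, opts):
    n, m = S0.shape
    steps = []          # (t0, y0, f0, t1, y1, f1) accepted state steps
    traj = np.empty((len(grid), n))
    traj[0] = x0

    start, end = grid[0], grid[-1]
    eps = 1e-12 * max(1.0, abs(end))
    t, y = start, x0.copy()
    f = exec_model.rhs(t, y)
    h = (end - start) / 100.0
    gi = 1
    # the sensitivity pass rides on the state's dense output, whose
    # interpolation error is one order below the step error; drive the state
    # pass tighter so both passes land at the requested accuracy
    state_rel = opts.rel_tol * 1e-3
    state_abs = opts.abs_tol
    while t < end - eps:
        h = min(h, end - t)
        if h < 1e-14 * max(1.0, abs(t)):
            raise StepFailureError(t)
        y5, y4, _, f_new = _dp_step(exec_model.rhs, t, y, h, f0=f)
        err = _error_norm(y5 - y4, y, y5, state_rel, state_abs)
        if err > 1.0:
            h = h * _step_factor(err)
            continue
        t1 = t + h
        interp = _hermite(t, y, f, t1, y5, f_new)
        while gi < len(grid) and grid[gi] <= t1 + eps:
            traj[gi] = interp(grid[gi])
            gi += 1
        steps.append((t, y, f, t1, y5, f_new))
        t, y, f = t1, y5, f_new
        h = h * _step_factor(err)
    while gi < len(grid):
        traj[gi] = y
        gi += 1

    # second pass: the linear sensitivity ODE is integrated over each
    # accepted state step with the same tableau and its own step control,
    # the state frozen on that step's Hermite dense output
    sens = np.empty((len(grid), m, n))
    sens[0] = S0.T
    S = S0.copy()
    gi = 1
    for (t0, y0, f0, t1, y1, f1) in steps:
        pos = _hermite(t0, y0, f0, t1, y1, f1)

        def fun(tt, Svec):
            x = pos(tt)
            dS = exec_model.jacobian(tt, x) @ Svec.reshape(n, m) + Fp(tt, x)
            return dS.ravel()

        targets = []
        while gi + len(targets) < len(grid) and grid[gi + len(targets)] <= t1 + eps:
            targets.append(grid[gi + len(targets)])
        local_grid = np.array([t0] + targets + [t1])

        recorded = {}

        def record(li, zt):
            recorded[li] = zt

        _adaptive_drive(fun, S.ravel(), local_grid, record, opts)
        for k, tg in enumerate(targets):
            sens[gi + k] = recorded[1 + k].reshape(n, m).T
        gi += len(targets)
        S = recorded[len(local_grid) - 1].reshape(n, m)
    while gi < len(grid):
        sens[gi] = S.T
        gi += 1
    return traj, sens


def finite_difference_sensitivities(exec_model: ExecutableModel, start, end,
                                    points, opts: SensitivityOptions | None = None
                                    ) -> SensitivityResult:
    """Central finite differences: two tight-tolerance simulations per
    parameter.  Unknown parameter ids produce zero columns (the oracle is
    permissive where the forward methods are strict)."""
    if opts is None:
        opts = SensitivityOptions(method="finite-difference")
    if opts.fd_step <= 0:
        raise ValueError("fd_step must be positive")
    exec_model._check_fresh()

    requested = list(opts.parameters) if opts.parameters is not None \
        else exec_model.constant_parameter_ids
    species_ids = exec_model.state_ids
    n = len(species_ids)
    grid = np.linspace(start, end, points)
    x0 = exec_model.state.copy()
    g0 = exec_model.g.copy()
    t0 = exec_model.time
    sim_opts = IntegratorOptions(name="rk45", rel_tol=min(opts.rel_tol, 1e-10),
                                 abs_tol=min(opts.abs_tol, 1e-14))

    def run(x_init):
        exec_model.state = x_init.copy()
        exec_model.time = start
        tc = simulate(exec_model, start, end, points, sim_opts)
        return tc.values[:, 1:]

    sens = np.zeros((len(grid), len(requested), n))
    lay = exec_model.layout
    baseline_traj = run(x0)
    for j, p in enumerate(requested):
        if p in lay.g_index:
            base = exec_model.g[lay.g_index[p]]
            delta = opts.fd_step * max(abs(base), 1.0)
            exec_model.g[lay.g_index[p]] = base + delta
            plus = run(x0)
            exec_model.g[lay.g_index[p]] = base - delta
            minus = run(x0)
            exec_model.g[lay.g_index[p]] = base
        elif p in species_ids:
            i = species_ids.index(p)
            delta = opts.fd_step * max(abs(x0[i]), 1.0)
            xp = x0.copy(); xp[i] += delta
            xm = x0.copy(); xm[i] -= delta
            plus, minus = run(xp), run(xm)
        else:
            continue    # absent from the model: zero column
        sens[:, j, :] = (plus - minus) / (2.0 * delta)

    exec_model.state = x0.copy()
    exec_model.g = g0
    exec_model.time = t0
    p_vals = np.array([exec_model.g[lay.g_index[p]] if p in lay.g_index
                       else (x0[species_ids.index(p)] if p in species_ids else 1.0)
                       for p in requested])
    values = _normalize(sens, baseline_traj, p_vals, opts.normalization)
    return SensitivityResult(grid, requested, list(species_ids), values,
                             opts.normalization, "finite-difference")


def steady_state_sensitivities(exec_model: ExecutableModel, parameters=None,
                               normalization: str = "none") -> np.ndarray:
    """Steady-state sensitivities dx*/dp as a (parameter x species) matrix.

    Solves J_R (dx*/dp) = -df/dp on the reduced system at the current state,
    which must be a converged steady state.  ``fully-scaled`` returns the
    power-law exponents (p/x) dx*/dp.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalization!r}")
    exec_model._check_fresh()
    parameters, g_params, init_params = _split_parameters(exec_model, parameters)
    if init_params:
        raise KinsimError("steady-state sensitivities are defined for constant "
                          "parameters only")
    t = exec_model.time
    x = exec_model.state.copy()
    red = Reduction(exec_model, x)
    J_R = red.jacobian(t, x[red.ind])
    F = exec_model.rhs_param_jacobian(t, x, tuple(parameters))
    F_R = F[red.ind, :]
    try:
        X = np.linalg.solve(J_R, -F_R)       # ind x m
    except np.linalg.LinAlgError as err:
        raise SingularJacobianError(str(err)) from err
    n = exec_model.layout.n_state
    dxdp = np.zeros((n, len(parameters)))
    dxdp[red.ind, :] = X
    if red.dep:
        dxdp[red.dep, :] = red.L0 @ X
    out = dxdp.T                            # parameter x species
    if normalization != "none":
        p_vals = np.array([exec_model.g[exec_model.layout.g_index[p]]
                           for p in parameters])
        out = out * p_vals[:, None]
        if normalization == "fully-scaled":
            with np.errstate(divide="ignore", invalid="ignore"):
                out = out / x[None, :]
    return out
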