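"""Deterministic and stochastic time-course simulation.

Three integrators share one results contract:

``rk45``
    adaptive embedded Dormand-Prince 5(4) pair with PI-free step control
    (safety 0.9, growth clamped to [0.2, 5]) and cubic-Hermite dense output
    onto the requested grid.  The default.
``euler``
    fixed-step explicit Euler, for time-critical work and as a cheap
    cross-check of the adaptive solution.
``gillespie``
    the stochastic simulation algorithm (direct method), interpreting
    kinetic-law values as propensities and the state as molecule counts.

Events are detected inside accepted steps by bisection on the dense output
and applied simultaneously in document order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import ExecutableModel, handle_events
from .errors import KinsimError, NegativePropensityError, StepFailureError

__all__ = ["IntegratorOptions", "TimeCourse", "simulate", "step_euler",
           "step_rk45", "gillespie"]


@dataclass
class IntegratorOptions:
    name: str = "rk45"              # rk45 | euler | gillespie | bdf
    rel_tol: float = 1e-6
    abs_tol: float = 1e-12
    fixed_step: float = 1e-3        # euler
    max_step: float = np.inf
    seed: Optional[int] = None      # gillespie

    def __post_init__(self):
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.fixed_step <= 0:
            raise ValueError("fixed_step must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["max_step"] = None if np.isinf(self.max_step) else self.max_step
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IntegratorOptions":
        d = dict(d)
        if d.get("max_step") is None:
            d["max_step"] = np.inf
        return cls(**d)


@dataclass
class TimeCourse:
    column_ids: list[str]
    values: np.ndarray              # points x columns
    integrator_name: str
    seed_used: Optional[int] = None

    @property
    def times(self) -> np.ndarray:
        return self.values[:, 0]

    def __getitem__(self, column: str) -> np.ndarray:
        return self.values[:, self.column_ids.index(column)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_ids)

    def to_csv(self, path) -> None:
        """Full double precision CSV (17 significant digits)."""
        with open(path, "w") as fh:
            fh.write(",".join(self.column_ids) + "\n")
            for row in self.values:
                fh.write(",".join(format(v, ".17g") for v in row) + "\n")


# -- Dormand-Prince 5(4) tableau --------------------------------------------

_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = [
    [],
    [1 / 5],
    [3 / 40, 9 / 40],
    [44 / 45, -56 / 15, 32 / 9],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
]
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200,
                187 / 2100, 1 / 40])

_SAFETY, _MIN_FACTOR, _MAX_FACTOR = 0.9, 0.2, 5.0


def _dp_step(fun, t, y, h, f0=None):
    """One Dormand-Prince step; returns (y5, y4, f0, f_new)."""
    k = np.empty((7, len(y)))
    k[0] = fun(t, y) if f0 is None else f0
    for i in range(1, 7):
        yi = y + h * sum(a * k[j] for j, a in enumerate(_A[i]))
        k[i] = fun(t + _C[i] * h, yi)
    y5 = y + h * (_B5 @ k)
    y4 = y + h * (_B4 @ k)
    return y5, y4, k[0], k[6]   # FSAL: k7 = f(t+h, y5)


def step_rk45(exec_model: ExecutableModel, t, state, h,
              rel_tol=1e-6, abs_tol=1e-12):
    """One embedded 5(4) step.

    Returns ``(state5, error_estimate, h_next)``.  The error estimate is the
    weighted RMS of the difference between the 5th- and 4th-order solutions;
    a value above 1 signals rejection.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    state = np.asarray(state, dtype=float)
    y5, y4, _, _ = _dp_step(exec_model.rhs, t, state, h)
    err = _error_norm(y5 - y4, state, y5, rel_tol, abs_tol)
    return y5, err, h * _step_factor(err)


def _error_norm(diff, y0, y1, rel_tol, abs_tol):
    scale = abs_tol + rel_tol * np.maximum(np.abs(y0), np.abs(y1))
    if len(diff) == 0:
        return 0.0
    return float(np.sqrt(np.mean((diff / scale) ** 2)))


def _step_factor(err):
    if err == 0.0:
        return _MAX_FACTOR
    return min(_MAX_FACTOR, max(_MIN_FACTOR, _SAFETY * err ** -0.2))


def step_euler(exec_model: ExecutableModel, t, state, h):
    """One explicit Euler step: ``state + h * f(t, state)``."""
    if h <= 0:
        raise ValueError("h must be positive")
    state = np.asarray(state, dtype=float)
    return state + h * exec_model.rhs(t, state)


def _hermite(t0, y0, f0, t1, y1, f1):
    """Cubic Hermite interpolant over one accepted step."""
    h = t1 - t0

    def interp(t):
        if h == 0:
            return y1.copy()
        s = (t - t0) / h
        h00 = 2 * s**3 - 3 * s**2 + 1
        h10 = s**3 - 2 * s**2 + s
        h01 = -2 * s**3 + 3 * s**2
        h11 = s**3 - s**2
        return h00 * y0 + h10 * h * f0 + h01 * y1 + h11 * h * f1

    return interp


def _fire_initial_events(exec_model, t0):
    """Events whose trigger is already true at t0 but whose initial trigger
    value is false fire immediately."""
    if not exec_model.ir.events:
        return
    trig = exec_model.eval_triggers(t0, exec_model.state)
    rising = [i for i, (now, init) in
              enumerate(zip(trig, exec_model.trigger_state)) if now and not init]
    if rising:
        exec_model.state = exec_model.apply_event_assignments(
            rising, t0, exec_model.state)
    exec_model.trigger_state = exec_model.eval_triggers(t0, exec_model.state)


def simulate(exec_model: ExecutableModel, start: float, end: float,
             points: int, opts: IntegratorOptions | None = None,
             species: Sequence[str] | None = None) -> TimeCourse:
    """Simulate on the uniform grid of ``points`` times from start to end
    (both included).  Advances the executable model's state and clock.
    """
    if opts is None:
        opts = IntegratorOptions()
    if end <= start:
        raise ValueError("end must be greater than start")
    if points < 2:
        raise ValueError("points must be at least 2")
    exec_model._check_fresh()
    if opts.name == "gillespie":
        return gillespie(exec_model, start, end, points, opts, species)

    columns = list(species) if species is not None else exec_model.state_ids
    col_idx = [exec_model.state_ids.index(c) for c in columns]
    grid = np.linspace(start, end, points)
    out = np.empty((points, 1 + len(columns)))
    out[:, 0] = grid

    exec_model.time = start
    _fire_initial_events(exec_model, start)
    y = exec_model.state.copy()
    out[0, 1:] = y[col_idx]

    if opts.name == "euler":
        _advance = _euler_driver
    elif opts.name == "rk45":
        _advance = _rk45_driver
    elif opts.name == "bdf":
        _advance = _bdf_driver
    else:
        raise ValueError(f"unknown integrator {opts.name!r}")

    _advance(exec_model, y, grid, out, col_idx, opts)
    return TimeCourse(["time"] + columns, out, opts.name, None)


def _record(out, grid, gi, t1, interp, col_idx, eps):
    """Fill grid rows with times in (t_prev, t1] using the interpolant."""
    while gi < len(grid) and grid[gi] <= t1 + eps:
        out[gi, 1:] = interp(grid[gi])[col_idx]
        gi += 1
    return gi


def _rk45_driver(exec_model, y, grid, out, col_idx, opts):
    start, end = grid[0], grid[-1]
    eps = 1e-12 * max(1.0, abs(end))
    t = start
    f = exec_model.rhs(t, y)
    h = min(opts.max_step, (end - start) / 100.0)
    gi = 1
    hmin_floor = 1e-14
    while t < end - eps:
        h = min(h, end - t, opts.max_step)
        if h < hmin_floor * max(1.0, abs(t)):
            raise StepFailureError(t)
        y5, y4, _, f_new = _dp_step(exec_model.rhs, t, y, h, f0=f)
        err = _error_norm(y5 - y4, y, y5, opts.rel_tol, opts.abs_tol)
        if err > 1.0:
            h = h * _step_factor(err)
            continue
        t1 = t + h
        interp = _hermite(t, y, f, t1, y5, f_new)
        fired = handle_events(exec_model, t, t1, y, y5, interp)
        if fired is not None:
            t_fire, post = fired
            gi = _record(out, grid, gi, t_fire, interp, col_idx, eps)
            t, y = t_fire, post
            exec_model.trigger_state = exec_model.eval_triggers(t, y)
            f = exec_model.rhs(t, y)
            # restart conservatively after the discontinuity
            h = min(h, (end - start) / 100.0)
            continue
        gi = _record(out, grid, gi, t1, interp, col_idx, eps)
        t, y, f = t1, y5, f_new
        h = h * _step_factor(err)
    # fill any trailing rows (roundoff at the endpoint)
    while gi < len(grid):
        out[gi, 1:] = y[col_idx]
        gi += 1
    exec_model.state = y
    exec_model.time = end


def _euler_driver(exec_model, y, grid, out, col_idx, opts):
    eps = 1e-12 * max(1.0, abs(grid[-1]))
    t = grid[0]
    gi = 1
    h0 = opts.fixed_step
    while gi < len(grid):
        t_target = grid[gi]
        span = t_target - t
        nsub = max(1, int(np.ceil(span / h0 - 1e-9)))
        hs = span / nsub
        for _ in range(nsub):
            f = exec_model.rhs(t, y)
            y1 = y + hs * f
            t1 = t + hs
            fired = handle_events(exec_model, t, t1, y, y1)
            if fired is not None:
                t_fire, post = fired
                t, y = t_fire, post
                exec_model.trigger_state = exec_model.eval_triggers(t, y)
                continue
            t, y = t1, y1
        # land exactly on the grid point
        t = t_target
        out[gi, 1:] = y[col_idx]
        gi += 1
    exec_model.state = y
    exec_model.time = grid[-1]


def _bdf_driver(exec_model, y, grid, out, col_idx, opts):
    """Optional stiff backend delegating to scipy's BDF (no event support)."""
    from scipy.integrate import solve_ivp
    if exec_model.ir.events:
        raise KinsimError("the bdf backend does not support events")
    sol = solve_ivp(exec_model.rhs, (grid[0], grid[-1]), y, method="BDF",
                    t_eval=grid, rtol=opts.rel_tol, atol=opts.abs_tol,
                    jac=lambda t, x: exec_model.jacobian(t, x))
    if not sol.success:
        raise StepFailureError(sol.t[-1] if len(sol.t) else grid[0], sol.message)
    out[:, 1:] = sol.y.T[:, col_idx]
    exec_model.state = sol.y[:, -1].copy()
    exec_model.time = grid[-1]


def gillespie(exec_model: ExecutableModel, start: float, end: float,
              points: int = 51, opts: IntegratorOptions | None = None,
              species: Sequence[str] | None = None) -> TimeCourse:
    """Gillespie direct method.

    Kinetic-law values are the propensities and the state vector holds
    molecule counts (they must be non-negative integers at start).  The
    output grid is sampled piecewise-constantly (last event carries forward).
    Fixing the seed makes the trajectory bit-reproducible.
    """
    if opts is None:
        opts = IntegratorOptions(name="gillespie")
    if end <= start:
        raise ValueError("end must be greater than start")
    exec_model._check_fresh()
    seed = opts.seed if opts.seed is not None else exec_model.rng_seed
    rng = np.random.default_rng(seed)

    y = exec_model.state.copy()
    if np.any(y < 0) or np.any(np.abs(y - np.rint(y)) > 1e-9):
        raise KinsimError("stochastic simulation requires non-negative integer "
                          "amounts at start")
    y = np.rint(y)
    N = exec_model.stoichiometry_matrix
    columns = list(species) if species is not None else exec_model.state_ids
    col_idx = [exec_model.state_ids.index(c) for c in columns]
    grid = np.linspace(start, end, points)
    out = np.empty((points, 1 + len(columns)))
    out[:, 0] = grid
    out[0, 1:] = y[col_idx]

    t = start
    gi = 1
    rxn_ids = exec_model.reaction_ids
    while True:
        a = exec_model.evaluate_rates(t, y)
        if np.any(a < 0):
            j = int(np.argmin(a))
            raise NegativePropensityError(
                f"negative propensity {a[j]} for reaction {rxn_ids[j]!r}")
        a0 = float(a.sum())
        if a0 <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / a0)
        if t_next > end:
            break
        while gi < len(grid) and grid[gi] < t_next:
            out[gi, 1:] = y[col_idx]
            gi += 1
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
        y = y + N[:, j]
        t = t_next
    while gi < len(grid):
        out[gi, 1:] = y[col_idx]
        gi += 1
    exec_model.state = y.copy()
    exec_model.time = end
    return TimeCourse(["time"] + columns, out, "gillespie", int(seed))
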