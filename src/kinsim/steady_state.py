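"""Steady-state location on the moiety-reduced system.

Closed reaction networks conserve linear combinations of species (moieties),
which makes the full Jacobian singular at every point.  The solvers here
therefore always operate on the reduced system: conserved moieties are found
by exact rational row reduction of the stoichiometry matrix, dependent
species are eliminated through the conservation totals, and Newton iterates
only on the independent species.

Two Newton strategies are available: ``exact`` solves each linear system by
dense LU to machine precision; ``inexact`` solves it with GMRES to the
forcing tolerance ``eta_k = min(0.5, sqrt(||f||))``, the classic inexact
Newton choice.  Both damp by backtracking halving (at most 20 halvings) and
clip negative concentrations to zero with a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.sparse.linalg as spla

from .engine import ExecutableModel
from .errors import SingularJacobianError
from .simulate import IntegratorOptions, simulate

__all__ = ["ConservationAnalysis", "SteadyStateResult", "conserved_moieties",
           "newton_steady_state", "presimulate_then_solve"]


@dataclass
class ConservationAnalysis:
    rank: int
    independent: list[int]              # row indices of independent species
    dependent: list[int]
    link_matrix: np.ndarray             # n x r, reordered (independent first)
    conservation_matrix: np.ndarray     # (n-r) x n, reordered; Gamma N = 0
    species_order: list[int]            # reordered -> original row index
    link_zero: np.ndarray               # (n-r) x r dependent block of L
    independent_ids: list[str] = field(default_factory=list)

    def totals(self, x0: np.ndarray) -> np.ndarray:
        x = np.asarray(x0, dtype=float)[self.species_order]
        return self.conservation_matrix @ x


def _to_fraction(x) -> Fraction:
    f = Fraction(x).limit_denominator(10**9)
    return f


def conserved_moieties(N, species_ids=None) -> ConservationAnalysis:
    """Structural analysis of a stoichiometry matrix by exact row reduction.

    Returns the rank r, an ordered choice of r independent species (first
    linearly independent rows in document order), the link matrix L with
    N = L N_R (identity on its top r rows), and the conservation matrix
    Gamma with Gamma N = 0 exactly.
    """
    N = np.asarray(N, dtype=float)
    n, m = N.shape
    rows = [[_to_fraction(N[i, j]) for j in range(m)] for i in range(n)]

    basis: list[tuple[list[Fraction], dict[int, Fraction]]] = []
    independent: list[int] = []
    link_zero_rows: list[dict[int, Fraction]] = []
    dependent: list[int] = []

    for i in range(n):
        r = list(rows[i])
        combo: dict[int, Fraction] = {i: Fraction(1)}
        for vec, bc in basis:
            piv = next(j for j, v in enumerate(vec) if v != 0)
            if r[piv] != 0:
                factor = r[piv] / vec[piv]
                r = [a - factor * b for a, b in zip(r, vec)]
                for k, v in bc.items():
                    combo[k] = combo.get(k, Fraction(0)) - factor * v
        if any(v != 0 for v in r):
            independent.append(i)
            basis.append((r, combo))
        else:
            # 0 = sum_j combo[j] row_j with combo[i] = 1
            dependent.append(i)
            link_zero_rows.append({j: -c for j, c in combo.items() if j != i})

    rank = len(independent)
    order = independent + dependent
    L = np.zeros((n, rank))
    L[:rank, :rank] = np.eye(rank)
    L0 = np.zeros((len(dependent), rank))
    for d, lz in enumerate(link_zero_rows):
        for j, c in lz.items():
            L0[d, independent.index(j)] = float(c)
    L[rank:, :] = L0
    Gamma = np.zeros((len(dependent), n))
    Gamma[:, :rank] = -L0
    Gamma[:, rank:] = np.eye(len(dependent))
    # exact check: Gamma (reordered N) = 0
    ids = ([species_ids[i] for i in independent] if species_ids is not None
           else [str(i) for i in independent])
    return ConservationAnalysis(rank, independent, dependent, L, Gamma,
                                order, L0, ids)


@dataclass
class SteadyStateResult:
    state: np.ndarray
    residual_norm: float
    iterations: int
    solver_name: str
    converged: bool
    diagnostics: list[str] = field(default_factory=list)
    residual_history: list[float] = field(default_factory=list)

    def as_dict(self, ids) -> dict:
        return {sid: float(v) for sid, v in zip(ids, self.state)}


class Reduction:
    """Dependent-species elimination for one model at one set of totals."""

    def __init__(self, exec_model: ExecutableModel, x0: np.ndarray):
        lay = exec_model.layout
        rule_targets = set(lay.rate_rule_order)
        # conservation analysis applies to reaction-governed entries only
        reaction_rows = [i for i, sid in enumerate(exec_model.state_ids)
                         if sid not in rule_targets]
        N = exec_model.stoichiometry_matrix[reaction_rows, :]
        cons = conserved_moieties(N, [exec_model.state_ids[i] for i in reaction_rows])
        self.analysis = cons
        self.exec = exec_model
        # map back to state-vector indices; rate-rule targets are always independent
        self.ind = [reaction_rows[i] for i in cons.independent] + \
                   [i for i, sid in enumerate(exec_model.state_ids) if sid in rule_targets]
        self.dep = [reaction_rows[i] for i in cons.dependent]
        r = cons.rank
        q = len(self.ind) - r
        self.L0 = np.zeros((len(self.dep), len(self.ind)))
        self.L0[:, :r] = cons.link_zero
        x0 = np.asarray(x0, dtype=float)
        self.offset = x0[self.dep] - self.L0 @ x0[self.ind]

    def full_state(self, u: np.ndarray) -> np.ndarray:
        x = np.empty(self.exec.layout.n_state)
        x[self.ind] = u
        x[self.dep] = self.L0 @ u + self.offset
        return x

    def residual(self, t, u):
        return self.exec.rhs(t, self.full_state(u))[self.ind]

    def jacobian(self, t, u):
        J = self.exec.jacobian(t, self.full_state(u))
        return J[np.ix_(self.ind, self.ind)] + J[np.ix_(self.ind, self.dep)] @ self.L0


def newton_steady_state(exec_model: ExecutableModel, x0=None, tol: float = 1e-9,
                        max_iter: int = 100,
                        strategy: str = "exact") -> SteadyStateResult:
    """Damped Newton on the reduced system; ``strategy`` is exact | inexact."""
    if strategy not in ("exact", "inexact"):
        raise ValueError("strategy must be 'exact' or 'inexact'")
    if exec_model.layout.n_state == 0:
        raise SingularJacobianError("model has no floating quantities")
    t = exec_model.time
    x0 = exec_model.state.copy() if x0 is None else np.asarray(x0, dtype=float)
    red = Reduction(exec_model, x0)
    u = x0[red.ind].copy()
    diagnostics: list[str] = []
    n_species_ind = sum(1 for i in red.ind
                        if exec_model.state_ids[i] in exec_model.layout.species_index)

    f = red.residual(t, u)
    fnorm = float(np.max(np.abs(f))) if len(f) else 0.0
    history = [fnorm]
    solver = f"newton-{strategy}"
    if fnorm <= tol:
        x = red.full_state(u)
        exec_model.state = x.copy()
        return SteadyStateResult(x, fnorm, 0, solver, True, diagnostics, history)

    for it in range(1, max_iter + 1):
        J = red.jacobian(t, u)
        try:
            if strategy == "exact":
                delta = np.linalg.solve(J, -f)
            else:
                eta = min(0.5, float(np.sqrt(np.linalg.norm(f))))
                delta, info = spla.gmres(J, -f, rtol=eta, atol=0.0,
                                         restart=min(20, len(f)))
                if info != 0 or not np.all(np.isfinite(delta)):
                    delta = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as err:
            raise SingularJacobianError(str(err)) from err

        lam = 1.0
        for _ in range(21):
            u_try = u + lam * delta
            clipped = False
            for k in range(n_species_ind):
                if u_try[k] < 0:
                    u_try[k] = 0.0
                    clipped = True
            f_try = red.residual(t, u_try)
            if np.max(np.abs(f_try)) < fnorm:
                if clipped:
                    diagnostics.append(
                        f"iteration {it}: negative concentrations clipped to 0")
                break
            lam *= 0.5
        u, f = u_try, f_try
        fnorm = float(np.max(np.abs(f)))
        history.append(fnorm)
        if fnorm <= tol:
            x = red.full_state(u)
            exec_model.state = x.copy()
            return SteadyStateResult(x, fnorm, it, solver, True, diagnostics, history)

    return SteadyStateResult(red.full_state(u), fnorm, max_iter, solver, False,
                             diagnostics + ["no-convergence"], history)


def presimulate_then_solve(exec_model: ExecutableModel, t_pre: float,
                           tol: float = 1e-9, **newton_kw) -> SteadyStateResult:
    """Integrate to ``t_pre`` with rk45, then run Newton from the endpoint.

    Integration moves the iterate into the attracting basin, which selects
    the corresponding root of multistable systems.
    """
    if t_pre <= 0:
        raise ValueError("t_pre must be positive")
    simulate(exec_model, exec_model.time, exec_model.time + t_pre, 2,
             IntegratorOptions(name="rk45", rel_tol=1e-8))
    return newton_steady_state(exec_model, tol=tol, **newton_kw)
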