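"""Compile a :class:`ModelIR` into a fast executable evaluator.

"Compilation" here means generating Python source for one kernel function per
model (all kinetic laws, assignment rules and rate-rule derivatives inlined),
executing it once, and caching the artifact by model content hash.  Inner
simulation loops therefore never walk expression trees — the compile-once
contract of a JIT-backed simulator, without machine code.

State convention: the state vector holds *amounts* of floating species
(document order) followed by the values of rate-rule parameter targets.
Kinetic laws and rules see species as *concentrations* (amount / compartment
size).  Boundary and constant species live outside the state, in the globals
vector, alongside parameters, compartment sizes and stoichiometry ids.
"""

from __future__ import annotations

import math

import numpy as np

from . import expr as ex
from .errors import (
    CyclicAssignmentError,
    DomainError,
    InvalidModelError,
    StaleModelError,
    UnsupportedConstructError,
)
from .model_ir import ModelIR

__all__ = ["ExecutableModel", "compile_model", "differentiate", "draw",
           "handle_events", "artifact_cache_info", "clear_artifact_cache"]

differentiate = ex.differentiate


def _b(x):
    return x != 0


def draw(e: ex.Expr, rng, env=None) -> float:
    """Resolve one distribution-draw expression with a seeded generator."""
    if e.kind != ex.DRAW:
        raise ValueError("draw() expects a distribution-draw node")
    params = [ex.eval_expr(c, env or {}, rng) for c in e.children]
    return ex.sample_draw(e.value, params, rng)


# --------------------------------------------------------------------------
# artifact cache

_CACHE: dict[str, "_Artifact"] = {}
_COMPILE_COUNT = 0
_CACHE_HITS = 0


def artifact_cache_info() -> dict:
    return {"compiles": _COMPILE_COUNT, "hits": _CACHE_HITS, "size": len(_CACHE)}


def clear_artifact_cache() -> None:
    _CACHE.clear()


class _Artifact:
    """Everything derivable from the IR structure alone (no runtime state)."""

    def __init__(self, ir: ModelIR):
        global _COMPILE_COUNT
        _COMPILE_COUNT += 1
        # freeze a structural copy so later edits to the source IR can never
        # leak into a cached artifact
        ir = ModelIR.from_dict(ir.to_dict())
        self.layout = _Layout(ir)
        self.source, namespace = self._generate(ir, self.layout)
        self.kernel = namespace["_kernel"]
        self.triggers = namespace["_triggers"]
        self._deriv_cache: dict = {}
        self.ir_snapshot = ir.to_dict()

    # -- code generation ------------------------------------------------
    def _generate(self, ir: ModelIR, lay: "_Layout"):
        pre = lay.assignment_preamble()
        res = lay.resolver
        rates = [ex.to_python(r.kinetic_law, res) for r in ir.reactions]
        derivs = []
        for target in lay.rate_rule_order:
            rule = lay.rate_rules[target]
            code = ex.to_python(rule.math, res)
            if target in lay.species_index:  # d(amount)/dt = size * d(conc)/dt
                ci = lay.g_index[ir.species_by_id(target).compartment]
                code = f"(({code}) * g[{ci}])"
            derivs.append(code)
        trig = [ex.to_python(e.trigger, res) for e in ir.events]

        lines = ["def _kernel(t, y, g, math=math, _b=_b):"]
        lines += [f"    {ln}" for ln in pre]
        lines.append(f"    return ({_tuple(rates)}, {_tuple(derivs)})")
        lines.append("def _triggers(t, y, g, math=math, _b=_b):")
        lines += [f"    {ln}" for ln in pre]
        lines.append(f"    return {_tuple(trig)}")
        src = "\n".join(lines) + "\n"
        ns = {"math": math, "_b": _b}
        exec(compile(src, f"<kinsim:{ir.id}>", "exec"), ns)
        return src, ns

    def derivative_kernel(self, exprs_key, builder, lay):
        """Compile (and cache) a flat kernel for a list of derivative Exprs.

        ``builder`` is only invoked on a cache miss — symbolic
        differentiation happens once per (model, symbol-tuple).
        """
        if exprs_key in self._deriv_cache:
            return self._deriv_cache[exprs_key]
        codes = [ex.to_python(e, lay.resolver) for e in builder()]
        lines = ["def _deriv(t, y, g, math=math, _b=_b):"]
        lines += [f"    {ln}" for ln in lay.assignment_preamble()]
        lines.append(f"    return {_tuple(codes)}")
        ns = {"math": math, "_b": _b}
        exec(compile("\n".join(lines), "<kinsim:deriv>", "exec"), ns)
        fn = ns["_deriv"]
        self._deriv_cache[exprs_key] = fn
        return fn


def _tuple(items: list[str]) -> str:
    if not items:
        return "()"
    return "(" + ", ".join(items) + ("," if len(items) == 1 else "") + ")"


class _Layout:
    """Symbol -> slot assignment and stoichiometry structure."""

    def __init__(self, ir: ModelIR):
        self.ir = ir
        self.assignment_targets = {r.target: r for r in ir.rules
                                   if r.kind == "assignment"}
        self.rate_rules = {r.target: r for r in ir.rules if r.kind == "rate"}

        for r in ir.rules:
            tgt = ir.find(r.target)
            if r.kind == "rate" and tgt.__class__.__name__ == "Compartment":
                raise UnsupportedConstructError("rate rules on compartments")
        for rxn in ir.reactions:
            if rxn.kinetic_law.contains_draw():
                raise UnsupportedConstructError(
                    f"distribution draw inside kinetic law of {rxn.id!r}; draws are "
                    "restricted to initial assignments and event assignments")
        for r in ir.rules:
            if r.math.contains_draw():
                raise UnsupportedConstructError("distribution draw inside a rule")

        # floating species: enter the ODE state
        self.floating = [s.id for s in ir.species
                         if not s.boundary and not s.constant
                         and s.id not in self.assignment_targets]
        self.species_index = {sid: i for i, sid in enumerate(self.floating)}
        # rate-rule parameter targets appended to the state
        self.rate_param_targets = [p.id for p in ir.parameters
                                   if p.id in self.rate_rules]
        self.n_float = len(self.floating)
        self.state_index = dict(self.species_index)
        for j, pid in enumerate(self.rate_param_targets):
            self.state_index[pid] = self.n_float + j
        self.n_state = self.n_float + len(self.rate_param_targets)
        # rate-rule evaluation order: species targets then parameter targets
        self.rate_rule_order = ([sid for sid in self.floating
                                 if sid in self.rate_rules]
                                + self.rate_param_targets)

        # globals vector
        self.g_index: dict[str, int] = {}
        self.g_init: list[float] = []

        def slot(name, value):
            self.g_index[name] = len(self.g_init)
            self.g_init.append(float(value))

        for c in ir.compartments:
            slot(c.id, c.size)
        for p in ir.parameters:
            if p.id not in self.state_index and p.id not in self.assignment_targets:
                slot(p.id, p.value)
        for s in ir.species:
            if (s.boundary or s.constant) and s.id not in self.assignment_targets:
                comp = ir.compartment_by_id(s.compartment)
                amt = s.initial_value * comp.size if s.initial_is_concentration \
                    else s.initial_value
                slot(s.id, amt)
        for rxn in ir.reactions:
            for sr in rxn.reactants + rxn.products:
                if sr.stoich_id:
                    v = sr.stoichiometry if not isinstance(sr.stoichiometry, ex.Expr) else 1.0
                    slot(sr.stoich_id, v)

        self.boundary_like = {s.id for s in ir.species if s.boundary or s.constant}
        self._species_comp = {s.id: s.compartment for s in ir.species}
        self._asg_order = self._topo_assignments()

    # resolver: symbol name -> python code fragment
    def resolver(self, name: str) -> str:
        if name == ex.TIME:
            return "t"
        if name in self.assignment_targets:
            return f"_a_{name}"
        if name in self.species_index:
            ci = self.g_index[self._species_comp[name]]
            return f"(y[{self.species_index[name]}] / g[{ci}])"
        if name in self.state_index:  # rate-rule parameter
            return f"y[{self.state_index[name]}]"
        if name in self.boundary_like:
            ci = self.g_index[self._species_comp[name]]
            return f"(g[{self.g_index[name]}] / g[{ci}])"
        if name in self.g_index:
            return f"g[{self.g_index[name]}]"
        raise UnsupportedConstructError(
            f"symbol {name!r} (a reaction flux or unsupported quantity) cannot "
            "be referenced inside expressions")

    def _topo_assignments(self) -> list[str]:
        targets = self.assignment_targets
        deps = {t: (r.math.free_symbols() & set(targets))
                for t, r in targets.items()}
        order, done = [], set()
        mark = set()

        def visit(t):
            if t in done:
                return
            if t in mark:
                raise CyclicAssignmentError(
                    f"assignment rules form a cycle involving {t!r}")
            mark.add(t)
            for d in deps[t]:
                visit(d)
            mark.discard(t)
            done.add(t)
            order.append(t)

        for t in targets:
            visit(t)
        return order

    def assignment_preamble(self) -> list[str]:
        lines = []
        for t in self._asg_order:
            lines.append(f"_a_{t} = {ex.to_python(self.assignment_targets[t].math, self.resolver)}")
        return lines

    # symbolic view with assignment rules substituted in, for differentiation
    def resolved_sympy(self, e: ex.Expr):
        s = ex.to_sympy(e)
        import sympy
        for t in reversed(self._asg_order):
            s = s.subs(sympy.Symbol(t), ex.to_sympy(self.assignment_targets[t].math))
        return s

    def stoichiometry(self, g: np.ndarray) -> np.ndarray:
        """(n_state x n_reactions) net stoichiometry; zero rows for rule targets."""
        ir = self.ir
        N = np.zeros((self.n_state, len(ir.reactions)))
        for j, rxn in enumerate(ir.reactions):
            for sign, refs in ((-1.0, rxn.reactants), (1.0, rxn.products)):
                for sr in refs:
                    i = self.species_index.get(sr.species)
                    if i is None or sr.species in self.rate_rules:
                        continue
                    if sr.stoich_id:
                        val = g[self.g_index[sr.stoich_id]]
                    elif isinstance(sr.stoichiometry, ex.Expr):
                        env = {k: g[v] for k, v in self.g_index.items()}
                        val = ex.eval_expr(sr.stoichiometry, env)
                    else:
                        val = sr.stoichiometry
                    N[i, j] += sign * val
        return N

    def has_variable_stoichiometry(self) -> bool:
        for rxn in self.ir.reactions:
            for sr in rxn.reactants + rxn.products:
                if sr.stoich_id or isinstance(sr.stoichiometry, ex.Expr):
                    return True
        return False


# --------------------------------------------------------------------------

class ExecutableModel:
    """Compiled, stateful model evaluator.

    Exposes reaction rates, the ODE right-hand side, symbolic Jacobians,
    event handling and seeded distribution draws.  Becomes *stale* (and
    refuses to evaluate) as soon as the underlying IR is edited.
    """

    def __init__(self, ir: ModelIR, artifact: _Artifact, seed: int = 0):
        self.ir = ir
        self._artifact = artifact
        self.layout = artifact.layout
        self._compiled_revision = ir.revision
        self.rng_seed = int(seed)
        self.rng = np.random.default_rng(self.rng_seed)
        lay = self.layout
        self.g = np.array(lay.g_init, dtype=float)
        self.state = np.zeros(lay.n_state)
        self.time = 0.0
        self._init_state()
        self._initial_state = self.state.copy()
        self._initial_g = self.g.copy()
        self._N = None
        self._n_variable = lay.has_variable_stoichiometry()
        self.trigger_state = [bool(e.initial_trigger_value) for e in ir.events]

    # -- initialization -------------------------------------------------
    def _init_state(self):
        ir, lay = self.ir, self.layout
        for sid, i in lay.species_index.items():
            s = ir.species_by_id(sid)
            vol = self.g[lay.g_index[s.compartment]]
            self.state[i] = s.initial_value * vol if s.initial_is_concentration \
                else s.initial_value
        for pid in lay.rate_param_targets:
            p = next(p for p in ir.parameters if p.id == pid)
            self.state[lay.state_index[pid]] = p.value
        for ia in ir.initial_assignments:
            env = self.build_env(0.0, self.state)
            val = ex.eval_expr(ia.math, env, self.rng)
            self._write_quantity(ia.target, val)

    def _write_quantity(self, target: str, value: float):
        """Write a concentration-facing value to wherever `target` lives."""
        lay = self.layout
        if target in lay.species_index:
            vol = self.g[lay.g_index[lay._species_comp[target]]]
            self.state[lay.species_index[target]] = value * vol
        elif target in lay.state_index:
            self.state[lay.state_index[target]] = value
        elif target in lay.boundary_like:
            vol = self.g[lay.g_index[lay._species_comp[target]]]
            self.g[lay.g_index[target]] = value * vol
        elif target in lay.g_index:
            self.g[lay.g_index[target]] = value
            self._N = None if self._n_variable else self._N
        else:
            raise UnsupportedConstructError(f"cannot assign to {target!r}")

    # -- bookkeeping ----------------------------------------------------
    @property
    def stale(self) -> bool:
        return self.ir.revision != self._compiled_revision

    def _check_fresh(self):
        if self.stale:
            raise StaleModelError(
                "model IR was edited after compilation; recompile first")

    def reset(self):
        """Restore the post-initialization state (draws are not re-sampled)."""
        self.state = self._initial_state.copy()
        self.g = self._initial_g.copy()
        self.time = 0.0
        self._N = None
        self.trigger_state = [bool(e.initial_trigger_value) for e in self.ir.events]
        return self

    @property
    def floating_species_ids(self) -> list[str]:
        return list(self.layout.floating)

    @property
    def state_ids(self) -> list[str]:
        return list(self.layout.floating) + list(self.layout.rate_param_targets)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.ir.reactions]

    @property
    def constant_parameter_ids(self) -> list[str]:
        lay = self.layout
        return [p.id for p in self.ir.parameters
                if p.constant and p.id in lay.g_index]

    @property
    def stoichiometry_matrix(self) -> np.ndarray:
        """n_state x n_reactions net stoichiometry (floating species rows)."""
        if self._N is None:
            self._N = self.layout.stoichiometry(self.g)
        return self._N

    @property
    def source(self) -> str:
        return self._artifact.source

    def set_value(self, id_: str, value: float):
        self._check_fresh()
        self._write_quantity(id_, float(value))
        return self

    def get_value(self, id_: str) -> float:
        env = self.build_env(self.time, self.state)
        if id_ in env:
            return env[id_]
        raise UnsupportedConstructError(f"no value for {id_!r}")

    def build_env(self, t: float, state: np.ndarray) -> dict:
        """Interpreter environment: concentrations, parameters, rule targets."""
        lay = self.layout
        env = {ex.TIME: t}
        for name, gi in lay.g_index.items():
            env[name] = self.g[gi]
        for sid in lay.boundary_like:
            if sid in lay.g_index:
                env[sid] = self.g[lay.g_index[sid]] / self.g[lay.g_index[lay._species_comp[sid]]]
        for sid, i in lay.species_index.items():
            env[sid] = state[i] / self.g[lay.g_index[lay._species_comp[sid]]]
        for pid in lay.rate_param_targets:
            env[pid] = state[lay.state_index[pid]]
        for t_ in lay._asg_order:
            env[t_] = ex.eval_expr(lay.assignment_targets[t_].math, env)
        return env

    # -- evaluation -----------------------------------------------------
    def _kernel(self, t, state):
        try:
            return self._artifact.kernel(t, state, self.g)
        except (ValueError, ZeroDivisionError, OverflowError) as err:
            loc = self._locate_failure(t, state)
            raise DomainError(str(err), loc) from err

    def _locate_failure(self, t, state):
        env = None
        try:
            env = self.build_env(t, state)
        except Exception:
            return None
        for rxn in self.ir.reactions:
            try:
                ex.eval_expr(rxn.kinetic_law, env)
            except Exception:
                return rxn.id
        return None

    def evaluate_rates(self, t: float, state=None) -> np.ndarray:
        """Reaction rates v(t, x) in document order."""
        self._check_fresh()
        if state is None:
            state = self.state
        rates, _ = self._kernel(t, np.asarray(state, dtype=float))
        return np.array(rates, dtype=float)

    def rhs(self, t: float, state=None) -> np.ndarray:
        """dx/dt = N v(x, t), with rate-rule targets using their rule."""
        self._check_fresh()
        if state is None:
            state = self.state
        state = np.asarray(state, dtype=float)
        rates, derivs = self._kernel(t, state)
        f = self.stoichiometry_matrix @ np.array(rates, dtype=float) \
            if rates else np.zeros(self.layout.n_state)
        lay = self.layout
        for target, d in zip(lay.rate_rule_order, derivs):
            f[lay.state_index[target]] = d
        return f

    # -- symbolic derivatives -------------------------------------------
    def _sym_rate_derivs(self, wrt: tuple[str, ...], key):
        """Flat kernel of d(rate_i)/d(sym_j) for every reaction x symbol."""
        lay = self.layout

        def build():
            import sympy
            exprs = []
            for rxn in self.ir.reactions:
                s = lay.resolved_sympy(rxn.kinetic_law)
                for name in wrt:
                    exprs.append(ex.from_sympy(sympy.diff(s, sympy.Symbol(name))))
            return exprs

        return self._artifact.derivative_kernel(key, build, lay)

    def _sym_rule_derivs(self, wrt: tuple[str, ...], key):
        lay = self.layout

        def build():
            import sympy
            exprs = []
            for target in lay.rate_rule_order:
                s = lay.resolved_sympy(lay.rate_rules[target].math)
                scale = 1
                if target in lay.species_index:
                    scale = sympy.Symbol(lay._species_comp[target])
                for name in wrt:
                    exprs.append(ex.from_sympy(scale * sympy.diff(s, sympy.Symbol(name))))
            return exprs

        return self._artifact.derivative_kernel(key, build, lay)

    def _state_symbols(self) -> tuple[str, ...]:
        return tuple(self.state_ids)

    def rate_jacobian_species(self, t: float, state=None) -> np.ndarray:
        """dv/dx (n_reactions x n_state), x in amounts."""
        self._check_fresh()
        if state is None:
            state = self.state
        state = np.asarray(state, dtype=float)
        syms = self._state_symbols()
        fn = self._sym_rate_derivs(syms, ("dvdx", syms))
        flat = np.array(fn(t, state, self.g), dtype=float)
        lay = self.layout
        nr = len(self.ir.reactions)
        M = flat.reshape(nr, lay.n_state) if nr else np.zeros((0, lay.n_state))
        # chain rule: laws see concentrations, the state holds amounts
        scale = np.ones(lay.n_state)
        for sid, i in lay.species_index.items():
            scale[i] = 1.0 / self.g[lay.g_index[lay._species_comp[sid]]]
        return M * scale[None, :]

    def rate_jacobian_params(self, t, state, params: tuple[str, ...]) -> np.ndarray:
        """dv/dp (n_reactions x n_params) for globals-vector parameters."""
        self._check_fresh()
        state = np.asarray(state, dtype=float)
        fn = self._sym_rate_derivs(tuple(params), ("dvdp", tuple(params)))
        flat = np.array(fn(t, state, self.g), dtype=float)
        nr = len(self.ir.reactions)
        return flat.reshape(nr, len(params)) if nr else np.zeros((0, len(params)))

    def jacobian(self, t: float = None, state=None) -> np.ndarray:
        """df/dx of the full floating-species system (n_state x n_state)."""
        self._check_fresh()
        if t is None:
            t = self.time
        if state is None:
            state = self.state
        state = np.asarray(state, dtype=float)
        lay = self.layout
        J = self.stoichiometry_matrix @ self.rate_jacobian_species(t, state) \
            if self.ir.reactions else np.zeros((lay.n_state, lay.n_state))
        if lay.rate_rule_order:
            syms = self._state_symbols()
            fn = self._sym_rule_derivs(syms, ("dDdx", syms))
            flat = np.array(fn(t, state, self.g), dtype=float)
            D = flat.reshape(len(lay.rate_rule_order), lay.n_state)
            scale = np.ones(lay.n_state)
            for sid, i in lay.species_index.items():
                scale[i] = 1.0 / self.g[lay.g_index[lay._species_comp[sid]]]
            D = D * scale[None, :]
            for row, target in enumerate(lay.rate_rule_order):
                J[lay.state_index[target], :] = D[row]
        return J

    def rhs_param_jacobian(self, t, state, params: tuple[str, ...]) -> np.ndarray:
        """df/dp (n_state x n_params)."""
        state = np.asarray(state, dtype=float)
        lay = self.layout
        F = self.stoichiometry_matrix @ self.rate_jacobian_params(t, state, params) \
            if self.ir.reactions else np.zeros((lay.n_state, len(params)))
        if lay.rate_rule_order:
            fn = self._sym_rule_derivs(tuple(params), ("dDdp", tuple(params)))
            flat = np.array(fn(t, state, self.g), dtype=float)
            D = flat.reshape(len(lay.rate_rule_order), len(params))
            for row, target in enumerate(lay.rate_rule_order):
                F[lay.state_index[target], :] = D[row]
        return F

    # -- events ---------------------------------------------------------
    def eval_triggers(self, t: float, state) -> list[bool]:
        self._check_fresh()
        vals = self._artifact.triggers(t, np.asarray(state, dtype=float), self.g)
        return [bool(_b(v)) for v in vals]

    def apply_event_assignments(self, event_indices, t, state) -> np.ndarray:
        """Apply assignments of the given events simultaneously, document order.

        All right-hand sides are evaluated against the pre-event state before
        any target is written.  Returns the post-event state vector; targets
        living in the globals vector are written in place.
        """
        state = np.asarray(state, dtype=float).copy()
        env = self.build_env(t, state)
        writes = []
        for idx in sorted(event_indices):
            evt = self.ir.events[idx]
            for target, math_ in evt.assignments:
                writes.append((target, ex.eval_expr(math_, env, self.rng)))
        saved = self.state
        self.state = state
        try:
            for target, value in writes:
                self._write_quantity(target, value)
            return self.state.copy()
        finally:
            self.state = saved


def handle_events(exec_model: ExecutableModel, t_prev, t_new, state_prev,
                  state_new, interp=None):
    """Detect and apply the earliest false->true trigger transition in
    ``(t_prev, t_new]``.

    ``interp(t)`` provides dense output inside the step (linear interpolation
    by default).  Returns ``(firing_time, post_event_state)`` or ``None``.
    Simultaneously firing events are applied together in document order.
    """
    ir = exec_model.ir
    if not ir.events:
        return None
    state_prev = np.asarray(state_prev, dtype=float)
    state_new = np.asarray(state_new, dtype=float)
    if interp is None:
        def interp(t):
            w = 0.0 if t_new == t_prev else (t - t_prev) / (t_new - t_prev)
            return state_prev + w * (state_new - state_prev)

    before = exec_model.eval_triggers(t_prev, state_prev)
    after = exec_model.eval_triggers(t_new, state_new)
    rising = [i for i in range(len(ir.events)) if not before[i] and after[i]]
    if not rising:
        return None

    tol = 1e-12 * (1.0 + abs(t_new))
    times = {}
    for i in rising:
        lo, hi = t_prev, t_new
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if exec_model.eval_triggers(mid, interp(mid))[i]:
                hi = mid
            else:
                lo = mid
        times[i] = hi
    t_fire = min(times.values())
    firing = [i for i, tf in times.items() if tf <= t_fire + tol]
    post = exec_model.apply_event_assignments(firing, t_fire, interp(t_fire))
    return t_fire, post


def compile_model(ir: ModelIR, force_regenerate: bool = False,
                  seed: int = 0) -> ExecutableModel:
    """Compile an IR into an :class:`ExecutableModel`.

    Identical IR content hits the in-memory artifact cache unless
    ``force_regenerate`` is set.  ``seed`` drives every distribution draw
    the model performs (initial assignments, event assignments).
    """
    global _CACHE_HITS
    diags = ir.validate()
    if diags:
        raise InvalidModelError(diags)
    key = ir.content_hash()
    if not force_regenerate and key in _CACHE:
        _CACHE_HITS += 1
        artifact = _CACHE[key]
    else:
        artifact = _Artifact(ir)
        _CACHE[key] = artifact
    return ExecutableModel(ir, artifact, seed=seed)
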