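"""Expression trees for kinetic laws, rules, triggers and distribution draws.

An :class:`Expr` is a small immutable tree.  ``kind`` is one of

``number``
    numeric literal; ``value`` is a float.
``symbol``
    reference to a model quantity (or ``time``); ``value`` is the identifier.
``binop``
    binary arithmetic; ``value`` in ``+ - * / ^``; exactly two children.
``unop``
    unary minus (``-``) or plus (``+``); one child.
``call``
    function application; ``value`` is the function name from the registry.
``piecewise``
    alternating (value, condition) children with an optional trailing
    otherwise-value, mirroring MathML ``<piecewise>``.
``relational``
    comparison; ``value`` in ``< <= > >= == !=``; two children.
``boolop``
    ``and``/``or``/``xor`` (two children) or ``not`` (one child).
``draw``
    distribution draw; ``value`` is the distribution tag, children are its
    parameters.  Draws are resolved once (initial assignments, event
    assignments), never inside compiled rate laws.

Booleans and numbers coerce both ways: true is 1.0, a number is true iff it
is nonzero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterator

import sympy

from .errors import (
    InvalidDistributionParameterError,
    NonDifferentiableError,
    ParseError,
    UnresolvedSymbolError,
)

NUMBER = "number"
SYMBOL = "symbol"
BINOP = "binop"
UNOP = "unop"
CALL = "call"
PIECEWISE = "piecewise"
RELATIONAL = "relational"
BOOLOP = "boolop"
DRAW = "draw"

KINDS = {NUMBER, SYMBOL, BINOP, UNOP, CALL, PIECEWISE, RELATIONAL, BOOLOP, DRAW}

#: special symbol representing simulation time
TIME = "time"

DISTRIBUTIONS = ("normal", "uniform", "lognormal", "exponential", "gamma", "poisson", "binomial")

_REL_OPS = {"<", "<=", ">", ">=", "==", "!="}
_BIN_OPS = {"+", "-", "*", "/", "^"}
_BOOL_OPS = {"and", "or", "xor", "not"}


@dataclass(frozen=True)
class Expr:
    kind: str
    value: object = None
    children: tuple["Expr", ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))
        _check_arity(self)

    # -- introspection -------------------------------------------------
    def walk(self) -> Iterator["Expr"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def free_symbols(self) -> set:
        return {n.value for n in self.walk() if n.kind == SYMBOL}

    def contains_draw(self) -> bool:
        return any(n.kind == DRAW for n in self.walk())

    def __repr__(self):  # compact, used in diagnostics
        return f"Expr<{to_infix(self)}>"


def _check_arity(e: Expr) -> None:
    n = len(e.children)
    if e.kind not in KINDS:
        raise ValueError(f"unknown Expr kind {e.kind!r}")
    if e.kind == NUMBER:
        if n or not isinstance(e.value, (int, float)):
            raise ValueError("number node takes a numeric value and no children")
    elif e.kind == SYMBOL:
        if n or not isinstance(e.value, str):
            raise ValueError("symbol node takes a name and no children")
    elif e.kind == BINOP:
        if e.value not in _BIN_OPS or n != 2:
            raise ValueError(f"binop {e.value!r} requires exactly 2 children")
    elif e.kind == UNOP:
        if e.value not in {"-", "+"} or n != 1:
            raise ValueError("unop requires op in {+,-} and 1 child")
    elif e.kind == RELATIONAL:
        if e.value not in _REL_OPS or n != 2:
            raise ValueError(f"relational {e.value!r} requires exactly 2 children")
    elif e.kind == BOOLOP:
        if e.value not in _BOOL_OPS:
            raise ValueError(f"unknown boolean op {e.value!r}")
        if e.value == "not" and n != 1:
            raise ValueError("'not' takes exactly 1 child")
        if e.value != "not" and n != 2:
            raise ValueError(f"'{e.value}' takes exactly 2 children")
    elif e.kind == PIECEWISE:
        if n < 1:
            raise ValueError("piecewise requires at least one child")
    elif e.kind == CALL:
        if e.value not in FUNCTIONS:
            raise ValueError(f"unknown function {e.value!r}")
        lo, hi = FUNCTIONS[e.value].arity
        if not (lo <= n <= hi):
            raise ValueError(f"{e.value} takes {lo}..{hi} arguments, got {n}")
    elif e.kind == DRAW:
        if e.value not in DISTRIBUTIONS:
            raise ValueError(f"unsupported distribution {e.value!r}")
        if n != _DRAW_ARITY[e.value]:
            raise ValueError(f"{e.value} draw takes {_DRAW_ARITY[e.value]} parameters")


# -- constructors ------------------------------------------------------

def num(x) -> Expr:
    return Expr(NUMBER, float(x))


def sym(name: str) -> Expr:
    return Expr(SYMBOL, name)


def binop(op: str, a: Expr, b: Expr) -> Expr:
    return Expr(BINOP, op, (a, b))


def add(a, b):
    return binop("+", a, b)


def sub(a, b):
    return binop("-", a, b)


def mul(a, b):
    return binop("*", a, b)


def div(a, b):
    return binop("/", a, b)


def pow_(a, b):
    return binop("^", a, b)


def neg(a):
    return Expr(UNOP, "-", (a,))


def call(name: str, *args: Expr) -> Expr:
    return Expr(CALL, name, tuple(args))


def rel(op: str, a: Expr, b: Expr) -> Expr:
    return Expr(RELATIONAL, op, (a, b))


def boolop(op: str, *args: Expr) -> Expr:
    return Expr(BOOLOP, op, tuple(args))


def piecewise(*children: Expr) -> Expr:
    return Expr(PIECEWISE, None, tuple(children))


def draw(tag: str, *params: Expr) -> Expr:
    return Expr(DRAW, tag, tuple(params))


# -- function registry -------------------------------------------------

class _Func:
    __slots__ = ("arity", "code", "fn", "sym")

    def __init__(self, arity, code, fn, sym=None):
        self.arity = arity          # (min, max) argument count
        self.code = code            # codegen template or callable(args)->str
        self.fn = fn                # python callable for interpretation
        self.sym = sym              # sympy constructor (None: handled ad hoc)


def _sec(x):
    return 1.0 / math.cos(x)


def _csc(x):
    return 1.0 / math.sin(x)


def _cot(x):
    return math.cos(x) / math.sin(x)


def _log(*a):
    # one argument: SBML default base 10; two: log(base, x)
    if len(a) == 1:
        return math.log10(a[0])
    return math.log(a[1]) / math.log(a[0])


def _root(n, x):
    return x ** (1.0 / n)


FUNCTIONS: dict[str, _Func] = {
    "exp": _Func((1, 1), "math.exp({0})", math.exp, sympy.exp),
    "ln": _Func((1, 1), "math.log({0})", math.log, sympy.log),
    "log": _Func((1, 2), lambda a: f"math.log10({a[0]})" if len(a) == 1
                 else f"(math.log({a[1]})/math.log({a[0]}))", _log),
    "log10": _Func((1, 1), "math.log10({0})", math.log10),
    "log2": _Func((1, 1), "math.log2({0})", math.log2),
    "sqrt": _Func((1, 1), "math.sqrt({0})", math.sqrt, sympy.sqrt),
    "root": _Func((2, 2), "({1}**(1.0/{0}))", _root),
    "abs": _Func((1, 1), "abs({0})", abs, sympy.Abs),
    "floor": _Func((1, 1), "math.floor({0})", math.floor, sympy.floor),
    "ceiling": _Func((1, 1), "math.ceil({0})", math.ceil, sympy.ceiling),
    "factorial": _Func((1, 1), "math.factorial(int({0}))",
                       lambda x: math.factorial(int(x)), sympy.factorial),
    "power": _Func((2, 2), "({0}**{1})", lambda a, b: a ** b, sympy.Pow),
    "max": _Func((2, 2), "max({0}, {1})", max, sympy.Max),
    "min": _Func((2, 2), "min({0}, {1})", min, sympy.Min),
    "rem": _Func((2, 2), "math.fmod({0}, {1})", math.fmod),
    "quotient": _Func((2, 2), "float(int({0}) // int({1}))",
                      lambda a, b: float(int(a) // int(b))),
    "sin": _Func((1, 1), "math.sin({0})", math.sin, sympy.sin),
    "cos": _Func((1, 1), "math.cos({0})", math.cos, sympy.cos),
    "tan": _Func((1, 1), "math.tan({0})", math.tan, sympy.tan),
    "sec": _Func((1, 1), "(1.0/math.cos({0}))", _sec, sympy.sec),
    "csc": _Func((1, 1), "(1.0/math.sin({0}))", _csc, sympy.csc),
    "cot": _Func((1, 1), "(math.cos({0})/math.sin({0}))", _cot, sympy.cot),
    "arcsin": _Func((1, 1), "math.asin({0})", math.asin, sympy.asin),
    "arccos": _Func((1, 1), "math.acos({0})", math.acos, sympy.acos),
    "arctan": _Func((1, 1), "math.atan({0})", math.atan, sympy.atan),
    "sinh": _Func((1, 1), "math.sinh({0})", math.sinh, sympy.sinh),
    "cosh": _Func((1, 1), "math.cosh({0})", math.cosh, sympy.cosh),
    "tanh": _Func((1, 1), "math.tanh({0})", math.tanh, sympy.tanh),
    "arcsinh": _Func((1, 1), "math.asinh({0})", math.asinh, sympy.asinh),
    "arccosh": _Func((1, 1), "math.acosh({0})", math.acosh, sympy.acosh),
    "arctanh": _Func((1, 1), "math.atanh({0})", math.atanh, sympy.atanh),
}

_DRAW_ARITY = {
    "normal": 2, "uniform": 2, "lognormal": 2, "exponential": 1,
    "gamma": 2, "poisson": 1, "binomial": 2,
}


def sample_draw(tag: str, params, rng) -> float:
    """Draw one variate from a seeded numpy Generator, validating parameters."""
    p = [float(v) for v in params]
    if tag == "normal":
        mu, sd = p
        if sd < 0:
            raise InvalidDistributionParameterError(f"normal: sd {sd} < 0")
        return float(rng.normal(mu, sd))
    if tag == "uniform":
        a, b = p
        if b < a:
            raise InvalidDistributionParameterError(f"uniform: upper {b} < lower {a}")
        if a == b:
            return a
        return float(rng.uniform(a, b))
    if tag == "lognormal":
        mu, sd = p
        if sd < 0:
            raise InvalidDistributionParameterError(f"lognormal: sd {sd} < 0")
        return float(rng.lognormal(mu, sd))
    if tag == "exponential":
        (rate,) = p
        if rate <= 0:
            raise InvalidDistributionParameterError(f"exponential: rate {rate} <= 0")
        return float(rng.exponential(1.0 / rate))
    if tag == "gamma":
        shape, scale = p
        if shape <= 0 or scale <= 0:
            raise InvalidDistributionParameterError(f"gamma: shape/scale must be > 0, got {p}")
        return float(rng.gamma(shape, scale))
    if tag == "poisson":
        (lam,) = p
        if lam < 0:
            raise InvalidDistributionParameterError(f"poisson: rate {lam} < 0")
        return float(rng.poisson(lam))
    if tag == "binomial":
        n_, pr = p
        if n_ < 0 or n_ != int(n_) or not (0.0 <= pr <= 1.0):
            raise InvalidDistributionParameterError(f"binomial: invalid (n, p) = {p}")
        return float(rng.binomial(int(n_), pr))
    raise InvalidDistributionParameterError(f"unknown distribution {tag!r}")


# -- interpretation ----------------------------------------------------

def _truth(x) -> bool:
    return x != 0


def eval_expr(e: Expr, env: dict, rng=None):
    """Interpret an expression against ``env`` (symbol -> value).

    Used for initial assignments and event assignments, where distribution
    draws are legal (``rng`` must then be given).  Compiled rate laws use
    generated code instead.
    """
    k = e.kind
    if k == NUMBER:
        return e.value
    if k == SYMBOL:
        try:
            return env[e.value]
        except KeyError:
            raise UnresolvedSymbolError(f"undefined symbol {e.value!r}") from None
    if k == BINOP:
        a = eval_expr(e.children[0], env, rng)
        b = eval_expr(e.children[1], env, rng)
        op = e.value
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return a / b
        return a ** b
    if k == UNOP:
        v = eval_expr(e.children[0], env, rng)
        return -v if e.value == "-" else +v
    if k == CALL:
        args = [eval_expr(c, env, rng) for c in e.children]
        f = FUNCTIONS[e.value]
        return f.fn(*args)
    if k == RELATIONAL:
        a = eval_expr(e.children[0], env, rng)
        b = eval_expr(e.children[1], env, rng)
        return {"<": a < b, "<=": a <= b, ">": a > b, ">=": a >= b,
                "==": a == b, "!=": a != b}[e.value]
    if k == BOOLOP:
        if e.value == "not":
            return not _truth(eval_expr(e.children[0], env, rng))
        a = _truth(eval_expr(e.children[0], env, rng))
        b = _truth(eval_expr(e.children[1], env, rng))
        return {"and": a and b, "or": a or b, "xor": a != b}[e.value]
    if k == PIECEWISE:
        ch = e.children
        i = 0
        while i + 1 < len(ch):
            if _truth(eval_expr(ch[i + 1], env, rng)):
                return eval_expr(ch[i], env, rng)
            i += 2
        if i < len(ch):  # otherwise branch
            return eval_expr(ch[i], env, rng)
        return 0.0
    if k == DRAW:
        if rng is None:
            raise NonDifferentiableError(
                "distribution draw evaluated without a random generator")
        params = [eval_expr(c, env, rng) for c in e.children]
        return sample_draw(e.value, params, rng)
    raise AssertionError(k)


# -- code generation ---------------------------------------------------

def to_python(e: Expr, resolve: Callable[[str], str]) -> str:
    """Render an expression as a Python source fragment.

    ``resolve`` maps a symbol name to the code that yields its value
    (e.g. ``"y[0]/g[2]"``).  Draw nodes are rejected: compiled code must be
    deterministic per evaluation.
    """
    k = e.kind
    if k == NUMBER:
        return repr(e.value)
    if k == SYMBOL:
        return resolve(e.value)
    if k == BINOP:
        a = to_python(e.children[0], resolve)
        b = to_python(e.children[1], resolve)
        op = {"^": "**"}.get(e.value, e.value)
        return f"({a} {op} {b})"
    if k == UNOP:
        return f"({e.value}{to_python(e.children[0], resolve)})"
    if k == CALL:
        args = [to_python(c, resolve) for c in e.children]
        tmpl = FUNCTIONS[e.value].code
        if callable(tmpl):
            return tmpl(args)
        return tmpl.format(*args)
    if k == RELATIONAL:
        a = to_python(e.children[0], resolve)
        b = to_python(e.children[1], resolve)
        return f"({a} {e.value} {b})"
    if k == BOOLOP:
        parts = [f"_b({to_python(c, resolve)})" for c in e.children]
        if e.value == "not":
            return f"(not {parts[0]})"
        if e.value == "xor":
            return f"({parts[0]} != {parts[1]})"
        return f"({parts[0]} {e.value} {parts[1]})"
    if k == PIECEWISE:
        ch = e.children
        pairs = []
        i = 0
        while i + 1 < len(ch):
            pairs.append((to_python(ch[i], resolve),
                          f"_b({to_python(ch[i + 1], resolve)})"))
            i += 2
        tail = to_python(ch[i], resolve) if i < len(ch) else "0.0"
        out = tail
        for v, c in reversed(pairs):
            out = f"({v} if {c} else {out})"
        return out
    if k == DRAW:
        raise NonDifferentiableError(
            f"distribution draw '{e.value}' is not allowed in compiled expressions")
    raise AssertionError(k)


# -- sympy bridge ------------------------------------------------------

_SYMPY_REL = {"<": sympy.Lt, "<=": sympy.Le, ">": sympy.Gt, ">=": sympy.Ge,
              "==": sympy.Eq, "!=": sympy.Ne}


def to_sympy(e: Expr):
    k = e.kind
    if k == NUMBER:
        return sympy.Float(e.value) if e.value != int(e.value) else sympy.Integer(int(e.value))
    if k == SYMBOL:
        return sympy.Symbol(e.value)
    if k == BINOP:
        a, b = (to_sympy(c) for c in e.children)
        return {"+": lambda: a + b, "-": lambda: a - b, "*": lambda: a * b,
                "/": lambda: a / b, "^": lambda: a ** b}[e.value]()
    if k == UNOP:
        v = to_sympy(e.children[0])
        return -v if e.value == "-" else v
    if k == CALL:
        f = FUNCTIONS[e.value]
        args = [to_sympy(c) for c in e.children]
        if f.sym is not None:
            return f.sym(*args)
        if e.value == "log":
            return sympy.log(args[0], 10) if len(args) == 1 else sympy.log(args[1], args[0])
        if e.value == "log10":
            return sympy.log(args[0], 10)
        if e.value == "log2":
            return sympy.log(args[0], 2)
        if e.value == "root":
            return args[1] ** (sympy.Integer(1) / args[0])
        if e.value == "rem":
            return sympy.Mod(args[0], args[1])
        if e.value == "quotient":
            return sympy.floor(args[0] / args[1])
        raise NonDifferentiableError(f"no sympy mapping for function {e.value!r}")
    if k == RELATIONAL:
        a, b = (to_sympy(c) for c in e.children)
        return _SYMPY_REL[e.value](a, b)
    if k == BOOLOP:
        args = [to_sympy(c) for c in e.children]
        return {"and": sympy.And, "or": sympy.Or, "xor": sympy.Xor,
                "not": sympy.Not}[e.value](*args)
    if k == PIECEWISE:
        ch = e.children
        pieces = []
        i = 0
        while i + 1 < len(ch):
            pieces.append((to_sympy(ch[i]), to_sympy(ch[i + 1])))
            i += 2
        if i < len(ch):
            pieces.append((to_sympy(ch[i]), sympy.true))
        return sympy.Piecewise(*pieces)
    if k == DRAW:
        raise NonDifferentiableError(
            f"distribution draw '{e.value}' has no symbolic counterpart")
    raise AssertionError(k)


_FROM_SYMPY_FUNCS = {
    sympy.exp: "exp", sympy.log: "ln", sympy.sqrt: "sqrt", sympy.Abs: "abs",
    sympy.floor: "floor", sympy.ceiling: "ceiling", sympy.factorial: "factorial",
    sympy.sin: "sin", sympy.cos: "cos", sympy.tan: "tan",
    sympy.sec: "sec", sympy.csc: "csc", sympy.cot: "cot",
    sympy.asin: "arcsin", sympy.acos: "arccos", sympy.atan: "arctan",
    sympy.sinh: "sinh", sympy.cosh: "cosh", sympy.tanh: "tanh",
    sympy.asinh: "arcsinh", sympy.acosh: "arccosh", sympy.atanh: "arctanh",
    sympy.Max: "max", sympy.Min: "min", sympy.Mod: "rem",
}

_FROM_SYMPY_REL = {sympy.StrictLessThan: "<", sympy.LessThan: "<=",
                   sympy.StrictGreaterThan: ">", sympy.GreaterThan: ">=",
                   sympy.Equality: "==", sympy.Unequality: "!="}


def from_sympy(s) -> Expr:
    if s is sympy.true:
        return num(1.0)
    if s is sympy.false:
        return num(0.0)
    if s.is_Number:
        if s is sympy.pi:
            return num(math.pi)
        if isinstance(s, sympy.Rational) and not isinstance(s, sympy.Integer):
            return div(num(float(s.p)), num(float(s.q)))
        return num(float(s))
    if s is sympy.pi:
        return num(math.pi)
    if s is sympy.E:
        return num(math.e)
    if s.is_Symbol:
        return sym(s.name)
    if s.is_Add:
        args = [from_sympy(a) for a in s.args]
        out = args[0]
        for a in args[1:]:
            out = add(out, a)
        return out
    if s.is_Mul:
        args = [from_sympy(a) for a in s.args]
        out = args[0]
        for a in args[1:]:
            out = mul(out, a)
        return out
    if s.is_Pow:
        return pow_(from_sympy(s.args[0]), from_sympy(s.args[1]))
    if isinstance(s, sympy.Piecewise):
        kids = []
        for v, c in s.args:
            if c is sympy.true:
                kids.append(from_sympy(v))
                break
            kids.extend((from_sympy(v), from_sympy(c)))
        return piecewise(*kids)
    for cls, name in _FROM_SYMPY_REL.items():
        if isinstance(s, cls):
            return rel(name, from_sympy(s.args[0]), from_sympy(s.args[1]))
    if isinstance(s, sympy.And):
        out = from_sympy(s.args[0])
        for a in s.args[1:]:
            out = boolop("and", out, from_sympy(a))
        return out
    if isinstance(s, sympy.Or):
        out = from_sympy(s.args[0])
        for a in s.args[1:]:
            out = boolop("or", out, from_sympy(a))
        return out
    if isinstance(s, sympy.Not):
        return boolop("not", from_sympy(s.args[0]))
    if s.func in _FROM_SYMPY_FUNCS:
        return call(_FROM_SYMPY_FUNCS[s.func], *[from_sympy(a) for a in s.args])
    if isinstance(s, sympy.log):
        return call("ln", from_sympy(s.args[0]))
    if isinstance(s, sympy.Derivative):
        raise NonDifferentiableError(f"sympy left an unevaluated derivative: {s}")
    raise NonDifferentiableError(f"cannot convert sympy expression {s!r}")


def differentiate(e: Expr, symbol: str) -> Expr:
    """Exact symbolic partial derivative ``d e / d symbol``.

    Piecewise expressions are differentiated branch-wise; draw nodes are
    rejected because a sampled value has no derivative.
    """
    if e.contains_draw():
        raise NonDifferentiableError("cannot differentiate through a distribution draw")
    d = sympy.diff(to_sympy(e), sympy.Symbol(symbol))
    return from_sympy(sympy.simplify(d) if d.has(sympy.Derivative) else d)


# -- infix text parser -------------------------------------------------
#
# Grammar (used by the chain notation and the CLI):
#   expr     := or
#   or       := and ( ("||" | "or") and )*
#   and      := cmp ( ("&&" | "and") cmp )*
#   cmp      := sum ( relop sum )?
#   sum      := term ( (+|-) term )*
#   term     := unary ( (*|/) unary )*
#   unary    := (+|-) unary | power
#   power    := atom ( ^ unary )?          (right associative)
#   atom     := number | name | name(args) | ( expr )

_TOKEN_SPEC = [
    ("NUM", r"(?:\d+\.?\d*|\.\d+)(?:[eE][+-]\d+|[eE]\d+)?"),
    ("NAME", r"[A-Za-z_][A-Za-z0-9_]*"),
    ("OP", r"<=|>=|==|!=|&&|\|\||->|[-+*/^()<>,;=$]"),
    ("WS", r"[ \t]+"),
]

import re as _re

_TOKEN_RE = _re.compile("|".join(f"(?P<{n}>{p})" for n, p in _TOKEN_SPEC))


def tokenize(text: str, line: int = 1):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", line, pos + 1)
        if m.lastgroup != "WS":
            tokens.append((m.lastgroup, m.group(), pos + 1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, line=1):
        self.toks = tokens
        self.i = 0
        self.line = line

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else (None, None, None)

    def next(self):
        t = self.peek()
        self.i += 1
        return t

    def expect(self, text):
        kind, val, col = self.next()
        if val != text:
            raise ParseError(f"expected {text!r}, got {val!r}", self.line, col)

    def fail(self, msg):
        _, val, col = self.peek()
        raise ParseError(msg + (f" near {val!r}" if val else " at end of input"),
                         self.line, col)

    def parse(self) -> Expr:
        e = self.expr()
        if self.i != len(self.toks):
            self.fail("trailing input")
        return e

    def expr(self):
        return self.or_()

    def or_(self):
        e = self.and_()
        while self.peek()[1] in ("||",) or (self.peek()[0] == "NAME" and self.peek()[1] == "or"):
            self.next()
            e = boolop("or", e, self.and_())
        return e

    def and_(self):
        e = self.cmp()
        while self.peek()[1] in ("&&",) or (self.peek()[0] == "NAME" and self.peek()[1] == "and"):
            self.next()
            e = boolop("and", e, self.cmp())
        return e

    def cmp(self):
        e = self.sum()
        if self.peek()[1] in _REL_OPS:
            op = self.next()[1]
            e = rel(op, e, self.sum())
        return e

    def sum(self):
        e = self.term()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            e = binop(op, e, self.term())
        return e

    def term(self):
        e = self.unary()
        while self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            e = binop(op, e, self.unary())
        return e

    def unary(self):
        if self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            inner = self.unary()
            return Expr(UNOP, op, (inner,))
        return self.power()

    def power(self):
        e = self.atom()
        if self.peek()[1] == "^":
            self.next()
            e = pow_(e, self.unary())
        return e

    def atom(self):
        kind, val, col = self.next()
        if kind == "NUM":
            return num(float(val))
        if kind == "NAME":
            if self.peek()[1] == "(":
                self.next()
                args = []
                if self.peek()[1] != ")":
                    args.append(self.expr())
                    while self.peek()[1] == ",":
                        self.next()
                        args.append(self.expr())
                self.expect(")")
                if val == "piecewise":
                    return piecewise(*args)
                if val in DISTRIBUTIONS:
                    return draw(val, *args)
                if val in FUNCTIONS:
                    return call(val, *args)
                raise ParseError(f"unknown function {val!r}", self.line, col)
            if val == "pi":
                return num(math.pi)
            return sym(val)
        if val == "(":
            e = self.expr()
            self.expect(")")
            return e
        raise ParseError(f"unexpected token {val!r}", self.line, col)


def parse_expr(text: str, line: int = 1) -> Expr:
    """Parse infix math (``k1*X0``, ``Vm*S/(Km+S)``, ``normal(0,1)``)."""
    toks = tokenize(text, line)
    if not toks:
        raise ParseError("empty expression", line)
    return _Parser(toks, line).parse()


# -- rendering ---------------------------------------------------------

def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


def to_infix(e: Expr) -> str:
    k = e.kind
    if k == NUMBER:
        return _fmt_num(e.value)
    if k == SYMBOL:
        return e.value
    if k == BINOP:
        return f"({to_infix(e.children[0])} {e.value} {to_infix(e.children[1])})"
    if k == UNOP:
        return f"({e.value}{to_infix(e.children[0])})"
    if k == CALL or k == DRAW:
        return f"{e.value}({', '.join(to_infix(c) for c in e.children)})"
    if k == RELATIONAL:
        return f"({to_infix(e.children[0])} {e.value} {to_infix(e.children[1])})"
    if k == BOOLOP:
        if e.value == "not":
            return f"(not {to_infix(e.children[0])})"
        return f"({to_infix(e.children[0])} {e.value} {to_infix(e.children[1])})"
    if k == PIECEWISE:
        return f"piecewise({', '.join(to_infix(c) for c in e.children)})"
    raise AssertionError(k)


def expr_to_dict(e: Expr) -> dict:
    """JSON-safe structural encoding (used by snapshots and the cache key)."""
    return {"k": e.kind, "v": e.value,
            "c": [expr_to_dict(c) for c in e.children]}


def expr_from_dict(d: dict) -> Expr:
    return Expr(d["k"], d["v"], tuple(expr_from_dict(c) for c in d["c"]))
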