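"""Read/write the SBML Level 3 core subset and the compact reaction-string
notation.

The supported SBML subset is: compartments, species (amount or
concentration), global and local parameters (locals hoisted to globals with
mangled ids), reactions, assignment and rate rules, initial assignments,
events without delay, and distribution-draw csymbols.  Anything else raises
:class:`UnsupportedConstructError` naming the construct — the reader fails
loudly rather than silently skipping model semantics.

Booleans and numbers coerce both ways at evaluation time (true = 1.0, a
number is true iff nonzero), so MathML that mixes them maps onto the same
expression tree without explicit coercion nodes.

The reaction-string notation covers statements separated by ``;`` or
newlines: a reaction arrow statement (``X0 -> S1``, optionally ``J1: ...``)
followed by its rate expression, and ``name = value`` assignments that set
parameters or species initial values.  ``$``-prefixed species — or species
that are only consumed, never produced, and carry an explicit assigned
value — are boundary species.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass

from lxml import etree

from . import expr as ex
from .errors import (
    InvalidModelError,
    ParseError,
    UnsupportedConstructError,
)
from .model_ir import (
    Compartment,
    Event,
    InitialAssignment,
    ModelIR,
    Parameter,
    Reaction,
    Rule,
    Species,
    SpeciesReference,
)

__all__ = ["SbmlDocument", "read_sbml", "write_sbml", "read_chain_notation",
           "write_chain_notation", "load_model"]

_SBML_NS_L3V2 = "http://www.sbml.org/sbml/level3/version2/core"
_SBML_NS_L3V1 = "http://www.sbml.org/sbml/level3/version1/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_TIME_URLS = {"http://www.sbml.org/sbml/symbols/time"}
_DELAY_URLS = {"http://www.sbml.org/sbml/symbols/delay"}
_DISTRIB_PREFIX = "http://www.sbml.org/sbml/symbols/distrib/"


@dataclass
class SbmlDocument:
    xml_text: str
    level: int = 3
    version: int = 2

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.xml_text)


def _tag(el) -> str:
    return etree.QName(el).localname


# ---------------------------------------------------------------------------
# MathML -> Expr

_MATHML_NARY = {"plus": "+", "times": "*"}
_MATHML_REL = {"lt": "<", "leq": "<=", "gt": ">", "geq": ">=",
               "eq": "==", "neq": "!="}
_MATHML_FUNCS = {
    "exp", "ln", "abs", "floor", "ceiling", "factorial", "sin", "cos", "tan",
    "sec", "csc", "cot", "arcsin", "arccos", "arctan", "sinh", "cosh", "tanh",
    "arcsinh", "arccosh", "arctanh", "power", "max", "min", "rem", "quotient",
}
_MATHML_CONSTANTS = {
    "true": ex.num(1.0), "false": ex.num(0.0),
    "pi": ex.num(math.pi), "exponentiale": ex.num(math.e),
    "infinity": ex.num(math.inf), "notanumber": ex.num(math.nan),
}


def _children(el):
    return [c for c in el if isinstance(c.tag, str)]


def parse_mathml(el) -> ex.Expr:
    """Parse the content of a <math> element (or any MathML node)."""
    tag = _tag(el)
    if tag == "math":
        kids = _children(el)
        if len(kids) != 1:
            raise ParseError("<math> must contain exactly one expression")
        return parse_mathml(kids[0])
    if tag == "cn":
        return _parse_cn(el)
    if tag == "ci":
        return ex.sym(el.text.strip())
    if tag == "csymbol":
        url = el.get("definitionURL", "")
        if url in _TIME_URLS:
            return ex.sym(ex.TIME)
        if url in _DELAY_URLS:
            raise UnsupportedConstructError("delay")
        raise UnsupportedConstructError(f"csymbol {url!r}")
    if tag in _MATHML_CONSTANTS:
        return _MATHML_CONSTANTS[tag]
    if tag == "piecewise":
        kids: list[ex.Expr] = []
        otherwise = None
        for c in _children(el):
            if _tag(c) == "piece":
                v, cond = (_children(c) + [None, None])[:2]
                if v is None or cond is None:
                    raise ParseError("<piece> needs value and condition")
                kids.extend((parse_mathml(v), parse_mathml(cond)))
            elif _tag(c) == "otherwise":
                otherwise = parse_mathml(_children(c)[0])
            else:
                raise UnsupportedConstructError(f"piecewise child {_tag(c)}")
        if otherwise is not None:
            kids.append(otherwise)
        return ex.piecewise(*kids)
    if tag == "apply":
        return _parse_apply(el)
    raise UnsupportedConstructError(f"MathML element <{tag}>")


def _parse_cn(el) -> ex.Expr:
    typ = el.get("type", "real")
    if typ in ("real", "integer", "double"):
        return ex.num(float(el.text.strip()))
    if typ == "e-notation":
        parts = [el.text or "0"]
        for c in el:
            parts.append(c.tail or "0")
        mantissa, exponent = (p.strip() for p in parts[:2])
        return ex.num(float(mantissa) * 10.0 ** float(exponent))
    if typ == "rational":
        parts = [el.text or "0"]
        for c in el:
            parts.append(c.tail or "1")
        p, q = (s.strip() for s in parts[:2])
        return ex.div(ex.num(float(p)), ex.num(float(q)))
    raise UnsupportedConstructError(f"cn type {typ!r}")


def _fold(op: str, args: list[ex.Expr]) -> ex.Expr:
    out = args[0]
    for a in args[1:]:
        out = ex.binop(op, out, a)
    return out


def _parse_apply(el) -> ex.Expr:
    kids = _children(el)
    if not kids:
        raise ParseError("empty <apply>")
    head, *rest = kids
    op = _tag(head)
    if op == "csymbol":
        url = head.get("definitionURL", "")
        if url in _DELAY_URLS:
            raise UnsupportedConstructError("delay")
        if url.startswith(_DISTRIB_PREFIX):
            dist = url[len(_DISTRIB_PREFIX):]
            if dist not in ex.DISTRIBUTIONS:
                raise UnsupportedConstructError(f"distribution {dist!r}")
            return ex.draw(dist, *[parse_mathml(a) for a in rest])
        raise UnsupportedConstructError(f"csymbol {url!r}")
    args = [parse_mathml(a) for a in rest]
    if op in _MATHML_NARY:
        if op == "plus" and not args:
            return ex.num(0.0)
        if op == "times" and not args:
            return ex.num(1.0)
        return _fold(_MATHML_NARY[op], args)
    if op == "minus":
        return ex.neg(args[0]) if len(args) == 1 else ex.sub(args[0], args[1])
    if op == "divide":
        return ex.div(args[0], args[1])
    if op == "power":
        return ex.pow_(args[0], args[1])
    if op in _MATHML_REL:
        return ex.rel(_MATHML_REL[op], args[0], args[1])
    if op in ("and", "or", "xor"):
        return _foldbool(op, args)
    if op == "not":
        return ex.boolop("not", args[0])
    if op == "root":
        degree = _qualifier(el, "degree")
        deg = parse_mathml(degree) if degree is not None else ex.num(2.0)
        return ex.call("root", deg, args[-1])
    if op == "log":
        logbase = _qualifier(el, "logbase")
        if logbase is not None:
            return ex.call("log", parse_mathml(logbase), args[-1])
        return ex.call("log", args[0])
    if op in _MATHML_FUNCS:
        return ex.call(op, *args)
    raise UnsupportedConstructError(f"MathML operator <{op}>")


def _foldbool(op, args):
    if len(args) == 1:
        return args[0]
    out = ex.boolop(op, args[0], args[1])
    for a in args[2:]:
        out = ex.boolop(op, out, a)
    return out


def _qualifier(apply_el, name):
    for c in _children(apply_el):
        if _tag(c) == name:
            inner = _children(c)
            return inner[0] if inner else None
    return None


# ---------------------------------------------------------------------------
# Expr -> MathML

def _m(name, *kids, **attrs):
    el = etree.Element(f"{{{_MATHML_NS}}}{name}", nsmap={None: _MATHML_NS})
    for k, v in attrs.items():
        el.set(k, v)
    for c in kids:
        el.append(c)
    return el


def expr_to_mathml(e: ex.Expr):
    k = e.kind
    if k == ex.NUMBER:
        el = _m("cn")
        v = e.value
        el.text = str(int(v)) if v == int(v) and abs(v) < 1e15 else repr(v)
        if v == int(v) and abs(v) < 1e15:
            el.set("type", "integer")
        return el
    if k == ex.SYMBOL:
        if e.value == ex.TIME:
            el = _m("csymbol", encoding="text",
                    definitionURL="http://www.sbml.org/sbml/symbols/time")
            el.text = "time"
            return el
        el = _m("ci")
        el.text = f" {e.value} "
        return el
    if k == ex.BINOP:
        op = {"+": "plus", "-": "minus", "*": "times", "/": "divide",
              "^": "power"}[e.value]
        return _m("apply", _m(op), *[expr_to_mathml(c) for c in e.children])
    if k == ex.UNOP:
        if e.value == "+":
            return expr_to_mathml(e.children[0])
        return _m("apply", _m("minus"), expr_to_mathml(e.children[0]))
    if k == ex.CALL:
        name = e.value
        if name == "log" and len(e.children) == 2:
            base = _m("logbase", expr_to_mathml(e.children[0]))
            return _m("apply", _m("log"), base, expr_to_mathml(e.children[1]))
        if name == "log":
            return _m("apply", _m("log"), expr_to_mathml(e.children[0]))
        if name == "log10":
            base = _m("logbase", expr_to_mathml(ex.num(10.0)))
            return _m("apply", _m("log"), base, expr_to_mathml(e.children[0]))
        if name == "log2":
            base = _m("logbase", expr_to_mathml(ex.num(2.0)))
            return _m("apply", _m("log"), base, expr_to_mathml(e.children[0]))
        if name == "sqrt":
            return _m("apply", _m("root"),
                      _m("degree", expr_to_mathml(ex.num(2.0))),
                      expr_to_mathml(e.children[0]))
        if name == "root":
            return _m("apply", _m("root"),
                      _m("degree", expr_to_mathml(e.children[0])),
                      expr_to_mathml(e.children[1]))
        return _m("apply", _m(name), *[expr_to_mathml(c) for c in e.children])
    if k == ex.RELATIONAL:
        name = {v: k2 for k2, v in _MATHML_REL.items()}[e.value]
        return _m("apply", _m(name), *[expr_to_mathml(c) for c in e.children])
    if k == ex.BOOLOP:
        return _m("apply", _m(e.value), *[expr_to_mathml(c) for c in e.children])
    if k == ex.PIECEWISE:
        pw = _m("piecewise")
        ch = e.children
        i = 0
        while i + 1 < len(ch):
            pw.append(_m("piece", expr_to_mathml(ch[i]), expr_to_mathml(ch[i + 1])))
            i += 2
        if i < len(ch):
            pw.append(_m("otherwise", expr_to_mathml(ch[i])))
        return pw
    if k == ex.DRAW:
        cs = _m("csymbol", encoding="text",
                definitionURL=_DISTRIB_PREFIX + e.value)
        cs.text = e.value
        return _m("apply", cs, *[expr_to_mathml(c) for c in e.children])
    raise AssertionError(k)


def _math_element(e: ex.Expr):
    math_el = _m("math")
    math_el.append(expr_to_mathml(e))
    return math_el


# ---------------------------------------------------------------------------
# SBML document -> ModelIR

def _truthy(val, default=False) -> bool:
    if val is None:
        return default
    return val in ("true", "1", True)


def read_sbml(source: str | SbmlDocument) -> ModelIR:
    """Parse an SBML L3V1/L3V2 document (path, XML string, or SbmlDocument)."""
    if isinstance(source, SbmlDocument):
        text = source.xml_text
    elif isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith("<"):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as err:
        raise ParseError(f"malformed XML: {err}") from err
    if _tag(root) != "sbml":
        raise ParseError("root element is not <sbml>")
    ns = etree.QName(root).namespace
    if ns not in (_SBML_NS_L3V2, _SBML_NS_L3V1):
        raise UnsupportedConstructError(f"SBML namespace {ns!r} (level 3 only)")
    model_el = next((c for c in _children(root) if _tag(c) == "model"), None)
    if model_el is None:
        raise ParseError("document has no <model>")

    ir = ModelIR(id=model_el.get("id", "model"))
    for section in _children(model_el):
        tag = _tag(section)
        if tag == "listOfCompartments":
            for c in _children(section):
                ir.compartments.append(Compartment(
                    c.get("id"), float(c.get("size", "1")),
                    _truthy(c.get("constant"), True)))
        elif tag == "listOfSpecies":
            for s in _children(section):
                conc = s.get("initialConcentration")
                amt = s.get("initialAmount")
                if conc is not None:
                    init, is_conc = float(conc), True
                elif amt is not None:
                    init, is_conc = float(amt), False
                else:
                    init, is_conc = 0.0, True
                ir.species.append(Species(
                    s.get("id"), s.get("compartment"), init, is_conc,
                    _truthy(s.get("boundaryCondition")),
                    _truthy(s.get("constant"))))
        elif tag == "listOfParameters":
            for p in _children(section):
                ir.parameters.append(Parameter(
                    p.get("id"), float(p.get("value", "0")),
                    _truthy(p.get("constant"), True)))
        elif tag == "listOfInitialAssignments":
            for ia in _children(section):
                math_el = _find_math(ia)
                ir.initial_assignments.append(InitialAssignment(
                    ia.get("symbol"), parse_mathml(math_el)))
        elif tag == "listOfRules":
            for r in _children(section):
                rtag = _tag(r)
                if rtag == "algebraicRule":
                    raise UnsupportedConstructError("algebraicRule")
                kind = "assignment" if rtag == "assignmentRule" else "rate"
                ir.rules.append(Rule(kind, r.get("variable"),
                                     parse_mathml(_find_math(r))))
        elif tag == "listOfReactions":
            for r in _children(section):
                ir.reactions.append(_read_reaction(r, ir))
        elif tag == "listOfEvents":
            for e in _children(section):
                ir.events.append(_read_event(e))
        elif tag == "listOfFunctionDefinitions":
            raise UnsupportedConstructError("functionDefinition")
        elif tag == "listOfConstraints":
            raise UnsupportedConstructError("constraint")
        elif tag in ("listOfUnitDefinitions", "annotation", "notes"):
            continue
        else:
            raise UnsupportedConstructError(f"<{tag}>")
    return ir


def _find_math(el):
    for c in _children(el):
        if _tag(c) == "math":
            return c
    raise ParseError(f"<{_tag(el)}> has no <math>")


def _read_reaction(r, ir: ModelIR) -> Reaction:
    rxn = Reaction(r.get("id"), reversible=_truthy(r.get("reversible"), True))
    local_renames: dict[str, str] = {}
    for section in _children(r):
        tag = _tag(section)
        if tag in ("listOfReactants", "listOfProducts"):
            target = rxn.reactants if tag == "listOfReactants" else rxn.products
            for sr in _children(section):
                target.append(SpeciesReference(
                    sr.get("species"), float(sr.get("stoichiometry", "1")),
                    sr.get("id")))
        elif tag == "listOfModifiers":
            rxn.modifiers = [m.get("species") for m in _children(section)]
        elif tag == "kineticLaw":
            for part in _children(section):
                ptag = _tag(part)
                if ptag == "math":
                    rxn.kinetic_law = parse_mathml(part)
                elif ptag in ("listOfLocalParameters", "listOfParameters"):
                    for lp in _children(part):
                        pid = lp.get("id")
                        mangled = f"{rxn.id}_{pid}"
                        local_renames[pid] = mangled
                        ir.parameters.append(Parameter(
                            mangled, float(lp.get("value", "0")), True))
        elif tag in ("annotation", "notes"):
            continue
        else:
            raise UnsupportedConstructError(f"reaction child <{tag}>")
    if local_renames:
        rxn.kinetic_law = _rename_symbols(rxn.kinetic_law, local_renames)
    return rxn


def _rename_symbols(e: ex.Expr, renames: dict[str, str]) -> ex.Expr:
    if e.kind == ex.SYMBOL and e.value in renames:
        return ex.sym(renames[e.value])
    if not e.children:
        return e
    return ex.Expr(e.kind, e.value,
                   tuple(_rename_symbols(c, renames) for c in e.children))


def _read_event(e) -> Event:
    evt = Event(e.get("id") or "event", trigger=ex.num(0.0))
    for section in _children(e):
        tag = _tag(section)
        if tag == "trigger":
            evt.initial_trigger_value = _truthy(section.get("initialValue"), True)
            evt.persistent = _truthy(section.get("persistent"), True)
            evt.trigger = parse_mathml(_find_math(section))
        elif tag == "listOfEventAssignments":
            for ea in _children(section):
                evt.assignments.append((ea.get("variable"),
                                        parse_mathml(_find_math(ea))))
        elif tag in ("delay", "priority"):
            raise UnsupportedConstructError(f"event {tag}")
        elif tag in ("annotation", "notes"):
            continue
        else:
            raise UnsupportedConstructError(f"event child <{tag}>")
    return evt


# ---------------------------------------------------------------------------
# ModelIR -> SBML document

def write_sbml(ir: ModelIR) -> SbmlDocument:
    """Serialize to an SBML L3V2 document; the model must validate."""
    diags = ir.validate()
    if diags:
        raise InvalidModelError(diags)
    nsmap = {None: _SBML_NS_L3V2}
    root = etree.Element(f"{{{_SBML_NS_L3V2}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, f"{{{_SBML_NS_L3V2}}}model")
    model.set("id", ir.id)

    def sub(parent, name, **attrs):
        el = etree.SubElement(parent, f"{{{_SBML_NS_L3V2}}}{name}")
        for k, v in attrs.items():
            el.set(k, v)
        return el

    def boolstr(b):
        return "true" if b else "false"

    if ir.compartments:
        lst = sub(model, "listOfCompartments")
        for c in ir.compartments:
            sub(lst, "compartment", id=c.id, size=repr(c.size),
                constant=boolstr(c.constant), spatialDimensions="3")
    if ir.species:
        lst = sub(model, "listOfSpecies")
        for s in ir.species:
            el = sub(lst, "species", id=s.id, compartment=s.compartment,
                     boundaryCondition=boolstr(s.boundary),
                     constant=boolstr(s.constant),
                     hasOnlySubstanceUnits="false")
            if s.initial_is_concentration:
                el.set("initialConcentration", repr(s.initial_value))
            else:
                el.set("initialAmount", repr(s.initial_value))
    if ir.parameters:
        lst = sub(model, "listOfParameters")
        for p in ir.parameters:
            sub(lst, "parameter", id=p.id, value=repr(p.value),
                constant=boolstr(p.constant))
    if ir.initial_assignments:
        lst = sub(model, "listOfInitialAssignments")
        for ia in ir.initial_assignments:
            el = sub(lst, "initialAssignment", symbol=ia.target)
            el.append(_math_element(ia.math))
    if ir.rules:
        lst = sub(model, "listOfRules")
        for r in ir.rules:
            name = "assignmentRule" if r.kind == "assignment" else "rateRule"
            el = sub(lst, name, variable=r.target)
            el.append(_math_element(r.math))
    if ir.reactions:
        lst = sub(model, "listOfReactions")
        for r in ir.reactions:
            el = sub(lst, "reaction", id=r.id, reversible=boolstr(r.reversible))
            for name, refs in (("listOfReactants", r.reactants),
                               ("listOfProducts", r.products)):
                if refs:
                    rl = sub(el, name)
                    for sr in refs:
                        if isinstance(sr.stoichiometry, ex.Expr):
                            raise UnsupportedConstructError(
                                "expression stoichiometry must use a stoichiometry "
                                "id (assignment rule target) for serialization")
                        attrs = {"species": sr.species,
                                 "stoichiometry": repr(float(sr.stoichiometry)),
                                 "constant": boolstr(sr.stoich_id is None)}
                        if sr.stoich_id:
                            attrs["id"] = sr.stoich_id
                        sub(rl, "speciesReference", **attrs)
            if r.modifiers:
                ml = sub(el, "listOfModifiers")
                for m in r.modifiers:
                    sub(ml, "modifierSpeciesReference", species=m)
            kl = sub(el, "kineticLaw")
            kl.append(_math_element(r.kinetic_law))
    if ir.events:
        lst = sub(model, "listOfEvents")
        for e in ir.events:
            el = sub(lst, "event", id=e.id, useValuesFromTriggerTime="true")
            tr = sub(el, "trigger", initialValue=boolstr(e.initial_trigger_value),
                     persistent=boolstr(e.persistent))
            tr.append(_math_element(e.trigger))
            al = sub(el, "listOfEventAssignments")
            for target, m in e.assignments:
                ea = sub(al, "eventAssignment", variable=target)
                ea.append(_math_element(m))
    text = etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()
    return SbmlDocument(text, 3, 2)


# ---------------------------------------------------------------------------
# chain notation

_ASSIGN_RE = re.compile(r"^\s*([A-Za-z_$][A-Za-z0-9_]*)\s*=\s*(.+)$")
_REACTION_ID_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_]*)\s*:\s*(.*)$")
_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s*\*?\s*)?(\$?)([A-Za-z_][A-Za-z0-9_]*)\s*$")


def read_chain_notation(source: str, model_id: str = "chain_model",
                        compartment: str = "default_compartment") -> ModelIR:
    """Parse compact reaction-string notation into a model.

    ``X0 -> S1; k1*X0; S1 -> S2; k2*S1; k1 = 0.1; X0 = 10`` builds two
    reactions, three species (X0 boundary because it is only consumed and
    has an assigned value) and the listed parameters.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.sep in str(source) \
            and os.path.exists(source):
        with open(source) as fh:
            source = fh.read()
    text = str(source)
    statements: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines() or [text], start=1):
        line = line.split("//")[0].split("#")[0]
        for stmt in line.split(";"):
            if stmt.strip():
                statements.append((lineno, stmt.strip()))

    reactions: list[dict] = []
    assignments: list[tuple[int, str, str]] = []
    boundary_marked: set[str] = set()

    i = 0
    while i < len(statements):
        lineno, stmt = statements[i]
        if "->" in stmt:
            rid = None
            m = _REACTION_ID_RE.match(stmt)
            if m and "->" in m.group(2):
                rid, stmt = m.group(1), m.group(2)
            lhs_text, rhs_text = stmt.split("->", 1)
            lhs = _parse_side(lhs_text, lineno, boundary_marked)
            rhs = _parse_side(rhs_text, lineno, boundary_marked)
            if i + 1 >= len(statements) or "->" in statements[i + 1][1] \
                    or _ASSIGN_RE.match(statements[i + 1][1]):
                raise ParseError("reaction is missing its rate expression", lineno)
            rate_line, rate_text = statements[i + 1]
            rate = ex.parse_expr(rate_text, rate_line)
            reactions.append({"id": rid, "lhs": lhs, "rhs": rhs, "rate": rate})
            i += 2
        else:
            m = _ASSIGN_RE.match(stmt)
            if not m:
                raise ParseError(f"cannot parse statement {stmt!r}", lineno)
            name = m.group(1)
            if name.startswith("$"):
                boundary_marked.add(name[1:])
                name = name[1:]
            assignments.append((lineno, name, m.group(2)))
            i += 1

    species_order: list[str] = []
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in reactions:
        for coeff, name in r["lhs"]:
            if name not in species_order:
                species_order.append(name)
            consumed.add(name)
        for coeff, name in r["rhs"]:
            if name not in species_order:
                species_order.append(name)
            produced.add(name)

    # resolve assignments: species initial values vs parameters
    species_init: dict[str, float] = {}
    parameters: list[tuple[str, float]] = []
    known_species = set(species_order)
    for lineno, name, value_text in assignments:
        if name not in known_species:
            normalized = name.replace("o", "0").replace("O", "0")
            if normalized in known_species:
                name = normalized
        value = ex.eval_expr(ex.parse_expr(value_text, lineno), {})
        if name in known_species:
            species_init[name] = float(value)
        else:
            parameters.append((name, float(value)))

    boundary = set(boundary_marked)
    for name in species_order:
        if name in species_init and name in consumed and name not in produced:
            boundary.add(name)

    ir = ModelIR(id=model_id)
    ir.compartments.append(Compartment(compartment, 1.0, True))
    for name in species_order:
        ir.species.append(Species(name, compartment,
                                  species_init.get(name, 0.0), True,
                                  name in boundary, False))
    for name, value in parameters:
        ir.parameters.append(Parameter(name, value, True))
    for j, r in enumerate(reactions, start=1):
        rxn = Reaction(r["id"] or f"J{j}", kinetic_law=r["rate"])
        for coeff, name in r["lhs"]:
            rxn.reactants.append(SpeciesReference(name, coeff))
        for coeff, name in r["rhs"]:
            rxn.products.append(SpeciesReference(name, coeff))
        ir.reactions.append(rxn)

    diags = ir.validate()
    if diags:
        raise InvalidModelError(diags)
    return ir


def _parse_side(text: str, lineno: int, boundary_marked: set[str]):
    text = text.strip()
    if not text:
        return []
    terms = []
    for part in text.split("+"):
        m = _TERM_RE.match(part)
        if not m:
            raise ParseError(f"cannot parse species term {part.strip()!r}", lineno)
        coeff = float(m.group(1)) if m.group(1) else 1.0
        if m.group(2):
            boundary_marked.add(m.group(3))
        terms.append((coeff, m.group(3)))
    return terms


def write_chain_notation(ir: ModelIR) -> str:
    """Serialize a mass-action-style model back to reaction-string text."""
    lines = []

    def side(refs):
        parts = []
        for sr in refs:
            c = float(sr.stoichiometry) if not isinstance(sr.stoichiometry, ex.Expr) else 1.0
            prefix = "" if c == 1.0 else (f"{int(c)} " if c == int(c) else f"{c} ")
            parts.append(prefix + sr.species)
        return " + ".join(parts)

    for r in ir.reactions:
        lines.append(f"{r.id}: {side(r.reactants)} -> {side(r.products)}; "
                     f"{ex.to_infix(r.kinetic_law)}")
    for s in ir.species:
        if s.boundary:
            lines.append(f"${s.id} = {s.initial_value!r}")
        elif s.initial_value:
            lines.append(f"{s.id} = {s.initial_value!r}")
    for p in ir.parameters:
        lines.append(f"{p.id} = {p.value!r}")
    return "\n".join(lines) + "\n"


def load_model(source: str, fmt: str | None = None) -> ModelIR:
    """Load from SBML XML or chain notation, auto-detecting by content."""
    text = source
    if isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith("<") \
            and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    text = str(text)
    if fmt is None:
        fmt = "sbml" if text.lstrip().startswith("<") else "chain"
    if fmt == "sbml":
        return read_sbml(text)
    if fmt == "chain":
        return read_chain_notation(text)
    raise ValueError(f"unknown format {fmt!r}")
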