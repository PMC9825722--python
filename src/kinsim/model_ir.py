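"""Declarative model representation and the direct editing API.

A :class:`ModelIR` holds compartments, species, parameters, reactions, rules,
initial assignments and events in document order, with a single flat,
case-sensitive symbol namespace (compartments, species, parameters, reactions
and stoichiometry ids all share it).  Editing never re-parses a source
document: components are appended/removed in place and the model's revision
counter is bumped so compiled evaluators can detect staleness.
"""

from __future__ import annotations

import copy as _copy
import hashlib
import json
from dataclasses import dataclass, field, replace

from . import expr as ex
from .errors import (
    DanglingReferenceError,
    DuplicateIdError,
    UnknownIdError,
)


@dataclass
class Compartment:
    id: str
    size: float = 1.0
    constant: bool = True


@dataclass
class Species:
    id: str
    compartment: str
    initial_value: float = 0.0
    initial_is_concentration: bool = True
    boundary: bool = False
    constant: bool = False


@dataclass
class Parameter:
    id: str
    value: float = 0.0
    constant: bool = True


@dataclass
class SpeciesReference:
    species: str
    stoichiometry: object = 1.0     # constant float or Expr
    stoich_id: str | None = None    # addressable like a parameter when set


@dataclass
class Reaction:
    id: str
    reactants: list[SpeciesReference] = field(default_factory=list)
    products: list[SpeciesReference] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    kinetic_law: ex.Expr = field(default_factory=lambda: ex.num(0.0))
    reversible: bool = True


@dataclass
class Rule:
    kind: str       # "assignment" | "rate"
    target: str
    math: ex.Expr


@dataclass
class InitialAssignment:
    target: str
    math: ex.Expr


@dataclass
class Event:
    id: str
    trigger: ex.Expr
    assignments: list[tuple[str, ex.Expr]] = field(default_factory=list)
    initial_trigger_value: bool = True
    persistent: bool = True


@dataclass
class Diagnostic:
    component: str
    rule: str
    message: str

    def __str__(self):
        return f"[{self.component}] {self.rule}: {self.message}"


#: symbols always resolvable inside kinetic laws
RESERVED_SYMBOLS = {ex.TIME}


@dataclass
class ModelIR:
    id: str = "model"
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)
    initial_assignments: list[InitialAssignment] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    metadata: dict = field(default_factory=dict, compare=False)
    revision: int = field(default=0, compare=False)

    # -- namespace -----------------------------------------------------
    def symbol_ids(self) -> set[str]:
        ids = set()
        for coll in (self.compartments, self.species, self.parameters,
                     self.reactions, self.events):
            ids.update(c.id for c in coll)
        for r in self.reactions:
            for sr in r.reactants + r.products:
                if sr.stoich_id:
                    ids.add(sr.stoich_id)
        return ids

    def find(self, id_: str):
        for coll in (self.compartments, self.species, self.parameters,
                     self.reactions, self.events):
            for c in coll:
                if c.id == id_:
                    return c
        return None

    def species_by_id(self, id_: str) -> Species:
        for s in self.species:
            if s.id == id_:
                return s
        raise UnknownIdError(f"no species {id_!r}")

    def compartment_by_id(self, id_: str) -> Compartment:
        for c in self.compartments:
            if c.id == id_:
                return c
        raise UnknownIdError(f"no compartment {id_!r}")

    def reaction_by_id(self, id_: str) -> Reaction:
        for r in self.reactions:
            if r.id == id_:
                return r
        raise UnknownIdError(f"no reaction {id_!r}")

    def _touch(self):
        self.revision += 1

    def _require_fresh(self, id_: str):
        if id_ in self.symbol_ids():
            raise DuplicateIdError(f"identifier {id_!r} already in use")

    # -- direct editing API ---------------------------------------------
    def add_compartment(self, id_: str, size: float = 1.0, constant: bool = True):
        self._require_fresh(id_)
        self.compartments.append(Compartment(id_, float(size), constant))
        self._touch()
        return self

    def add_species(self, id_: str, compartment: str, init_value: float = 0.0,
                    is_concentration: bool = True, boundary: bool = False,
                    constant: bool = False):
        self._require_fresh(id_)
        self.compartment_by_id(compartment)  # raises UnknownIdError
        self.species.append(Species(id_, compartment, float(init_value),
                                    is_concentration, boundary, constant))
        self._touch()
        return self

    def add_parameter(self, id_: str, value: float = 0.0, constant: bool = True):
        self._require_fresh(id_)
        self.parameters.append(Parameter(id_, float(value), constant))
        self._touch()
        return self

    def add_reaction(self, id_: str, reactants, products, rate_law,
                     reversible: bool = True, modifiers=()):
        """Append a reaction.

        ``reactants``/``products`` are species-id lists; listing a species
        twice accumulates stoichiometry.  ``rate_law`` may be an Expr or an
        infix string.
        """
        self._require_fresh(id_)
        if isinstance(rate_law, str):
            rate_law = ex.parse_expr(rate_law)
        known = self.symbol_ids() | RESERVED_SYMBOLS
        unresolved = rate_law.free_symbols() - known
        if unresolved:
            raise UnknownIdError(
                f"rate law of {id_!r} references undeclared symbols {sorted(unresolved)}")
        species_ids = {s.id for s in self.species}
        for sid in list(reactants) + list(products):
            if sid not in species_ids:
                raise UnknownIdError(f"unknown species {sid!r} in reaction {id_!r}")

        def collect(ids):
            refs: list[SpeciesReference] = []
            for sid in ids:
                for ref in refs:
                    if ref.species == sid:
                        ref.stoichiometry = float(ref.stoichiometry) + 1.0
                        break
                else:
                    refs.append(SpeciesReference(sid, 1.0))
            return refs

        self.reactions.append(Reaction(id_, collect(reactants), collect(products),
                                       list(modifiers), rate_law, reversible))
        self._touch()
        return self

    def add_rule(self, kind: str, target: str, math):
        if isinstance(math, str):
            math = ex.parse_expr(math)
        if kind not in ("assignment", "rate"):
            raise ValueError(f"rule kind must be assignment|rate, not {kind!r}")
        if self.find(target) is None:
            raise UnknownIdError(f"rule targets unknown identifier {target!r}")
        self.rules.append(Rule(kind, target, math))
        self._touch()
        return self

    def add_initial_assignment(self, target: str, math):
        if isinstance(math, str):
            math = ex.parse_expr(math)
        if self.find(target) is None:
            raise UnknownIdError(f"initial assignment targets unknown {target!r}")
        self.initial_assignments.append(InitialAssignment(target, math))
        self._touch()
        return self

    def add_event(self, id_: str, trigger, assignments,
                  initial_trigger_value: bool = True, persistent: bool = True):
        self._require_fresh(id_)
        if isinstance(trigger, str):
            trigger = ex.parse_expr(trigger)
        asg = []
        for target, math in assignments:
            if isinstance(math, str):
                math = ex.parse_expr(math)
            if self.find(target) is None:
                raise UnknownIdError(f"event assigns to unknown identifier {target!r}")
            asg.append((target, math))
        self.events.append(Event(id_, trigger, asg, initial_trigger_value, persistent))
        self._touch()
        return self

    def _references_to(self, id_: str) -> list[str]:
        """Components (other than `id_` itself) that mention `id_`."""
        users = []
        for s in self.species:
            if s.compartment == id_:
                users.append(s.id)
        for r in self.reactions:
            mentioned = {sr.species for sr in r.reactants + r.products}
            mentioned.update(r.modifiers)
            mentioned |= r.kinetic_law.free_symbols()
            if id_ in mentioned:
                users.append(r.id)
        for i, rule in enumerate(self.rules):
            if rule.target == id_ or id_ in rule.math.free_symbols():
                users.append(f"rule[{i}]")
        for i, ia in enumerate(self.initial_assignments):
            if ia.target == id_ or id_ in ia.math.free_symbols():
                users.append(f"initialAssignment[{i}]")
        for ev in self.events:
            syms = set(ev.trigger.free_symbols())
            for target, math in ev.assignments:
                syms.add(target)
                syms |= math.free_symbols()
            if id_ in syms:
                users.append(ev.id)
        return users

    def remove_component(self, id_: str, cascade: bool = False):
        """Remove a compartment, species, parameter, reaction or event.

        Without ``cascade`` the removal fails if anything still references the
        component; with it, referencing rules/initial-assignments/events and
        reactions are removed too (recursively).
        """
        comp = self.find(id_)
        if comp is None:
            raise UnknownIdError(f"no component {id_!r}")
        users = self._references_to(id_)
        if users and not cascade:
            raise DanglingReferenceError(
                f"{id_!r} is still referenced by {users}; pass cascade=True")
        if cascade and users:
            self.rules = [r for r in self.rules
                          if r.target != id_ and id_ not in r.math.free_symbols()]
            self.initial_assignments = [
                ia for ia in self.initial_assignments
                if ia.target != id_ and id_ not in ia.math.free_symbols()]
            for user in users:
                if self.find(user) is not None and user != id_:
                    self.remove_component(user, cascade=True)
        for coll in (self.compartments, self.species, self.parameters,
                     self.reactions, self.events):
            for c in list(coll):
                if c.id == id_:
                    coll.remove(c)
        self._touch()
        return self

    # -- validation ------------------------------------------------------
    def validate(self) -> list[Diagnostic]:
        """Check every structural invariant; returns diagnostics, raises nothing."""
        out: list[Diagnostic] = []
        seen: dict[str, str] = {}
        for kind, coll in (("compartment", self.compartments), ("species", self.species),
                           ("parameter", self.parameters), ("reaction", self.reactions),
                           ("event", self.events)):
            for c in coll:
                if c.id in seen:
                    out.append(Diagnostic(c.id, "duplicate-id",
                                          f"also declared as {seen[c.id]}"))
                seen[c.id] = kind
        for r in self.reactions:
            for sr in r.reactants + r.products:
                if sr.stoich_id:
                    if sr.stoich_id in seen:
                        out.append(Diagnostic(sr.stoich_id, "duplicate-id",
                                              "stoichiometry id collides"))
                    seen[sr.stoich_id] = "stoichiometry"

        known = set(seen) | RESERVED_SYMBOLS
        comp_ids = {c.id for c in self.compartments}
        species_ids = {s.id for s in self.species}

        for c in self.compartments:
            if not c.size > 0:
                out.append(Diagnostic(c.id, "nonpositive-size", f"size {c.size}"))
        for s in self.species:
            if s.compartment not in comp_ids:
                out.append(Diagnostic(s.id, "unknown-compartment", s.compartment))
            if s.initial_value < 0:
                out.append(Diagnostic(s.id, "negative-initial", str(s.initial_value)))

        rate_targets = set()
        for i, rule in enumerate(self.rules):
            comp = self.find(rule.target)
            if comp is None:
                out.append(Diagnostic(f"rule[{i}]", "unknown-target", rule.target))
                continue
            if getattr(comp, "constant", False):
                out.append(Diagnostic(f"rule[{i}]", "constant-target", rule.target))
            if rule.target in rate_targets:
                out.append(Diagnostic(f"rule[{i}]", "multiple-rules", rule.target))
            rate_targets.add(rule.target)
            bad = rule.math.free_symbols() - known
            if bad:
                out.append(Diagnostic(f"rule[{i}]", "unresolved-symbol", str(sorted(bad))))

        for r in self.reactions:
            for sr in r.reactants + r.products:
                if sr.species not in species_ids:
                    out.append(Diagnostic(r.id, "unknown-species", sr.species))
                if not isinstance(sr.stoichiometry, ex.Expr) and not sr.stoichiometry > 0:
                    out.append(Diagnostic(r.id, "nonpositive-stoichiometry",
                                          f"{sr.species}: {sr.stoichiometry}"))
            for m in r.modifiers:
                if m not in species_ids:
                    out.append(Diagnostic(r.id, "unknown-modifier", m))
            bad = r.kinetic_law.free_symbols() - known
            if bad:
                out.append(Diagnostic(r.id, "unresolved-symbol", str(sorted(bad))))
            changed = {sr.species for sr in r.reactants + r.products}
            for sid in changed:
                sp = next((s for s in self.species if s.id == sid), None)
                if sp is not None and sp.constant:
                    out.append(Diagnostic(r.id, "constant-species-changed", sid))

        for ia in self.initial_assignments:
            if self.find(ia.target) is None:
                out.append(Diagnostic("initialAssignment", "unknown-target", ia.target))
            bad = ia.math.free_symbols() - known
            if bad:
                out.append(Diagnostic("initialAssignment", "unresolved-symbol",
                                      str(sorted(bad))))

        for ev in self.events:
            bad = ev.trigger.free_symbols() - known
            if bad:
                out.append(Diagnostic(ev.id, "unresolved-symbol", str(sorted(bad))))
            for target, math in ev.assignments:
                comp = self.find(target)
                if comp is None:
                    out.append(Diagnostic(ev.id, "unknown-target", target))
                elif getattr(comp, "constant", False):
                    out.append(Diagnostic(ev.id, "constant-target", target))
                bad = math.free_symbols() - known
                if bad:
                    out.append(Diagnostic(ev.id, "unresolved-symbol", str(sorted(bad))))
        return out

    # -- serialization ---------------------------------------------------
    def copy(self) -> "ModelIR":
        m = _copy.deepcopy(self)
        return m

    def to_dict(self) -> dict:
        def stoich(sr: SpeciesReference):
            s = (ex.expr_to_dict(sr.stoichiometry)
                 if isinstance(sr.stoichiometry, ex.Expr) else sr.stoichiometry)
            return {"species": sr.species, "stoichiometry": s,
                    "stoich_id": sr.stoich_id}

        return {
            "id": self.id,
            "compartments": [vars(c).copy() for c in self.compartments],
            "species": [vars(s).copy() for s in self.species],
            "parameters": [vars(p).copy() for p in self.parameters],
            "reactions": [{
                "id": r.id,
                "reactants": [stoich(sr) for sr in r.reactants],
                "products": [stoich(sr) for sr in r.products],
                "modifiers": list(r.modifiers),
                "kinetic_law": ex.expr_to_dict(r.kinetic_law),
                "reversible": r.reversible,
            } for r in self.reactions],
            "rules": [{"kind": r.kind, "target": r.target,
                       "math": ex.expr_to_dict(r.math)} for r in self.rules],
            "initial_assignments": [{"target": ia.target,
                                     "math": ex.expr_to_dict(ia.math)}
                                    for ia in self.initial_assignments],
            "events": [{
                "id": e.id, "trigger": ex.expr_to_dict(e.trigger),
                "assignments": [[t, ex.expr_to_dict(m)] for t, m in e.assignments],
                "initial_trigger_value": e.initial_trigger_value,
                "persistent": e.persistent,
            } for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelIR":
        def stoich(sd):
            s = sd["stoichiometry"]
            if isinstance(s, dict):
                s = ex.expr_from_dict(s)
            return SpeciesReference(sd["species"], s, sd.get("stoich_id"))

        m = cls(id=d["id"])
        m.compartments = [Compartment(**c) for c in d["compartments"]]
        m.species = [Species(**s) for s in d["species"]]
        m.parameters = [Parameter(**p) for p in d["parameters"]]
        m.reactions = [Reaction(r["id"],
                                [stoich(s) for s in r["reactants"]],
                                [stoich(s) for s in r["products"]],
                                list(r["modifiers"]),
                                ex.expr_from_dict(r["kinetic_law"]),
                                r["reversible"]) for r in d["reactions"]]
        m.rules = [Rule(r["kind"], r["target"], ex.expr_from_dict(r["math"]))
                   for r in d["rules"]]
        m.initial_assignments = [InitialAssignment(ia["target"],
                                                   ex.expr_from_dict(ia["math"]))
                                 for ia in d["initial_assignments"]]
        m.events = [Event(e["id"], ex.expr_from_dict(e["trigger"]),
                          [(t, ex.expr_from_dict(mm)) for t, mm in e["assignments"]],
                          e["initial_trigger_value"], e["persistent"])
                    for e in d["events"]]
        return m

    def content_hash(self) -> str:
        """Stable hash of the structural content (ignores revision/metadata)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def structurally_equal(self, other: "ModelIR") -> bool:
        return self.to_dict() == other.to_dict()
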