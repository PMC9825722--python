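"""Deterministic, seeded model generators used throughout the test corpus.

Every generator returns a validated :class:`ModelIR` that compiles and
simulates cleanly; closed-form reference values (steady states, root
locations) are attached under ``model.metadata`` so analyses can be checked
against independent arithmetic.

The canonical two-step linear chain (boundary source X0 = 10 feeding S1 and
S2 with first-order steps k1 = 0.1, k2 = 0.3, k3 = 0.14) uses k1*X0 as the
first rate: with S1(0) = 0 a first rate proportional to S1 would freeze the
whole chain at zero, so the literal variant is kept only as a parser fixture
(``two_step_chain_literal_text``).
"""

from __future__ import annotations

import numpy as np

from . import expr as ex
from .errors import KinsimError
from .model_ir import ModelIR

__all__ = ["two_step_chain", "two_step_chain_text", "two_step_chain_literal_text",
           "linear_chain", "closed_pair", "immigration_death",
           "random_mass_action", "bistable_switch", "michaelis_menten",
           "corpus"]

#: canonical chain-notation source for the two-step linear chain
two_step_chain_text = ("X0 -> S1; k1*X0; S1 -> S2; k2*S1; S2 ->; k3*S2; "
                   "k1 = 0.1; k2 = 0.3; k3 = 0.14; X0 = 10")

#: the literal published variant (first rate k1*S1, spelled Xo) for parser tests
two_step_chain_literal_text = ("X0 -> S1; k1*S1; S1 -> S2; k2*S2; S2 ->; k3*S2; "
                          "k1 = 0.1; k2 = 0.3; k3 = 0.14; Xo = 10")


def two_step_chain() -> ModelIR:
    """The two-step linear chain with its closed-form steady state.

    X0 (boundary, 10) -> S1 -> S2 -> sink with rates k1*X0, k2*S1, k3*S2;
    steady state S1* = k1*X0/k2 = 10/3, S2* = k1*X0/k3 = 50/7.
    """
    m = ModelIR(id="linear_chain_2")
    m.add_compartment("default_compartment", 1.0)
    m.add_species("X0", "default_compartment", 10.0, boundary=True)
    m.add_species("S1", "default_compartment", 0.0)
    m.add_species("S2", "default_compartment", 0.0)
    m.add_parameter("k1", 0.1)
    m.add_parameter("k2", 0.3)
    m.add_parameter("k3", 0.14)
    m.add_reaction("J1", ["X0"], ["S1"], "k1*X0")
    m.add_reaction("J2", ["S1"], ["S2"], "k2*S1")
    m.add_reaction("J3", ["S2"], [], "k3*S2")
    k1, k2, k3, x0 = 0.1, 0.3, 0.14, 10.0
    m.metadata["steady_state"] = {"S1": k1 * x0 / k2, "S2": k1 * x0 / k3}
    m.metadata["flux"] = k1 * x0
    m.revision = 0
    return m


def linear_chain(n: int, seed: int = 0) -> ModelIR:
    """Open first-order chain X0 -> S1 -> ... -> Sn -> sink.

    Rate constants are log-uniform in [0.01, 1] under the seed; the
    closed-form steady state S_i* = k_in*X0 / k_out,i is stored as metadata.
    """
    if n < 1:
        raise KinsimError("chain length must be at least 1")
    rng = np.random.default_rng(seed)
    ks = np.exp(rng.uniform(np.log(0.01), np.log(1.0), size=n + 1))
    m = ModelIR(id=f"linear_chain_{n}")
    m.add_compartment("default_compartment", 1.0)
    m.add_species("X0", "default_compartment", 10.0, boundary=True)
    for i in range(1, n + 1):
        m.add_species(f"S{i}", "default_compartment", 0.0)
    for i, k in enumerate(ks):
        m.add_parameter(f"k{i + 1}", float(k))
    m.add_reaction("J1", ["X0"], ["S1"], "k1*X0")
    for i in range(1, n):
        m.add_reaction(f"J{i + 1}", [f"S{i}"], [f"S{i + 1}"], f"k{i + 1}*S{i}")
    m.add_reaction(f"J{n + 1}", [f"S{n}"], [], f"k{n + 1}*S{n}")
    influx = ks[0] * 10.0
    m.metadata["steady_state"] = {f"S{i}": float(influx / ks[i])
                                  for i in range(1, n + 1)}
    m.metadata["flux"] = float(influx)
    m.revision = 0
    return m


def closed_pair(k_forward: float = 1.0, k_backward: float = 1.0,
                s1_init: float = 5.0, s2_init: float = 5.0) -> ModelIR:
    """Closed isomerisation S1 <-> S2: one conservation law S1 + S2."""
    m = ModelIR(id="closed_pair")
    m.add_compartment("default_compartment", 1.0)
    m.add_species("S1", "default_compartment", s1_init)
    m.add_species("S2", "default_compartment", s2_init)
    m.add_parameter("kf", k_forward)
    m.add_parameter("kb", k_backward)
    m.add_reaction("Jf", ["S1"], ["S2"], "kf*S1")
    m.add_reaction("Jb", ["S2"], ["S1"], "kb*S2")
    total = s1_init + s2_init
    m.metadata["total"] = total
    m.metadata["steady_state"] = {
        "S1": total * k_backward / (k_forward + k_backward),
        "S2": total * k_forward / (k_forward + k_backward)}
    m.revision = 0
    return m


def immigration_death(k_in: float = 10.0, gamma: float = 1.0,
                      s_init: float = 0.0) -> ModelIR:
    """Birth-death process 0 -> S (rate k), S -> 0 (rate gamma*S).

    Its stationary law is Poisson with mean k/gamma (so Fano factor 1), the
    standard calibration target for the stochastic simulator.
    """
    m = ModelIR(id="immigration_death")
    m.add_compartment("default_compartment", 1.0)
    m.add_species("S", "default_compartment", s_init)
    m.add_parameter("k_in", k_in)
    m.add_parameter("gamma", gamma)
    m.add_reaction("Jin", [], ["S"], "k_in")
    m.add_reaction("Jout", ["S"], [], "gamma*S")
    m.metadata["stationary_mean"] = k_in / gamma
    m.metadata["steady_state"] = {"S": k_in / gamma}
    m.revision = 0
    return m


def michaelis_menten(vmax: float = 1.0, km: float = 0.5, k_in: float = 0.4,
                     k_out: float = 0.2) -> ModelIR:
    """Open two-species pathway with a saturable middle step.

    X0 -> S (k_in*X0), S -> P (Vm*S/(Km+S)), P -> sink (k_out*P); at steady
    state the flux is k_in*X0 so S* = Km*J/(Vm-J) and P* = J/k_out.
    """
    m = ModelIR(id="michaelis_menten")
    m.add_compartment("default_compartment", 1.0)
    m.add_species("X0", "default_compartment", 1.0, boundary=True)
    m.add_species("S", "default_compartment", 0.1)
    m.add_species("P", "default_compartment", 0.0)
    m.add_parameter("k_in", k_in)
    m.add_parameter("Vm", vmax)
    m.add_parameter("Km", km)
    m.add_parameter("k_out", k_out)
    m.add_reaction("Jin", ["X0"], ["S"], "k_in*X0")
    m.add_reaction("Jcat", ["S"], ["P"], "Vm*S/(Km+S)")
    m.add_reaction("Jout", ["P"], [], "k_out*P")
    J = k_in * 1.0
    if J < vmax:
        m.metadata["steady_state"] = {"S": km * J / (vmax - J), "P": J / k_out}
        m.metadata["flux"] = J
    m.revision = 0
    return m


def bistable_switch(k1: float = 1.0, K: float = 1.0, k2: float = 0.4) -> ModelIR:
    """One-species positive-feedback switch dS/dt = k1*S^2/(K+S^2) - k2*S.

    With the defaults the roots are 0 (stable), 0.5 (unstable) and 2
    (stable); their locations are recomputed by bisection at build time and
    stored as metadata.
    """
    m = ModelIR(id="bistable_switch")
    m.add_compartment("default_compartment", 1.0)
    m.add_species("S", "default_compartment", 0.1)
    m.add_parameter("k1", k1)
    m.add_parameter("K", K)
    m.add_parameter("k2", k2)
    m.add_reaction("Jprod", [], ["S"], "k1*S^2/(K+S^2)", modifiers=["S"])
    m.add_reaction("Jdeg", ["S"], [], "k2*S")

    def f(s):
        return k1 * s * s / (K + s * s) - k2 * s

    roots = [0.0]
    # bracket the two positive roots on a log-spaced scan
    scan = np.linspace(1e-3, 10.0, 4001)
    vals = f(scan)
    for i in range(len(scan) - 1):
        if vals[i] == 0.0:
            roots.append(float(scan[i]))
        elif vals[i] * vals[i + 1] < 0:
            lo, hi = scan[i], scan[i + 1]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            roots.append(0.5 * (lo + hi))
    roots = sorted(set(round(r, 12) for r in roots))
    m.metadata["roots"] = roots
    if len(roots) == 3:
        m.metadata["stable_roots"] = [roots[0], roots[2]]
        m.metadata["unstable_root"] = roots[1]
    m.revision = 0
    return m


def random_mass_action(n_species: int, n_reactions: int, seed: int = 0) -> ModelIR:
    """Connected random uni/bimolecular mass-action network.

    A boundary source feeds a spanning chain so every species is reachable;
    remaining reactions are random conversions (A -> B) or condensations
    (A + B -> C), plus a first-order sink per terminal species to keep the
    network open.  All rate constants are positive, log-uniform in
    [0.05, 0.5] under the seed.
    """
    if n_species < 2 or n_reactions < 1:
        raise KinsimError("need at least 2 species and 1 reaction")
    rng = np.random.default_rng(seed)
    m = ModelIR(id=f"random_mass_action_{n_species}_{n_reactions}_{seed}")
    m.add_compartment("default_compartment", 1.0)
    m.add_species("X0", "default_compartment", 5.0, boundary=True)
    names = [f"S{i + 1}" for i in range(n_species)]
    for name in names:
        m.add_species(name, "default_compartment", float(rng.uniform(0.5, 2.0)))

    def k():
        return float(np.exp(rng.uniform(np.log(0.05), np.log(0.5))))

    ridx = 0

    def add(reactants, products, law):
        nonlocal ridx
        ridx += 1
        m.add_parameter(f"k{ridx}", k())
        m.add_reaction(f"R{ridx}", reactants, products,
                       law.format(k=f"k{ridx}"))

    add(["X0"], [names[0]], "{k}*X0")
    # spanning chain guarantees reachability from the source
    for i in range(len(names) - 1):
        if ridx >= n_reactions:
            break
        add([names[i]], [names[i + 1]], "{k}*" + names[i])
    while ridx < n_reactions:
        kind = rng.integers(0, 3)
        if kind == 0:
            a, b = rng.choice(n_species, size=2, replace=False)
            add([names[a]], [names[b]], "{k}*" + names[a])
        elif kind == 1:
            a, b, c = rng.choice(n_species, size=3, replace=True)
            add([names[a], names[b]], [names[c]],
                "{k}*" + f"{names[a]}*{names[b]}")
        else:
            a = int(rng.integers(0, n_species))
            add([names[a]], [], "{k}*" + names[a])
    # every species decays weakly so trajectories stay bounded
    for name in names:
        ridx += 1
        m.add_parameter(f"k{ridx}", 0.1)
        m.add_reaction(f"R{ridx}", [name], [], f"k{ridx}*{name}")
    m.revision = 0
    return m


def corpus(n_models: int = 20, seed: int = 0) -> list[ModelIR]:
    """A deterministic batch of small models for multi-model loading tests."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_models):
        kind = i % 3
        if kind == 0:
            m = linear_chain(int(rng.integers(1, 5)), seed=int(rng.integers(0, 2**31)))
        elif kind == 1:
            m = random_mass_action(int(rng.integers(2, 5)),
                                   int(rng.integers(2, 6)),
                                   seed=int(rng.integers(0, 2**31)))
        else:
            m = closed_pair(float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2)))
        m.id = f"{m.id}_{i}"
        out.append(m)
    return out
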