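"""Reference models: factor processes and their products.

Every entry is a factory for a classical structured epidemic model built
*as a product* of simpler factor processes -- community-structured SI
(the Watson model), SI with demography in several communities, SIR with
compartmental aging, risk- and gender-stratified STI transmission, the
joint leprosy-tuberculosis model, a two-strain SIS model with
co-transmission, and a four-factor gonorrhea screening model together
with its family of partial products. Entries that correspond to a
printed closed-form system carry a hand-entered reference ODE system for
regression comparison via :func:`epiproducts.dynamics.compare_odes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import sympy as sp

from .core import SINK, SOURCE, CompartmentalModel, Naming
from .dynamics import ODESystem
from .products import (
    ProductRule,
    extended_cartesian,
    enumerate_partial_products,
    n_ary_product,
    strong_product,
    subscript_selector,
)

__all__ = ["ZooEntry", "registry", "build"]


# ----------------------------------------------------------------------
# factor models
# ----------------------------------------------------------------------
def si_factor() -> CompartmentalModel:
    """SI transmission with disease-induced removal:
    dS/dt = -beta*S*I, dI/dt = beta*S*I - gamma*I."""
    m = CompartmentalModel("si")
    m.add_compartment("S").add_compartment("I")
    m.add_arc("S", "I", "beta*S*I", args=["I"])
    m.add_arc("I", SINK, "gamma*I")
    return m


def community_factor(n: int = 2) -> CompartmentalModel:
    """n communities, no migration, no demographic turnover
    (dN_k/dt = 0 for all k)."""
    naming = Naming(
        explicit={(f"N{k}",): f"N{k}" for k in range(1, n + 1)},
        subscript_maps=({f"N{k}": str(k) for k in range(1, n + 1)},),
    )
    m = CompartmentalModel(f"community{n}", naming)
    for k in range(1, n + 1):
        m.add_compartment(f"N{k}")
    return m


def si_demography_factor() -> CompartmentalModel:
    """SI with constant recruitment and background mortality:
    dS/dt = Lambda - beta*S*I - mu*S, dI/dt = beta*S*I - mu*I."""
    m = CompartmentalModel("si_demography")
    m.add_compartment("S").add_compartment("I")
    m.add_arc(SOURCE, "S", "Lambda")
    m.add_arc("S", "I", "beta*S*I", args=["I"])
    m.add_arc("S", SINK, "mu*S")
    m.add_arc("I", SINK, "mu*I")
    return m


def sir_factor() -> CompartmentalModel:
    """Closed SIR: dS=-beta*S*I, dI=beta*S*I-gamma*I, dR=gamma*I."""
    m = CompartmentalModel("sir")
    for c in "SIR":
        m.add_compartment(c)
    m.add_arc("S", "I", "beta*S*I", args=["I"])
    m.add_arc("I", "R", "gamma*I")
    return m


def aging_factor(classes: int = 3) -> CompartmentalModel:
    """Compartmental aging: recruitment into the youngest class, aging at
    rate alpha (one year per year), age-specific mortality mu_k; the
    oldest class ages out to the sink."""
    naming = Naming(
        explicit={(f"A{k}",): f"A{k}" for k in range(classes)},
        subscript_maps=({f"A{k}": str(k) for k in range(classes)},),
    )
    m = CompartmentalModel(f"aging{classes}", naming)
    for k in range(classes):
        m.add_compartment(f"A{k}")
    m.add_arc(SOURCE, "A0", "Lambda")
    for k in range(classes):
        nxt = f"A{k + 1}" if k + 1 < classes else SINK
        m.add_arc(f"A{k}", nxt, f"alpha*A{k}")
        m.add_arc(f"A{k}", SINK, f"mu_{k}*A{k}")
    return m


def sti_factor(recovery_to: str | None = None) -> CompartmentalModel:
    """STI transmission in one population with partner-acquisition rate c
    and partner-choice probability p (p = 1 in the single-population
    factor; differentiated in products):
    dS = Lambda - beta*c*p*S*I/N - mu*S [+ gamma*I if SIS],
    dI = beta*c*p*S*I/N - gamma*I - mu*I.
    ``recovery_to="S"`` gives the SIS form; the default removes
    recovered individuals (SI with disease mortality)."""
    m = CompartmentalModel("sis" if recovery_to else "si_sti")
    m.add_compartment("S").add_compartment("I")
    m.define_aggregate("N", ["S", "I"])
    m.add_arc(SOURCE, "S", "Lambda")
    m.add_arc("S", "I", "beta*c*p*S*I/N", args=["I"])
    if recovery_to:
        m.add_arc("I", recovery_to, "gamma*I")
    else:
        m.add_arc("I", SINK, "gamma*I")
    m.add_arc("S", SINK, "mu*S")
    m.add_arc("I", SINK, "mu*I")
    return m


def risk_factor() -> CompartmentalModel:
    """High-activity (A) and low-activity (B) groups with movement
    between them: dA = -rho*A + sigma*B, dB = rho*A - sigma*B."""
    m = CompartmentalModel("risk")
    m.add_compartment("A").add_compartment("B")
    m.add_arc("A", "B", "rho*A")
    m.add_arc("B", "A", "sigma*B")
    return m


def risk3_factor() -> CompartmentalModel:
    """Three activity groups -- low (L), partial (P), high (H) -- with
    two-way movement along the chain."""
    m = CompartmentalModel("risk3")
    for c in "LPH":
        m.add_compartment(c)
    m.add_arc("L", "P", "rho_1*L")
    m.add_arc("P", "L", "sigma_1*P")
    m.add_arc("P", "H", "rho_2*P")
    m.add_arc("H", "P", "sigma_2*H")
    return m


def gender_factor() -> CompartmentalModel:
    """Static female/male partition: dF/dt = dM/dt = 0."""
    m = CompartmentalModel("gender")
    m.add_compartment("F").add_compartment("M")
    return m


def exposure_factor() -> CompartmentalModel:
    """Groups unexposed (U) and exposed (E) to a control measure such as
    frequent screening, with enrollment rate eta and drop-out delta."""
    m = CompartmentalModel("exposure")
    m.add_compartment("U").add_compartment("E")
    m.add_arc("U", "E", "eta*U")
    m.add_arc("E", "U", "delta*E")
    return m


def tb_factor() -> CompartmentalModel:
    """Tuberculosis natural history: susceptible X, latent L, active T;
    a fraction p of new infections progress rapidly to active disease,
    latent infection reactivates at rate nu."""
    m = CompartmentalModel("tb")
    for c in ("X", "L", "T"):
        m.add_compartment(c)
    m.add_arc(SOURCE, "X", "Lambda")
    m.add_arc("X", "L", "(1-p)*beta*X*T", args=["T"])
    m.add_arc("X", "T", "p*beta*X*T", args=["T"])
    m.add_arc("L", "T", "nu*L")
    m.add_arc("X", SINK, "mu*X")
    m.add_arc("L", SINK, "mu*L")
    m.add_arc("T", SINK, "mu*T")
    return m


def leprosy_factor() -> CompartmentalModel:
    """Leprosy natural history: susceptible U, latent W, paucibacillary P
    and multibacillary M disease; transmission coefficients b (from P)
    and c (from M), progression rates theta and phi."""
    m = CompartmentalModel("leprosy")
    for c in ("U", "W", "P", "M"):
        m.add_compartment(c)
    m.add_arc("U", "W", "(b*P + c*M)*U", args=["P", "M"])
    m.add_arc("W", "P", "theta*W")
    m.add_arc("W", "M", "phi*W")
    return m


def sis_closed_factor() -> CompartmentalModel:
    """Closed single-strain SIS with frequency-dependent transmission:
    dS = -beta*S*I/N + gamma*I, dI = beta*S*I/N - gamma*I, N = S + I."""
    m = CompartmentalModel("sis_closed")
    m.add_compartment("S").add_compartment("I")
    m.define_aggregate("N", ["S", "I"])
    m.add_arc("S", "I", "beta*S*I/N", args=["I"])
    m.add_arc("I", "S", "gamma*I")
    return m


# ----------------------------------------------------------------------
# product builders
# ----------------------------------------------------------------------
def _si_reference() -> ODESystem:
    S, I, beta, gamma = sp.symbols("S I beta gamma")
    return ODESystem(("S", "I"), {"S": -beta * S * I, "I": beta * S * I - gamma * I})


def _watson(n: int = 2) -> CompartmentalModel:
    return extended_cartesian(si_factor(), community_factor(n))


def _watson_reference(n: int = 2) -> ODESystem:
    S = [sp.Symbol(f"S_{i}") for i in range(1, n + 1)]
    I = [sp.Symbol(f"I_{i}") for i in range(1, n + 1)]
    beta = {(i, j): sp.Symbol(f"beta_{i}{j}") for i in range(1, n + 1)
            for j in range(1, n + 1)}
    gamma = [sp.Symbol(f"gamma_{i}") for i in range(1, n + 1)]
    rhs = {}
    for i in range(n):
        force = sp.Add(*[beta[(i + 1, j + 1)] * S[i] * I[j] for j in range(n)])
        rhs[S[i].name] = -force
        rhs[I[i].name] = force - gamma[i] * I[i]
    states = tuple([s.name for s in S] + [x.name for x in I])
    return ODESystem(states, rhs)


def _si_demography(n: int = 2) -> CompartmentalModel:
    return extended_cartesian(si_demography_factor(), community_factor(n))


def _si_demography_reference(n: int = 2) -> ODESystem:
    rhs = {}
    states = []
    for i in range(1, n + 1):
        Si, Ii = sp.Symbol(f"S_{i}"), sp.Symbol(f"I_{i}")
        force = sp.Add(*[
            sp.Symbol(f"beta_{i}{j}") * Si * sp.Symbol(f"I_{j}")
            for j in range(1, n + 1)
        ])
        rhs[Si.name] = sp.Symbol(f"Lambda_{i}") - force - sp.Symbol(f"mu_{i}") * Si
        rhs[Ii.name] = force - sp.Symbol(f"mu_{i}") * Ii
        states += [Si.name, Ii.name]
    return ODESystem(tuple(states), rhs)


def _sir_age(classes: int = 3) -> CompartmentalModel:
    return extended_cartesian(sir_factor(), aging_factor(classes))


def _risk_sti() -> CompartmentalModel:
    return extended_cartesian(sti_factor(), risk_factor())


_GENDER_RULE = ProductRule(
    parameter_policy=subscript_selector({"beta": (0,), "c": (0,)})
)

_HETERO_BINDINGS = {"p_FF": 0, "p_MM": 0, "p_FM": 1, "p_MF": 1}


def _gender_sti(heterosexual: bool = True) -> CompartmentalModel:
    prod = extended_cartesian(
        sti_factor(recovery_to="S"), gender_factor(), rule=_GENDER_RULE
    )
    if heterosexual:
        prod = prod.substitute(_HETERO_BINDINGS)
    return prod


def _gender_sti_reference() -> ODESystem:
    rhs = {}
    states = []
    aggs = {}
    for g, o in (("F", "M"), ("M", "F")):
        Sg, Ig = sp.Symbol(f"S_{g}"), sp.Symbol(f"I_{g}")
        Io, No = sp.Symbol(f"I_{o}"), sp.Symbol(f"N_{o}")
        force = sp.Symbol(f"beta_{g}") * sp.Symbol(f"c_{g}") * Io / No * Sg
        lam, mu, gam = (sp.Symbol(f"{p}_{g}") for p in ("Lambda", "mu", "gamma"))
        rhs[Sg.name] = lam - force - mu * Sg + gam * Ig
        rhs[Ig.name] = force - mu * Ig - gam * Ig
        states += [Sg.name, Ig.name]
        aggs[f"N_{g}"] = (f"S_{g}", f"I_{g}")
    return ODESystem(tuple(states), rhs, aggs)


def _leprosy_tb() -> CompartmentalModel:
    """Joint leprosy-tuberculosis product with free cross-immunity
    multipliers: each transmission arc whose source is not fully
    susceptible to the *other* disease is scaled by chi_<level> (TB
    transmission modified by leprosy state) or xi_<level> (leprosy
    transmission modified by TB state)."""
    prod = extended_cartesian(tb_factor(), leprosy_factor())
    susceptible_other = {0: ("U",), 1: ("X",)}  # factor index -> naive level
    for arc in prod.arcs:
        for prov in arc.provenance:
            fi = prov.factor_arcs[0][0]
            if not prov.assignment:
                continue  # not a transmission arc
            other_level = prov.anchor[1 - fi]
            if (other_level,) == (susceptible_other[fi][0],):
                continue
            base = "chi" if fi == 0 else "xi"
            arc.rate = arc.rate * sp.Symbol(f"{base}_{other_level}")
    return prod


def _transmission_only(members) -> bool:
    return all(m.arc.args for m in members)


def _two_strain_sis() -> CompartmentalModel:
    naming = Naming(explicit={
        ("S", "S"): "S", ("I", "S"): "I_1",
        ("S", "I"): "I_2", ("I", "I"): "I_12",
    })
    rule = ProductRule(
        simultaneous_set_policy=_transmission_only,
        aggregate_scope="global",
    )
    return strong_product(sis_closed_factor(), sis_closed_factor(),
                          rule=rule, naming=naming)


_GONORRHEA_RULE = ProductRule(
    # level tuple of a transmission arc: (a,b,c, d,e,f) = exposure, gender,
    # risk of the susceptible, then of the infective
    parameter_policy=subscript_selector({
        "beta": (1, 4),       # gender pair
        "c": (1, 2),          # susceptible's gender and risk
        "p": (1, 2, 4, 5),    # both sides' gender and risk
        "gamma": (0,),        # removal rate depends on screening exposure
    })
)


def _gonorrhea_factors(risk3: bool = False):
    return [
        sti_factor(recovery_to="S"),
        exposure_factor(),
        gender_factor(),
        risk3_factor() if risk3 else risk_factor(),
    ]


def _gonorrhea_full() -> CompartmentalModel:
    return n_ary_product(_gonorrhea_factors(), rule=_GONORRHEA_RULE)


def _gonorrhea_partials() -> list[CompartmentalModel]:
    base, *factors = _gonorrhea_factors()
    return enumerate_partial_products(base, factors)


def _gonorrhea_risk3() -> CompartmentalModel:
    return n_ary_product(_gonorrhea_factors(risk3=True), rule=_GONORRHEA_RULE)


# ----------------------------------------------------------------------
# registry
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ZooEntry:
    """A named reference model: builder, factor builders, and (where a
    closed-form system exists) a reference ODE builder."""

    name: str
    summary: str
    builder: Callable[..., object]
    factors: Callable[..., list[CompartmentalModel]] | None = None
    reference: Callable[..., ODESystem] | None = None


_ENTRIES: list[ZooEntry] = [
    ZooEntry("si", "single-population SI model with disease-induced removal",
             si_factor, reference=_si_reference),
    ZooEntry("watson", "multi-community SI (Watson) model with "
             "cross-community transmission coefficients beta_ij",
             _watson,
             factors=lambda n=2: [si_factor(), community_factor(n)],
             reference=_watson_reference),
    ZooEntry("si_demography", "SI with recruitment and mortality in "
             "multiple communities",
             _si_demography,
             factors=lambda n=2: [si_demography_factor(), community_factor(n)],
             reference=_si_demography_reference),
    ZooEntry("sir_age", "SIR crossed with compartmental aging, including "
             "vertical-transmission (Lambda_I) and immune-at-birth "
             "(Lambda_R) inflows",
             _sir_age,
             factors=lambda classes=3: [sir_factor(), aging_factor(classes)]),
    ZooEntry("risk_sti", "STI transmission with a high-activity core group",
             _risk_sti,
             factors=lambda: [sti_factor(), risk_factor()]),
    ZooEntry("gender_sti", "heterosexual STI model: SIS crossed with a "
             "static gender partition, same-gender partner probabilities "
             "set to zero",
             _gender_sti,
             factors=lambda: [sti_factor(recovery_to="S"), gender_factor()],
             reference=_gender_sti_reference),
    ZooEntry("tb", "tuberculosis natural history (susceptible/latent/active)",
             tb_factor),
    ZooEntry("leprosy", "leprosy natural history (susceptible/latent/"
             "paucibacillary/multibacillary)",
             leprosy_factor),
    ZooEntry("leprosy_tb", "joint leprosy-tuberculosis product with free "
             "cross-immunity multipliers",
             _leprosy_tb,
             factors=lambda: [tb_factor(), leprosy_factor()]),
    ZooEntry("two_strain_sis", "two-strain SIS strong product with "
             "co-transmission arcs",
             _two_strain_sis,
             factors=lambda: [sis_closed_factor(), sis_closed_factor()]),
    ZooEntry("gonorrhea_full", "four-factor gonorrhea screening model "
             "(SIS x exposure x gender x risk)",
             _gonorrhea_full,
             factors=_gonorrhea_factors),
    ZooEntry("gonorrhea_partials", "family of partial products over the "
             "gonorrhea model's optional factors (returns a list)",
             _gonorrhea_partials,
             factors=_gonorrhea_factors),
    ZooEntry("gonorrhea_risk3", "gonorrhea model with three risk groups",
             _gonorrhea_risk3,
             factors=lambda: _gonorrhea_factors(risk3=True)),
]


def registry() -> list[ZooEntry]:
    """All zoo entries, in a stable order."""
    return list(_ENTRIES)


def build(name: str, **options):
    """Build a zoo model by name.

    ``build("watson", n=3)`` etc.; unknown names raise with the list of
    available entries. ``gonorrhea_partials`` returns a list of models.
    """
    for entry in _ENTRIES:
        if entry.name == name:
            return entry.builder(**options)
    known = ", ".join(e.name for e in _ENTRIES)
    raise KeyError(f"unknown zoo model {name!r}; available: {known}")
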