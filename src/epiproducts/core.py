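"""Compartmental models as labeled directed multigraphs.

A :class:`CompartmentalModel` is a directed multigraph whose vertices are
compartments (counts of individuals in a state) and whose arcs are
transitions labeled with symbolic rates. Two distinguished
pseudo-compartments, :data:`SOURCE` and :data:`SINK`, carry recruitment
inflows and removal/mortality outflows; they are per-model sentinels, not
ordinary vertices, and never appear in product label tuples.

Compartment identity is the ordered tuple of level labels -- length 1 for
an atomic model, one entry per factor for a product. Display names such as
``S_1`` or ``I_FAU`` are derived from the tuple by the model's naming
convention and are presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Union

import sympy as sp

from .rates import (
    ExprLike,
    RateTerm,
    as_expr,
    bind_aggregates,
    render_subscripts,
    substitute,
)

__all__ = [
    "SOURCE",
    "SINK",
    "Labels",
    "Compartment",
    "Arc",
    "Provenance",
    "Naming",
    "CompartmentalModel",
    "DuplicateCompartmentError",
    "UnknownCompartmentError",
    "as_labels",
]


class _Terminal:
    """Sentinel pseudo-compartment (recruitment source / removal sink)."""

    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def __repr__(self) -> str:
        return self.name

    def __deepcopy__(self, memo):  # sentinels stay singletons
        return self


SOURCE = _Terminal("SOURCE")
SINK = _Terminal("SINK")

Labels = tuple[str, ...]
Endpoint = Union[Labels, _Terminal]


class DuplicateCompartmentError(ValueError):
    pass


class UnknownCompartmentError(KeyError):
    pass


def as_labels(value) -> Labels:
    """Coerce a compartment reference to its label tuple."""
    if isinstance(value, Compartment):
        return value.labels
    if isinstance(value, str):
        return (value,)
    return tuple(str(v) for v in value)


@dataclass(frozen=True)
class Compartment:
    """A model state, identified by its ordered tuple of level labels."""

    labels: Labels


@dataclass(frozen=True)
class Provenance:
    """Record of the factor arc(s) and level assignment that generated a
    product arc: which ``(factor index, arc index)`` pairs fired, the
    level-carrying compartment the arc was anchored at, and the chosen
    interaction-argument compartments."""

    factor_arcs: tuple[tuple[int, int], ...]
    anchor: Labels
    assignment: tuple[Labels, ...] = ()


@dataclass
class Arc:
    """A transition with a symbolic total rate.

    ``args`` lists the interaction arguments of the rate -- the
    compartments, other than the source, whose occupancy the rate depends
    on (the infective compartment of a transmission term). Their order is
    significant: it fixes the subscript order of product parameters.
    """

    source: Endpoint
    target: Endpoint
    rate: sp.Expr
    args: tuple[Labels, ...] = ()
    provenance: tuple[Provenance, ...] = ()


@dataclass
class Naming:
    """Display-name convention: per-position subscript tokens plus
    optional explicit names for whole tuples.

    The default renders ``("S",)`` as ``S`` and ``("S", "N1")`` as ``S_1``
    (community compartment ``N1`` contributes subscript token ``1``).
    """

    explicit: dict[Labels, str] = field(default_factory=dict)
    subscript_maps: tuple[Mapping[str, str], ...] = ()

    def token(self, position: int, label: str) -> str:
        if position < len(self.subscript_maps):
            return self.subscript_maps[position].get(label, label)
        return label

    def name(self, labels: Labels) -> str:
        if labels in self.explicit:
            return self.explicit[labels]
        tokens = [self.token(i, lab) for i, lab in enumerate(labels)]
        if len(tokens) == 1:
            return tokens[0]
        return tokens[0] + "_" + render_subscripts(tokens[1:])


class CompartmentalModel:
    """Directed multigraph of compartments with symbolic arc rates."""

    def __init__(self, name: str = "model", naming: Naming | None = None):
        self.name = name
        self.naming = naming if naming is not None else Naming()
        self._compartments: dict[Labels, Compartment] = {}
        self.arcs: list[Arc] = []
        self.aggregates: dict[str, tuple[Labels, ...]] = {}

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    def add_compartment(self, labels) -> "CompartmentalModel":
        labels = as_labels(labels)
        if labels in self._compartments:
            raise DuplicateCompartmentError(
                f"compartment {labels!r} already present in model {self.name!r}"
            )
        self._compartments[labels] = Compartment(labels)
        return self

    def add_arc(self, source, target, rate: ExprLike, args=None,
                provenance: tuple[Provenance, ...] = ()) -> "CompartmentalModel":
        src: Endpoint = source if isinstance(source, _Terminal) else as_labels(source)
        tgt: Endpoint = target if isinstance(target, _Terminal) else as_labels(target)
        if src is SINK:
            raise ValueError("an arc cannot originate at SINK")
        if tgt is SOURCE:
            raise ValueError("an arc cannot point to SOURCE")
        for end in (src, tgt):
            if not isinstance(end, _Terminal) and end not in self._compartments:
                raise UnknownCompartmentError(
                    f"arc endpoint {end!r} is not a compartment of {self.name!r}"
                )
        expr = as_expr(rate)
        if args is None:
            arg_tuple = self._infer_args(src, expr)
        else:
            arg_tuple = tuple(as_labels(a) for a in args)
            for a in arg_tuple:
                if a not in self._compartments:
                    raise UnknownCompartmentError(
                        f"rate of arc {src!r} -> {tgt!r} references unknown "
                        f"compartment {self.naming.name(a)!r}"
                    )
        self.arcs.append(Arc(src, tgt, expr, arg_tuple, tuple(provenance)))
        return self

    def define_aggregate(self, name: str, members: Iterable) -> "CompartmentalModel":
        mems = tuple(as_labels(m) for m in members)
        for m in mems:
            if m not in self._compartments:
                raise UnknownCompartmentError(
                    f"aggregate {name!r} references unknown compartment {m!r}"
                )
        if name in self.aggregates and self.aggregates[name] != mems:
            raise ValueError(f"aggregate {name!r} redefined with a different scope")
        self.aggregates[name] = mems
        return self

    def _infer_args(self, source: Endpoint, expr: sp.Expr) -> tuple[Labels, ...]:
        """Interaction arguments default to the state symbols in the rate
        other than the source, in display-name order."""
        by_name = {self.display_name(c): c for c in self._compartments}
        src_name = None if isinstance(source, _Terminal) else self.display_name(source)
        found = sorted(
            s.name for s in expr.free_symbols
            if s.name in by_name and s.name != src_name
        )
        return tuple(by_name[n] for n in found)

    # ------------------------------------------------------------------
    # inspection
    # ------------------------------------------------------------------
    @property
    def compartments(self) -> tuple[Compartment, ...]:
        return tuple(self._compartments.values())

    def labels(self) -> list[Labels]:
        return list(self._compartments)

    def __contains__(self, labels) -> bool:
        return as_labels(labels) in self._compartments

    def __len__(self) -> int:
        return len(self._compartments)

    @property
    def label_width(self) -> int:
        if not self._compartments:
            return 0
        return len(next(iter(self._compartments)))

    def display_name(self, labels) -> str:
        return self.naming.name(as_labels(labels))

    def symbol(self, labels) -> sp.Symbol:
        return sp.Symbol(self.display_name(labels))

    def state_names(self) -> list[str]:
        return [self.display_name(c) for c in self._compartments]

    def aggregate_name_defs(self) -> dict[str, tuple[str, ...]]:
        """Aggregate definitions keyed/valued by display names."""
        return {
            name: tuple(self.display_name(m) for m in members)
            for name, members in self.aggregates.items()
        }

    def rate_term(self, arc: Arc) -> RateTerm:
        return RateTerm.classify(arc.rate, self.state_names(), self.aggregates)

    @property
    def is_closed(self) -> bool:
        """No recruitment or removal flows: mass is conserved."""
        return not any(
            isinstance(a.source, _Terminal) or isinstance(a.target, _Terminal)
            for a in self.arcs
        )

    def parameters(self) -> set[sp.Symbol]:
        out: set[sp.Symbol] = set()
        for arc in self.arcs:
            out |= set(self.rate_term(arc).parameters)
        return out

    def net_flow(self, labels) -> sp.Expr:
        """Symbolic inflow-minus-outflow for one compartment."""
        labels = as_labels(labels)
        total = sp.Integer(0)
        for arc in self.arcs:
            if arc.target == labels:
                total += arc.rate
            if arc.source == labels:
                total -= arc.rate
        return total

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> list[str]:
        """Diagnostics, one per invariant violation; empty iff well formed."""
        diags: list[str] = []
        widths = {len(c) for c in self._compartments}
        if len(widths) > 1:
            diags.append(f"mixed label-tuple widths {sorted(widths)}")
        names: dict[str, Labels] = {}
        for c in self._compartments:
            n = self.display_name(c)
            if n in names:
                diags.append(f"display name {n!r} used by both {names[n]!r} and {c!r}")
            names[n] = c
        for i, arc in enumerate(self.arcs):
            if arc.source is SINK:
                diags.append(f"arc {i}: source is SINK")
            if arc.target is SOURCE:
                diags.append(f"arc {i}: target is SOURCE")
            for end in (arc.source, arc.target):
                if not isinstance(end, _Terminal) and end not in self._compartments:
                    diags.append(f"arc {i}: endpoint {end!r} is not a compartment")
            for a in arc.args:
                if a not in self._compartments:
                    diags.append(
                        f"arc {i}: rate references unknown compartment {a!r}"
                    )
            if not isinstance(arc.rate, sp.Expr):
                diags.append(f"arc {i}: rate is not a symbolic expression")
        for name, members in self.aggregates.items():
            for m in members:
                if m not in self._compartments:
                    diags.append(
                        f"aggregate {name!r}: unknown compartment {m!r}"
                    )
        return diags

    # ------------------------------------------------------------------
    # canonicalization
    # ------------------------------------------------------------------
    @staticmethod
    def _endpoint_key(end: Endpoint):
        if end is SOURCE:
            return (0, ())
        if isinstance(end, _Terminal):
            return (2, ())
        return (1, end)

    def _arc_key(self, arc: Arc):
        return (
            self._endpoint_key(arc.source),
            self._endpoint_key(arc.target),
            sp.srepr(arc.rate),
            arc.args,
        )

    def _shell(self, name_suffix: str = "") -> "CompartmentalModel":
        out = CompartmentalModel(self.name + name_suffix, self.naming)
        return out

    def canonicalize(self) -> "CompartmentalModel":
        """Deterministic form: compartments and arcs in lexicographic order.

        Two models built by permuted insertion orders canonicalize
        identically.
        """
        out = self._shell()
        for labels in sorted(self._compartments):
            out.add_compartment(labels)
        for name in sorted(self.aggregates):
            out.define_aggregate(name, self.aggregates[name])
        for arc in sorted(self.arcs, key=self._arc_key):
            out.arcs.append(replace(arc))
        return out

    def structurally_equal(self, other: "CompartmentalModel") -> bool:
        a, b = self.canonicalize(), other.canonicalize()
        if a.labels() != b.labels() or a.aggregates != b.aggregates:
            return False
        if len(a.arcs) != len(b.arcs):
            return False
        return all(
            a._arc_key(x) == b._arc_key(y) for x, y in zip(a.arcs, b.arcs)
        )

    def aggregate_parallel_arcs(self) -> "CompartmentalModel":
        """Canonical single-arc form: parallel arcs between one ordered
        pair of endpoints are replaced by one arc whose rate is the
        symbolic sum; provenance records are merged. Idempotent, and
        preserves every compartment's net flow."""
        out = self._shell()
        for labels in self._compartments:
            out.add_compartment(labels)
        for name, members in self.aggregates.items():
            out.define_aggregate(name, members)
        groups: dict[tuple, list[Arc]] = {}
        order: list[tuple] = []
        for arc in self.arcs:
            key = (self._endpoint_key(arc.source), self._endpoint_key(arc.target))
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(arc)
        for key in order:
            members = groups[key]
            rate = sp.Add(*[a.rate for a in members])
            args: list[Labels] = []
            prov: list[Provenance] = []
            for a in members:
                for z in a.args:
                    if z not in args:
                        args.append(z)
                prov.extend(a.provenance)
            out.arcs.append(
                Arc(members[0].source, members[0].target, rate, tuple(args), tuple(prov))
            )
        return out

    # ------------------------------------------------------------------
    # transformation
    # ------------------------------------------------------------------
    def substitute(self, bindings: Mapping, drop_zero: bool = True) -> "CompartmentalModel":
        """Apply symbol bindings to every arc rate.

        Arcs whose rate simplifies to zero are pruned (canonicalization;
        the generated structure itself is never altered by bindings).
        """
        out = self._shell()
        for labels in self._compartments:
            out.add_compartment(labels)
        for name, members in self.aggregates.items():
            out.define_aggregate(name, members)
        states = self.state_names()
        for arc in self.arcs:
            new_rate = sp.expand(substitute(arc.rate, bindings, states))
            if drop_zero and new_rate == 0:
                continue
            out.arcs.append(replace(arc, rate=new_rate))
        return out

    def copy(self) -> "CompartmentalModel":
        out = self._shell()
        for labels in self._compartments:
            out.add_compartment(labels)
        for name, members in self.aggregates.items():
            out.define_aggregate(name, members)
        for arc in self.arcs:
            out.arcs.append(replace(arc))
        return out

    def bind_rate(self, arc: Arc) -> sp.Expr:
        """Arc rate with aggregate symbols expanded into state sums."""
        return bind_aggregates(
            arc.rate, self.aggregate_name_defs(), declared=self.aggregates
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CompartmentalModel {self.name!r}: "
            f"{len(self)} compartments, {len(self.arcs)} arcs>"
        )
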