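"""Product operations on directed graphs and compartmental models.

Four related constructions are provided:

* :func:`graph_cartesian` / :func:`graph_strong` -- the classical
  Cartesian and strong products of finite directed multigraphs;
* :func:`linear_cartesian` -- the Cartesian product of *linear*
  compartmental models (constant inflows, per-capita transition rates,
  no interaction terms), in which every factor transition is replicated
  at every level of the other factor with its rate parameter subscripted
  by that level;
* :func:`extended_cartesian` -- the extension to interacting
  (epidemic) models: a transmission rate ``f(X_s, Z_1, ..., Z_k)``
  generates one product arc per choice of descendants of its interaction
  arguments, *independently* of the source's level, which is what creates
  cross-level transmission terms such as ``beta_12 * S_1 * I_2``;
* :func:`strong_product` -- adds diagonal arcs representing simultaneous
  occurrence of transitions from distinct factors (co-transmission of two
  pathogen strains in a single encounter).

All compartmental products run through one n-ary engine;
:func:`n_ary_product` composes any number of factors directly (label
tuples are flat, never nested), and
:func:`enumerate_partial_products` generates the model family over all
subsets of optional factors for structural sensitivity analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import sympy as sp

from .core import (
    SINK,
    SOURCE,
    Arc,
    CompartmentalModel,
    Labels,
    Naming,
    Provenance,
    _Terminal,
)
from .rates import ParameterSymbol, render_subscripts

__all__ = [
    "ProductRule",
    "ProductArcContext",
    "CombinedArcContext",
    "NonlinearModelError",
    "graph_cartesian",
    "graph_strong",
    "linear_cartesian",
    "extended_cartesian",
    "strong_product",
    "n_ary_product",
    "enumerate_partial_products",
    "subscript_selector",
    "is_isomorphic",
]


class NonlinearModelError(ValueError):
    """A factor is outside the linear class handled by linear_cartesian."""


# ----------------------------------------------------------------------
# graph products
# ----------------------------------------------------------------------
def graph_cartesian(A: nx.MultiDiGraph, B: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Cartesian product of directed multigraphs.

    Vertices are ordered pairs ``(v, w)``; every arc of one factor is
    replicated at every vertex (level) of the other, so
    ``|arcs| = n_A * m_B + n_B * m_A``.
    """
    P = nx.MultiDiGraph()
    P.add_nodes_from((v, w) for v in A.nodes for w in B.nodes)
    for vs, vt, _ in A.edges(keys=True):
        for w in B.nodes:
            P.add_edge((vs, w), (vt, w))
    for ws, wt, _ in B.edges(keys=True):
        for v in A.nodes:
            P.add_edge((v, ws), (v, wt))
    return P


def graph_strong(A: nx.MultiDiGraph, B: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Strong product: the Cartesian arcs plus one diagonal arc
    ``(v_s, w_s) -> (v_t, w_t)`` for every pair of factor arcs."""
    P = graph_cartesian(A, B)
    for vs, vt, _ in A.edges(keys=True):
        for ws, wt, _ in B.edges(keys=True):
            P.add_edge((vs, ws), (vt, wt))
    return P


# ----------------------------------------------------------------------
# product rules
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ProductArcContext:
    """Everything a rule needs to know about one candidate product arc
    generated from a single factor transition."""

    factor_index: int
    arc_index: int
    arc: Arc
    source: object            # product source: labels or SOURCE
    target: object            # product target: labels or SINK
    anchor: Labels            # the level-carrying compartment
    assignment: tuple[Labels, ...]
    source_tokens: tuple[str, ...]
    arg_tokens: tuple[tuple[str, ...], ...]

    @property
    def levels(self) -> tuple[str, ...]:
        """Subscript tokens in the conventional order: the source's levels
        first, then each interaction argument's levels in argument order."""
        out = list(self.source_tokens)
        for toks in self.arg_tokens:
            out.extend(toks)
        return tuple(out)


@dataclass(frozen=True)
class CombinedArcContext:
    """Context for a diagonal (simultaneous-transition) arc of a strong
    product: one transition from each of several distinct factors."""

    members: tuple[ProductArcContext, ...]
    source: Labels
    target: Labels
    assignment: tuple[Labels, ...]
    source_tokens: tuple[str, ...]
    arg_tokens: tuple[tuple[str, ...], ...]
    aggregate_symbols: tuple[sp.Symbol, ...]

    @property
    def factor_indices(self) -> tuple[int, ...]:
        return tuple(m.factor_index for m in self.members)


def default_parameter_policy(param: sp.Symbol, ctx: ProductArcContext) -> sp.Expr:
    """Subscript every parameter with the full level tuple of the arc."""
    if not ctx.levels:
        return param
    return ParameterSymbol(param.name, ctx.levels).symbol


def subscript_selector(index_map: Mapping[str, Sequence[int]]):
    """Parameter policy choosing, per parameter base, which positions of
    the level tuple become subscripts.

    ``{"beta": (1, 4)}`` reproduces rate shapes like ``beta_be`` in a
    four-factor product where the full level tuple is ``(a,b,c,d,e,f)``.
    Bases not listed get the full default subscript; an empty sequence
    leaves the parameter undifferentiated. Out-of-range indices are
    ignored (they refer to levels a smaller product does not have).
    """

    def policy(param: sp.Symbol, ctx: ProductArcContext) -> sp.Expr:
        if param.name not in index_map:
            return default_parameter_policy(param, ctx)
        idx = [i for i in index_map[param.name] if i < len(ctx.levels)]
        levels = tuple(ctx.levels[i] for i in idx)
        if not levels:
            return param
        return ParameterSymbol(param.name, levels).symbol

    return policy


def default_simultaneous_policy(members: tuple[ProductArcContext, ...]) -> bool:
    """Admit every cross-factor set of ordinary transitions."""
    return True


@dataclass(frozen=True)
class ProductRule:
    """User policy refining a product's rates and arc set.

    * ``parameter_policy(param, ctx)`` maps each factor-rate parameter to
      its product form (default: subscript by the full level tuple);
    * ``inclusion_predicate(ctx)`` decides whether a candidate arc is
      kept (default: keep all);
    * ``simultaneous_set_policy(members)`` admits or rejects a set of
      factor transitions firing together in a strong product (default:
      all cross-factor sets of ordinary transitions);
    * ``combined_rate(ctx)`` builds the rate of an admitted simultaneous
      arc (default: fresh bracketed parameter, see
      :func:`strong_product`);
    * ``aggregate_scope`` is ``"argument"`` (rescope an aggregate to the
      level of the arc's first interaction argument, giving per-group
      population sizes such as ``N_M``), ``"global"`` (sum over all
      descendants -- appropriate when both factors classify the same
      population, as in a multistrain model), or a per-base mapping.

    The defaults reproduce the plain extended Cartesian and strong
    product definitions.
    """

    parameter_policy: Callable[[sp.Symbol, ProductArcContext], sp.Expr] | None = None
    inclusion_predicate: Callable[[ProductArcContext], bool] | None = None
    simultaneous_set_policy: Callable[[tuple[ProductArcContext, ...]], bool] | None = None
    combined_rate: Callable[[CombinedArcContext], sp.Expr] | None = None
    aggregate_scope: Mapping[str, str] | str = "argument"

    def scope_for(self, aggregate_base: str) -> str:
        if isinstance(self.aggregate_scope, str):
            return self.aggregate_scope
        return self.aggregate_scope.get(aggregate_base, "argument")


# ----------------------------------------------------------------------
# the n-ary product engine
# ----------------------------------------------------------------------
class _Engine:
    def __init__(self, factors: Sequence[CompartmentalModel], rule: ProductRule,
                 naming: Naming | None):
        if not factors:
            raise ValueError("a product needs at least one factor")
        for f in factors:
            if len(f) == 0:
                raise ValueError(f"factor {f.name!r} has no compartments")
            diags = f.validate()
            if diags:
                raise ValueError(f"factor {f.name!r} is invalid: {diags[0]}")
        self.factors = list(factors)
        self.rule = rule
        self.widths = [f.label_width for f in factors]
        self.starts = [sum(self.widths[:i]) for i in range(len(factors))]
        if naming is None:
            maps: list[Mapping[str, str]] = []
            for f in self.factors:
                fmaps = list(f.naming.subscript_maps[: f.label_width])
                fmaps += [{}] * (f.label_width - len(fmaps))
                maps.extend(fmaps)
            naming = Naming(subscript_maps=tuple(maps))
        name = " x ".join(f.name for f in factors)
        self.product = CompartmentalModel(name, naming)
        for combo in itertools.product(*[f.labels() for f in factors]):
            self.product.add_compartment(tuple(itertools.chain.from_iterable(combo)))
        self.all_labels = self.product.labels()

    # -- coordinate helpers -------------------------------------------
    def slice_of(self, labels: Labels, fi: int) -> Labels:
        s = self.starts[fi]
        return labels[s: s + self.widths[fi]]

    def descendants(self, fi: int, factor_labels: Labels) -> list[Labels]:
        return [p for p in self.all_labels if self.slice_of(p, fi) == factor_labels]

    def other_positions(self, own: set[int]) -> list[int]:
        out = []
        for fi in range(len(self.factors)):
            if fi in own:
                continue
            out.extend(range(self.starts[fi], self.starts[fi] + self.widths[fi]))
        return out

    def tokens_at(self, labels: Labels, positions: Iterable[int]) -> tuple[str, ...]:
        nm = self.product.naming
        return tuple(nm.token(p, labels[p]) for p in positions)

    def replace_slice(self, labels: Labels, fi: int, new: Labels) -> Labels:
        s = self.starts[fi]
        return labels[:s] + new + labels[s + self.widths[fi]:]

    # -- aggregate handling -------------------------------------------
    def map_aggregate(self, fi: int, name: str, anchor: Labels,
                      other: list[int]) -> sp.Symbol:
        """Create (or reuse) the product-level aggregate corresponding to
        a factor aggregate, scoped per the rule, and return its symbol."""
        factor = self.factors[fi]
        scope = factor.aggregates[name]
        if self.rule.scope_for(name) == "global":
            members = [p for p in self.all_labels if self.slice_of(p, fi) in scope]
            agg_name = name
        else:
            anchor_other = tuple(anchor[p] for p in other)
            members = [
                p for p in self.all_labels
                if self.slice_of(p, fi) in scope
                and tuple(p[i] for i in other) == anchor_other
            ]
            toks = self.tokens_at(anchor, other)
            sub = render_subscripts(toks)
            agg_name = f"{name}_{sub}" if sub else name
        self.product.define_aggregate(agg_name, members)
        return sp.Symbol(agg_name)

    # -- singleton (Cartesian) arcs -----------------------------------
    def singleton_arcs(self) -> None:
        for fi, factor in enumerate(self.factors):
            own = {fi}
            other = self.other_positions(own)
            for ai, arc in enumerate(factor.arcs):
                self._replicate(fi, ai, arc, other)

    def _replicate(self, fi: int, ai: int, arc: Arc, other: list[int]) -> None:
        factor = self.factors[fi]
        if arc.source is SOURCE:
            anchors = self.descendants(fi, arc.target)  # type: ignore[arg-type]
        else:
            anchors = self.descendants(fi, arc.source)  # type: ignore[arg-type]
        arg_choices = [self.descendants(fi, a) for a in arc.args]
        for anchor in anchors:
            if arc.source is SOURCE:
                src, tgt = SOURCE, anchor
            elif arc.target is SINK:
                src, tgt = anchor, SINK
            else:
                src = anchor
                tgt = self.replace_slice(anchor, fi, arc.target)  # type: ignore[arg-type]
            src_tokens = self.tokens_at(anchor, other)
            for assignment in itertools.product(*arg_choices):
                arg_tokens = tuple(self.tokens_at(z, other) for z in assignment)
                ctx = ProductArcContext(
                    factor_index=fi, arc_index=ai, arc=arc,
                    source=src, target=tgt, anchor=anchor,
                    assignment=assignment, source_tokens=src_tokens,
                    arg_tokens=arg_tokens,
                )
                if self.rule.inclusion_predicate and not self.rule.inclusion_predicate(ctx):
                    continue
                rate = self._product_rate(fi, factor, arc, anchor, assignment, other, ctx)
                prov = Provenance(((fi, ai),), anchor, assignment)
                self.product.add_arc(src, tgt, rate, args=assignment, provenance=(prov,))

    def _product_rate(self, fi: int, factor: CompartmentalModel, arc: Arc,
                      anchor: Labels, assignment: tuple[Labels, ...],
                      other: list[int], ctx: ProductArcContext) -> sp.Expr:
        mapping: dict[sp.Symbol, sp.Expr] = {}
        if not isinstance(arc.source, _Terminal):
            mapping[factor.symbol(arc.source)] = self.product.symbol(anchor)
        elif anchor is not None and not isinstance(arc.target, _Terminal):
            # inflow arcs may reference the receiving state
            mapping[factor.symbol(arc.target)] = self.product.symbol(anchor)
        for a, z in zip(arc.args, assignment):
            mapping[factor.symbol(a)] = self.product.symbol(z)
        free = arc.rate.free_symbols
        factor_states = {factor.symbol(c) for c in factor.labels()}
        for name in factor.aggregates:
            sym = sp.Symbol(name)
            if sym in free:
                agg_anchor = assignment[0] if assignment else anchor
                mapping[sym] = self.map_aggregate(fi, name, agg_anchor, other)
        policy = self.rule.parameter_policy or default_parameter_policy
        params = sorted(
            (s for s in free
             if s not in factor_states and s.name not in factor.aggregates),
            key=lambda s: s.name,
        )
        for p in params:
            mapping[p] = policy(p, ctx)
        return arc.rate.xreplace(mapping)

    # -- diagonal (simultaneous) arcs ---------------------------------
    def diagonal_arcs(self) -> None:
        n = len(self.factors)
        ordinary: list[list[tuple[int, int, Arc]]] = []
        for fi, factor in enumerate(self.factors):
            ordinary.append([
                (fi, ai, a) for ai, a in enumerate(factor.arcs)
                if not isinstance(a.source, _Terminal)
                and not isinstance(a.target, _Terminal)
            ])
        for size in range(2, n + 1):
            for fis in itertools.combinations(range(n), size):
                pools = [ordinary[fi] for fi in fis]
                if any(not pool for pool in pools):
                    continue
                for choice in itertools.product(*pools):
                    self._combine(choice)

    def _combine(self, choice: tuple[tuple[int, int, Arc], ...]) -> None:
        own = {fi for fi, _, _ in choice}
        other = self.other_positions(own)
        anchors = [
            p for p in self.all_labels
            if all(self.slice_of(p, fi) == arc.source for fi, _, arc in choice)
        ]
        k = max(len(arc.args) for _, _, arc in choice)
        # positional argument constraints: z_j must descend from the j-th
        # argument of every member transition that has one
        arg_pools: list[list[Labels]] = []
        constrained_by: list[list[int]] = []
        for j in range(k):
            cons = [(fi, arc.args[j]) for fi, _, arc in choice if j < len(arc.args)]
            constrained_by.append([fi for fi, _ in cons])
            arg_pools.append([
                p for p in self.all_labels
                if all(self.slice_of(p, fi) == lab for fi, lab in cons)
            ])
        for anchor in anchors:
            target = anchor
            for fi, _, arc in choice:
                target = self.replace_slice(target, fi, arc.target)  # type: ignore[arg-type]
            src_tokens = self.tokens_at(anchor, other)
            member_ctxs = tuple(
                ProductArcContext(
                    factor_index=fi, arc_index=ai, arc=arc,
                    source=anchor, target=target, anchor=anchor,
                    assignment=(), source_tokens=src_tokens, arg_tokens=(),
                )
                for fi, ai, arc in choice
            )
            policy = self.rule.simultaneous_set_policy or default_simultaneous_policy
            if not policy(member_ctxs):
                continue
            for assignment in itertools.product(*arg_pools):
                arg_tokens = []
                for j, z in enumerate(assignment):
                    informative = self.other_positions(own | set(constrained_by[j]))
                    arg_tokens.append(self.tokens_at(z, informative))
                ctx = CombinedArcContext(
                    members=member_ctxs, source=anchor, target=target,
                    assignment=assignment, source_tokens=src_tokens,
                    arg_tokens=tuple(arg_tokens),
                    aggregate_symbols=self._member_aggregates(choice, assignment, anchor),
                )
                rate = (self.rule.combined_rate or self._default_combined)(ctx)
                prov = Provenance(
                    tuple((fi, ai) for fi, ai, _ in choice), anchor, assignment
                )
                self.product.add_arc(
                    anchor, target, rate, args=assignment, provenance=(prov,)
                )

    def _member_aggregates(self, choice, assignment, anchor) -> tuple[sp.Symbol, ...]:
        syms: list[sp.Symbol] = []
        for fi, _, arc in choice:
            factor = self.factors[fi]
            other = self.other_positions({fi})
            for name in factor.aggregates:
                if sp.Symbol(name) in arc.rate.free_symbols:
                    agg_anchor = assignment[0] if assignment else anchor
                    s = self.map_aggregate(fi, name, agg_anchor, other)
                    if s not in syms:
                        syms.append(s)
        return tuple(syms)

    def _default_combined(self, ctx: CombinedArcContext) -> sp.Expr:
        bases: list[str] = []
        for m in ctx.members:
            factor = self.factors[m.factor_index]
            term = factor.rate_term(m.arc)
            names = sorted(s.name for s in term.parameters)
            lead = names[0] if names else "kappa"
            if lead not in bases:
                bases.append(lead)
        tag = "".join(str(i + 1) for i in ctx.factor_indices)
        levels = list(ctx.source_tokens)
        for toks in ctx.arg_tokens:
            levels.extend(toks)
        sub = render_subscripts(levels)
        pname = "_".join(bases) + "__" + tag + (("_" + sub) if sub else "")
        expr: sp.Expr = sp.Symbol(pname) * self.product.symbol(ctx.source)
        for z in ctx.assignment:
            expr *= self.product.symbol(z)
        for agg in ctx.aggregate_symbols:
            expr /= agg
        return expr


def _run(factors, rule, kind, naming=None) -> CompartmentalModel:
    eng = _Engine(factors, rule or ProductRule(), naming)
    eng.singleton_arcs()
    if kind == "strong":
        eng.diagonal_arcs()
    return eng.product


# ----------------------------------------------------------------------
# public model products
# ----------------------------------------------------------------------
def extended_cartesian(A: CompartmentalModel, B: CompartmentalModel,
                       rule: ProductRule | None = None,
                       naming: Naming | None = None) -> CompartmentalModel:
    """Extended Cartesian product of two compartmental models.

    Compartments are the label pairs. Each factor arc with rate
    ``f(X_s, Z_1, ..., Z_k)`` generates one product arc per source
    descendant and per independent choice of descendants of the
    interaction arguments, targeting the source's same-level sibling;
    recruitment (SOURCE) and removal (SINK) transitions are replicated
    per level. Parallel arcs between a compartment pair are kept
    distinct; see
    :meth:`~epiproducts.core.CompartmentalModel.aggregate_parallel_arcs`.
    """
    return _run([A, B], rule, "cartesian", naming)


def strong_product(A: CompartmentalModel, B: CompartmentalModel,
                   rule: ProductRule | None = None,
                   naming: Naming | None = None) -> CompartmentalModel:
    """Strong product: the extended Cartesian arcs (singleton transition
    sets) plus diagonal arcs for every admitted set of simultaneous
    transitions from distinct factors. The two factors' transitions are
    treated as distinct even in a self-product."""
    return _run([A, B], rule, "strong", naming)


def _check_linear(model: CompartmentalModel) -> None:
    states = {model.symbol(c) for c in model.labels()}
    for i, arc in enumerate(model.arcs):
        if arc.args:
            raise NonlinearModelError(
                f"factor {model.name!r} arc {i} has interaction arguments; "
                "use extended_cartesian for interacting models"
            )
        if model.rate_term(arc).aggregates:
            raise NonlinearModelError(
                f"factor {model.name!r} arc {i} uses an aggregate symbol; "
                "use extended_cartesian for interacting models"
            )
        rate = sp.expand(arc.rate)
        if isinstance(arc.source, _Terminal):
            if rate.free_symbols & states:
                raise NonlinearModelError(
                    f"factor {model.name!r} inflow arc {i} depends on a state; "
                    "use extended_cartesian"
                )
            continue
        src = model.symbol(arc.source)
        coeff = sp.cancel(rate / src)
        if coeff.free_symbols & states:
            raise NonlinearModelError(
                f"factor {model.name!r} arc {i} rate {arc.rate} is not linear "
                "in its source compartment; use extended_cartesian"
            )


def linear_cartesian(A: CompartmentalModel, B: CompartmentalModel,
                     rule: ProductRule | None = None,
                     naming: Naming | None = None) -> CompartmentalModel:
    """Cartesian product of linear compartmental models (``dX/dt = a + MX``).

    Each factor transition is replicated at every level of the other
    factor with its rate parameter subscripted by that level; source
    inflows and sink outflows likewise. Factors with interaction terms
    are rejected with a pointer to :func:`extended_cartesian`.
    """
    _check_linear(A)
    _check_linear(B)
    return _run([A, B], rule, "cartesian", naming)


def n_ary_product(models: Sequence[CompartmentalModel],
                  rule: ProductRule | None = None,
                  kind: str = "cartesian",
                  naming: Naming | None = None) -> CompartmentalModel:
    """Product of any number of factors with flat label tuples.

    Implemented directly as the n-factor generalization of the binary
    definitions (each factor arc ranges over the levels of *all* other
    factors at once); composing binary products of products gives a
    structurally identical model, so the result is independent of
    bracketing up to relabeling.
    """
    if kind not in ("cartesian", "strong"):
        raise ValueError(f"unknown product kind {kind!r}")
    if len(models) == 1:
        return _run(list(models), rule, "cartesian", naming)
    return _run(list(models), rule, kind, naming)


def enumerate_partial_products(base: CompartmentalModel,
                               factors: Sequence[CompartmentalModel],
                               rule: ProductRule | None = None,
                               kind: str = "cartesian"
                               ) -> list[CompartmentalModel]:
    """The model family over all subsets of the optional factors.

    Returns ``2**k`` models in binary-counting order of the subset mask
    (base model first, full product last), for systematic comparison of
    refinements of the base process.
    """
    out: list[CompartmentalModel] = []
    k = len(factors)
    for mask in range(2 ** k):
        chosen = [factors[i] for i in range(k) if mask >> i & 1]
        out.append(n_ary_product([base] + chosen, rule, kind))
    return out


def is_isomorphic(m1: CompartmentalModel, m2: CompartmentalModel,
                  permutation: Sequence[int] | None = None) -> bool:
    """Structural isomorphism under a coordinate permutation.

    ``permutation`` reorders the label-tuple positions of ``m1`` to match
    ``m2`` (identity when omitted). Compares the compartment set and the
    multiset of (source, target) arc pairs; rates correspond under the
    induced subscript renaming and are not compared here.
    """
    width = m1.label_width
    perm = tuple(permutation) if permutation is not None else tuple(range(width))

    def relabel(end):
        if isinstance(end, _Terminal):
            return end.name
        return tuple(end[i] for i in perm)

    if {relabel(c) for c in m1.labels()} != set(m2.labels()):
        return False

    def arc_multiset(model, mapper):
        return sorted(
            (str(mapper(a.source)), str(mapper(a.target))) for a in model.arcs
        )

    return arc_multiset(m1, relabel) == arc_multiset(m2, lambda e: e.name if isinstance(e, _Terminal) else e)
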