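"""Symbolic algebra for transition-rate expressions.

Rates in a compartmental model are symbolic arithmetic expressions over
three kinds of symbols:

* **parameters** -- transmission coefficients, recovery rates, recruitment
  rates and the like (``beta``, ``gamma``, ``Lambda``, ``mu``, ...), possibly
  decorated with subscripts that name the levels of a product model
  (``beta_12`` is transmission from community-2 infectives to community-1
  susceptibles);
* **state symbols** -- one per compartment, named by the compartment's
  display name (``S``, ``I_1``, ``S_FA``);
* **aggregate symbols** -- shorthands for sums of state symbols, such as a
  total population size ``N = S + I``, which in product models are re-scoped
  per level (``N_M = S_M + I_M``).

This module provides parameter subscripting, expression parsing,
substitution, aggregate expansion, and a semantic-equality test used to
compare generated models against hand-entered reference systems.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import sympy as sp
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

__all__ = [
    "ParameterSymbol",
    "RateTerm",
    "RateSyntaxError",
    "RoleConfusionError",
    "UndefinedAggregateError",
    "render_subscripts",
    "subscript_parameter",
    "parse_rate",
    "as_expr",
    "substitute",
    "bind_aggregates",
    "semantically_equal",
]

ExprLike = Union[sp.Expr, str, int, float]


class RateSyntaxError(ValueError):
    """A rate string could not be parsed into an expression."""


class RoleConfusionError(ValueError):
    """A substitution would change the role of a symbol (state vs parameter)."""


class UndefinedAggregateError(ValueError):
    """An aggregate symbol has no definition."""


def render_subscripts(tokens: Iterable[str]) -> str:
    """Join subscript tokens the way the field writes them.

    Single-character tokens are concatenated (``("1","2")`` -> ``"12"``,
    mirroring beta_12); if any token is longer, tokens are joined with
    underscores to keep the decomposition unambiguous.
    """
    toks = tuple(str(t) for t in tokens)
    if not toks:
        return ""
    if all(len(t) == 1 for t in toks):
        return "".join(toks)
    return "_".join(toks)


@dataclass(frozen=True)
class ParameterSymbol:
    """A rate parameter with an ordered tuple of level subscripts.

    Identity is the structured pair ``(base, subscripts)``; the rendered
    name (``beta_12``) is presentation. Subscript order is significant:
    ``beta_12`` is transmission *to* level 1 *from* level 2 and differs
    from ``beta_21``.
    """

    base: str
    subscripts: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        sub = render_subscripts(self.subscripts)
        return f"{self.base}_{sub}" if sub else self.base

    @property
    def symbol(self) -> sp.Symbol:
        return sp.Symbol(self.name)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def subscript_parameter(
    param: Union[ParameterSymbol, sp.Symbol, str],
    levels: Iterable[str],
) -> ParameterSymbol:
    """Decorate a parameter with level-name subscripts (a pure function).

    Appends to any subscripts already present; an empty ``levels`` is the
    identity.
    """
    levels = tuple(str(level) for level in levels)
    if isinstance(param, ParameterSymbol):
        return ParameterSymbol(param.base, param.subscripts + levels)
    base = param.name if isinstance(param, sp.Symbol) else str(param)
    return ParameterSymbol(base, levels)


_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


def parse_rate(text: str) -> sp.Expr:
    """Parse an infix rate string into a sympy expression.

    Every identifier becomes a plain :class:`sympy.Symbol`; nothing is
    looked up in sympy's namespace, so ``I`` is a state symbol and not the
    imaginary unit, ``beta`` is a symbol and not a function. Supported
    syntax: ``+ - * / **``, parentheses, integer and float literals.
    """
    names = set(_IDENT.findall(text))
    local = {n: sp.Symbol(n) for n in names}
    try:
        expr = parse_expr(
            text,
            local_dict=local,
            transformations=standard_transformations,
            evaluate=True,
        )
    except Exception as exc:
        raise RateSyntaxError(f"cannot parse rate expression {text!r}: {exc}") from exc
    if not isinstance(expr, sp.Expr):
        raise RateSyntaxError(f"rate expression {text!r} is not arithmetic")
    return expr


def as_expr(rate: ExprLike) -> sp.Expr:
    """Coerce a rate given as string, number, or expression to sympy."""
    if isinstance(rate, sp.Expr):
        return rate
    if isinstance(rate, str):
        return parse_rate(rate)
    return sp.sympify(rate)


@dataclass(frozen=True)
class RateTerm:
    """A rate expression together with the classification of its symbols.

    Every free symbol belongs to exactly one of the three classes; the
    classification is computed against a model's compartments and
    aggregate definitions.
    """

    expression: sp.Expr
    parameters: frozenset[sp.Symbol]
    state_refs: frozenset[sp.Symbol]
    aggregates: frozenset[sp.Symbol]

    @classmethod
    def classify(
        cls,
        expression: ExprLike,
        state_names: Iterable[str],
        aggregate_names: Iterable[str] = (),
    ) -> "RateTerm":
        expr = as_expr(expression)
        states = set(state_names)
        aggs = set(aggregate_names)
        state_refs, aggregates, params = set(), set(), set()
        for sym in expr.free_symbols:
            if sym.name in states:
                state_refs.add(sym)
            elif sym.name in aggs:
                aggregates.add(sym)
            else:
                params.add(sym)
        return cls(expr, frozenset(params), frozenset(state_refs), frozenset(aggregates))


def _binding_key(key) -> sp.Symbol:
    if isinstance(key, ParameterSymbol):
        return key.symbol
    if isinstance(key, sp.Symbol):
        return key
    return sp.Symbol(str(key))


def substitute(
    expr: ExprLike,
    bindings: Mapping,
    state_symbols: Iterable[str] = (),
) -> sp.Expr:
    """Replace symbols by expressions or numbers.

    ``state_symbols`` (display names) enables the role check: binding a
    state symbol to a bare parameter symbol is rejected, since it would
    silently turn a dynamic quantity into a constant of the wrong kind.
    Identity bindings are permitted and are no-ops.
    """
    expr = as_expr(expr)
    states = set(state_symbols)
    resolved: dict[sp.Symbol, sp.Expr] = {}
    for key, value in bindings.items():
        sym = _binding_key(key)
        val = as_expr(value) if not isinstance(value, sp.Expr) else value
        if sym.name in states:
            if isinstance(val, sp.Symbol) and val.name not in states and val != sym:
                raise RoleConfusionError(
                    f"cannot bind state symbol {sym} to parameter {val}"
                )
        resolved[sym] = val
    return expr.subs(resolved, simultaneous=True)


def bind_aggregates(
    expr: ExprLike,
    definitions: Mapping[str, Iterable[str]],
    declared: Iterable[str] | None = None,
) -> sp.Expr:
    """Expand aggregate symbols into explicit sums of state symbols.

    ``definitions`` maps aggregate names to the display names of their
    member compartments. When ``declared`` is given, it is the set of
    symbols known to be aggregates; any declared aggregate appearing in
    the expression without a definition raises
    :class:`UndefinedAggregateError` naming it.
    """
    expr = as_expr(expr)
    free = {s.name for s in expr.free_symbols}
    if declared is not None:
        missing = sorted((set(declared) & free) - set(definitions))
        if missing:
            raise UndefinedAggregateError(
                f"aggregate symbol(s) without definition: {', '.join(missing)}"
            )
    mapping = {
        sp.Symbol(name): sp.Add(*[sp.Symbol(m) for m in members])
        for name, members in definitions.items()
        if name in free
    }
    return expr.xreplace(mapping)


def semantically_equal(e1: ExprLike, e2: ExprLike) -> bool:
    """True iff the two expressions agree as rational functions.

    Normalization is ring-style: put the difference over a common
    denominator, expand, and cancel. Rates in compartmental models are
    rational in the states and parameters, so this is decisive; a general
    ``simplify`` fallback guards pathological inputs.
    """
    diff = as_expr(e1) - as_expr(e2)
    d = sp.cancel(sp.together(sp.expand(diff)))
    if d == 0:
        return True
    return sp.simplify(d) == 0
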