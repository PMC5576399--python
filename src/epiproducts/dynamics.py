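"""ODE derivation, symbolic comparison, and numeric realization.

A compartmental model diagram determines an ODE system -- for each
compartment ``X``, ``dX/dt`` is the sum of inbound arc rates minus the
sum of outbound arc rates, recruitment and removal flows included -- and
equivalently a continuous-time Markov jump process whose transition
propensities are the arc rates evaluated at the integer state.

:func:`compare_odes` is the acceptance surface for product constructions:
it checks, compartment by compartment, that a generated system is
semantically equal to a reference system after aggregate symbols are
expanded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .core import SINK, SOURCE, CompartmentalModel, _Terminal
from .rates import bind_aggregates, semantically_equal

__all__ = [
    "ODESystem",
    "Trajectory",
    "EventPath",
    "ComparisonReport",
    "UnboundSymbolError",
    "NegativeRateError",
    "ode_system",
    "compare_odes",
    "linear_parts",
    "integrate",
    "jump_realization",
]


class UnboundSymbolError(ValueError):
    """A numeric operation met a symbol with no numeric binding."""


class NegativeRateError(RuntimeError):
    """A propensity evaluated negative during stochastic simulation."""


@dataclass
class ODESystem:
    """Symbolic right-hand sides, one per compartment (by display name)."""

    states: tuple[str, ...]
    rhs: dict[str, sp.Expr]
    aggregate_defs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    inflows: dict[str, list[sp.Expr]] = field(default_factory=dict)
    outflows: dict[str, list[sp.Expr]] = field(default_factory=dict)

    def bound_rhs(self) -> dict[str, sp.Expr]:
        """Right-hand sides with aggregate symbols expanded to sums."""
        return {
            x: bind_aggregates(e, self.aggregate_defs, declared=self.aggregate_defs)
            for x, e in self.rhs.items()
        }

    def total_derivative(self) -> sp.Expr:
        """Symbolic d/dt of the total population (zero iff closed)."""
        return sp.expand(sp.Add(*[self.bound_rhs()[x] for x in self.states]))

    def free_parameters(self) -> set[sp.Symbol]:
        state_syms = {sp.Symbol(x) for x in self.states}
        out: set[sp.Symbol] = set()
        for e in self.bound_rhs().values():
            out |= e.free_symbols - state_syms
        return out


def ode_system(model: CompartmentalModel) -> ODESystem:
    """Derive the ODE system of a model.

    ``rhs(X) = sum(inbound arc rates) - sum(outbound arc rates)``; flows
    to SINK and from SOURCE count as out- and inflows respectively.
    Term order is sympy-canonical and deterministic.
    """
    diags = model.validate()
    if diags:
        raise ValueError(f"model {model.name!r} is invalid: {diags[0]}")
    states = tuple(model.state_names())
    name_of = {c: model.display_name(c) for c in model.labels()}
    inflows: dict[str, list[sp.Expr]] = {x: [] for x in states}
    outflows: dict[str, list[sp.Expr]] = {x: [] for x in states}
    for arc in model.arcs:
        if not isinstance(arc.source, _Terminal):
            outflows[name_of[arc.source]].append(arc.rate)
        if not isinstance(arc.target, _Terminal):
            inflows[name_of[arc.target]].append(arc.rate)
    rhs = {
        x: sp.expand(sp.Add(*inflows[x]) - sp.Add(*outflows[x]))
        for x in states
    }
    return ODESystem(states, rhs, dict(model.aggregate_name_defs()),
                     inflows, outflows)


@dataclass
class ComparisonReport:
    """Per-compartment semantic-equality verdicts."""

    verdicts: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.verdicts.values())

    def failures(self) -> list[str]:
        return [x for x, ok in self.verdicts.items() if not ok]


def compare_odes(sys1: ODESystem, sys2: ODESystem,
                 compartment_map: Mapping[str, str] | None = None
                 ) -> ComparisonReport:
    """Compare two ODE systems compartment by compartment.

    ``compartment_map`` is a bijection from the states of ``sys1`` to
    those of ``sys2`` (identity by default). Aggregates are expanded on
    both sides before comparison, and the mapped state renaming is
    applied to the first system, so e.g. generated names can differ from
    reference names.
    """
    if compartment_map is None:
        compartment_map = {x: x for x in sys1.states}
    if set(compartment_map) != set(sys1.states):
        raise ValueError("compartment_map does not cover the first system's states")
    if sorted(compartment_map.values()) != sorted(set(compartment_map.values())) \
            or set(compartment_map.values()) != set(sys2.states):
        raise ValueError("compartment_map is not a bijection onto the second system")
    rename = {sp.Symbol(a): sp.Symbol(b) for a, b in compartment_map.items()}
    lhs = sys1.bound_rhs()
    rhs = sys2.bound_rhs()
    verdicts = {
        x: semantically_equal(lhs[x].xreplace(rename), rhs[compartment_map[x]])
        for x in sys1.states
    }
    return ComparisonReport(verdicts)


def linear_parts(system: ODESystem) -> tuple[sp.Matrix, sp.Matrix]:
    """Decompose a linear system as ``dX/dt = a + M X``.

    Raises :class:`ValueError` if any right-hand side is nonlinear in the
    states.
    """
    syms = [sp.Symbol(x) for x in system.states]
    bound = system.bound_rhs()
    n = len(syms)
    M = sp.zeros(n, n)
    a = sp.zeros(n, 1)
    for i, x in enumerate(system.states):
        e = sp.expand(bound[x])
        for j, s in enumerate(syms):
            c = sp.diff(e, s)
            if c.free_symbols & set(syms):
                raise ValueError(f"rhs of {x} is nonlinear in the states")
            M[i, j] = c
        a[i, 0] = e.xreplace({s: sp.Integer(0) for s in syms})
    return a, M


@dataclass
class Trajectory:
    """Numeric solution of an ODE system on a time grid."""

    t: np.ndarray
    states: tuple[str, ...]
    y: np.ndarray                      # shape (len(states), len(t))
    parameters: dict[str, float]
    solver: dict[str, object]

    def series(self, name: str) -> np.ndarray:
        return self.y[self.states.index(name)]


def _numeric_bindings(params: Mapping) -> dict[sp.Symbol, sp.Float]:
    out = {}
    for k, v in params.items():
        sym = k if isinstance(k, sp.Symbol) else sp.Symbol(str(k))
        out[sym] = sp.Float(v)
    return out


def integrate(system: ODESystem, params: Mapping, init: Mapping,
              t_span: tuple[float, float], steps: int = 200,
              rtol: float = 1e-8, atol: float = 1e-10,
              method: str = "LSODA") -> Trajectory:
    """Integrate the system numerically on a dense output grid.

    The default method is adaptive and stiff-capable, since products with
    many levels (compartmental aging in particular) yield large stiff
    systems. Every parameter must be bound to a finite number; unbound
    symbols are reported by name.
    """
    bindings = _numeric_bindings(params)
    state_syms = [sp.Symbol(x) for x in system.states]
    exprs = [system.bound_rhs()[x].xreplace(bindings) for x in system.states]
    unbound = sorted(
        {s.name for e in exprs for s in e.free_symbols} - set(system.states)
    )
    if unbound:
        raise UnboundSymbolError(f"unbound symbol(s): {', '.join(unbound)}")
    f = sp.lambdify(state_syms, exprs, modules="numpy")
    y0 = []
    for x in system.states:
        if x not in init:
            raise UnboundSymbolError(f"no initial value for state {x!r}")
        y0.append(float(init[x]))
    t_eval = np.linspace(t_span[0], t_span[1], steps)
    sol = solve_ivp(lambda t, y: np.asarray(f(*y), dtype=float),
                    t_span, y0, t_eval=t_eval, method=method,
                    rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - solver failure path
        raise RuntimeError(f"integration failed: {sol.message}")
    return Trajectory(
        sol.t, tuple(system.states), sol.y,
        {str(k): float(v) for k, v in params.items()},
        {"method": method, "rtol": rtol, "atol": atol},
    )


@dataclass
class EventPath:
    """Event log of a stochastic jump realization."""

    times: np.ndarray                  # event times
    events: list[int]                  # index into `arcs` per event
    states: tuple[str, ...]
    path: np.ndarray                   # state after each event, incl. row 0 = initial
    arcs: list[tuple[str, str]]        # (source, target) display pairs
    seed: int

    def occupancy_mean(self, state: str, t_end: float | None = None,
                       burn_in: float = 0.0) -> float:
        """Time-weighted mean occupancy of one compartment."""
        j = self.states.index(state)
        t = np.concatenate(([0.0], self.times))
        if t_end is None:
            t_end = t[-1]
        values = self.path[:, j]
        total, weight = 0.0, 0.0
        for i in range(len(values)):
            lo = max(t[i], burn_in)
            hi = t[i + 1] if i + 1 < len(t) else t_end
            if hi > lo:
                total += values[i] * (hi - lo)
                weight += hi - lo
        return total / weight if weight > 0 else float("nan")


def jump_realization(model: CompartmentalModel, params: Mapping, init: Mapping,
                     t_end: float | None = None, max_events: int = 10_000,
                     seed: int | None = None) -> EventPath:
    """Exact stochastic simulation (Gillespie direct method).

    The model is first put in canonical single-arc form so that parallel
    arcs do not double-count propensities. The seed is required for
    reproducibility: the same seed yields the identical event path.
    """
    if seed is None:
        raise ValueError("jump_realization requires an explicit seed")
    if t_end is None and max_events is None:
        raise ValueError("provide t_end or max_events")
    canon = model.aggregate_parallel_arcs()
    states = tuple(canon.state_names())
    state_syms = [sp.Symbol(x) for x in states]
    bindings = _numeric_bindings(params)
    name_of = {c: canon.display_name(c) for c in canon.labels()}
    prop_fns = []
    stoich = []
    arc_pairs = []
    for arc in canon.arcs:
        expr = canon.bind_rate(arc).xreplace(bindings)
        unbound = sorted({s.name for s in expr.free_symbols} - set(states))
        if unbound:
            raise UnboundSymbolError(f"unbound symbol(s): {', '.join(unbound)}")
        prop_fns.append(sp.lambdify(state_syms, expr, modules="numpy"))
        delta = np.zeros(len(states))
        src = "SOURCE" if arc.source is SOURCE else name_of[arc.source]
        tgt = "SINK" if arc.target is SINK else name_of[arc.target]
        if not isinstance(arc.source, _Terminal):
            delta[states.index(name_of[arc.source])] -= 1
        if not isinstance(arc.target, _Terminal):
            delta[states.index(name_of[arc.target])] += 1
        stoich.append(delta)
        arc_pairs.append((src, tgt))
    rng = np.random.default_rng(seed)
    y = np.array([float(init.get(x, 0)) for x in states])
    t = 0.0
    times: list[float] = []
    events: list[int] = []
    path = [y.copy()]
    while len(events) < max_events:
        props = np.array([float(f(*y)) for f in prop_fns])
        if np.any(props < -1e-12):
            bad = int(np.argmin(props))
            snapshot = dict(zip(states, y))
            raise NegativeRateError(
                f"negative rate {props[bad]:.3g} on arc "
                f"{arc_pairs[bad][0]}->{arc_pairs[bad][1]} at state {snapshot}"
            )
        props = np.clip(props, 0.0, None)
        total = props.sum()
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t_end is not None and t > t_end:
            break
        choice = int(rng.choice(len(props), p=props / total))
        y = y + stoich[choice]
        times.append(t)
        events.append(choice)
        path.append(y.copy())
    return EventPath(np.array(times), events, states, np.array(path),
                     arc_pairs, seed)
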