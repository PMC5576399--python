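"""ODE derivation, comparison, integration, and jump realizations."""

import numpy as np
import pytest
import sympy as sp

from epiproducts import (
    CompartmentalModel,
    compare_odes,
    integrate,
    jump_realization,
    linear_parts,
    ode_system,
    semantically_equal,
)
from epiproducts.core import SINK, SOURCE
from epiproducts.dynamics import NegativeRateError, UnboundSymbolError
from epiproducts import zoo


class TestOdeSystem:
    def test_si_right_hand_sides(self, si_model):
        sys = ode_system(si_model)
        assert semantically_equal(sys.rhs["S"], "-beta*S*I")
        assert semantically_equal(sys.rhs["I"], "beta*S*I - gamma*I")

    def test_empty_model(self):
        sys = ode_system(CompartmentalModel())
        assert sys.states == () and sys.rhs == {}

    def test_aggregation_never_changes_dynamics(self, watson):
        before = ode_system(watson)
        after = ode_system(watson.aggregate_parallel_arcs())
        assert compare_odes(before, after).passed

    def test_deterministic_term_order(self, watson):
        s1 = ode_system(watson)
        s2 = ode_system(zoo.build("watson"))
        assert [sp.srepr(s1.rhs[x]) for x in s1.states] == \
            [sp.srepr(s2.rhs[x]) for x in s2.states]

    def test_mass_conservation_symbolic(self):
        for name in ("two_strain_sis",):
            sys = ode_system(zoo.build(name))
            assert sp.simplify(sys.total_derivative()) == 0

    def test_linear_round_trip(self):
        # dX/dt = a + MX read back off the arc coefficients
        m = CompartmentalModel("lin")
        m.add_compartment("A").add_compartment("B")
        m.add_arc(SOURCE, "A", "Lambda")
        m.add_arc("A", "B", "k*A")
        m.add_arc("B", SINK, "mu*B")
        a, M = linear_parts(ode_system(m))
        k, mu, lam = sp.symbols("k mu Lambda")
        assert a == sp.Matrix([lam, 0])
        assert M == sp.Matrix([[-k, 0], [k, -mu]])


class TestCompareOdes:
    def test_self_comparison(self, watson):
        sys = ode_system(watson)
        assert compare_odes(sys, sys).passed

    def test_swapped_coefficient_fails_locally(self):
        # beta_12 <-> beta_21 perturbation shows up in exactly the four
        # transmission-coupled compartments it touches
        sys = ode_system(zoo.build("watson").aggregate_parallel_arcs())
        ref = zoo._watson_reference()
        swap = {sp.Symbol("beta_12"): sp.Symbol("beta_21"),
                sp.Symbol("beta_21"): sp.Symbol("beta_12")}
        perturbed = type(ref)(
            ref.states, {x: e.xreplace(swap) for x, e in ref.rhs.items()}
        )
        report = compare_odes(sys, perturbed)
        assert not report.passed
        assert set(report.failures()) == {"S_1", "S_2", "I_1", "I_2"}
        for x in report.failures():
            assert "beta" in str(sys.rhs[x])

    def test_non_bijective_map_rejected(self, si_model):
        sys = ode_system(si_model)
        with pytest.raises(ValueError):
            compare_odes(sys, sys, {"S": "I", "I": "I"})


class TestIntegrate:
    def test_closed_sir_conserves_population(self):
        sys = ode_system(zoo.sir_factor())
        traj = integrate(sys, {"beta": 0.3, "gamma": 0.1},
                         {"S": 99, "I": 1, "R": 0}, (0, 50), steps=101)
        total = traj.y.sum(axis=0)
        assert np.allclose(total, 100.0, rtol=1e-6)

    def test_si_logistic_closed_form_when_no_removal(self, si_model):
        # with gamma = 0, I(t) = I0*N / (I0 + (N - I0) e^{-beta N t})
        sys = ode_system(si_model)
        beta, i0, n = 0.02, 1.0, 100.0
        traj = integrate(sys, {"beta": beta, "gamma": 0.0},
                         {"S": n - i0, "I": i0}, (0, 8), steps=50)
        expected = i0 * n / (i0 + (n - i0) * np.exp(-beta * n * traj.t))
        rel = np.abs(traj.series("I") - expected) / expected
        assert rel.max() < 1e-6

    def test_pure_decay_when_no_transmission(self, watson):
        sys = ode_system(watson.aggregate_parallel_arcs())
        params = {p.name: 0.0 for p in sys.free_parameters()}
        params.update({"gamma_1": 0.5, "gamma_2": 0.25})
        init = {"S_1": 10, "S_2": 10, "I_1": 5, "I_2": 8}
        traj = integrate(sys, params, init, (0, 4), steps=21)
        for i, g in (("I_1", 0.5), ("I_2", 0.25)):
            assert np.allclose(traj.series(i),
                               init[i] * np.exp(-g * traj.t), rtol=1e-6)

    def test_unbound_symbol_named(self, si_model):
        sys = ode_system(si_model)
        with pytest.raises(UnboundSymbolError, match="gamma"):
            integrate(sys, {"beta": 1.0}, {"S": 1, "I": 1}, (0, 1))


class TestJumpRealization:
    def test_immigration_death_stationary_mean(self, immigration_death):
        # stationary occupancy is Poisson(Lambda/mu): time-averaged mean
        # within 3 standard errors, SE ~ sqrt(2 * var * tau / T)
        lam, mu = 50.0, 1.0
        path = jump_realization(immigration_death, {"Lambda": lam, "mu": mu},
                                {"N": lam / mu}, max_events=10_000, seed=7)
        t_total = path.times[-1]
        mean = path.occupancy_mean("N")
        se = np.sqrt(2 * (lam / mu) * (1 / mu) / t_total)
        assert abs(mean - lam / mu) < 3 * se

    def test_all_zero_rates_no_events(self, immigration_death):
        path = jump_realization(immigration_death, {"Lambda": 0, "mu": 0},
                                {"N": 5}, max_events=100, seed=1)
        assert len(path.events) == 0

    def test_seed_reproducibility(self, immigration_death):
        kw = dict(params={"Lambda": 3.0, "mu": 0.5}, init={"N": 4},
                  max_events=500, seed=42)
        p1 = jump_realization(immigration_death, **kw)
        p2 = jump_realization(immigration_death, **kw)
        assert np.array_equal(p1.times, p2.times)
        assert p1.events == p2.events

    def test_seed_required(self, immigration_death):
        with pytest.raises(ValueError, match="seed"):
            jump_realization(immigration_death, {"Lambda": 1, "mu": 1},
                             {"N": 1})

    def test_negative_rate_reported_with_state(self, immigration_death):
        with pytest.raises(NegativeRateError, match="N"):
            jump_realization(immigration_death, {"Lambda": 1, "mu": -2.0},
                             {"N": 5}, max_events=10, seed=3)


def test_closed_zoo_models_conserve_mass_symbolically():
    """Sum of right-hand sides is identically zero for every model
    without recruitment or removal flows."""
    closed = 0
    for entry in zoo.registry():
        models = entry.builder()
        if not isinstance(models, list):
            models = [models]
        for m in models:
            if m.is_closed and len(m.arcs):
                closed += 1
                assert sp.simplify(ode_system(m).total_derivative()) == 0, \
                    entry.name
    assert closed >= 1
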