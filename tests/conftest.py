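"""Shared fixtures: reference models and random-model generators."""

import numpy as np
import pytest
import sympy as sp

from epiproducts import CompartmentalModel
from epiproducts.core import SINK, SOURCE
from epiproducts import zoo


@pytest.fixture
def si_model():
    return zoo.si_factor()


@pytest.fixture
def watson():
    return zoo.build("watson", n=2)


@pytest.fixture
def two_strain():
    return zoo.build("two_strain_sis")


@pytest.fixture
def immigration_death():
    m = CompartmentalModel("imdeath")
    m.add_compartment("N")
    m.add_arc(SOURCE, "N", "Lambda")
    m.add_arc("N", SINK, "mu*N")
    return m


def random_linear_model(name: str, n_states: int, rng: np.random.Generator,
                        numeric: bool = True) -> CompartmentalModel:
    """Random linear compartmental model: per-capita transitions with
    numeric (or symbolic) coefficients, no sources or interactions."""
    m = CompartmentalModel(name)
    for i in range(n_states):
        m.add_compartment(f"{name}{i}")
    for i in range(n_states):
        for j in range(n_states):
            if i != j and rng.random() < 0.5:
                coeff = (sp.Float(rng.uniform(0.1, 2.0)) if numeric
                         else sp.Symbol(f"k_{name}{i}{j}"))
                m.add_arc(f"{name}{i}", f"{name}{j}",
                          coeff * m.symbol(f"{name}{i}"))
    return m


def random_epidemic_factor(name: str, rng: np.random.Generator
                           ) -> CompartmentalModel:
    """Small random factor model, possibly with one interaction term."""
    n = int(rng.integers(1, 4))
    m = CompartmentalModel(name)
    for i in range(n):
        m.add_compartment(f"{name}{i}")
    labels = [f"{name}{i}" for i in range(n)]
    n_arcs = int(rng.integers(0, 3))
    for a in range(n_arcs):
        i, j = rng.integers(0, n, 2)
        if i == j:
            continue
        rate = sp.Symbol(f"k{a}_{name}") * m.symbol(labels[i])
        if n > 1 and rng.random() < 0.5:
            z = labels[int(rng.integers(0, n))]
            if z != labels[i]:
                rate = rate * m.symbol(z)
        m.add_arc(labels[i], labels[j], rate)
    return m
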