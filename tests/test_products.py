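"""Graph products and compartmental-model products."""

import networkx as nx
import numpy as np
import pytest
import sympy as sp

from epiproducts import (
    CompartmentalModel,
    Naming,
    ProductRule,
    enumerate_partial_products,
    extended_cartesian,
    graph_cartesian,
    graph_strong,
    is_isomorphic,
    linear_cartesian,
    linear_parts,
    n_ary_product,
    ode_system,
    semantically_equal,
    strong_product,
)
from epiproducts.core import SINK, SOURCE
from epiproducts.products import NonlinearModelError
from epiproducts import zoo

from conftest import random_epidemic_factor, random_linear_model


def random_digraph(rng: np.random.Generator, n_max: int = 6,
                   loops: bool = True) -> nx.MultiDiGraph:
    n = int(rng.integers(1, n_max + 1))
    g = nx.MultiDiGraph()
    g.add_nodes_from(range(n))
    for _ in range(int(rng.integers(0, 2 * n))):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if loops or i != j:
            g.add_edge(i, j)
    return g


def cartesian_oracle(A, B):
    """Exhaustive enumeration straight from the definition."""
    arcs = []
    for v in A.nodes:
        for ws, wt, _ in B.edges(keys=True):
            arcs.append(((v, ws), (v, wt)))
    for w in B.nodes:
        for vs, vt, _ in A.edges(keys=True):
            arcs.append(((vs, w), (vt, w)))
    return sorted(arcs)


class TestGraphProducts:
    def test_counts_two_by_two(self):
        A = nx.MultiDiGraph([(0, 1)])
        B = nx.MultiDiGraph([("a", "b")])
        C = graph_cartesian(A, B)
        assert C.number_of_nodes() == 4 and C.number_of_edges() == 4
        S = graph_strong(A, B)
        assert S.number_of_nodes() == 4 and S.number_of_edges() == 5

    def test_single_vertex_is_identity(self):
        rng = np.random.default_rng(3)
        A = random_digraph(rng)
        unit = nx.MultiDiGraph()
        unit.add_node("u")
        for op in (graph_cartesian, graph_strong):
            P = op(A, unit)
            assert nx.is_isomorphic(
                P, A, edge_match=lambda a, b: True
            ) or (P.number_of_nodes() == A.number_of_nodes()
                  and P.number_of_edges() == A.number_of_edges())

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle_and_count_formula(self, seed):
        rng = np.random.default_rng(seed)
        A, B = random_digraph(rng, 5), random_digraph(rng, 5)
        nA, mA = A.number_of_nodes(), A.number_of_edges()
        nB, mB = B.number_of_nodes(), B.number_of_edges()
        C = graph_cartesian(A, B)
        assert sorted((s, t) for s, t, _ in C.edges(keys=True)) == \
            cartesian_oracle(A, B)
        assert C.number_of_edges() == nA * mB + nB * mA
        S = graph_strong(A, B)
        diag = sorted(
            ((vs, ws), (vt, wt))
            for vs, vt, _ in A.edges(keys=True)
            for ws, wt, _ in B.edges(keys=True)
        )
        assert sorted((s, t) for s, t, _ in S.edges(keys=True)) == \
            sorted(cartesian_oracle(A, B) + diag)
        assert S.number_of_edges() == nA * mB + nB * mA + mA * mB

    @pytest.mark.parametrize("seed", range(5))
    def test_cross_check_against_networkx(self, seed):
        # loop-free factors: networkx collapses same-key parallel arcs
        # that self-loops in both factors produce on one product pair
        rng = np.random.default_rng(100 + seed)
        A = random_digraph(rng, 4, loops=False)
        B = random_digraph(rng, 4, loops=False)
        assert nx.is_isomorphic(graph_cartesian(A, B),
                                nx.cartesian_product(A, B))
        assert nx.is_isomorphic(graph_strong(A, B), nx.strong_product(A, B))


class TestLinearCartesian:
    def test_immigration_death_times_migration(self):
        A = CompartmentalModel("imdeath").add_compartment("N")
        A.add_arc(SOURCE, "N", "Lambda").add_arc("N", SINK, "mu*N")
        B = CompartmentalModel(
            "migration2", Naming(explicit={("1",): "X1", ("2",): "X2"})
        )
        B.add_compartment("1").add_compartment("2")
        B.add_arc("1", "2", "rho*X1").add_arc("2", "1", "sigma*X2")
        P = linear_cartesian(A, B)
        assert len(P) == 2 and len(P.arcs) == 6
        expected = {
            ("SOURCE", "N_1"): "Lambda_1",
            ("SOURCE", "N_2"): "Lambda_2",
            ("N_1", "SINK"): "mu_1*N_1",
            ("N_2", "SINK"): "mu_2*N_2",
            ("N_1", "N_2"): "rho_N*N_1",
            ("N_2", "N_1"): "sigma_N*N_2",
        }
        got = {}
        for a in P.arcs:
            s = "SOURCE" if a.source is SOURCE else P.display_name(a.source)
            t = "SINK" if a.target is SINK else P.display_name(a.target)
            got[(s, t)] = a.rate
        assert set(got) == set(expected)
        for key, rate in expected.items():
            assert semantically_equal(got[key], rate), key

    def test_unit_factor_gives_singly_subscripted_copy(self):
        A = CompartmentalModel("chain")
        A.add_compartment("a").add_compartment("b")
        A.add_arc("a", "b", "k*a")
        U = CompartmentalModel("unit").add_compartment("u")
        P = linear_cartesian(A, U)
        assert len(P) == 2 and len(P.arcs) == 1
        assert semantically_equal(P.arcs[0].rate, "k_u*a_u")

    def test_nonlinear_factor_redirected(self, si_model):
        U = CompartmentalModel("unit").add_compartment("u")
        with pytest.raises(NonlinearModelError, match="extended_cartesian"):
            linear_cartesian(si_model, U)

    @pytest.mark.parametrize("seed", range(10))
    def test_kronecker_sum_identity(self, seed):
        # undifferentiated (numeric) rates, no sources: M_P = M_A (+) M_B
        rng = np.random.default_rng(seed)
        A = random_linear_model("a", int(rng.integers(1, 6)), rng)
        B = random_linear_model("b", int(rng.integers(1, 6)), rng)
        P = linear_cartesian(A, B)
        _, MA = linear_parts(ode_system(A))
        _, MB = linear_parts(ode_system(B))
        _, MP = linear_parts(ode_system(P))
        MA, MB, MP = (np.array(m, dtype=float) for m in (MA, MB, MP))
        kron_sum = np.kron(MA, np.eye(len(MB))) + np.kron(np.eye(len(MA)), MB)
        assert np.allclose(MP, kron_sum)


class TestExtendedCartesian:
    def test_watson_structure(self, watson):
        assert len(watson) == 4 and len(watson.arcs) == 6
        s1_to_i1 = [a for a in watson.arcs
                    if a.source == ("S", "N1") and a.target == ("I", "N1")]
        assert len(s1_to_i1) == 2  # own-community and cross-community arcs
        rates = {sp.srepr(a.rate) for a in s1_to_i1}
        assert {sp.srepr(r) for r in (
            sp.Symbol("beta_11") * sp.Symbol("S_1") * sp.Symbol("I_1"),
            sp.Symbol("beta_12") * sp.Symbol("S_1") * sp.Symbol("I_2"),
        )} == rates

    def test_unit_factor(self, si_model):
        U = CompartmentalModel("unit").add_compartment("u")
        P = extended_cartesian(si_model, U)
        assert len(P) == 2 and len(P.arcs) == 2
        assert semantically_equal(
            P.net_flow(("I", "u")), "beta_uu*S_u*I_u - gamma_u*I_u"
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_arc_count_formula_random_factors(self, seed):
        # per factor arc with k interaction args:
        # (levels of other factor) ** (k + 1) product arcs
        rng = np.random.default_rng(seed)
        A = random_epidemic_factor("a", rng)
        B = random_epidemic_factor("b", rng)
        P = extended_cartesian(A, B)
        assert len(P) == len(A) * len(B)
        expected = sum(len(B) ** (1 + len(arc.args)) for arc in A.arcs)
        expected += sum(len(A) ** (1 + len(arc.args)) for arc in B.arcs)
        assert len(P.arcs) == expected

    def test_commutativity_up_to_tuple_swap(self):
        A, B = zoo.si_factor(), zoo.community_factor(2)
        assert is_isomorphic(extended_cartesian(A, B),
                             extended_cartesian(B, A), permutation=(1, 0))

    def test_inclusion_predicate_filters_arcs(self):
        # keep only same-community interactions: recovers the naive product
        rule = ProductRule(
            inclusion_predicate=lambda ctx:
                all(z[1] == ctx.anchor[1] for z in ctx.assignment)
        )
        P = extended_cartesian(zoo.si_factor(), zoo.community_factor(2), rule)
        assert len(P.arcs) == 4  # 2 transmissions + 2 removals


class TestStrongProduct:
    def test_two_strain_diagonal_co_transmission(self, two_strain):
        diag = [a for a in two_strain.arcs
                if a.source == ("S", "S") and a.target == ("I", "I")]
        assert len(diag) == 1
        assert len(two_strain.arcs) == 13

    def test_interaction_with_dual_infective_has_three_arcs(self, two_strain):
        arcs = [
            a for a in two_strain.arcs
            for p in a.provenance
            if p.anchor == ("S", "S") and ("I", "I") in p.assignment
        ]
        assert len(arcs) == 3
        targets = {a.target for a in arcs}
        assert targets == {("I", "S"), ("S", "I"), ("I", "I")}

    def test_no_transmission_with_recovery_combinations(self, two_strain):
        for a in two_strain.arcs:
            for p in a.provenance:
                if len(p.factor_arcs) > 1:
                    # all admitted simultaneous sets are transmission-only
                    assert a.args, "combined arc without interaction args"
                    assert a.target == ("I", "I")

    def test_strong_contains_cartesian_exactly(self):
        A = zoo.sis_closed_factor()
        rule = ProductRule(aggregate_scope="global")
        cart = extended_cartesian(A, zoo.sis_closed_factor(), rule)
        strong = strong_product(A, zoo.sis_closed_factor(), rule)
        cart_keys = sorted(
            (str(a.source), str(a.target), sp.srepr(a.rate)) for a in cart.arcs
        )
        singleton = sorted(
            (str(a.source), str(a.target), sp.srepr(a.rate))
            for a in strong.arcs
            if all(len(p.factor_arcs) == 1 for p in a.provenance)
        )
        assert cart_keys == singleton


class TestNaryAndFamilies:
    def test_four_factor_gonorrhea_size(self):
        assert len(zoo.build("gonorrhea_full")) == 16

    def test_single_factor_product_is_the_model(self, si_model):
        P = n_ary_product([si_model])
        assert P.structurally_equal(si_model)

    @pytest.mark.parametrize("seed", range(10))
    def test_fold_order_and_factor_order_isomorphism(self, seed):
        rng = np.random.default_rng(seed)
        A = random_epidemic_factor("a", rng)
        B = random_epidemic_factor("b", rng)
        C = random_epidemic_factor("c", rng)
        direct = n_ary_product([A, B, C])
        left = n_ary_product([extended_cartesian(A, B), C])
        right = n_ary_product([A, extended_cartesian(B, C)])
        assert is_isomorphic(direct, left)
        assert is_isomorphic(direct, right)
        swapped = n_ary_product([B, A, C])
        assert is_isomorphic(direct, swapped, permutation=(1, 0, 2))

    def test_partial_product_family(self):
        base, *factors = zoo._gonorrhea_factors()
        fam = enumerate_partial_products(base, factors)
        assert len(fam) == 8
        sizes = [len(m) for m in fam]
        # compartment count = 2 * prod(subset factor sizes)
        expected = []
        for mask in range(8):
            p = 2
            for i in range(3):
                if mask >> i & 1:
                    p *= len(factors[i])
            expected.append(p)
        assert sizes == expected

    def test_no_optional_factors_gives_base_only(self, si_model):
        fam = enumerate_partial_products(si_model, [])
        assert len(fam) == 1 and fam[0].structurally_equal(si_model)
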