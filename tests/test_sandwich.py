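"""The sandwich solver: building blocks, witnesses, oracle agreement,
minimum-duplication search."""

import itertools
from random import Random

import pytest

from orthosandwich import (
    CapExceededError,
    ConstraintGraph,
    SimulationConfig,
    ValidationError,
    coloring_reduction,
    dstree_consistent_with,
    exact_min_dup,
    find_induced_p4,
    fixture_species_tree_pair,
    g_of,
    graph_consistent_with,
    is_satisfiable,
    oracle_chromatic_number,
    oracle_feasible,
    oracle_min_duplications,
    orthology_edges,
    planted_instance,
    reduction_rule_1,
    solve,
    solve_with_species_tree,
    species_graph,
)
from orthosandwich.core_model import Triplet, pair
from orthosandwich.generate import enumerate_binary_trees
from tests.conftest import random_constraint_graph


def assert_sound(result, graph):
    """The five witness invariants of a feasible answer."""
    assert graph.mandatory <= result.edges <= graph.mandatory_or_unknown
    assert find_induced_p4(graph.genes, result.edges) is None
    cert = graph_consistent_with(
        genes=graph.genes, edges=result.edges, assignment=graph.assignment,
        species_tree=result.species_tree,
    )
    assert cert.consistent
    assert orthology_edges(result.ds_tree) == result.edges
    assert dstree_consistent_with(result.ds_tree, graph.assignment, result.species_tree)


class TestBuildingBlocks:
    def test_g_of(self, worked_graph):
        assert g_of(worked_graph, ()) == worked_graph.mandatory
        assert g_of(worked_graph, worked_graph.unknown) == worked_graph.mandatory_or_unknown
        with pytest.raises(ValidationError):
            g_of(worked_graph, {("a1", "b1")})  # mandatory, not unknown

    def test_worked_example_mandatory_components(self, worked_graph):
        from orthosandwich.sandwich import _mandatory_components

        comps = _mandatory_components(worked_graph)
        assert sorted(map(tuple, comps)) == [
            ("a1", "b1", "c1", "d1"), ("a2", "b2", "c2", "d2")
        ]

    def test_reduction_rule_removes_bridge(self, worked_graph):
        reduced, removed = reduction_rule_1(worked_graph)
        assert removed == {pair("d1", "a2")}
        assert reduced.unknown == {pair("a1", "d1")}
        again, removed2 = reduction_rule_1(reduced)
        assert removed2 == frozenset() and again.unknown == reduced.unknown

    def test_reduction_noop_when_connected(self):
        g = ConstraintGraph.create(
            ["x", "y", "z"], [("x", "y"), ("y", "z")], [("x", "z")],
            {"x": "A", "y": "B", "z": "C"},
        )
        _, removed = reduction_rule_1(g)
        assert removed == frozenset()

    def test_species_graph_worked_example(self, worked_graph):
        reduced, _ = reduction_rule_1(worked_graph)
        h = species_graph(reduced)
        assert h.edges == {pair("A", "C"), pair("B", "D")}
        assert h.species == {"A", "B", "C", "D"}

    def test_species_graph_known_triplet_adds_edge(self, worked_graph):
        reduced, _ = reduction_rule_1(worked_graph)
        h = species_graph(reduced, [Triplet("A", "B", "C")])
        assert pair("A", "B") in h.edges
        # triplet over an absent species contributes nothing
        h2 = species_graph(reduced, [Triplet("A", "Z", "C")])
        assert pair("A", "Z") not in h2.edges

    def test_no_within_component_nonedge_gives_empty_species_graph(self):
        g = ConstraintGraph.create(
            ["x", "y"], [], [("x", "y")], {"x": "A", "y": "B"}
        )
        assert species_graph(g).edges == frozenset()


class TestSolve:
    def test_worked_example_facts(self, worked_graph):
        res = solve(worked_graph)
        assert res.feasible
        assert res.stats.removed_unknown == {pair("d1", "a2")}
        assert res.stats.first_split == (
            ("a1", "a2", "c1", "c2"), ("b1", "b2", "d1", "d2")
        )
        assert_sound(res, worked_graph)

    def test_mandatory_p4_infeasible(self):
        g = ConstraintGraph.create(
            list("wxyz"), [("w", "x"), ("x", "y"), ("y", "z")], [],
            {"w": "A", "x": "B", "y": "C", "z": "D"},
        )
        res = solve(g)
        assert not res.feasible
        cert = res.certificate
        assert cert is not None and cert.genes == frozenset("wxyz")
        # the brute-force oracle confirms the infeasibility certificate
        assert not oracle_feasible(g)

    def test_degenerate_inputs(self):
        empty = ConstraintGraph.create([], [], [], {})
        assert solve(empty).feasible
        one_species = ConstraintGraph.create(
            ["x", "y"], [], [], {"x": "A", "y": "A"}
        )
        res = solve(one_species)
        assert res.feasible and res.edges == frozenset()
        assert res.ds_tree is not None
        assert orthology_edges(res.ds_tree) == frozenset()

    def test_planted_instances_feasible_and_sound(self):
        for seed in range(60):
            cfg = SimulationConfig(
                n_species=3 + seed % 6,
                p_unknown=(0.0, 0.3, 0.7, 1.0)[seed % 4],
                seed=seed,
                max_genes=40,
            )
            inst = planted_instance(cfg)
            res = solve(inst.constraint)
            assert res.feasible
            assert_sound(res, inst.constraint)

    def test_matches_oracle_on_random_instances(self):
        rng = Random(17)
        for i in range(400):
            g = random_constraint_graph(rng, rng.randint(3, 7), rng.randint(2, 4),
                                        max_unknown=10)
            assert solve(g).feasible == oracle_feasible(g), i

    def test_monotonicity_of_infeasibility(self):
        """Freezing an unknown pair (either way) never repairs infeasibility."""
        rng = Random(23)
        checked = 0
        for _ in range(300):
            g = random_constraint_graph(rng, rng.randint(4, 7), rng.randint(2, 3),
                                        p_mandatory=0.45, max_unknown=8)
            if solve(g).feasible or not g.unknown:
                continue
            checked += 1
            victim = sorted(g.unknown)[rng.randrange(len(g.unknown))]
            remaining = g.unknown - {victim}
            tightened = ConstraintGraph.create(
                g.genes, g.mandatory | {victim}, remaining, g.assignment
            )
            dropped = g.with_unknown(remaining)
            assert not solve(tightened).feasible
            assert not solve(dropped).feasible
        assert checked >= 20


class TestSolveWithSpeciesTree:
    def test_species_tree_pair_resolutions(self, worked_graph):
        tree_a, tree_b = fixture_species_tree_pair()
        res_b = solve_with_species_tree(worked_graph, tree_b)
        assert res_b.feasible
        assert_sound(res_b, worked_graph)
        assert not solve_with_species_tree(worked_graph, tree_a).feasible

    def test_two_species_reduces_to_plain_solve(self):
        rng = Random(31)
        from orthosandwich.core_model import parse_newick

        s = parse_newick("(P0,P1);")
        for _ in range(50):
            g = random_constraint_graph(rng, rng.randint(2, 6), 2, max_unknown=8)
            if len(g.sigma) < 2:
                continue
            assert solve_with_species_tree(g, s).feasible == solve(g).feasible

    def test_matches_oracle_on_random_instances(self):
        rng = Random(37)
        for i in range(300):
            g = random_constraint_graph(rng, rng.randint(3, 7), rng.randint(2, 4),
                                        max_unknown=10)
            trees = list(enumerate_binary_trees(sorted(g.sigma)))
            s = trees[rng.randrange(len(trees))]
            got = solve_with_species_tree(g, s)
            assert got.feasible == oracle_feasible(g, s), i
            if got.feasible:
                assert_sound(got, g)
                # the DS-tree is consistent with the *given* tree
                assert dstree_consistent_with(got.ds_tree, g.assignment, s)


class TestSatisfiable:
    def test_p4_in_mandatory(self):
        g = ConstraintGraph.create(
            list("wxyz"), [("w", "x"), ("x", "y"), ("y", "z")], [],
            {"w": "A", "x": "B", "y": "C", "z": "D"},
        )
        assert not is_satisfiable(g).feasible

    def test_empty_mandatory_always_satisfiable(self):
        rng = Random(41)
        for _ in range(30):
            g = random_constraint_graph(rng, rng.randint(2, 6), rng.randint(2, 4),
                                        p_mandatory=0.0, p_unknown=0.5)
            res = is_satisfiable(g)
            assert res.feasible

    def test_matches_cograph_sandwich_bruteforce(self):
        from orthosandwich.generate import _contains_p4

        rng = Random(43)
        for i in range(200):
            g = random_constraint_graph(rng, rng.randint(3, 6), 6,
                                        p_mandatory=0.4, p_unknown=0.2)
            want = any(
                not _contains_p4(sorted(g.genes), g.mandatory | frozenset(chosen))
                for r in range(len(g.unknown) + 1)
                for chosen in itertools.combinations(sorted(g.unknown), r)
            )
            res = is_satisfiable(g)
            assert res.feasible == want, i
            if res.feasible:
                assert g.mandatory <= res.edges <= g.mandatory_or_unknown
                assert orthology_edges(res.ds_tree) == res.edges


class TestExactMinDup:
    def test_worked_reduction_all_modes(self, coloring_example):
        _, _, reduction = coloring_example
        for mode in ("any", "consistent"):
            res = exact_min_dup(reduction, mode)
            assert res.feasible and res.duplications == 2
        from orthosandwich.generate import random_species_tree

        s = random_species_tree(6, 0, labels=sorted(reduction.sigma))
        res = exact_min_dup(reduction, "given_tree", species_tree=s)
        assert res.duplications == 2

    def test_disjoint_cliques(self):
        genes = ["a1", "b1", "c2", "d2", "e3"]
        asg = {"a1": "A", "b1": "B", "c2": "C", "d2": "D", "e3": "E"}
        edges = [("a1", "b1"), ("c2", "d2")]
        g = ConstraintGraph.create(genes, edges, [], asg)
        res = exact_min_dup(g, "any")
        assert res.duplications == 2  # three cliques -> two unions

    def test_cap_refusal(self):
        genes = [f"g{j}" for j in range(13)]
        g = ConstraintGraph.create(genes, [], [], {x: f"P{j}" for j, x in enumerate(genes)})
        with pytest.raises(CapExceededError):
            exact_min_dup(g, "any", max_genes=12)

    def test_infeasible_when_mandatory_p4(self):
        g = ConstraintGraph.create(
            list("wxyz"), [("w", "x"), ("x", "y"), ("y", "z")], [],
            {"w": "A", "x": "B", "y": "C", "z": "D"},
        )
        for mode in ("any", "consistent"):
            res = exact_min_dup(g, mode)
            assert not res.feasible and res.duplications is None

    def test_matches_sandwich_shape_enumeration(self):
        """DP result equals brute force over all sandwiches x all binary
        DS-tree shapes on small instances."""
        rng = Random(47)
        for i in range(40):
            g = random_constraint_graph(rng, rng.randint(2, 6), 6,
                                        p_mandatory=0.35, p_unknown=0.3)
            best = None
            for r in range(len(g.unknown) + 1):
                for chosen in itertools.combinations(sorted(g.unknown), r):
                    k = oracle_min_duplications(
                        g.genes, g.mandatory | frozenset(chosen)
                    )
                    if k is not None and (best is None or k < best):
                        best = k
            res = exact_min_dup(g, "any")
            assert res.duplications == best, i
            if res.feasible:
                assert g.mandatory <= res.edges <= g.mandatory_or_unknown

    def test_coloring_reduction_identity_sample(self):
        import networkx as nx

        rng = Random(53)
        for _ in range(25):
            n = rng.randint(4, 7)
            while True:
                g0 = nx.gnp_random_graph(n, 0.5, seed=rng.randrange(10**6))
                if nx.is_connected(g0):
                    break
            nodes = [f"v{j}" for j in range(n)]
            edges = [(nodes[a], nodes[b]) for a, b in g0.edges]
            reduction = coloring_reduction(nodes, edges)
            chi = oracle_chromatic_number(nodes, edges)
            assert exact_min_dup(reduction, "any").duplications == chi - 1
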