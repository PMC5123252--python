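"""Triplet extraction, BUILD, consistency characterizations, discordance."""

import itertools
from random import Random

import pytest

from orthosandwich import (
    ConstraintGraph,
    SimulationConfig,
    Triplet,
    TripletsIncompatibleError,
    ValidationError,
    build_tree,
    displays,
    dstree_consistent_with,
    fixture_worked_example,
    fixture_species_tree_pair,
    graph_consistent_with,
    p3_triplets,
    parse_newick,
    planted_instance,
    solve_with_species_tree,
    tr_triplets,
    tree_triplets,
    triplet_conflict_ratio,
)
from orthosandwich.generate import enumerate_binary_trees
from orthosandwich.triplets import binary_refinement


class TestDisplays:
    def test_basic(self):
        t = parse_newick("((A,B),(C,D));")
        assert displays(t, Triplet("A", "B", "C"))
        assert not displays(t, Triplet("A", "C", "B"))

    def test_star_displays_nothing(self):
        star = parse_newick("(A,B,C);")
        for t in (Triplet("A", "B", "C"), Triplet("A", "C", "B"), Triplet("B", "C", "A")):
            assert not displays(star, t)

    def test_resolutions_mutually_exclusive(self):
        for nwk in ("((A,B),C);", "((A,C),B);", "((B,C),A);", "(A,B,C);"):
            t = parse_newick(nwk)
            shown = [
                tr
                for tr in (
                    Triplet("A", "B", "C"),
                    Triplet("A", "C", "B"),
                    Triplet("B", "C", "A"),
                )
                if displays(t, tr)
            ]
            assert len(shown) <= 1

    def test_missing_label_raises(self):
        with pytest.raises(ValidationError):
            displays(parse_newick("(A,B);"), Triplet("A", "B", "Z"))


class TestP3:
    def test_path_gives_one_triplet(self):
        trips = p3_triplets(
            genes=["x", "z", "y"],
            edges=[("x", "z"), ("z", "y")],
            assignment={"x": "A", "z": "C", "y": "B"},
        )
        assert trips == {Triplet("A", "B", "C")}

    def test_disjoint_cliques_give_nothing(self):
        genes = ["a1", "b1", "c2", "d2"]
        edges = [("a1", "b1"), ("c2", "d2")]
        asg = {"a1": "A", "b1": "B", "c2": "C", "d2": "D"}
        assert p3_triplets(genes=genes, edges=edges, assignment=asg) == frozenset()

    def test_same_species_endpoints_filtered(self):
        trips = p3_triplets(
            genes=["x", "z", "y"],
            edges=[("x", "z"), ("z", "y")],
            assignment={"x": "A", "z": "C", "y": "A"},
        )
        assert trips == frozenset()


class TestTr:
    def test_spec_root_three_leaves(self):
        asg = {"a": "A", "b": "B", "c": "C"}
        t = parse_newick("((a,b)S,c)S;")
        assert tr_triplets(t, asg) == {Triplet("A", "B", "C")}

    def test_inner_dup_does_not_block_spec_root(self):
        asg = {"a": "A", "b": "B", "c": "C"}
        t = parse_newick("((a,b)D,c)S;")
        assert tr_triplets(t, asg) == {Triplet("A", "B", "C")}

    def test_all_dup_tree_empty(self):
        asg = {"a": "A", "b": "B", "c": "C"}
        t = parse_newick("((a,b)D,c)D;")
        assert tr_triplets(t, asg) == frozenset()

    def test_p3_refines_tr_on_simulated_histories(self):
        for seed in range(25):
            inst = planted_instance(SimulationConfig(n_species=5, seed=seed, p_unknown=0))
            g = inst.constraint
            p3 = p3_triplets(g)
            tr = tr_triplets(inst.ds_tree, g.assignment)
            assert p3 <= tr
            assert all(displays(inst.species_tree, t) for t in tr)


class TestBuild:
    def test_two_cherries(self):
        t = build_tree(
            [Triplet("A", "B", "C"), Triplet("C", "D", "A")], "ABCD"
        )
        assert t.topology_key() == parse_newick("((A,B),(C,D));").topology_key()

    def test_contradiction_fails(self):
        with pytest.raises(TripletsIncompatibleError):
            build_tree([Triplet("A", "B", "C"), Triplet("A", "C", "B")], "ABC")

    def test_no_triplets_gives_star(self):
        t = build_tree([], "ABC")
        assert t.root.label is None
        assert len(t.root.children) == 3

    def test_output_displays_inputs_and_matches_enumeration_oracle(self):
        """On random small triplet sets, BUILD succeeds exactly when some
        binary tree displays the whole set, and its output displays it."""
        rng = Random(11)
        labels = list("ABCDE")
        universe = [
            Triplet(a, b, c)
            for a, b, c in itertools.permutations(labels, 3)
            if a < b
        ]
        trees = list(enumerate_binary_trees(labels))
        for _ in range(120):
            sub = [t for t in universe if rng.random() < 0.12]
            want = any(all(displays(s, t) for t in sub) for s in trees)
            try:
                out = build_tree(sub, labels)
                assert all(displays(out, t) for t in sub)
                got = True
            except TripletsIncompatibleError:
                got = False
            assert got == want

    def test_binary_refinement_keeps_triplets(self):
        t = build_tree([Triplet("A", "B", "E")], "ABCDE")
        r = binary_refinement(t)
        assert r.is_binary
        assert tree_triplets(t) <= tree_triplets(r)


class TestGraphConsistency:
    def test_disjoint_cliques_consistent_with_any_tree(self):
        genes = ["a1", "b1", "c2", "d2"]
        edges = [("a1", "b1"), ("c2", "d2")]
        asg = {"a1": "A", "b1": "B", "c2": "C", "d2": "D"}
        for s in enumerate_binary_trees("ABCD"):
            cert = graph_consistent_with(
                genes=genes, edges=edges, assignment=asg, species_tree=s
            )
            assert cert.consistent

    def test_path_yields_triplet_certificate(self):
        cert = graph_consistent_with(
            genes=["x", "z", "y"],
            edges=[("x", "z"), ("z", "y")],
            assignment={"x": "A", "z": "C", "y": "B"},
            species_tree=parse_newick("((A,C),(B,D));"),
        )
        assert not cert.consistent
        assert cert.triplet == Triplet("A", "B", "C")

    def test_p4_yields_p4_certificate(self):
        cert = graph_consistent_with(
            genes=list("wxyz"),
            edges=[("w", "x"), ("x", "y"), ("y", "z")],
            assignment={"w": "A", "x": "B", "y": "C", "z": "D"},
            species_tree=parse_newick("((A,B),(C,D));"),
        )
        assert not cert.consistent and cert.p4 is not None

    def test_heredity_of_consistency(self):
        """Consistency is inherited by induced subgraphs and restricted trees."""
        rng = Random(4)
        for seed in range(15):
            inst = planted_instance(
                SimulationConfig(n_species=5, seed=seed, p_unknown=0, max_genes=16)
            )
            g = inst.constraint
            full = graph_consistent_with(
                genes=g.genes, edges=g.mandatory, assignment=g.assignment,
                species_tree=inst.species_tree,
            )
            assert full.consistent
            subset = sorted(x for x in g.genes if rng.random() < 0.6)
            if not subset:
                continue
            sub = g.induced(subset)
            sp = sub.sigma
            cert = graph_consistent_with(
                genes=sub.genes, edges=sub.mandatory, assignment=sub.assignment,
                species_tree=inst.species_tree.restrict(sp),
            )
            assert cert.consistent


class TestDSTreeConsistency:
    def test_worked_uncertain_species_position(self):
        """The fixture constraint graph admits a consistent history for one
        resolution of the species tree but not the other."""
        tree_a, tree_b = fixture_species_tree_pair()
        g = fixture_worked_example()
        res_b = solve_with_species_tree(g, tree_b)
        assert res_b.feasible
        assert dstree_consistent_with(res_b.ds_tree, g.assignment, tree_b)
        assert not solve_with_species_tree(g, tree_a).feasible

    def test_all_dup_tree_vacuously_consistent(self):
        t = parse_newick("((a,b)D,c)D;")
        asg = {"a": "A", "b": "B", "c": "C"}
        for s in enumerate_binary_trees("ABC"):
            assert dstree_consistent_with(t, asg, s)

    def test_agrees_with_triplet_display_characterization(self):
        from orthosandwich.core_model import Node, RootedTree
        from orthosandwich.generate import random_species_tree

        rng = Random(9)
        for _ in range(150):
            n = rng.randint(3, 7)
            genes = [f"g{j}" for j in range(n)]
            shape = random_species_tree(n, rng.randrange(10**6), labels=genes)

            def relab(node):
                if node.is_leaf:
                    return Node(node.label)
                return Node(rng.choice("DS"), [relab(c) for c in node.children])

            tree = RootedTree(relab(shape.root), canonicalize=False)
            asg = {g: f"P{j}" for j, g in enumerate(genes)}
            trees = list(enumerate_binary_trees(sorted(set(asg.values()))))
            s = trees[rng.randrange(len(trees))]
            definitional = dstree_consistent_with(tree, asg, s)
            by_display = all(displays(s, t) for t in tr_triplets(tree, asg))
            assert definitional == by_display


class TestConflictRatio:
    def test_identical_trees(self):
        s = parse_newick("((A,B),(C,D));")
        assert triplet_conflict_ratio(s, s) == 0.0

    def test_fully_conflicting_resolution(self):
        s = parse_newick("((A,B),(C,D));")
        other = parse_newick("((A,C),(B,D));")
        assert triplet_conflict_ratio(s, other) == 1.0

    def test_star_contradicts_nothing(self):
        s = parse_newick("((A,B),(C,D));")
        star = parse_newick("(A,B,C,D);")
        assert triplet_conflict_ratio(s, star) == 0.0

    def test_partial_overlap(self):
        s = parse_newick("((A,B),(C,D));")
        other = parse_newick("((A,C),B);")  # contradicts AB|C only
        assert triplet_conflict_ratio(s, other) == 0.25
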