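"""Rooted species triplets: extraction, BUILD, and consistency checks.

Two triplet sets drive everything here.  ``tr(T, s)`` collects, from a
DS-tree T, the species triplets s(x)s(y)|s(z) for gene triplets xy|z that T
displays with a speciation node at the top and s(x) ≠ s(y).  ``P3(G, s)``
reads the same information directly off an orthology graph: a path x-z-y with
xy a non-edge forces the species of x and y to diverge from each other before
either diverges from the species of z, yielding s(x)s(y)|s(z).  A graph with
a DS-tree is consistent with a species tree S exactly when S displays every
triplet of P3(G, s).

BUILD is the classical recursive algorithm of Aho, Sagiv, Szymanski and
Ullman: partition the current label set by the components of the graph whose
edges are the cherry pairs of triplets fully contained in the label set;
failure to split certifies that no rooted tree displays the whole set.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .cograph import adjacency, components, find_induced_p4
from .core_model import (
    ConstraintGraph,
    Node,
    OrthoSandwichError,
    Pair,
    RootedTree,
    SpeciesAssignment,
    Triplet,
    ValidationError,
)


class TripletsIncompatibleError(OrthoSandwichError):
    """No rooted tree displays the given triplet set (BUILD failed)."""

    def __init__(self, label_set: frozenset[str]):
        self.label_set = label_set
        super().__init__(
            f"triplets incompatible: BUILD cannot split label set {sorted(label_set)}"
        )


def displays(tree: RootedTree, t: Triplet) -> bool:
    """True iff the tree displays ab|c, i.e. ``T|{a,b,c} = ab|c``.

    Equivalently: c is not below the LCA of a and b.  A star restriction
    displays nothing.
    """
    for lab in (t.a, t.b, t.c):
        if lab not in tree.leaf_labels:
            raise ValidationError(f"label {lab!r} not in tree")
    return t.c not in tree.leafset(tree.lca((t.a, t.b)))


def tree_triplets(tree: RootedTree) -> frozenset[Triplet]:
    """All triplets displayed by a rooted tree."""
    leaves = sorted(tree.leaf_labels)
    out: set[Triplet] = set()
    for i, x in enumerate(leaves):
        for y in leaves[i + 1 :]:
            below = tree.leafset(tree.lca((x, y)))
            for z in leaves:
                if z not in below:
                    out.add(Triplet(x, y, z))
    return frozenset(out)


def p3_triplets(
    graph: ConstraintGraph | None = None,
    *,
    genes: Iterable[str] | None = None,
    edges: Iterable[Pair] | None = None,
    assignment: Mapping[str, str] | SpeciesAssignment | None = None,
) -> frozenset[Triplet]:
    """The set P3(G, s) of species triplets forced by induced paths.

    Accepts either a fully decided :class:`ConstraintGraph` (no unknown
    pairs) or raw ``genes``/``edges``/``assignment``.  For each path x-z-y
    with xy a non-edge and s(x) ≠ s(y), contributes s(x)s(y)|s(z); the
    same-species assumption guarantees all three species are distinct.
    """
    if graph is not None:
        if not graph.is_orthology_graph:
            raise ValidationError("P3 requires a fixed edge set (no unknown pairs)")
        genes, edges, assignment = graph.genes, graph.mandatory, graph.assignment
    if genes is None or edges is None or assignment is None:
        raise ValidationError("p3_triplets needs a graph or genes/edges/assignment")
    edge_set = frozenset(edges)
    adj = adjacency(genes, edge_set)
    out: set[Triplet] = set()
    for z in sorted(adj):
        nbrs = sorted(adj[z])
        for i, x in enumerate(nbrs):
            for y in nbrs[i + 1 :]:
                if y in adj[x]:
                    continue
                sx, sy = assignment[x], assignment[y]
                if sx != sy:
                    out.add(Triplet(sx, sy, assignment[z]))
    return frozenset(out)


def tr_triplets(
    dstree: RootedTree, assignment: Mapping[str, str] | SpeciesAssignment
) -> frozenset[Triplet]:
    """The set tr(T, s): species triplets displayed under a speciation root.

    A gene triplet xy|w displayed by T contributes s(x)s(y)|s(w) when the LCA
    of all three is a speciation node and s(x) ≠ s(y).  (An inner duplication
    below the speciation root does not block the contribution.)  Triples whose
    three species are not pairwise distinct are skipped; for DS-trees whose
    orthology graph respects the same-species assumption none arise.
    """
    leaves = sorted(dstree.leaf_labels)
    out: set[Triplet] = set()
    for i, x in enumerate(leaves):
        for y in leaves[i + 1 :]:
            sx, sy = assignment[x], assignment[y]
            if sx == sy:
                continue
            z = dstree.lca((x, y))
            below = dstree.leafset(z)
            for w in leaves:
                if w in below:
                    continue
                sw = assignment[w]
                if sw == sx or sw == sy:
                    continue
                top = dstree.lca_nodes((z, dstree.node_of(w)))
                if top.label == "S":
                    out.add(Triplet(sx, sy, sw))
    return frozenset(out)


# ---------------------------------------------------------------------------
# BUILD
# ---------------------------------------------------------------------------


def build_tree(triplets: Iterable[Triplet], labels: Iterable[str]) -> RootedTree:
    """The BUILD algorithm: a rooted tree on ``labels`` displaying every
    triplet, or :class:`TripletsIncompatibleError` if none exists.

    Triplets whose three labels are not all inside the current label set are
    vacuously satisfied at that level (standard BUILD semantics).  The result
    may be non-binary; callers needing a binary tree can refine it with
    :func:`binary_refinement`.
    """
    trips = list(triplets)
    label_set = frozenset(labels)
    stray = set().union(*(t.labels for t in trips)) - label_set if trips else set()
    if stray:
        raise ValidationError(f"triplet labels outside label set: {sorted(stray)}")
    if not label_set:
        raise ValidationError("BUILD on an empty label set")

    def rec(current: frozenset[str]) -> Node:
        if len(current) == 1:
            return Node(next(iter(current)))
        active = [t for t in trips if t.labels <= current]
        adj: dict[str, set[str]] = {v: set() for v in current}
        for t in active:
            adj[t.a].add(t.b)
            adj[t.b].add(t.a)
        comps = components(current, adj)
        if len(comps) == 1:
            raise TripletsIncompatibleError(current)
        return Node(None, [rec(frozenset(c)) for c in comps])

    return RootedTree(rec(label_set), canonicalize=False)


def binary_refinement(tree: RootedTree) -> RootedTree:
    """Deterministic (lexicographic caterpillar) refinement to a binary tree.

    Refinement only adds displayed triplets, so every triplet displayed by
    the input is displayed by the output.
    """

    def min_leaf(node: Node) -> str:
        while not node.is_leaf:
            node = min(node.children, key=min_leaf)
        return node.label

    def rec(node: Node) -> Node:
        if node.is_leaf:
            return node
        kids = sorted((rec(c) for c in node.children), key=min_leaf)
        acc = kids[-1]
        for k in reversed(kids[:-1]):
            acc = Node(node.label, (k, acc))
        return acc

    return RootedTree(rec(tree.root), canonicalize=False)


# ---------------------------------------------------------------------------
# Consistency checks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsistencyCertificate:
    """Outcome of a graph-vs-species-tree consistency check.

    On failure exactly one of ``p4`` (an induced path showing the graph has
    no DS-tree at all) or ``triplet`` (a forced species triplet the species
    tree does not display) is set.
    """

    consistent: bool
    p4: tuple[str, str, str, str] | None = None
    triplet: Triplet | None = None


def graph_consistent_with(
    graph: ConstraintGraph | None = None,
    species_tree: RootedTree | None = None,
    *,
    genes: Iterable[str] | None = None,
    edges: Iterable[Pair] | None = None,
    assignment: Mapping[str, str] | SpeciesAssignment | None = None,
) -> ConsistencyCertificate:
    """Decide whether an orthology graph is consistent with a species tree.

    The graph must be P4-free (otherwise no DS-tree exists) and every triplet
    of P3(G, s) must be displayed by S.  A certificate (violating P4 or
    triplet) is always returned on failure.
    """
    if species_tree is None:
        raise ValidationError("a species tree is required")
    if graph is not None:
        if not graph.is_orthology_graph:
            raise ValidationError("consistency check requires a fixed edge set")
        genes, edges, assignment = graph.genes, graph.mandatory, graph.assignment
    if genes is None or edges is None or assignment is None:
        raise ValidationError("needs a graph or genes/edges/assignment")
    genes = frozenset(genes)
    present = {assignment[g] for g in genes}
    missing = present - species_tree.leaf_labels
    if missing:
        raise ValidationError(f"species missing from tree: {sorted(missing)}")
    p4 = find_induced_p4(genes, frozenset(edges))
    if p4 is not None:
        return ConsistencyCertificate(False, p4=p4)
    for t in sorted(p3_triplets(genes=genes, edges=edges, assignment=assignment)):
        if not displays(species_tree, t):
            return ConsistencyCertificate(False, triplet=t)
    return ConsistencyCertificate(True)


def dstree_consistent_with(
    dstree: RootedTree,
    assignment: Mapping[str, str] | SpeciesAssignment,
    species_tree: RootedTree,
) -> bool:
    """Definitional consistency of a DS-tree with a species tree.

    For every speciation node with children x, y, the species-tree LCAs of
    s(leaves(x)) and s(leaves(y)) must be separated (neither an ancestor of
    the other).  Duplication nodes impose nothing; an all-duplication tree is
    vacuously consistent with any species tree.
    """
    present = {assignment[g] for g in dstree.leaf_labels}
    missing = present - species_tree.leaf_labels
    if missing:
        raise ValidationError(f"species missing from tree: {sorted(missing)}")
    for node in dstree.internal_nodes():
        if node.label != "S":
            continue
        anchors = [
            species_tree.lca_nodes(
                species_tree.node_of(assignment[g]) for g in dstree.leafset(child)
            )
            for child in node.children
        ]
        for i, u in enumerate(anchors):
            for v in anchors[i + 1 :]:
                if not species_tree.separated(u, v):
                    return False
    return True


def triplet_conflict_ratio(reference: RootedTree, other: RootedTree) -> float:
    """Fraction of the reference tree's triplets contradicted by ``other``.

    A triplet ab|c of the reference is contradicted when all three labels
    occur in ``other`` and ``other`` displays a different resolution of
    {a, b, c}; unresolved (star) restrictions contradict nothing.  Label set
    of ``other`` must be a subset of the reference's.
    """
    extra = other.leaf_labels - reference.leaf_labels
    if extra:
        raise ValidationError(f"labels not in reference tree: {sorted(extra)}")
    ref_triplets = tree_triplets(reference)
    if not ref_triplets:
        return 0.0
    other_labels = other.leaf_labels
    contradicted = 0
    for t in ref_triplets:
        if not t.labels <= other_labels:
            continue
        if displays(other, t):
            continue
        a, b, c = t.a, t.b, t.c
        if displays(other, Triplet(a, c, b)) or displays(other, Triplet(b, c, a)):
            contradicted += 1
    return contradicted / len(ref_triplets)
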