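"""Cograph recognition, cotrees, DS-tree conversions and duplication counts.

Orthology graphs are exactly the cographs (P4-free graphs): a graph admits a
duplication/speciation-labeled gene tree whose speciation LCAs reproduce its
edges if and only if it contains no induced path on four vertices.  A cotree
represents a cograph with internal labels 0 (disjoint union) and 1 (series
composition); relabeling 0 → duplication and 1 → speciation turns a binary
cotree into a DS-tree.

The recognition here is the quadratic union/co-component recursion, which
doubles as canonical-cotree construction; the problem sizes this package
targets do not need the linear-time modular-decomposition algorithms.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

from .core_model import (
    ConstraintGraph,
    Node,
    OrthoSandwichError,
    Pair,
    RootedTree,
    SpeciesAssignment,
    ValidationError,
    orthology_graph,
    pair,
)


class NotCographError(OrthoSandwichError):
    """Raised when a graph is not a cograph; carries an induced-P4 witness."""

    def __init__(self, witness: tuple[str, str, str, str]):
        self.witness = witness
        a, b, c, d = witness
        super().__init__(f"graph contains an induced P4: {a}-{b}-{c}-{d}")


def adjacency(nodes: Iterable[str], edges: Iterable[Pair]) -> dict[str, set[str]]:
    """Adjacency-set map of a simple undirected graph."""
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for x, y in edges:
        if x == y:
            raise ValidationError(f"self-loop at {x!r}")
        adj[x].add(y)
        adj[y].add(x)
    return adj


def components(vertices: Iterable[str], adj: Mapping[str, set[str]]) -> list[list[str]]:
    """Connected components within ``vertices``, each sorted, ordered by minimum."""
    vs = set(vertices)
    out: list[list[str]] = []
    while vs:
        seed = min(vs)
        comp = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            new = (adj[v] & vs) - comp
            comp |= new
            frontier.extend(new)
        vs -= comp
        out.append(sorted(comp))
    out.sort(key=lambda c: c[0])
    return out


def co_components(vertices: Iterable[str], adj: Mapping[str, set[str]]) -> list[list[str]]:
    """Connected components of the complement graph, without materializing it."""
    vs = set(vertices)
    out: list[list[str]] = []
    remaining = set(vs)
    while remaining:
        seed = min(remaining)
        remaining.discard(seed)
        comp = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            new = remaining - adj[v]
            remaining -= new
            comp |= new
            frontier.extend(new)
        out.append(sorted(comp))
    out.sort(key=lambda c: c[0])
    return out


def find_induced_p4(
    nodes: Iterable[str], edges: Iterable[Pair]
) -> tuple[str, str, str, str] | None:
    """Return vertices (a, b, c, d) inducing a path a-b-c-d, or None.

    None is returned exactly when the graph is a cograph.  The scan walks the
    middle edge bc and looks for private neighbors a of b and d of c with ad a
    non-edge; it is a witness/verification path, not the solver's hot path.
    """
    adj = adjacency(nodes, edges)
    for b in sorted(adj):
        for c in sorted(adj[b]):
            b_only = adj[b] - adj[c] - {c}
            c_only = adj[c] - adj[b] - {b}
            if not b_only or not c_only:
                continue
            for a in sorted(b_only):
                for d in sorted(c_only):
                    if a != d and d not in adj[a]:
                        return (a, b, c, d)
    return None


def canonical_cotree(nodes: Iterable[str], edges: Iterable[Pair]) -> RootedTree:
    """The canonical cotree of a cograph (unique up to child order).

    Recursion: a singleton is a leaf; a disconnected graph is a 0-node over
    its components; a graph with disconnected complement is a 1-node over its
    co-components; anything else contains an induced P4 and raises
    :class:`NotCographError` with a witness.
    """
    adj = adjacency(nodes, edges)
    if not adj:
        raise ValidationError("cotree of an empty vertex set")

    def rec(vs: list[str]) -> Node:
        if len(vs) == 1:
            return Node(vs[0])
        comps = components(vs, adj)
        if len(comps) > 1:
            return Node("0", [rec(c) for c in comps])
        cocomps = co_components(vs, adj)
        if len(cocomps) > 1:
            return Node("1", [rec(c) for c in cocomps])
        vset = set(vs)
        witness = find_induced_p4(
            vs, [pair(x, y) for x in vs for y in adj[x] if x < y and y in vset]
        )
        assert witness is not None
        raise NotCographError(witness)

    return RootedTree(rec(sorted(adj)), canonicalize=False)


def is_cograph(nodes: Iterable[str], edges: Iterable[Pair]) -> bool:
    try:
        canonical_cotree(nodes, edges)
        return True
    except NotCographError:
        return False


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


def _caterpillar(label: str | None, kids: list[Node]) -> Node:
    """Fold children into a right-leaning caterpillar of same-labeled nodes,
    in lexicographic order of each subtree's smallest leaf."""

    def min_leaf(node: Node) -> str:
        while not node.is_leaf:
            node = min(node.children, key=min_leaf_key)
        return node.label

    def min_leaf_key(node: Node) -> str:
        return min_leaf(node)

    ordered = sorted(kids, key=min_leaf_key)
    acc = ordered[-1]
    for k in reversed(ordered[:-1]):
        acc = Node(label, (k, acc))
    return acc


class GuidedBinarizationError(OrthoSandwichError):
    """A series node cannot be split along the guide species tree.

    Surfaces when a child of a 1-node spans both arms of the guide at the
    relevant level, which certifies that no binarization of that cotree is
    consistent with the guide.
    """


def binarize_cotree(
    cotree: RootedTree,
    assignment: SpeciesAssignment | None = None,
    guide: RootedTree | None = None,
    strict_guide: bool = False,
) -> RootedTree:
    """Expand every node with more than two children into binary nodes.

    The represented graph is unchanged (contracting same-label arcs recovers
    the input).  Without a guide, children are folded lexicographically.  With
    a ``guide`` species tree and an ``assignment``, children of 1-nodes are
    merged following the guide's topology over the children's species sets:
    children falling under the same guide subtree are joined first, which is
    what makes the resulting DS-tree satisfy the speciation-separation
    condition whenever the represented graph is consistent with the guide.
    With ``strict_guide=True``, an unsplittable series node raises
    :class:`GuidedBinarizationError` instead of falling back to the
    lexicographic order.
    """
    if guide is not None and assignment is None:
        raise ValidationError("guided binarization requires a species assignment")

    def species_of(node: Node, cache: dict) -> frozenset[str]:
        got = cache.get(id(node))
        if got is not None:
            return got
        if node.is_leaf:
            res = frozenset((assignment[node.label],))
        else:
            acc: set[str] = set()
            for c in node.children:
                acc |= species_of(c, cache)
            res = frozenset(acc)
        cache[id(node)] = res
        return res

    spcache: dict = {}

    def join_series(kids: list[Node]) -> Node:
        if len(kids) == 1:
            return kids[0]
        all_species = frozenset().union(*(species_of(k, spcache) for k in kids))
        top = guide.lca(all_species)
        groups: list[list[Node]] = [[] for _ in top.children]
        spanning: list[Node] = []
        for k in kids:
            sp = species_of(k, spcache)
            for i, arm in enumerate(top.children):
                if sp <= guide.leafset(arm):
                    groups[i].append(k)
                    break
            else:
                spanning.append(k)
        nonempty = [g for g in groups if g]
        if spanning or len(nonempty) < 2:
            if strict_guide:
                raise GuidedBinarizationError(
                    "series node spans both sides of the guide species tree"
                )
            return _caterpillar("1", kids)
        arm_trees = [join_series(g) for g in nonempty]
        # binary guide => exactly two arms; fold defensively otherwise
        acc = arm_trees[-1]
        for t in reversed(arm_trees[:-1]):
            acc = Node("1", (t, acc))
        return acc

    def rec(node: Node) -> Node:
        if node.is_leaf:
            return node
        kids = [rec(c) for c in node.children]
        if len(kids) == 2:
            return Node(node.label, kids)
        if node.label == "1" and guide is not None:
            return join_series(kids)
        return _caterpillar(node.label, kids)

    return RootedTree(rec(cotree.root), canonicalize=False)


def contract_same_label(tree: RootedTree) -> RootedTree:
    """Contract arcs whose endpoints carry the same internal label.

    Inverse of binarization: recovers the canonical cotree from a binarized
    one.
    """

    def rec(node: Node) -> Node:
        if node.is_leaf:
            return node
        kids: list[Node] = []
        for c in node.children:
            r = rec(c)
            if not r.is_leaf and r.label == node.label:
                kids.extend(r.children)
            else:
                kids.append(r)
        return Node(node.label, kids)

    return RootedTree(rec(tree.root), canonicalize=False)


# ---------------------------------------------------------------------------
# Cotree <-> DS-tree and duplication counting
# ---------------------------------------------------------------------------

_COTREE_TO_DS = {"0": "D", "1": "S"}
_DS_TO_COTREE = {"D": "0", "S": "1"}


def cotree_to_dstree(cotree: RootedTree) -> RootedTree:
    """Relabel a (binary) cotree into a DS-tree: 0 → Dup, 1 → Spec."""
    return cotree.relabel_internal(_COTREE_TO_DS)


def dstree_to_cotree(dstree: RootedTree) -> RootedTree:
    return dstree.relabel_internal(_DS_TO_COTREE)


def _edges_under_label(tree: RootedTree, labels: frozenset[str]) -> frozenset[Pair]:
    edges: set[Pair] = set()

    def rec(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.label]
        parts = [rec(c) for c in node.children]
        if node.label in labels:
            for i, left in enumerate(parts):
                for right in parts[i + 1 :]:
                    for x in left:
                        for y in right:
                            edges.add(pair(x, y))
        return [g for part in parts for g in part]

    rec(tree.root)
    return frozenset(edges)


def orthology_edges(dstree: RootedTree) -> frozenset[Pair]:
    """Edges of the orthology graph of a DS-tree: pairs with a Spec LCA."""
    return _edges_under_label(dstree, frozenset("S"))


def cotree_edges(cotree: RootedTree) -> frozenset[Pair]:
    """Edges of the cograph a cotree represents: pairs with a 1-labeled LCA."""
    return _edges_under_label(cotree, frozenset("1"))


def dstree_to_orthology_graph(
    dstree: RootedTree, assignment: Mapping[str, str] | SpeciesAssignment
) -> ConstraintGraph:
    """The orthology graph of a DS-tree, validated against the assignment."""
    return orthology_graph(dstree.leaf_labels, orthology_edges(dstree), assignment)


def count_duplications(dstree: RootedTree) -> int:
    """Number of internal nodes labeled as duplications."""
    return sum(1 for n in dstree.internal_nodes() if n.label == "D")


def min_duplications_of_cograph(nodes: Iterable[str], edges: Iterable[Pair]) -> int:
    """Minimum duplication count over all binary DS-trees representing a cograph.

    Every binary DS-tree for the graph contracts to the unique canonical
    cotree, and binarizing a d-child union node always costs d-1 duplication
    nodes, so the count Σ over 0-nodes of (children - 1) is an invariant of
    the graph.  (The test suite validates this against exhaustive DS-tree
    enumeration on small vertex sets.)  Raises :class:`NotCographError` on a
    non-cograph.
    """
    cotree = canonical_cotree(nodes, edges)
    return sum(
        len(n.children) - 1 for n in cotree.internal_nodes() if n.label == "0"
    )


def complement_coloring(dstree: RootedTree) -> dict[str, int]:
    """A proper coloring of the complement of the DS-tree's orthology graph.

    Uses at most k+1 colors where k is the duplication count of the (binary)
    DS-tree: below a duplication node the two sides get disjoint palettes
    (they are non-adjacent in the graph, hence cliques-crossing in the
    complement); below a speciation node both sides share one palette (all
    cross pairs are graph edges, i.e. complement non-edges).
    """
    if not dstree.is_binary:
        raise ValidationError("complement_coloring expects a binary DS-tree")

    def rec(node: Node) -> tuple[dict[str, int], int]:
        if node.is_leaf:
            return {node.label: 1}, 1
        (ca, na), (cb, nb) = rec(node.children[0]), rec(node.children[1])
        if node.label == "D":
            merged = dict(ca)
            merged.update({g: c + na for g, c in cb.items()})
            return merged, na + nb
        merged = dict(ca)
        merged.update(cb)
        return merged, max(na, nb)

    coloring, _ = rec(dstree.root)
    return coloring
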