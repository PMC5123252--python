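"""Synthetic instances, in-text worked fixtures, and brute-force oracles.

The simulator plants a solution: a uniform random binary species tree, a
gene history evolved down it with Bernoulli duplications (no losses, no
transfers), and a constraint graph obtained by masking the resulting
orthology graph.  With no relation noise, the true edge set is a sandwich of
the masked graph, so the instance is feasible by construction — this is what
the correctness suites rely on.

The oracles are deliberately naive and capped: feasibility by enumerating
all sandwiches and all binary species trees, minimum duplications by
enumerating all binary DS-tree shapes, chromatic number by backtracking.
They are the ground truth the polynomial solver is validated against, never
a substitute for it.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from random import Random

import networkx as nx

from .cograph import orthology_edges
from .core_model import (
    ConstraintGraph,
    Node,
    OrthoSandwichError,
    Pair,
    RootedTree,
    SpeciesAssignment,
    ValidationError,
    pair,
)
from .triplets import displays, p3_triplets


class SimulationError(OrthoSandwichError):
    """The simulator could not produce an instance within its caps."""


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic instance.

    ``n_species`` species, per-event duplication probability ``dup_prob``,
    masking probability ``p_unknown`` (a pair's relation is withheld), flip
    probability ``p_noise`` (a non-masked relation is inverted, producing
    possibly infeasible instances), and a total gene-count cap with
    resampling.  Identical seeds reproduce identical instances.
    """

    n_species: int = 6
    dup_prob: float = 0.2
    p_unknown: float = 0.3
    p_noise: float = 0.0
    seed: int = 0
    max_genes: int = 50
    min_genes: int = 1

    def __post_init__(self):
        for name in ("dup_prob", "p_unknown", "p_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if not 1 <= self.min_genes <= self.max_genes:
            raise ValidationError("need 1 <= min_genes <= max_genes")


def default_species_labels(m: int) -> list[str]:
    """A, B, ... for small m; S01, S02, ... beyond the alphabet."""
    if m <= 26:
        return [chr(ord("A") + i) for i in range(m)]
    width = len(str(m))
    return [f"S{i + 1:0{width}d}" for i in range(m)]


def random_species_tree(
    m: int, seed: int | Random, labels: list[str] | None = None
) -> RootedTree:
    """A uniform random rooted binary topology on m labeled species.

    Built by sequential random attachment: the k-th leaf is grafted onto one
    of the 2k-3 edges or above the root, each with equal probability, which
    yields every rooted binary topology with probability 1/(2m-3)!!.
    Deterministic for a fixed seed.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    rng = seed if isinstance(seed, Random) else Random(seed)
    labels = list(labels) if labels is not None else default_species_labels(m)
    if len(labels) != m:
        raise ValidationError("need exactly m labels")

    root: list = [labels[0], None, None]  # [label, left, right]
    for lab in labels[1:]:
        # attachment points: the edge above every non-root node, plus a new
        # root above the current one — 2k-1 equiprobable choices in total
        nodes: list[list] = []
        stack = [root]
        while stack:
            nd = stack.pop()
            if nd is not root:
                nodes.append(nd)
            if nd[1] is not None:
                stack.extend((nd[1], nd[2]))
        choice = rng.randrange(len(nodes) + 1)
        new_leaf = [lab, None, None]
        if choice == len(nodes):
            root = [None, root, new_leaf]
        else:
            target = nodes[choice]
            moved = [target[0], target[1], target[2]]
            target[0], target[1], target[2] = None, moved, new_leaf

    def conv(nd: list) -> Node:
        if nd[1] is None:
            return Node(nd[0])
        return Node(None, (conv(nd[1]), conv(nd[2])))

    return RootedTree(conv(root), canonicalize=False)


def simulate_history(
    species_tree: RootedTree, config: SimulationConfig, rng: Random | None = None
) -> tuple[RootedTree, SpeciesAssignment]:
    """Evolve a gene history down a binary species tree.

    A gene lineage entering a species-tree node duplicates with probability
    ``dup_prob`` (a Dup node whose two children re-enter the same node) or
    follows the tree (a Spec node whose children enter the two subtrees; at a
    species leaf the lineage becomes an extant gene).  The resulting DS-tree
    is consistent with the species tree by construction.  Histories breaching
    the gene-count window are resampled.
    """
    if not species_tree.is_binary:
        raise ValidationError("simulation requires a binary species tree")
    rng = rng if rng is not None else Random(config.seed)

    class _TooMany(Exception):
        pass

    for _ in range(10_000):
        counter = {sp: 0 for sp in species_tree.leaf_labels}
        total = [0]
        assignment: dict[str, str] = {}

        nodes = [0]

        def grow(sp_node) -> Node:
            nodes[0] += 1
            # a binary tree on max_genes leaves has < 2*max_genes nodes, and
            # duplications only add leaves further down — so this bound can
            # only trip on histories that would breach the gene cap anyway
            if nodes[0] > 4 * config.max_genes:
                raise _TooMany
            if rng.random() < config.dup_prob:
                return Node("D", (grow(sp_node), grow(sp_node)))
            if sp_node.is_leaf:
                sp = sp_node.label
                counter[sp] += 1
                total[0] += 1
                if total[0] > config.max_genes:
                    raise _TooMany
                gene = f"{sp.lower()}{counter[sp]}"
                assignment[gene] = sp
                return Node(gene)
            return Node("S", tuple(grow(c) for c in sp_node.children))

        try:
            root = grow(species_tree.root)
        except _TooMany:
            continue
        if total[0] < config.min_genes:
            continue
        tree = RootedTree(root, canonicalize=False)
        return tree, SpeciesAssignment(assignment)
    raise SimulationError(
        "could not sample a history within the gene-count window; "
        "loosen min_genes/max_genes or lower dup_prob"
    )


def mask_orthology_graph(
    graph: ConstraintGraph,
    p_unknown: float,
    p_noise: float = 0.0,
    seed: int | Random = 0,
) -> ConstraintGraph:
    """Degrade a full orthology graph into a partial constraint graph.

    Each distinct-species pair independently becomes unknown with probability
    ``p_unknown``; otherwise its relation is flipped with probability
    ``p_noise``.  Same-species pairs stay paralogs (the assumption is never
    violated).  With ``p_noise = 0`` the true edge set remains a sandwich, so
    the masked instance is feasible.
    """
    if not graph.is_orthology_graph:
        raise ValidationError("masking expects a fully decided orthology graph")
    rng = seed if isinstance(seed, Random) else Random(seed)
    s = graph.assignment
    mandatory: list[Pair] = []
    unknown: list[Pair] = []
    for x, y in itertools.combinations(sorted(graph.genes), 2):
        if s[x] == s[y]:
            continue
        p = pair(x, y)
        is_edge = p in graph.mandatory
        if rng.random() < p_unknown:
            unknown.append(p)
            continue
        if p_noise and rng.random() < p_noise:
            is_edge = not is_edge
        if is_edge:
            mandatory.append(p)
    return ConstraintGraph.create(graph.genes, mandatory, unknown, s)


@dataclass(frozen=True)
class PlantedInstance:
    """A masked constraint graph together with its planted ground truth."""

    constraint: ConstraintGraph
    true_edges: frozenset[Pair]
    ds_tree: RootedTree
    species_tree: RootedTree
    assignment: SpeciesAssignment


def planted_instance(config: SimulationConfig) -> PlantedInstance:
    """One synthetic instance: species tree → history → mask."""
    rng = Random(config.seed)
    s_tree = random_species_tree(config.n_species, rng)
    ds, assignment = simulate_history(s_tree, config, rng)
    edges = orthology_edges(ds)
    truth = ConstraintGraph.create(ds.leaf_labels, edges, (), assignment)
    masked = mask_orthology_graph(truth, config.p_unknown, config.p_noise, rng)
    return PlantedInstance(masked, edges, ds, s_tree, assignment)


# ---------------------------------------------------------------------------
# The coloring reduction
# ---------------------------------------------------------------------------


def coloring_reduction(
    nodes: Iterable[str], edges: Iterable[Pair]
) -> ConstraintGraph:
    """Encode graph coloring as duplication minimization.

    From a (connected) graph G0, build the constraint graph with M = ∅,
    U = the complement edges of G0, and one fresh species per vertex.  G0 is
    k-colorable iff the constraint graph admits a sandwich DS-tree with at
    most k-1 duplication nodes, and any optimum is attainable consistently
    with an arbitrary species tree.
    """
    vs = sorted(set(nodes))
    edge_set = frozenset(pair(*e) for e in edges)
    g = nx.Graph()
    g.add_nodes_from(vs)
    g.add_edges_from(edge_set)
    if len(vs) > 1 and not nx.is_connected(g):
        warnings.warn(
            "coloring_reduction: input graph is not connected; the "
            "duplication/chromatic correspondence assumes connectivity",
            stacklevel=2,
        )
    complement = frozenset(
        pair(x, y) for x, y in itertools.combinations(vs, 2) if pair(x, y) not in edge_set
    )
    return ConstraintGraph.create(vs, (), complement, {v: f"sp-{v}" for v in vs})


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


class CapError(OrthoSandwichError):
    """An oracle was invoked beyond its enumeration cap."""


def _contains_p4(vertices: list[str], edge_set: frozenset[Pair]) -> bool:
    """Literal induced-P4 test by quadruple enumeration (oracle-side)."""

    def adjacent(x, y):
        return pair(x, y) in edge_set

    for quad in itertools.combinations(vertices, 4):
        for perm in itertools.permutations(quad):
            a, b, c, d = perm
            if a > d:
                continue  # each path counted once
            if (
                adjacent(a, b)
                and adjacent(b, c)
                and adjacent(c, d)
                and not adjacent(a, c)
                and not adjacent(a, d)
                and not adjacent(b, d)
            ):
                return True
    return False


def enumerate_binary_trees(labels: Iterable[str]):
    """All rooted binary tree topologies on the given labels, as trees.

    (2n-3)!! shapes; deterministic order.  Intended for oracle duty on small
    label sets.
    """
    labs = tuple(sorted(set(labels)))
    if not labs:
        raise ValidationError("no labels")

    def rec(ls: tuple[str, ...]):
        if len(ls) == 1:
            yield Node(ls[0])
            return
        rest = ls[1:]
        for r in range(len(rest)):
            for combo in itertools.combinations(rest, r):
                left = (ls[0],) + combo
                right = tuple(x for x in rest if x not in combo)
                for tl in rec(left):
                    for tr in rec(right):
                        yield Node(None, (tl, tr))

    for root in rec(labs):
        yield RootedTree(root, canonicalize=False)


def oracle_feasible(
    graph: ConstraintGraph,
    species_tree: RootedTree | None = None,
    max_unknown: int = 16,
    max_species: int = 6,
) -> bool:
    """Ground-truth feasibility by double enumeration.

    Iterates every sandwich (each subset of U turned into edges); a sandwich
    counts if it is P4-free and all its forced species triplets are displayed
    by the given species tree (or by some enumerated binary species tree when
    none is given).  Capped; this is the acceptance oracle, not a solver.
    """
    if len(graph.unknown) > max_unknown:
        raise CapError(f"|U| = {len(graph.unknown)} exceeds oracle cap {max_unknown}")
    sigma = sorted(graph.sigma)
    if len(sigma) > max_species:
        raise CapError(f"|Sigma| = {len(sigma)} exceeds oracle cap {max_species}")
    if not graph.genes:
        return True
    genes = sorted(graph.genes)
    unknown = sorted(graph.unknown)
    if species_tree is not None:
        missing = set(sigma) - species_tree.leaf_labels
        if missing:
            raise ValidationError(f"species missing from tree: {sorted(missing)}")
        candidate_trees = [species_tree]
    else:
        candidate_trees = list(enumerate_binary_trees(sigma)) if sigma else []
    for r in range(len(unknown) + 1):
        for chosen in itertools.combinations(unknown, r):
            edge_set = graph.mandatory | frozenset(chosen)
            if _contains_p4(genes, edge_set):
                continue
            trips = p3_triplets(
                genes=genes, edges=edge_set, assignment=graph.assignment
            )
            if not trips:
                return True
            for cand in candidate_trees:
                if all(displays(cand, t) for t in trips):
                    return True
    return False


def _shapes(n: int):
    """All binary tree shapes on leaf indices 0..n-1 as (mask, left, right)
    nested tuples; leaves are (mask, None, None).  Memoized per mask."""
    memo: dict[int, list] = {}

    def rec(mask: int) -> list:
        got = memo.get(mask)
        if got is not None:
            return got
        if mask & (mask - 1) == 0:
            memo[mask] = [(mask, None, None)]
            return memo[mask]
        low = mask & -mask
        out = []
        sub = (mask - 1) & mask
        while sub:
            # requiring the lowest bit on the left visits each unordered
            # split exactly once
            if sub & low:
                other = mask ^ sub
                for left in rec(sub):
                    for right in rec(other):
                        out.append((mask, left, right))
            sub = (sub - 1) & mask
        memo[mask] = out
        return out

    return rec((1 << n) - 1)


def oracle_min_duplications(
    genes: Iterable[str], edges: Iterable[Pair], max_genes: int = 6
) -> int | None:
    """Minimum duplications by literal enumeration of binary DS-trees.

    For every binary tree shape on the gene set, each internal node's label
    is forced by the graph (all cross pairs edges → Spec, none → Dup, mixed →
    the shape represents no DS-tree for this graph); returns the minimum
    duplication count over valid shapes, or None when no shape is valid
    (i.e. the graph is not a cograph).
    """
    gene_list = sorted(set(genes))
    n = len(gene_list)
    if n > max_genes:
        raise CapError(f"{n} genes exceeds oracle cap {max_genes}")
    if n == 0:
        raise ValidationError("empty gene set")
    index = {g: i for i, g in enumerate(gene_list)}
    adj = [0] * n
    for x, y in edges:
        adj[index[x]] |= 1 << index[y]
        adj[index[y]] |= 1 << index[x]

    def bits(mask: int):
        while mask:
            low = mask & -mask
            yield low.bit_length() - 1
            mask ^= low

    def dup_count(shape) -> int | None:
        mask, left, right = shape
        if left is None:
            return 0
        lcount = dup_count(left)
        if lcount is None:
            return None
        rcount = dup_count(right)
        if rcount is None:
            return None
        lmask, rmask = left[0], right[0]
        full = all(adj[i] & rmask == rmask for i in bits(lmask))
        if full:
            return lcount + rcount
        empty = all(adj[i] & rmask == 0 for i in bits(lmask))
        if empty:
            return lcount + rcount + 1
        return None

    best: int | None = None
    for shape in _shapes(n):
        k = dup_count(shape)
        if k is not None and (best is None or k < best):
            best = k
            if best == 0:
                break
    return best


def oracle_chromatic_number(
    nodes: Iterable[str], edges: Iterable[Pair], max_nodes: int = 10
) -> int:
    """Exact chromatic number by backtracking (capped input size)."""
    vs = sorted(set(nodes))
    if len(vs) > max_nodes:
        raise CapError(f"{len(vs)} vertices exceeds oracle cap {max_nodes}")
    if not vs:
        return 0
    adj = {v: set() for v in vs}
    for x, y in edges:
        adj[x].add(y)
        adj[y].add(x)

    def colorable(k: int) -> bool:
        color: dict[str, int] = {}

        def assign(i: int, used: int) -> bool:
            if i == len(vs):
                return True
            v = vs[i]
            banned = {color[u] for u in adj[v] if u in color}
            # break color symmetry: allow at most one brand-new color
            for c in range(1, min(k, used + 1) + 1):
                if c in banned:
                    continue
                color[v] = c
                if assign(i + 1, max(used, c)):
                    return True
                del color[v]
            return False

        return assign(0, 0)

    for k in range(1, len(vs) + 1):
        if colorable(k):
            return k
    raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Worked fixtures
# ---------------------------------------------------------------------------


def fixture_worked_example() -> ConstraintGraph:
    """The eight-gene, four-species worked example.

    Two mandatory-edge components {a1, b1, c1, d1} and {a2, b2, c2, d2}; the
    first has known-paralog pairs a1c1 and b1d1, the second only b2d2; one
    unknown edge d1-a2 bridges the components and is deleted by Reduction
    Rule 1; the species graph then has edge set {AC, BD}.  The exact split of
    the worked example's within-component pairs between mandatory and unknown is a
    documented completion consistent with all of those printed facts.
    """
    species = {
        "a1": "A", "a2": "A",
        "b1": "B", "b2": "B",
        "c1": "C", "c2": "C",
        "d1": "D", "d2": "D",
    }
    mandatory = [
        ("a1", "b1"), ("b1", "c1"), ("c1", "d1"),
        ("a2", "b2"), ("b2", "c2"), ("c2", "d2"), ("a2", "c2"), ("a2", "d2"),
    ]
    unknown = [("a1", "d1"), ("d1", "a2")]
    return ConstraintGraph.create(species.keys(), mandatory, unknown, species)


def fixture_coloring_example() -> tuple[list[str], frozenset[Pair], ConstraintGraph]:
    """The six-vertex coloring-reduction example.

    The plain graph on {a, ..., f} is complete except for the non-adjacent
    pairs {a, e}, {b, f}, {c, d}; its reduction has M = ∅ and U equal to
    exactly those three pairs.  Returns (vertices, edges of the plain graph,
    reduced constraint graph).
    """
    vs = ["a", "b", "c", "d", "e", "f"]
    non_edges = {pair("a", "e"), pair("b", "f"), pair("c", "d")}
    edges = frozenset(
        pair(x, y)
        for x, y in itertools.combinations(vs, 2)
        if pair(x, y) not in non_edges
    )
    return vs, edges, coloring_reduction(vs, edges)


def fixture_species_tree_pair() -> tuple[RootedTree, RootedTree]:
    """Two candidate species trees for the fixture_worked_example graph.

    The first places C with the (A, B) clade and is incompatible with the
    constraint graph (every sandwich forces the triplet AC|B); the second,
    obtained by moving C next to A, is compatible.
    """
    tree_a = RootedTree.from_newick("(((A,B),C),D);")
    tree_b = RootedTree.from_newick("((A,C),(B,D));")
    return tree_a, tree_b


def worked_min_dup_dstree() -> tuple[RootedTree, Mapping[str, str]]:
    """The worked DS-tree over {a..f}: a duplication root over (a,e)S and a
    second duplication over (b,f)S and (c,d)S; two duplication nodes, and the
    partition {a,e}, {b,f}, {c,d} 3-colors the fixture_coloring_example graph."""
    tree = RootedTree.from_newick("((a,e)S,((b,f)S,(c,d)S)D)D;")
    return tree, {v: f"sp-{v}" for v in "abcdef"}
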