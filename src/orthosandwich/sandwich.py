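"""The consistent orthology-graph sandwich solver and exact min-dup oracles.

Given a constraint graph (G = (V, M ⊎ U), s), the solver decides in cubic
time whether some *sandwich* graph H (M ⊆ E(H) ⊆ M ∪ U) together with some
species tree S admits a DS-tree whose orthology graph is H and whose
speciation nodes respect S, and constructs witnesses (H, S, and the DS-tree)
when the answer is yes.

The divide-and-conquer works on the *species graph* H_{G,s}: species a and b
are linked when two genes of a and b sit in the same mandatory-edge component
but are known paralogs — such a pair forces a and b to be split below the
species-tree root on the same side, so a connected species graph over more
than one species certifies infeasibility.  When the species graph is
disconnected, the species set is split along one of its components, all
cross unknown pairs are frozen to orthologs, and the two halves are solved
independently; the species tree is assembled directly from the recursion
(new root over the two halves' trees).

The minimization variants (fewest duplication nodes) are NP-hard even for
two duplications, so the exact solvers here are explicitly small-scale
oracles: a subset-split dynamic program over gene subsets, equivalent to
exhaustive enumeration of all binary DS-trees, with a hard cap on |V|.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable
from dataclasses import dataclass, field

from .cograph import (
    adjacency,
    binarize_cotree,
    canonical_cotree,
    components,
    cotree_to_dstree,
    orthology_edges,
)
from .core_model import (
    ConstraintGraph,
    Node,
    OrthoSandwichError,
    Pair,
    RootedTree,
    Triplet,
    ValidationError,
    pair,
)
from .triplets import graph_consistent_with, tree_triplets


class CapExceededError(OrthoSandwichError):
    """An exact exponential solver was invoked beyond its configured cap."""


class InternalInconsistencyError(OrthoSandwichError):
    """A feasible answer failed its own verification; indicates a defect and
    must be surfaced, never patched silently."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesGraph:
    """The auxiliary species graph H_{G,s} of one recursion step."""

    species: frozenset[str]
    edges: frozenset[Pair]

    def components(self) -> list[list[str]]:
        return components(self.species, adjacency(self.species, self.edges))


@dataclass
class SolveStats:
    """Bookkeeping of one solver run (deterministic given the input)."""

    recursion_nodes: int = 0
    removed_unknown: set[Pair] = field(default_factory=set)
    first_split: tuple[tuple[str, ...], tuple[str, ...]] | None = None


@dataclass(frozen=True)
class InfeasibilityCertificate:
    """Where the recursion failed: the gene subset whose species graph was
    connected over more than one species."""

    genes: frozenset[str]
    species_graph: SpeciesGraph


@dataclass(frozen=True)
class SolveResult:
    """Outcome of the sandwich solver.

    On feasibility, ``edges`` is the sandwich edge set E' with
    M ⊆ E' ⊆ M ∪ U, ``species_tree`` a binary witness species tree built
    during the recursion, and ``ds_tree`` a binary DS-tree whose orthology
    graph is exactly E' and which is consistent with the species tree.
    """

    feasible: bool
    constraint: ConstraintGraph
    edges: frozenset[Pair] | None = None
    species_tree: RootedTree | None = None
    ds_tree: RootedTree | None = None
    certificate: InfeasibilityCertificate | None = None
    stats: SolveStats = field(default_factory=SolveStats)


class _Infeasible(Exception):
    def __init__(self, certificate: InfeasibilityCertificate):
        self.certificate = certificate


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def g_of(graph: ConstraintGraph, frozen: Iterable[Pair]) -> frozenset[Pair]:
    """The edge set of G(F) = (V, M ∪ F) for F ⊆ U."""
    f = frozenset(pair(*p) for p in frozen)
    extra = f - graph.unknown
    if extra:
        raise ValidationError(f"F must be a subset of U; offending pairs: {sorted(extra)}")
    return graph.mandatory | f


def _mandatory_components(graph: ConstraintGraph) -> list[list[str]]:
    """Connected components of G(∅) = (V, M)."""
    return components(graph.genes, adjacency(graph.genes, graph.mandatory))


def reduction_rule_1(graph: ConstraintGraph) -> tuple[ConstraintGraph, frozenset[Pair]]:
    """Freeze to paralogy every unknown pair joining two components of G(∅).

    Returns the reduced graph and the removed pairs; idempotent, preserves
    feasibility.
    """
    comp_id: dict[str, int] = {}
    for i, comp in enumerate(_mandatory_components(graph)):
        for g in comp:
            comp_id[g] = i
    removed = frozenset(p for p in graph.unknown if comp_id[p[0]] != comp_id[p[1]])
    if not removed:
        return graph, removed
    return graph.with_unknown(graph.unknown - removed), removed


def species_graph(
    graph: ConstraintGraph, known: Iterable[Triplet] = ()
) -> SpeciesGraph:
    """Build H_{G,s} for a graph already reduced by Reduction Rule 1.

    Species a, b are adjacent when some same-component gene pair with those
    species is a known paralog pair (not in M ∪ U), or when a known species
    triplet ab|c has all three species present.  Known triplets encode a
    partially known species tree.
    """
    s = graph.assignment
    sigma = graph.sigma
    mu = graph.mandatory_or_unknown
    edges: set[Pair] = set()
    for comp in _mandatory_components(graph):
        for x, y in itertools.combinations(comp, 2):
            if s[x] != s[y] and pair(x, y) not in mu:
                edges.add(pair(s[x], s[y]))
    for t in known:
        if t.a in sigma and t.b in sigma and t.c in sigma:
            edges.add(pair(t.a, t.b))
    return SpeciesGraph(sigma, frozenset(edges))


# ---------------------------------------------------------------------------
# The solver
# ---------------------------------------------------------------------------


def solve(graph: ConstraintGraph, known: Iterable[Triplet] = ()) -> SolveResult:
    """Decide the consistent orthology-graph sandwich problem.

    Recursion: with at most one species present, the same-species assumption
    forces M = U = ∅ and the empty sandwich is trivially consistent.
    Otherwise apply Reduction Rule 1, build the species graph, and fail if it
    is connected; else split the species set along the component containing
    the lexicographically smallest species, freeze cross unknown pairs to
    orthologs, and recurse.  The witness species tree is assembled on the way
    back up (root over the halves' trees); the witness DS-tree is read off
    the canonical cotree of the sandwich, binarized following the species
    tree so that speciation nodes separate their children's species sets.
    """
    known = frozenset(known)
    stats = SolveStats()

    def rec(cg: ConstraintGraph, depth: int) -> tuple[set[Pair], Node | None]:
        stats.recursion_nodes += 1
        sigma = cg.sigma
        if len(sigma) <= 1:
            # Assumption 1 forces M = U = empty here.
            leaf = Node(next(iter(sigma))) if sigma else None
            return set(), leaf
        reduced, removed = reduction_rule_1(cg)
        stats.removed_unknown |= removed
        h = species_graph(reduced, known)
        comps = h.components()
        if len(comps) == 1:
            raise _Infeasible(InfeasibilityCertificate(frozenset(cg.genes), h))
        side_a = set(comps[0])
        genes_a = sorted(g for g in reduced.genes if reduced.assignment[g] in side_a)
        genes_b = sorted(g for g in reduced.genes if reduced.assignment[g] not in side_a)
        if depth == 0:
            stats.first_split = (tuple(genes_a), tuple(genes_b))
        edges_a, tree_a = rec(reduced.induced(genes_a), depth + 1)
        edges_b, tree_b = rec(reduced.induced(genes_b), depth + 1)
        set_a = set(genes_a)
        cross = {
            p
            for p in reduced.mandatory_or_unknown
            if (p[0] in set_a) != (p[1] in set_a)
        }
        assert tree_a is not None and tree_b is not None
        return edges_a | edges_b | cross, Node(None, (tree_a, tree_b))

    try:
        edge_set, species_root = rec(graph, 0)
    except _Infeasible as inf:
        return SolveResult(
            False, graph, certificate=inf.certificate, stats=stats
        )

    edges = frozenset(edge_set)
    if not graph.genes:
        return SolveResult(True, graph, edges=edges, stats=stats)
    s_tree = RootedTree(species_root, canonicalize=False) if species_root else None
    cotree = canonical_cotree(graph.genes, edges)
    ds = cotree_to_dstree(
        binarize_cotree(cotree, assignment=graph.assignment, guide=s_tree)
    )
    return SolveResult(
        True,
        graph,
        edges=edges,
        species_tree=s_tree,
        ds_tree=ds,
        stats=stats,
    )


def solve_with_species_tree(graph: ConstraintGraph, species_tree: RootedTree) -> SolveResult:
    """Sandwich solving when the species tree is (fully) known.

    Runs the recursion with the species graph augmented by every triplet the
    given tree displays over the present species, then verifies the feasible
    answer against the tree (every forced P3 triplet displayed) and rebuilds
    the witness DS-tree guided by the given tree.  A feasible answer that
    fails verification raises :class:`InternalInconsistencyError`.
    """
    if not species_tree.is_binary:
        raise ValidationError("the known species tree must be binary")
    sigma = graph.sigma
    missing = sigma - species_tree.leaf_labels
    if missing:
        raise ValidationError(f"species missing from tree: {sorted(missing)}")
    if len(sigma) >= 3:
        known = tree_triplets(species_tree.restrict(sigma))
    else:
        known = frozenset()
    result = solve(graph, known)
    if not result.feasible:
        return result
    if not graph.genes:
        return result
    cert = graph_consistent_with(
        genes=graph.genes,
        edges=result.edges,
        assignment=graph.assignment,
        species_tree=species_tree,
    )
    if not cert.consistent:
        raise InternalInconsistencyError(
            f"sandwich found but not consistent with the given tree: {cert}"
        )
    restricted = species_tree.restrict(sigma) if sigma else None
    ds = cotree_to_dstree(
        binarize_cotree(
            canonical_cotree(graph.genes, result.edges),
            assignment=graph.assignment,
            guide=restricted,
        )
    )
    return SolveResult(
        True,
        graph,
        edges=result.edges,
        species_tree=restricted,
        ds_tree=ds,
        stats=result.stats,
    )


def is_satisfiable(graph: ConstraintGraph) -> SolveResult:
    """Decide whether some sandwich of the constraint graph is a cograph.

    Reassigning every gene to its own fresh species preserves M, U and the
    same-species assumption while making every species tree vacuously
    agreeable, so consistency of the relabeled instance is equivalent to the
    existence of a cograph sandwich.  The returned DS-tree is a valid DS-tree
    for the sandwich under the original assignment; the species tree of the
    relabeled instance is dropped.
    """
    relabeled = ConstraintGraph.create(
        graph.genes,
        graph.mandatory,
        graph.unknown,
        {g: f"species-of-{g}" for g in graph.genes},
    )
    inner = solve(relabeled)
    return SolveResult(
        inner.feasible,
        graph,
        edges=inner.edges,
        species_tree=None,
        ds_tree=inner.ds_tree,
        certificate=inner.certificate,
        stats=inner.stats,
    )


# ---------------------------------------------------------------------------
# Exact minimum-duplication solvers (exponential, capped)
# ---------------------------------------------------------------------------

MIN_DUP_MODES = ("any", "consistent", "given_tree")

_INF = float("inf")


@dataclass(frozen=True)
class MinDupResult:
    """Outcome of an exact minimum-duplication search."""

    feasible: bool
    duplications: int | None
    constraint: ConstraintGraph
    mode: str
    edges: frozenset[Pair] | None = None
    ds_tree: RootedTree | None = None
    species_tree: RootedTree | None = None


def _enumerate_species_trees(labels: list[str]):
    """All rooted binary tree shapes over ``labels`` (deterministic order)."""

    def rec(ls: tuple[str, ...]):
        if len(ls) == 1:
            yield Node(ls[0])
            return
        rest = ls[1:]
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                left = (ls[0],) + combo
                right = tuple(x for x in rest if x not in combo)
                if not right:
                    continue
                for tl in rec(left):
                    for tr in rec(right):
                        yield Node(None, (tl, tr))

    for root in rec(tuple(sorted(labels))):
        yield RootedTree(root, canonicalize=False)


def _min_dup_dp(
    genes: list[str],
    m_adj: list[int],
    mu_adj: list[int],
    sp_tree: RootedTree | None,
    species: list[str],
):
    """Subset-split DP over gene subsets: the exact minimum duplication count.

    ``best(W)`` minimizes over binary DS-trees on W whose orthology graph is
    a sandwich of G[W]: a speciation root needs every cross pair in M ∪ U
    (frozen to edges) and, when a species tree is imposed, separated LCAs of
    the two sides' species sets; a duplication root needs no cross pair in M
    (frozen to non-edges) and costs one.  Equivalent to exhaustive
    enumeration of all binary DS-trees, memoized.
    """
    n = len(genes)
    full = (1 << n) - 1
    memo: dict[int, tuple[float, tuple[int, str] | None]] = {}

    sep_cache: dict[tuple[int, int], bool] = {}
    sp_lca_cache: dict[int, object] = {}

    def species_lca(mask: int):
        got = sp_lca_cache.get(mask)
        if got is None:
            labels = {species[i] for i in range(n) if mask >> i & 1}
            got = sp_lca_cache[mask] = sp_tree.lca(labels)
        return got

    def separated_masks(a: int, b: int) -> bool:
        key = (a, b) if a < b else (b, a)
        got = sep_cache.get(key)
        if got is None:
            got = sep_cache[key] = sp_tree.separated(species_lca(a), species_lca(b))
        return got

    def bits(mask: int):
        while mask:
            low = mask & -mask
            yield low.bit_length() - 1
            mask ^= low

    def best(mask: int) -> tuple[float, tuple[int, str] | None]:
        got = memo.get(mask)
        if got is not None:
            return got
        if mask & (mask - 1) == 0:
            memo[mask] = (0.0, None)
            return memo[mask]
        low = mask & -mask
        best_cost: float = _INF
        best_choice: tuple[int, str] | None = None
        sub = (mask - 1) & mask
        while sub:
            if sub & low:
                other = mask ^ sub
                spec_ok = all(other & ~mu_adj[i] == 0 for i in bits(sub))
                dup_ok = all(other & m_adj[i] == 0 for i in bits(sub))
                if spec_ok and sp_tree is not None:
                    spec_ok = separated_masks(sub, other)
                if spec_ok or dup_ok:
                    ca, _ = best(sub)
                    cb, _ = best(other)
                    base = ca + cb
                    if spec_ok and base < best_cost:
                        best_cost, best_choice = base, (sub, "S")
                    if dup_ok and base + 1 < best_cost:
                        best_cost, best_choice = base + 1, (sub, "D")
            sub = (sub - 1) & mask
        memo[mask] = (best_cost, best_choice)
        return memo[mask]

    cost, _ = best(full)
    if cost == _INF:
        return None, None

    def build(mask: int) -> Node:
        if mask & (mask - 1) == 0:
            return Node(genes[mask.bit_length() - 1])
        _, choice = memo[mask]
        assert choice is not None
        sub, label = choice
        return Node(label, (build(sub), build(mask ^ sub)))

    return int(cost), RootedTree(build(full), canonicalize=False)


def exact_min_dup(
    graph: ConstraintGraph,
    mode: str = "any",
    species_tree: RootedTree | None = None,
    max_genes: int = 12,
    max_species_for_consistent: int = 8,
) -> MinDupResult:
    """Exact minimum number of duplication nodes over all sandwich DS-trees.

    Modes: ``any`` (just a sandwich DS-tree), ``given_tree`` (the DS-tree
    must additionally be consistent with ``species_tree``), ``consistent``
    (consistent with some species tree, found by enumeration with an early
    exit once the unconstrained optimum is matched).  These problems are
    NP-hard already for two duplications, hence the hard cap on instance
    size: this is an oracle, not a scalable feature.
    """
    if mode not in MIN_DUP_MODES:
        raise ValidationError(f"mode must be one of {MIN_DUP_MODES}")
    genes = sorted(graph.genes)
    n = len(genes)
    if n > max_genes:
        raise CapExceededError(
            f"{n} genes exceeds the exact-solver cap of {max_genes}; "
            "the minimization problems are NP-hard"
        )
    if n == 0:
        raise ValidationError("exact_min_dup on an empty gene set")
    index = {g: i for i, g in enumerate(genes)}
    species = [graph.assignment[g] for g in genes]
    m_adj = [0] * n
    mu_adj = [0] * n
    for x, y in graph.mandatory:
        m_adj[index[x]] |= 1 << index[y]
        m_adj[index[y]] |= 1 << index[x]
    for x, y in graph.mandatory_or_unknown:
        mu_adj[index[x]] |= 1 << index[y]
        mu_adj[index[y]] |= 1 << index[x]

    def finish(k, tree, sp):
        if k is None:
            return MinDupResult(False, None, graph, mode)
        return MinDupResult(
            True, k, graph, mode,
            edges=orthology_edges(tree), ds_tree=tree, species_tree=sp,
        )

    if mode == "any":
        k, tree = _min_dup_dp(genes, m_adj, mu_adj, None, species)
        return finish(k, tree, None)

    sigma = sorted(set(species))
    if mode == "given_tree":
        if species_tree is None:
            raise ValidationError("mode 'given_tree' requires a species tree")
        missing = set(sigma) - species_tree.leaf_labels
        if missing:
            raise ValidationError(f"species missing from tree: {sorted(missing)}")
        guide = species_tree.restrict(sigma)
        k, tree = _min_dup_dp(genes, m_adj, mu_adj, guide, species)
        return finish(k, tree, guide)

    # mode == "consistent": minimize over all binary species trees, with an
    # early exit once the unconstrained lower bound is attained.
    if len(sigma) > max_species_for_consistent:
        raise CapExceededError(
            f"{len(sigma)} species exceeds the species-tree enumeration cap "
            f"of {max_species_for_consistent}"
        )
    k_any, _ = _min_dup_dp(genes, m_adj, mu_adj, None, species)
    if k_any is None:
        return MinDupResult(False, None, graph, mode)
    best_k, best_tree, best_sp = None, None, None
    for cand in _enumerate_species_trees(sigma):
        k, tree = _min_dup_dp(genes, m_adj, mu_adj, cand, species)
        if k is not None and (best_k is None or k < best_k):
            best_k, best_tree, best_sp = k, tree, cand
            if best_k == k_any:
                break
    return finish(best_k, best_tree, best_sp)
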