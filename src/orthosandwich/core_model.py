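"""Domain types and I/O for orthology/paralogy constraint analysis.

The central object is the *constraint graph* ``(G = (V, M ⊎ U), s)``: a set of
homologous genes ``V``, a set ``M`` of gene pairs known to be orthologs
(mandatory edges), a set ``U`` of pairs whose relation is unknown, and a
species assignment ``s`` mapping every gene to the species it belongs to.
Pairs outside ``M ∪ U`` are known paralogs.  In the absence of gene transfers,
two homologous genes from the same species are necessarily paralogs, so a
valid constraint graph never carries an ortholog or unknown edge between two
genes of the same species; violations are rejected, never silently repaired.

Evolutionary histories are *DS-trees*: binary rooted gene trees whose internal
nodes are labeled as duplications (``D``) or speciations (``S``).  Species
trees are rooted trees on species labels, binary on input (triplet-based
reconstruction may return non-binary trees).  Both are represented by
:class:`RootedTree`; DS-tree event labels and cotree 0/1 labels live in the
``label`` slot of internal nodes.

File formats:

* relations TSV with header ``gene_a  gene_b  relation`` where relation is one
  of ``ortholog``, ``paralog``, ``unknown`` (an explicit ``paralog`` row is
  equivalent to the pair being absent);
* species map TSV with header ``gene  species``;
* Newick for trees, branch lengths ignored on read and omitted on write;
  DS-trees use internal labels ``D``/``S``.
"""

from __future__ import annotations

import re
import sys
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import dendropy
import pandas as pd

# Deep caterpillar trees are legitimate inputs; plain recursion is used
# throughout for clarity, so leave headroom on the interpreter stack.
sys.setrecursionlimit(max(sys.getrecursionlimit(), 20_000))

RELATION_VALUES = ("ortholog", "paralog", "unknown")

Pair = tuple[str, str]


class OrthoSandwichError(Exception):
    """Base class for all package errors."""


class ValidationError(OrthoSandwichError):
    """Invalid input data (malformed tables, inconsistent labels, ...)."""


class AssumptionViolation(ValidationError):
    """An ortholog/unknown relation between two genes of the same species.

    Homologous genes from the same species are necessarily paralogs when gene
    transfers are excluded, so such a record contradicts the model.
    """


class ConflictingRecordsError(ValidationError):
    """Two relation rows assign different relations to the same gene pair."""


class NewickError(OrthoSandwichError):
    """Malformed Newick text or duplicate leaf labels."""


def pair(x: str, y: str) -> Pair:
    """Return the canonical (sorted) form of an unordered gene/species pair."""
    if x == y:
        raise ValidationError(f"pair with repeated element: {x!r}")
    return (x, y) if x < y else (y, x)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Node:
    """A tree node: a leaf (no children, leaf label) or an internal node.

    Internal labels are optional and carry event information where relevant
    ("D"/"S" for DS-trees, "0"/"1" for cotrees).  Nodes are treated as
    immutable once placed in a :class:`RootedTree`.
    """

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: Sequence["Node"] = ()):
        self.label = label
        self.children = tuple(children)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.label!r})"
        return f"Node({self.label!r}, {len(self.children)} children)"


def _suppress_unary(node: Node) -> Node:
    """Suppress out-degree-1 nodes (the standard tree canonicalization)."""
    if node.is_leaf:
        return node
    kids = [_suppress_unary(c) for c in node.children]
    if len(kids) == 1:
        return kids[0]
    return Node(node.label, kids)


class RootedTree:
    """A rooted tree with uniquely labeled leaves.

    Construction canonicalizes by suppressing out-degree-1 nodes (unless
    ``canonicalize=False``, for callers that guarantee canonical input) and
    indexes parents, depths and leaf labels for O(depth) LCA queries.
    """

    def __init__(self, root: Node, canonicalize: bool = True):
        if canonicalize:
            root = _suppress_unary(root)
        self.root = root
        self._parent: dict[Node, Node] = {}
        self._depth: dict[Node, int] = {root: 0}
        self._leaf: dict[str, Node] = {}
        self._preorder: list[Node] = []
        stack = [root]
        while stack:
            nd = stack.pop()
            self._preorder.append(nd)
            if nd.is_leaf:
                if nd.label is None:
                    raise ValidationError("leaf without a label")
                if nd.label in self._leaf:
                    raise NewickError(f"duplicate leaf label {nd.label!r}")
                self._leaf[nd.label] = nd
            else:
                for c in nd.children:
                    self._parent[c] = nd
                    self._depth[c] = self._depth[nd] + 1
                    stack.append(c)
        self._leafsets: dict[Node, frozenset[str]] = {}

    # -- basic accessors ----------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self._leaf)

    def node_of(self, label: str) -> Node:
        try:
            return self._leaf[label]
        except KeyError:
            raise ValidationError(f"label {label!r} not in tree") from None

    def nodes(self) -> list[Node]:
        """All nodes in preorder."""
        return list(self._preorder)

    def internal_nodes(self) -> list[Node]:
        return [n for n in self._preorder if not n.is_leaf]

    def parent(self, node: Node) -> Node | None:
        return self._parent.get(node)

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def leafset(self, node: Node) -> frozenset[str]:
        """Leaf labels below ``node`` (cached)."""
        cached = self._leafsets.get(node)
        if cached is not None:
            return cached
        if node.is_leaf:
            result = frozenset((node.label,))
        else:
            acc: set[str] = set()
            for c in node.children:
                acc |= self.leafset(c)
            result = frozenset(acc)
        self._leafsets[node] = result
        return result

    # -- ancestry -----------------------------------------------------------

    def _as_node(self, x: str | Node) -> Node:
        return x if isinstance(x, Node) else self.node_of(x)

    def is_ancestor(self, u: str | Node, v: str | Node) -> bool:
        """True iff ``u`` is an ancestor of ``v`` (every node is its own)."""
        u, v = self._as_node(u), self._as_node(v)
        while self._depth[v] > self._depth[u]:
            v = self._parent[v]
        return u is v

    def separated(self, x: str | Node, y: str | Node) -> bool:
        """True iff neither of ``x``, ``y`` is an ancestor of the other."""
        return not (self.is_ancestor(x, y) or self.is_ancestor(y, x))

    def lca_nodes(self, nodes: Iterable[Node]) -> Node:
        it = iter(nodes)
        try:
            cur = next(it)
        except StopIteration:
            raise ValidationError("lca of an empty set") from None
        for other in it:
            a, b = cur, other
            while self._depth[a] > self._depth[b]:
                a = self._parent[a]
            while self._depth[b] > self._depth[a]:
                b = self._parent[b]
            while a is not b:
                a = self._parent[a]
                b = self._parent[b]
            cur = a
        return cur

    def lca(self, labels: Iterable[str]) -> Node:
        """Least common ancestor of a set of leaf labels."""
        return self.lca_nodes(self.node_of(l) for l in labels)

    # -- structural operations ---------------------------------------------

    def restrict(self, labels: Iterable[str]) -> "RootedTree":
        """Restriction ``T|L'``: the minimal subtree spanning ``L'`` with
        out-degree-1 non-root nodes suppressed."""
        keep = set(labels)
        if not keep:
            raise ValidationError("restriction to an empty label set")
        missing = keep - self.leaf_labels
        if missing:
            raise ValidationError(f"labels not in tree: {sorted(missing)}")

        def rec(node: Node) -> Node | None:
            if node.is_leaf:
                return node if node.label in keep else None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return Node(node.label, kids)

        new_root = rec(self.root)
        assert new_root is not None
        return RootedTree(new_root, canonicalize=False)

    def topology_key(self, labeled: bool = False):
        """A hashable canonical key, invariant under child reordering.

        With ``labeled=True`` internal labels participate (for DS-trees and
        cotrees); otherwise only the leaf partition structure matters.
        """

        def rec(node: Node):
            if node.is_leaf:
                return ("L", node.label)
            kids = tuple(sorted(rec(c) for c in node.children))
            return ("I", node.label if labeled else None, kids)

        return rec(self.root)

    def relabel_internal(self, mapping: Mapping[str, str]) -> "RootedTree":
        """Return a copy with internal labels mapped through ``mapping``."""

        def rec(node: Node) -> Node:
            if node.is_leaf:
                return node
            lab = mapping.get(node.label, node.label) if node.label else node.label
            return Node(lab, [rec(c) for c in node.children])

        return RootedTree(rec(self.root), canonicalize=False)

    # -- Newick -------------------------------------------------------------

    def newick(self) -> str:
        return serialize_newick(self)

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        return parse_newick(text)

    def __len__(self) -> int:
        return len(self._leaf)


_NEEDS_QUOTE = re.compile(r"[\s()\[\]':;,]")


def _quoted(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def serialize_newick(tree: RootedTree) -> str:
    """Serialize to Newick; internal labels written, no branch lengths."""

    def rec(node: Node) -> str:
        if node.is_leaf:
            return _quoted(node.label)
        inner = ",".join(rec(c) for c in node.children)
        lab = _quoted(node.label) if node.label else ""
        return f"({inner}){lab}"

    return rec(tree.root) + ";"


def parse_newick(text: str) -> RootedTree:
    """Parse Newick text into a :class:`RootedTree`.

    Branch lengths are accepted and discarded; internal node labels are kept
    (this is how DS-tree ``D``/``S`` labels travel).  Malformed text or
    duplicate leaf labels raise :class:`NewickError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"cannot parse Newick: {exc}") from exc

    def conv(nd) -> Node:
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None:
                raise NewickError("leaf without a label")
            return Node(label)
        return Node(nd.label, [conv(c) for c in nd.child_nodes()])

    return RootedTree(conv(dtree.seed_node))


def restrict_tree(tree: RootedTree, labels: Iterable[str]) -> RootedTree:
    """Functional form of :meth:`RootedTree.restrict`."""
    return tree.restrict(labels)


def tree_lca(tree: RootedTree, labels: Iterable[str]) -> Node:
    """Functional form of :meth:`RootedTree.lca`."""
    return tree.lca(labels)


def separated(tree: RootedTree, x: str | Node, y: str | Node) -> bool:
    """Functional form of :meth:`RootedTree.separated`."""
    return tree.separated(x, y)


# ---------------------------------------------------------------------------
# Triplets
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Triplet:
    """A rooted triplet ``ab|c``: the cherry pair {a, b} with outgroup c.

    The cherry pair is stored sorted, so ``Triplet("B", "A", "C")`` and
    ``Triplet("A", "B", "C")`` compare equal.
    """

    a: str
    b: str
    c: str

    def __post_init__(self):
        if len({self.a, self.b, self.c}) != 3:
            raise ValidationError(
                f"triplet labels must be distinct: {self.a!r}, {self.b!r}, {self.c!r}"
            )
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset((self.a, self.b, self.c))

    def __str__(self) -> str:
        return f"{self.a}{self.b}|{self.c}"


# ---------------------------------------------------------------------------
# Species assignment and constraint graphs
# ---------------------------------------------------------------------------


class SpeciesAssignment(Mapping):
    """Total mapping gene → species; the species universe Σ is its image."""

    __slots__ = ("_map", "_sigma")

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)
        for g, sp in self._map.items():
            if not isinstance(sp, str) or not sp:
                raise ValidationError(f"invalid species for gene {g!r}: {sp!r}")
        self._sigma = frozenset(self._map.values())

    @property
    def sigma(self) -> frozenset[str]:
        return self._sigma

    def species_of(self, genes: Iterable[str]) -> frozenset[str]:
        return frozenset(self._map[g] for g in genes)

    def restrict(self, genes: Iterable[str]) -> "SpeciesAssignment":
        return SpeciesAssignment({g: self._map[g] for g in genes})

    def __getitem__(self, gene: str) -> str:
        return self._map[gene]

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other) -> bool:
        if isinstance(other, SpeciesAssignment):
            return self._map == other._map
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._map.items()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesAssignment({len(self._map)} genes, {len(self._sigma)} species)"


@dataclass(frozen=True)
class ConstraintGraph:
    """Partial orthology knowledge ``(G = (V, M ⊎ U), s)``.

    ``mandatory`` are known ortholog pairs, ``unknown`` are undecided pairs,
    every other distinct pair is a known paralog pair.  Use
    :meth:`ConstraintGraph.create` to construct with validation.
    """

    genes: frozenset[str]
    mandatory: frozenset[Pair]
    unknown: frozenset[Pair]
    assignment: SpeciesAssignment

    @classmethod
    def create(
        cls,
        genes: Iterable[str],
        mandatory: Iterable[Pair | tuple[str, str]],
        unknown: Iterable[Pair | tuple[str, str]],
        assignment: Mapping[str, str] | SpeciesAssignment,
    ) -> "ConstraintGraph":
        gene_set = frozenset(genes)
        if not isinstance(assignment, SpeciesAssignment):
            assignment = SpeciesAssignment(assignment)
        missing = gene_set - set(assignment)
        if missing:
            raise ValidationError(f"genes without a species: {sorted(missing)}")
        if set(assignment) != gene_set:
            assignment = assignment.restrict(gene_set)
        m = frozenset(pair(*p) for p in mandatory)
        u = frozenset(pair(*p) for p in unknown)
        overlap = m & u
        if overlap:
            raise ValidationError(
                f"pairs both mandatory and unknown: {sorted(overlap)}"
            )
        for edge_set, kind in ((m, "ortholog"), (u, "unknown")):
            for x, y in sorted(edge_set):
                if x not in gene_set or y not in gene_set:
                    raise ValidationError(f"pair ({x}, {y}) uses genes outside V")
                if assignment[x] == assignment[y]:
                    raise AssumptionViolation(
                        f"{kind} relation between same-species genes "
                        f"{x!r} and {y!r} (species {assignment[x]!r}): homologous "
                        "genes of one species must be paralogs"
                    )
        return cls(gene_set, m, u, assignment)

    # -- accessors ----------------------------------------------------------

    @property
    def sigma(self) -> frozenset[str]:
        return self.assignment.species_of(self.genes)

    @property
    def mandatory_or_unknown(self) -> frozenset[Pair]:
        return self.mandatory | self.unknown

    @property
    def is_orthology_graph(self) -> bool:
        """True when there are no unknown pairs (fully decided relations)."""
        return not self.unknown

    def relation_of(self, x: str, y: str) -> str:
        p = pair(x, y)
        if p in self.mandatory:
            return "ortholog"
        if p in self.unknown:
            return "unknown"
        return "paralog"

    def induced(self, genes: Iterable[str]) -> "ConstraintGraph":
        """The induced sub-constraint-graph on a gene subset."""
        keep = frozenset(genes)
        extra = keep - self.genes
        if extra:
            raise ValidationError(f"genes not in graph: {sorted(extra)}")
        m = frozenset(p for p in self.mandatory if p[0] in keep and p[1] in keep)
        u = frozenset(p for p in self.unknown if p[0] in keep and p[1] in keep)
        return ConstraintGraph(keep, m, u, self.assignment.restrict(keep))

    def with_unknown(self, unknown: Iterable[Pair]) -> "ConstraintGraph":
        return ConstraintGraph(
            self.genes, self.mandatory, frozenset(unknown), self.assignment
        )


def orthology_graph(
    genes: Iterable[str],
    edges: Iterable[Pair | tuple[str, str]],
    assignment: Mapping[str, str] | SpeciesAssignment,
) -> ConstraintGraph:
    """An orthology graph: a constraint graph with no unknown pairs."""
    return ConstraintGraph.create(genes, edges, (), assignment)


# ---------------------------------------------------------------------------
# Tabular parsing
# ---------------------------------------------------------------------------


def parse_relations(
    relation_rows: Iterable[Sequence[str]],
    species_rows: Iterable[Sequence[str]],
    strict: bool = False,
) -> ConstraintGraph:
    """Build a validated constraint graph from tabular records.

    ``relation_rows`` are ``(gene_a, gene_b, relation)`` with relation in
    {ortholog, paralog, unknown}; ``species_rows`` are ``(gene, species)``.
    The gene universe V is the set of genes in the species map; pairs absent
    from the relation rows are paralogs (an explicit ``paralog`` row is
    equivalent to absence).  With ``strict=True`` every distinct-species pair
    must be listed explicitly.
    """
    species: dict[str, str] = {}
    for row in species_rows:
        gene, sp = row[0], row[1]
        if gene in species and species[gene] != sp:
            raise ConflictingRecordsError(
                f"gene {gene!r} mapped to both {species[gene]!r} and {sp!r}"
            )
        species[gene] = sp

    seen: dict[Pair, str] = {}
    for row in relation_rows:
        ga, gb, rel = row[0], row[1], row[2]
        if rel not in RELATION_VALUES:
            raise ValidationError(
                f"invalid relation {rel!r} for pair ({ga}, {gb}); "
                f"expected one of {RELATION_VALUES}"
            )
        for g in (ga, gb):
            if g not in species:
                raise ValidationError(f"gene {g!r} has no species-map entry")
        p = pair(ga, gb)
        if p in seen and seen[p] != rel:
            raise ConflictingRecordsError(
                f"conflicting relations for pair ({p[0]}, {p[1]}): "
                f"{seen[p]!r} vs {rel!r}"
            )
        seen[p] = rel
        if rel in ("ortholog", "unknown") and species[ga] == species[gb]:
            raise AssumptionViolation(
                f"{rel} relation between same-species genes {ga!r} and {gb!r} "
                f"(species {species[ga]!r})"
            )

    if strict:
        genes_sorted = sorted(species)
        for i, x in enumerate(genes_sorted):
            for y in genes_sorted[i + 1 :]:
                if species[x] != species[y] and pair(x, y) not in seen:
                    raise ValidationError(
                        f"strict mode: pair ({x}, {y}) not listed in relations"
                    )

    mandatory = [p for p, r in seen.items() if r == "ortholog"]
    unknown = [p for p, r in seen.items() if r == "unknown"]
    return ConstraintGraph.create(species.keys(), mandatory, unknown, species)


def read_relations_tsv(path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "relation"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"relations TSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return list(df[["gene_a", "gene_b", "relation"]].itertuples(index=False, name=None))


def read_species_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "species"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"species TSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return list(df[["gene", "species"]].itertuples(index=False, name=None))


def load_constraint_graph(relations_path, species_path, strict: bool = False) -> ConstraintGraph:
    return parse_relations(
        read_relations_tsv(relations_path), read_species_tsv(species_path), strict=strict
    )


def write_relations_tsv(graph: ConstraintGraph, path, include_paralogs: bool = False) -> None:
    """Write a constraint graph as a relations TSV (sorted, deterministic)."""
    rows = []
    for x, y in sorted(graph.mandatory):
        rows.append((x, y, "ortholog"))
    for x, y in sorted(graph.unknown):
        rows.append((x, y, "unknown"))
    if include_paralogs:
        genes_sorted = sorted(graph.genes)
        mu = graph.mandatory_or_unknown
        for i, x in enumerate(genes_sorted):
            for y in genes_sorted[i + 1 :]:
                if graph.assignment[x] != graph.assignment[y] and pair(x, y) not in mu:
                    rows.append((x, y, "paralog"))
        rows.sort()
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "relation"]).to_csv(
        path, sep="\t", index=False
    )


def write_species_tsv(assignment: SpeciesAssignment, path) -> None:
    rows = sorted(assignment.items())
    pd.DataFrame(rows, columns=["gene", "species"]).to_csv(path, sep="\t", index=False)


def read_triplets_tsv(path) -> frozenset[Triplet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"a", "b", "outgroup"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"triplet TSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return frozenset(
        Triplet(r.a, r.b, r.outgroup) for r in df.itertuples(index=False)
    )


def write_triplets_tsv(triplets: Iterable[Triplet], path) -> None:
    rows = sorted((t.a, t.b, t.c) for t in triplets)
    pd.DataFrame(rows, columns=["a", "b", "outgroup"]).to_csv(path, sep="\t", index=False)
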