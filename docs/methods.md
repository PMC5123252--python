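# Methods

## The model

A gene family's history is a *DS-tree*: a binary rooted tree on the genes
whose internal nodes are labeled duplication (`D`) or speciation (`S`). Two
genes are orthologs with respect to the tree when their LCA is a speciation,
paralogs otherwise. The graphs realizable this way are exactly the cographs
(P4-free graphs), with the canonical cotree (0 = disjoint union ↔
duplication, 1 = series composition ↔ speciation) as the bridge between the
graph view and the tree view.

Relation-inference pipelines produce *partial* call sets: some pairs are
confidently orthologs (mandatory edges `M`), some confidently paralogs
(non-edges), some undecided (`U`). Gene transfers are excluded, so two
homologous genes of one species are always paralogs; inputs violating this
are rejected. The package answers, for such a constraint graph
`(G = (V, M ⊎ U), s)`:

* **satisfiability** — does some sandwich `H` (`M ⊆ E(H) ⊆ M ∪ U`) admit a
  DS-tree at all (equivalently, is some sandwich a cograph)?
* **consistency** — does some sandwich admit a DS-tree whose speciation
  nodes respect *some* binary species tree `S`, i.e. for every speciation
  node the species sets of its two subtrees have separated LCAs in `S`?
* **consistency with a known `S`** — same, for a given tree.

Consistency with `S` is equivalent to: the sandwich is P4-free and `S`
displays every triplet of `P3(H, s) = {s(x)s(y)|s(z) : xz, zy ∈ E, xy ∉ E,
s(x) ≠ s(y)}`. Both directions of that equivalence are exercised by the test
suite (graph-level check vs. the definitional DS-tree check).

## The sandwich algorithm

The solver is a divide-and-conquer on the species set:

1. If at most one species is present, `M = U = ∅` is forced and the empty
   sandwich is trivially consistent.
2. *Reduction:* unknown edges joining distinct connected components of
   `G(∅) = (V, M)` are frozen to paralogy; they can never help.
3. *Species graph:* species `a`, `b` are joined when some same-component
   pair of genes with those species is a known paralog pair. Such a pair
   forces, in any sandwich, a chordless path of length 2, hence a triplet
   `ab|·` that places `a` and `b` strictly below the species-tree root on
   the same side. A connected species graph over ≥ 2 species therefore
   certifies infeasibility, and that certificate (the gene subset and the
   species graph) is returned.
4. *Branching:* otherwise the species set splits along a species-graph
   component (deterministically: the component containing the
   lexicographically smallest species). Cross unknown pairs are frozen to
   orthologs, both halves are solved recursively, and the witness species
   tree is a new root over the halves' trees.

The recursion tree is binary with at most `|Σ|` leaves, so at most
`2|Σ| − 1` nodes; each node costs quadratic work, giving the cubic bound.
The scaling test runs ~500 genes over 50 species and asserts the
recursion-node bound.

**Witness DS-tree.** The witness DS-tree is read off the canonical cotree of
the returned sandwich, binarized with the witness species tree as a guide:
children of a series (speciation) node are grouped by the side of the guide
their species fall under and merged recursively, so every speciation node
separates its children's species sets; union (duplication) nodes are folded
lexicographically. This is equivalent to assembling the tree inside the
recursion (series composition across the split within each component,
disjoint union across components) but keeps the construction in one place;
the suite verifies every witness against the definitional consistency check,
so a guide failure cannot pass silently.

**Known species tree.** With a known binary `S`, the species graph is
augmented with an edge `ab` for every triplet `ab|c` that `S` displays over
the present species, which forces the recursion to follow `S`'s splits. The
adaptation has no published completeness proof for fully known trees, so the
feasible answer is always re-verified against `S` (P3 display) and the
DS-tree is rebuilt guided by `S`; a verification failure raises an internal
error rather than being patched. Empirically the adaptation matched the
brute-force oracle on every instance of the systematic and random sweeps.

## Minimum duplications (exact, capped)

Minimizing duplication nodes over sandwich DS-trees is NP-hard already for
two duplications, and hard to approximate, so the exact solvers are small
oracles by design. The search is a subset-split dynamic program over gene
subsets `W`: a speciation root needs all cross pairs in `M ∪ U` (and, when a
species tree is imposed, separated species-set LCAs — a purely local check,
since the consistency condition is per-speciation-node); a duplication root
needs no cross pair in `M` and costs one. This enumerates exactly the binary
DS-trees, memoized (`O(3^n)`); the cap is 12 genes by default. Mode
`consistent` minimizes over enumerated binary species trees with an early
exit once the unconstrained optimum is matched.

The coloring connection is implemented both ways: the reduction from a
connected graph `G₀` (M = ∅, U = complement edges, one species per vertex)
satisfies `k* = χ(G₀) − 1`, and `complement_coloring` turns any binary
DS-tree with `k` duplications into a proper `≤ k+1` coloring of the
complement of its orthology graph (disjoint palettes under duplications,
shared palette under speciations). Both identities are tested on random
connected graphs against a backtracking chromatic-number oracle.

A useful derived fact, validated exhaustively for ≤ 6 vertices against
enumeration of all binary DS-trees: the duplication count of a cograph is an
invariant — every binary DS-tree representing the graph has Σ over cotree
union nodes of (children − 1) duplications — so `min_duplications_of_cograph`
can read it off the canonical cotree.

## Species-tree reconstruction and discordance

From a consistent sandwich, a species tree displaying all of `P3` can also
be rebuilt by BUILD (Aho et al.); the recursion's own tree and the BUILD
tree display the same forced triplets. BUILD output may be non-binary when
the triplets are sparse and is returned as-is (a deterministic lexicographic
refinement is provided for callers needing binary trees).

Discordance between a reference species tree `S` and a reconstruction `S′`
is reported as the fraction of `S`'s triplets that `S′` actively
contradicts (displays a different resolution); unresolved restrictions
contradict nothing. This is a deliberately self-contained surrogate for
supertree-based discordance scores that depend on an external maximization
step with no standalone specification; absolute values from such pipelines
are not comparable to this ratio.

## The synthetic generator

No public benchmark ships with the package; test inputs are planted:

* a uniform random rooted binary species tree on `m` species (sequential
  random attachment over the `2k−1` positions; uniformity is tested);
* a gene history grown down the species tree, each lineage entering a node
  duplicating with probability `dup_prob` (children re-enter the same node)
  or following the tree; no losses, no transfers. Consistency with the
  species tree holds by construction;
* masking of the resulting orthology graph: each distinct-species pair
  becomes unknown with probability `p_unknown`, otherwise flipped with
  probability `p_noise`.

Defaults: 6 species, `dup_prob = 0.2`, `p_unknown = 0.3`, `p_noise = 0`,
gene cap 50 with resampling. The masking rate reflects that
similarity-based callers leave a substantial fraction of pairs undecided;
the duplication rate gives gene families a few times larger than the
species count, typical of the multi-copy families such tools are run on.
With `p_noise = 0` the true edge set is a sandwich, so planted instances
are feasible — this is the ground truth behind the soundness suite. Noise
(`p_noise > 0`) produces possibly-infeasible instances for exercising
certificates. What the generator does **not** emulate: gene losses,
transfers, correlated errors of a specific inference tool, or real sequence
evolution — so passing tests show algorithmic correctness on the model's
own terms, not robustness to real-data error structure.

## Numerical and design choices

* All set-valued outputs and tie-breaks are lexicographic; runs are
  deterministic for a fixed seed regardless of hash randomization.
* Degenerate inputs: an empty gene set is feasible with empty outputs;
  all genes in one species is feasible with the all-paralog graph.
* Species with no genes are dropped from Σ; they can only re-enter through
  a known species tree.
* Cograph recognition is the quadratic union/co-component recursion (it
  doubles as cotree construction); `find_induced_p4` is a brute-force
  witness path, not the solver's hot path.
* Test-suite problem sizes: systematic solver-vs-oracle sweeps are
  exhaustive up to 4 genes (every species partition × every relation
  pattern) and randomized (10,000 instances) up to 8 genes and 4 species
  with the oracle's enumeration caps; BUILD is checked exhaustively on 4
  labels and by sampling on 5; duplication-count invariance is exhaustive
  on ≤ 6 vertices; witness soundness runs 500 planted instances up to 40
  genes. These sizes keep the brute-force oracles exact while covering the
  combinatorial space densely.

## Known limitations

* The exact minimization path is capped (12 genes / 8 species by default)
  because the underlying problems are NP-hard and inapproximable; there are
  deliberately no heuristics.
* `solve_with_species_tree` requires a *binary* known tree; partial
  knowledge can instead be passed as a triplet set to `solve`.
* The discordance ratio is not numerically comparable to supertree-based
  scores from external pipelines (see above).
* Real-data error structure is out of scope for the generator; conclusions
  about specific inference tools require their actual outputs as relation
  tables.
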