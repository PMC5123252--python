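# orthosandwich

Consistency checking for partial orthology/paralogy relations on a gene
family — with or without a known species tree — plus witness reconstruction
and exact small-scale duplication minimization.

## The problem

Similarity- or synteny-based ortholog callers (ProteinOrtho-style tools)
emit pairwise relations for a set of homologous genes: some pairs are
confidently *orthologs*, some confidently *paralogs*, many are left
*unknown*. Such a partial call set may be impossible to realize by any
evolutionary history, or realizable but only under species trees that
contradict the accepted phylogeny. `orthosandwich` decides these questions
exactly and constructs the witnesses.

The input is a *constraint graph* `(G = (V, M ⊎ U), s)`: genes `V`,
mandatory ortholog edges `M`, unknown edges `U` (absent pairs are known
paralogs), and a species assignment `s`. Histories are *DS-trees* — binary
rooted gene trees with internal nodes labeled duplication or speciation;
two genes are orthologs exactly when their LCA is a speciation. A graph
admits a DS-tree iff it is a cograph (P4-free), and a graph–assignment pair
is consistent with a species tree `S` iff additionally `S` displays every
triplet `s(x)s(y)|s(z)` forced by an induced path `x–z–y`
(`P3(G, s)`). The solver answers, in polynomial time (cubic in the number
of genes), whether some *sandwich* `H` with `M ⊆ E(H) ⊆ M ∪ U` is
consistent with some (or a given) species tree, by a divide-and-conquer on
an auxiliary *species graph* whose connected components drive the
branching — a connected species graph certifies infeasibility.

The duplication-minimization variants (is there a sandwich DS-tree with at
most `k` duplication nodes?) are NP-hard already for `k = 2`, by reduction
from graph coloring: a connected graph `G₀` is `k`-colorable iff the
constraint graph with `M = ∅`, `U = complement(G₀)` and one species per
gene has a solution with `k − 1` duplications. The package ships that
reduction, exact capped solvers for all three variants, and the
complement-coloring algorithm that extracts a proper `≤ k+1` coloring from
any DS-tree with `k` duplications.

## Worked example

The eight-gene, four-species example (two mandatory-edge components, one
unknown edge bridging them):

```sh
orthosandwich check --relations relations.tsv --species species.tsv \
    --consistent --out-dir out
```

prints `consistent: feasible` and writes a summary reporting that
Reduction Rule 1 removed exactly one unknown edge (`a2–d1`, which bridges
the two components) and that the first branching split the genes into
`{a1, a2, c1, c2}` versus `{b1, b2, d1, d2}` — the species graph has edges
`AC` and `BD`, so species `{A, C}` must separate from `{B, D}`:

```json
{
  "status": "feasible",
  "n_removed_unknown_edges": 1,
  "removed_unknown_edges": [["a2", "d1"]],
  "first_split": [["a1", "a2", "c1", "c2"], ["b1", "b2", "d1", "d2"]],
  "recursion_nodes": 7,
  "n_sandwich_edges": 9
}
```

`orthosandwich infer` additionally writes the witnesses: the species tree
`((A,C),(B,D));` and the DS-tree
`(((a1,c1)D,(b1,d1)D)S,((a2,c2)S,(b2,d2)D)S)D;`, whose orthology graph is
exactly the 9-edge sandwich and whose speciation nodes separate their
children's species in the species tree. Re-running `check` on the inferred
outputs exits 0 (self-consistency).

The same library calls are available directly:

```python
from orthosandwich import fixture_worked_example, solve
res = solve(fixture_worked_example())
res.feasible                 # True
res.stats.removed_unknown    # {('a2', 'd1')}
res.species_tree.newick()    # '((A,C),(B,D));'
```

Other subcommands: `validate`, `mindup` (exact minimum duplications, capped
— the problem is NP-hard), `simulate` (planted synthetic instances with
ground truth) and `discordance` (triplet conflict ratio between two trees).
See `docs/methods.md` for the model, algorithm and generator details.

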