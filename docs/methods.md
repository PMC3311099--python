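# Methods

## Pedigree model

A pedigree is a DAG of individuals with at most one father and one mother
each; founders have no recorded parents. Files use the 5-column PED/.fam
dialect (family, id, father, mother, sex; `0` = missing, sex 1/2/0 =
male/female/unknown, `#` comments). Multiple families in one file are
encoded independently. Single-parent records are legal; the absent parent
is treated as an unrelated, non-inbred unknown. Input order is part of the
semantics: child order within each parent — hence every sibling index —
follows file order, which is what makes the encoding deterministic where
the underlying scheme leaves sibling order free.

All label algorithms work on the *rooted* pedigree: a virtual progenitor
(in-degree 0) with a tree edge to each founder, in input order. The virtual
root is excluded from ancestor sets — it is not an individual and must not
act as a "common ancestor" of unrelated founders.

## The encodings

**PET.** Components are (sibling index, sex mark); marks `.` `,` `;` mean
female/male/unknown and double as delimiters, so multi-digit base-64
indices (alphabet `0-9A-Za-z+/`) parse unambiguously. The tree parent's
PET is the label minus its last component.

**CPE.** The encoder processes individuals in Kahn topological
breadth-first order (ties broken by input order) so both parents are
finalized before each child — required because a child's non-tree-edge list
is the union of its parents' finalized lists plus, for a two-parent child,
its own *direct* edge from the non-tree parent. Case tags are recomputed
per node from set membership in the parents' lists. Serialization groups
edges by case tag ($, *, #, &), stable within a group by first-inheritance
order (father's list, then the mother's new entries, the direct edge last);
inheritance itself uses the un-grouped insertion order. The `%` generic tag
appears only on parent labels reconstructed from a child's label, where
case information is meaningless. The `?` shorthand (direct edge's
destination is always the node itself) is an opt-in serialization dialect,
default off.

**Tree-parent policy.** With `tree_policy="first"` (default) the parent
finalized earliest donates the tree edge — the classic queue discipline.
Note that this does *not* produce a shortest-path spanning tree: a node can
be reached by a long chain that finalizes before a short one (P7 in the
example pedigree has PET depth 5 but BFS distance 3). `tree_policy=
"shallowest"` picks the finalized parent with the shortest PET instead; by
induction over the topological order this makes every PET depth equal the
BFS distance from the virtual root, which minimizes the total label size.
The default is kept at `"first"` because it is the canonical discipline
for this encoding; the space difference is small in practice and both
policies yield identical path sets and coefficients.

**NodeCodes.** One code per distinct root path: child code = parent code +
sibling index + sex mark, assigned in the same topological order. NodeCodes
sibling indices number *all* children of a parent; PET indices number tree
children only. The two numbering conventions are deliberate — they are what
makes each scheme internally consistent (every prefix of a NodeCode is a
NodeCode of the ancestor on that path; every PET prefix is a tree
ancestor's PET).

## Path reconstruction and Wright's formula

Paths from an ancestor to a labelled node are rebuilt from the node's label
alone: the unique tree path exists iff the ancestor's PET is a component
prefix of the node's, and every other path is classified by its first
non-tree edge (u, w) — tree path to u, the edge, then recursively any path
from w. Distinct first edges give distinct paths, so the enumeration is
exact and duplicate-free; results are memoized per (start, target) and the
cache is shared across all ancestors of one coefficient query.

Ancestor sets are read off labels as component prefixes of the PET plus
component prefixes of every non-tree-edge *source*; a node belongs to its
own set, which lets a parent that is also an ancestor of the other parent
participate through a zero-length path (s = 0) without special-casing
parent–offspring matings.

Non-overlapping pairs are found with an inverted index keyed by the common
ancestors: any node shared by a father path and a mother path other than
the queried ancestor is itself a common ancestor-or-self of the two
parents, so indexing only the common-ancestor set is exhaustive. In
Wright's term (1/2)^(s+r+1)(1+F_A), s and r count edges on the paths from
A to the father and mother respectively; F_A is computed by the same
path-counting method, memoized, with topological processing guaranteeing
availability. All arithmetic uses exact rationals; floats appear only in
reports.

**Pruning (I-CPE).** A common ancestor with exactly one child inside the
subgraph of its paths to the two parents funnels every path through that
child, so all its pairs overlap and it can be skipped before path
enumeration. The parents themselves are never pruned: a zero-length path
does not pass through any child, so the funnel argument does not apply to
them. Overlap detection always indexes the *unpruned* ancestor set, since
a pruned ancestor can still be the crossover node of pairs rooted
elsewhere. Pruning provably never changes F, only the number of ancestors
evaluated; the tests assert both.

**NodeCodes pipeline.** Same formula; paths from a to n are code pairs
(x, y) with x ∈ NC(a) a component prefix of y ∈ NC(n), translated to
node-id sequences via the code → individual map (two code pairs can encode
the same a → n path through different root prefixes, so sequences are
deduplicated). Overlap is decided by direct node-set intersection.

**Recursive oracle.** φ(a, a) = (1 + φ(father, mother))/2; for distinct
individuals the one later in topological order (never an ancestor of the
other) is expanded into its parents, missing parents contributing zero;
distinct founders are unrelated. Exact, memoized on unordered pairs, and
fully independent of the label machinery — the agreement tests
(fixture + 100 random pedigrees up to 200 individuals, all four methods,
exact equality) are the package's core correctness evidence.

## Space accounting

The component-unit total (sex delimiters ignored) is

    Space(G) = Σ_v |PET(v)| + Σ_{e=(vi,vj) non-tree} (|PET(vi)| + |PET(vj)|) · (|Des(vj)| + 1)

because an edge into vj is carried by exactly vj and its descendants. The
tests verify this identity against direct per-node summation, and the
two-chain worst-case family (both parents shared at every level) shows the
cubic growth ceiling: Space/V³ stays within a bounded ratio as V grows.
Serialized character totals are reported separately and drive the CPE vs
NodeCodes comparison. On very small pedigrees the two schemes are close
and the edge overhead can even favor NodeCodes (the 8-individual example:
168 vs 152 characters, though 72 vs 76 component units); CPE's advantage
appears and grows with path multiplicity — simulated pedigrees of 300 and
1000 individuals at immigration 0.005 average roughly +15% and +53%
respectively.

## Simulator

Yearly cycle: aging → mortality (piecewise-constant hazard by age bracket)
→ immigration (unrelated adult founders, alternating sexes, expected count
= rate × living population) → marriage (eligible singles ≥ 17 enter a pool
with probability 0.12/yr and are paired male/female at random, remarriage
after widowhood) → births (probability 0.22/yr per couple while the wife is
≤ 45). Defaults: years 1500–2000, 30 initial individuals with a fixed age
histogram, cap 1000. The defaults were chosen once to make a small founding
population grow to the cap within a few centuries with appreciable
inbreeding (mean F ≈ 0.05 at immigration 0.003, ≈ 0.007 at 0.01, 10 seeds);
they are not calibrated to any real population, and every field is settable
via `SimConfig` or YAML. Mean inbreeding decreasing in the immigration rate
is the one demographic direction the tests assert, averaged over ten fixed
seeds because three-seed averages are visibly noisy.

What the simulator does *not* emulate: assortative or kin-avoiding mate
choice, age-dependent fertility within the window, migration out,
genotypes, geography. Tests passing on its output therefore demonstrate
algorithmic correctness on structurally realistic DAGs (overlapping
generations, half-sibs, remarriage, variable founder influx), not
demographic realism.

`random_pedigree` is the small property-test generator: founders first,
later individuals draw parents uniformly from earlier males/females
(acyclic by construction), with small probabilities of extra founders and
single-parent records.

## Numerical and degenerate-input choices

* Exact rationals end to end; the cross-method tolerance in tests is exact
  equality (the stated 1e-12 float bound is implied).
* F = 0 for founders and any individual with fewer than two recorded
  parents.
* Full siblings share one computation (coefficient cache keyed by parent
  pair); results are shared objects, not recomputed.
* Cycles (corrupt data) raise rather than return values; `validate`
  reports them, and sex/slot mismatches are warnings, not errors.
* An empty PED file parses to an empty pedigree; rooting one is an error.
* Role ambiguity in parent identification (both parent labels carrying the
  same or unknown sex marks) falls back to the pedigree records behind the
  label table; with no records available it raises.

## Known limitations

* No generalized kinship/identity coefficients, no X-linked variants, no
  genotype-based (realized) inbreeding.
* Path enumeration is exponential in the number of root paths, which is
  intrinsic to path counting; the recursive oracle remains fast and is the
  right tool for very deep, highly inbred pedigrees.
* No incremental re-encoding after pedigree edits; re-encode the family.
* The label table is the decoding context: labels from different encodings
  (or different tree policies) must not be mixed.
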