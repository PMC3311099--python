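# pedpaths

Path-based computations on pedigree graphs with compact encodings.

A pedigree is a directed acyclic graph whose nodes are individuals and whose
edges run parent → child. Quantities such as the inbreeding coefficient of
an individual are functions of the *paths* from common ancestors of its
parents: Wright's path-counting formula gives

    F_n = Σ_A Σ_P (1/2)^(s + r + 1) · (1 + F_A)

summed over every common ancestor A of n's father f and mother m and every
non-overlapping pair of paths P from A to f (s edges) and to m (r edges); a
pair is non-overlapping when the two paths share no node besides A, and F_A
is A's own inbreeding coefficient. Evaluating this on large pedigrees
(medical genetics registries, livestock herdbooks, isolated-population
genealogies) requires identifying and manipulating all those paths
efficiently — which is a graph-labelling problem.

`pedpaths` implements a **compact path encoding (CPE)**: every individual
gets *one* label consisting of

* **PET** — its prefix code on a spanning tree of the rooted pedigree: a
  sequence of (sibling index, sex mark) components, where the tree parent's
  label is always a prefix; and
* **NTE** — the list of non-tree edges of its path-induced subgraph, each a
  (source PET, dest PET) pair tagged by whether it came through the father
  (`*`), the mother (`#`), both (`&`), or is the individual's own non-tree
  parent edge (`$`).

All paths from any ancestor are reconstructed from this single label on
demand. The package also provides the **NodeCodes** baseline (one code per
root path — simple, but the code count explodes with path multiplicity), an
exact **recursive kinship oracle** (`φ(a,b)` with rational arithmetic) that
independently verifies every coefficient, a nonessential-ancestor pruning
step (I-CPE) that skips common ancestors which cannot produce a
non-overlapping pair, and a seedable **population simulator** (overlapping
generations, marriage, immigration, mortality) for generating arbitrarily
large test pedigrees.

Intended users: developers of pedigree databases and genetic-counselling
tools, and anyone needing verified inbreeding/kinship computations on
PED/.fam files.

## Worked example

The built-in eight-individual pedigree (founders P0, P1; P7's parents P5
and P6 share the ancestors P1 and the inbred P4):

```python
from pedpaths import example_pedigree, add_virtual_root, encode_cpe, inbreeding_cpe

table = encode_cpe(add_virtual_root(example_pedigree()))
print(table.cpe("P7"))
res = inbreeding_cpe("P7", table, improved=True)
print(res.F, [(c.ancestor_id, str(c.term)) for c in res.contributions])
```

prints

```
0.0,0.0,0,$1,1.$0.0,0.0,0,#0.0,0.#1,1.&1,&0.0,&1,0.&0.0,0.
13/64 [('P1', '1/16'), ('P4', '9/64')]
```

— P7's single label encodes all five root paths to it; its coefficient
13/64 = 0.203125 splits into 9/64 through grandmother P4 (one
non-overlapping pair, lengths 1+1, scaled by 1 + F_P4 = 9/8) and 2 · 1/32
through great-grandfather P1 (two pairs of lengths 1+3). The same values
come from the NodeCodes pipeline and from the recursive oracle.

The same through the CLI:

```sh
$ pedpaths inbreed --in fam.ped --method icpe
individual_id   F         n_common_ancestors  n_pairs
...
P4              0.125     1                   1
P6              0.25      1                   2
P7              0.203125  2                   3
```

Other subcommands: `encode` (label table as TSV, CPE or NodeCodes),
`paths` (ancestor → individual path listing), `ancestors` (ancestor or
common-ancestor sets), `simulate` (synthetic PED files), `stats`
(CPE vs NodeCodes space comparison).

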