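# uted — exact edit distance for rooted, labelled, unordered trees

`uted` computes the **tree edit distance** between rooted labelled trees when
sibling order does not matter — the natural setting for glycans (sugar
chains), and more generally for any tree-structured data where children are
a set rather than a sequence. Computing this distance exactly is NP-hard, so
most toolkits either restrict to ordered trees or fall back to heuristics.
`uted` solves the problem exactly for moderate-size trees (tens of nodes) by
reducing it to a **maximum vertex-weighted clique** problem and attacking
that with a colour-bounded branch-and-bound solver.

It is aimed at structural bioinformatics users who want a principled
(dis)similarity measure for glycan structures in KCF format, and at anyone
comparing labelled trees (RNA-like hierarchies, taxonomies, vascular trees)
who needs the *unordered* distance, a guaranteed optimum, and the optimal
node mapping — not just a score.

## The method

An *edit script* transforms tree `T1` into `T2` by node deletions,
insertions and label substitutions, with costs given by a function `γ` over
`Σ ∪ {ε}` satisfying the metric axioms (non-negativity, identity, symmetry,
triangle inequality). The distance `dist(T1,T2)` is the minimum script cost.

Dual to scripts are *edit distance mappings* (Tai mappings): sets
`M ⊆ V(T1) × V(T2)` that are one-to-one and preserve the ancestor relation
in both directions. With `f(u,v) = γ(ℓ(u),ε) + γ(ε,ℓ(v)) − γ(ℓ(u),ℓ(v))`
(the *gain* of matching `u` to `v` instead of deleting and inserting both),

```
dist(T1,T2) = Σ_{u∈V(T1)} γ(ℓ(u),ε) + Σ_{v∈V(T2)} γ(ε,ℓ(v)) − max_M Σ_{(u,v)∈M} f(u,v)
```

so minimising edit cost means maximising total gain. `uted` builds an
*association graph*: one vertex per cross-tree node pair `(u,v)` with weight
`f(u,v)`, and an edge between two vertices exactly when the two pairs are
mutually compatible as mapping entries. Cliques of this graph are exactly
the valid mappings, so a maximum-weight clique is an optimal mapping. Both
trees are first wrapped in sentinel "dummy roots" so that the real roots can
be edited like any other node.

The solver is an MCQ/MWCQ-style branch and bound: vertices ordered by
degree, candidate sets greedily colour-sorted, and the sum of per-colour
maximum weights used as the pruning bound. It ships as a pure-Python
reference engine and a semantically identical numba-compiled bitset kernel
(the default).

Also included: the ordered-tree distance (same clique construction plus a
sibling-order condition, cross-checked by an independent keyroot dynamic
program), the largest common subtree (unit-weight clique under the
delete/insert = 1, mismatch = 2 scheme), general user-supplied cost tables,
and ROC/AUC machinery for evaluating similarity search against class labels.

## Worked example

```python
from uted import parse_bracket, unit_scheme, unordered_ted, ordered_ted

t1 = parse_bracket("r(a(b,c),d)")   # root r; child a has children b, c
t2 = parse_bracket("r(d,a(b,c))")   # same subtrees, opposite order

s = unit_scheme({"r", "a", "b", "c", "d"})   # every edit costs 1
print(unordered_ted(t1, t2, s).distance)     # 0.0
print(ordered_ted(t1, t2, s).distance)       # 2.0
```

Ignoring sibling order the trees are identical (`0.0`); respecting it, the
subtree `d` has to be deleted on one side and re-inserted on the other
(`2.0`). The optimal mapping and the per-node operation classification are
on the result object:

```python
s2 = unit_scheme({"r", "a", "b", "c", "d", "x"})
res = unordered_ted(t1, parse_bracket("r(a(b,x),d)"), s2)
print(res.distance)              # 1.0
print(res.operations["substituted"])   # {(3, 3)}  -- node c relabelled to x
```

The same computations are available from a shell:

```
$ uted ted tree1.txt tree2.kcf --mode unordered --cost unit
$ uted matrix glycans/ --out dist.tsv
$ uted roc --matrix dist.tsv --labels classes.tsv
$ uted gen --n 35 --alphabet-size 6 --count 10 --seed 1 --outdir fixtures/
```

KCF glycan records (`NODE`/`EDGE` sections) are detected automatically; the
reducing-end (rightmost-drawn) residue is taken as the root.

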