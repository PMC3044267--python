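# Methods

## Model

A tree here is rooted and node-labelled over an alphabet `Σ`; child
sequences are stored in order but consulted only by the ordered-mode
comparisons. Edit operations are the classical three:

- **deletion** of a non-root node `v`, splicing `v`'s children into its
  parent's child sequence at `v`'s position;
- **insertion**, the exact inverse: a new node adopts a contiguous block of
  an existing node's children;
- **substitution** of a node's label.

Costs come from a scheme `γ : Σ′ × Σ′ → ℝ≥0` with `Σ′ = Σ ∪ {ε}`. Four
axioms — non-negativity, `γ(a,a) = 0`, symmetry, and the triangle
inequality over `Σ′` (ε allowed in any position) — are required for the
distance to be a metric and for the clique reduction to be sound: they make
the match gain `f(u,v) = γ(ℓ(u),ε) + γ(ε,ℓ(v)) − γ(ℓ(u),ℓ(v))` symmetric
and non-negative, which is what lets zero-gain vertices be ignored and lets
the maximum-weight clique equal the optimal mapping. Schemes failing
validation are usable only behind an explicit `allow_invalid` override, and
nothing is guaranteed about them.

The equivalence used throughout: valid edit mappings (one-to-one,
ancestor-preserving in both directions) are exactly the cliques of the
association graph over non-root node pairs, and

```
dist = Σ deletions + Σ insertions − score(M_OPT),   score(M) = Σ f(u,v).
```

Both trees are always wrapped in sentinel dummy roots before the graph is
built, so real roots are ordinary matchable nodes; the forced sentinel pair
costs nothing. Every solve prices its mapping twice — by the direct
delete/insert/substitute decomposition and by totals-minus-score — and
raises if the two disagree beyond 1e-9.

### Ordered mode

Ordered mappings additionally preserve left-to-right order: for two mapped
pairs whose nodes are unrelated by ancestry, the first-tree nodes compare in
sibling order the same way the second-tree nodes do (implemented via
preorder positions). That condition only removes association-graph edges,
which gives the expected relation `unordered distance ≤ ordered distance`.
The ordered clique engine is cross-checked against an independent
implementation of the keyroot/forest dynamic program over ordered forests;
the two must agree exactly, and do on every tested pair. The DP engine
returns the distance only — mapping recovery is the clique engine's job.

### Largest common subtree

Under the scheme `γ(del) = γ(ins) = 1`, `γ(mismatch) = 2`, matching unequal
labels gains nothing, so after pruning zero-gain vertices all remaining
weights equal 2 and an unweighted maximum clique suffices. The matched-pair
count `size` satisfies `|V1| + |V2| − 2·size = dist` under that scheme,
which is asserted in tests and recomputed by the acceptance script.

## Clique solver

Branch and bound in the MCQ/MWCQ family. Initial vertex order:
non-increasing degree, ties by input order. At every search node the
candidate set is greedily colour-sorted (sequential colouring in the fixed
order); a clique takes at most one vertex per colour class, so the running
sum of per-class maximum weights bounds the achievable weight — for unit
weights this is the familiar "number of colours" bound. Candidates are
expanded in reverse colour order and the search prunes (and returns, since
the bound is monotone along the order) when `current + bound ≤ incumbent`.
Ties everywhere break by stable input order, and incumbents are replaced
only on strict improvement, so results are deterministic bit-for-bit.

Two engines implement this identical search: a plain Python reference and a
numba-compiled kernel over explicit uint64 bitset words (the default; ~25×
faster). Their result identity — value *and* vertex set — is property-tested,
and both are checked against exhaustive clique enumeration on small random
graphs and against an external solver on integer weights.

Unordered solves are warm-started by default: the ordered-mode problem (a
sparser graph, usually fast) is solved first and its optimum — a valid
unordered mapping — becomes the starting incumbent. This never changes the
returned optimum; it only prunes earlier, and on timeout it guarantees the
reported upper bound is at least as good as the ordered distance.

Numerical choices: weights are floats; incumbent/bound comparisons use an
absolute tolerance of 1e-9; negative weights are rejected (the reduction
guarantees `f ≥ 0`). An optional wall-clock timeout returns the incumbent —
always a valid clique, hence a valid mapping and an upper bound on the
distance — flagged `timed_out` rather than failing.

## Synthetic data

The generators make the package testable with no external data.

- `random_tree(GenSpec)`: node `i ≥ 1` attaches to a parent among nodes
  `0..i−1`. `uniform-parent` (default) picks uniformly, giving shallow bushy
  trees — a deliberately adversarial topology for the unordered problem;
  `preferential` weights parents by child count + 1; `chain-biased` mostly
  extends a current leaf and branches off a uniform node with probability
  0.15, emulating the narrow, chain-dominated shape of real glycans (a
  35-node draw typically has depth ≥ 8 and a handful of branches). Labels
  are uniform over the alphabet. Default alphabet size 3 for the oracle
  suites (small alphabets maximise label collisions, the hard case for
  mapping enumeration); the glycan-scale runs use 6, about the number of
  distinct monosaccharides in a typical glycan.
- `random_valid_scheme`: deletion/insertion costs uniform in [0.5, 2],
  substitutions uniform in [0, del+ins], then a shortest-path
  (Floyd–Warshall) closure over `Σ′` repairs the triangle inequality.
  Closure only shrinks costs and never below zero, so all four axioms hold
  by construction; this is property-tested across seeds.
- `perturb`: applies `k` random edits with the exact operation semantics
  above and returns the summed script cost, giving distance-bounded pairs
  for the upper-bound property `dist(t, perturb(t,k)) ≤ script cost`.

All generators are pure functions of their seeds.

What the generators do **not** emulate: real glycan label frequencies,
anomeric configurations or linkage positions (stripped by the KCF reader),
and real class structure for the ROC layer. Passing tests therefore
demonstrate algorithmic correctness and glycan-scale tractability, not
biological retrieval performance on curated datasets.

## Evaluation layer

Distance matrices are computed per mode (`unordered`, `ordered`,
`ordered-reversed` — the last reverses every child sequence of the second
tree, a control separating genuine unordered similarity from sibling-order
agreement). Timed-out pairs become NaN with a log entry, not failures.

ROC curves sweep a threshold over the pair statistic; with `distance`
polarity smaller-than-threshold is called positive, with `score` larger.
Pairs are labelled same-class when the two items share at least one class
annotation (multi-label inputs allowed). All pairs tied at a threshold flip
together, which with trapezoidal integration equals half-credit for ties;
the trapezoidal AUC is verified in tests to match the Mann–Whitney rank
statistic to 1e-12. The sweep itself is delegated to scikit-learn's
`roc_curve` behind this module's interface.

## Problem sizes

The oracle suites use 300 tree pairs of 4–7 nodes (where exhaustive mapping
enumeration is the ground truth) and 200 random graphs of ≤ 14 vertices
(exhaustive clique enumeration); both finish in seconds. The scale
demonstration solves a 35+35-node chain-biased pair exactly, typically in
seconds to about a minute. Solve times are heavy-tailed: a minority of
chain-biased pairs at this size exceed a 10-minute budget and return a
certified upper bound instead (the `timed_out` flag). Uniform-parent random
trees of that size generate ~65%-dense association graphs of ~1200 vertices
— a far harder clique class than glycan-like trees, where exact solves
routinely need many minutes; the scale claim is about the glycan-like
regime.

## Known limitations

- Worst-case time is exponential: adversarial (bushy, few-label) inputs of
  60+ total nodes can exhaust any budget; use the timeout to get certified
  upper bounds instead.
- One optimal mapping is reported (the solver's deterministic incumbent);
  optima are generally non-unique and are not enumerated.
- KCF reading fixes a dialect: root = node with maximum x-coordinate (tie:
  smallest index), children ordered by descending y (tie: index), `:anomer`
  / `:position` annotations discarded, cyclic or disconnected records
  rejected. Other glycan formats (WURCS, GlycoCT, SMILES) are out of scope.
- `add_dummy_roots` is not idempotent; callers compose it once (the
  distance functions do this internally).
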