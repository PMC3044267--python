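"""Tree edit distances assembled from maximum-weight cliques.

The edit distance between two rooted labelled trees equals the minimum total
cost of deletions, insertions and substitutions turning one into the other.
Dual to edit scripts are edit distance mappings: one-to-one node
correspondences preserving the ancestor relation in both directions. Writing
I1/I2 for the unmapped nodes of either tree, any mapping M prices out as

    cost(M) = sum_{(u,v) in M} gamma(l(u), l(v))
            + sum_{u in I1} gamma(l(u), eps) + sum_{v in I2} gamma(eps, l(v))

and with the match gain f(u,v) = gamma(l(u),eps) + gamma(eps,l(v)) -
gamma(l(u),l(v)) this rearranges to

    dist(T1, T2) = sum_u gamma(l(u), eps) + sum_v gamma(eps, l(v)) - score(M*)

where score(M) = sum f(u,v) and M* maximises it. Maximising score is solved
exactly as a maximum vertex-weighted clique on the association graph; both
trees are wrapped in sentinel dummy roots first so the real roots take part
in matching like any node.

For ordered trees the same clique route applies with an extra sibling-order
edge condition; an independent keyroot dynamic program over ordered forests
cross-checks it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .assoc import AssociationGraph, build_association_graph, clique_to_mapping
from .clique import SolveResult, max_clique, max_weight_clique
from .costs import CostScheme, lcs_scheme, score_f
from .tree import Tree, add_dummy_roots, reverse_children

_AGREE_TOL = 1e-9


@dataclass
class MappingReport:
    violations: list[str]

    @property
    def valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.valid


def is_valid_mapping(t1: Tree, t2: Tree, m) -> MappingReport:
    """Check the two mapping conditions: one-to-one on both sides, and the
    ancestor relation preserved in both directions, for every pair of pairs."""
    pairs = sorted(m)
    for u, v in pairs:
        t1._node(u)
        t2._node(v)
    anc1 = {u: t1.ancestors(u) for u, _ in pairs}
    anc2 = {v: t2.ancestors(v) for _, v in pairs}
    out = []
    for a in range(len(pairs)):
        u1, v1 = pairs[a]
        for b in range(a + 1, len(pairs)):
            u2, v2 = pairs[b]
            if (u1 == u2) != (v1 == v2):
                out.append(f"one-to-one violated by ({u1},{v1}) and ({u2},{v2})")
                continue
            if u1 == u2:
                continue
            if (u1 in anc1[u2]) != (v1 in anc2[v2]) or \
               (u2 in anc1[u1]) != (v2 in anc2[v1]):
                out.append(f"ancestry violated by ({u1},{v1}) and ({u2},{v2})")
    return MappingReport(out)


@dataclass
class TedResult:
    """An edit distance together with the mapping that realises it.

    ``operations`` classifies every node: pairs matched at zero cost, pairs
    substituted at positive cost, and the unmapped deleted/inserted nodes.
    The DP engine reports the distance only (mapping/operations are None).
    """

    distance: float
    score: float
    mapping: Optional[set[tuple[int, int]]]
    operations: Optional[dict] = None
    timed_out: bool = False
    solver: Optional[SolveResult] = None

    def report(self) -> str:
        """Tab-separated summary: distance, score, node classification."""
        lines = [f"distance\t{self.distance:g}", f"score\t{self.score:g}"]
        if self.timed_out:
            lines.append("timed_out\ttrue (distance is an upper bound)")
        if self.operations is not None:
            ops = self.operations
            lines.append("matched\t" + ",".join(f"{u}:{v}" for u, v in sorted(ops["matched"])))
            lines.append("substituted\t" + ",".join(f"{u}:{v}" for u, v in sorted(ops["substituted"])))
            lines.append("deleted\t" + ",".join(str(u) for u in sorted(ops["deleted"])))
            lines.append("inserted\t" + ",".join(str(v) for v in sorted(ops["inserted"])))
        return "\n".join(lines) + "\n"


def _totals(t1: Tree, t2: Tree, s: CostScheme) -> float:
    return (sum(s.delete(t1.label(u)) for u in t1.node_ids())
            + sum(s.insert(t2.label(v)) for v in t2.node_ids()))


def _assemble(t1: Tree, t2: Tree, s: CostScheme,
              mapping: set[tuple[int, int]], score: float,
              timed_out: bool, solver: SolveResult) -> TedResult:
    """Price a mapping both ways and package the result.

    The decomposition sum and the totals-minus-score form must agree; a gap
    would mean the clique weights and the cost scheme fell out of sync.
    """
    sub_cost = sum(s.gamma(t1.label(u), t2.label(v)) for u, v in mapping)
    m1 = {u for u, _ in mapping}
    m2 = {v for _, v in mapping}
    del_cost = sum(s.delete(t1.label(u)) for u in t1.node_ids() if u not in m1)
    ins_cost = sum(s.insert(t2.label(v)) for v in t2.node_ids() if v not in m2)
    direct = sub_cost + del_cost + ins_cost
    via_score = _totals(t1, t2, s) - score
    if abs(direct - via_score) > _AGREE_TOL:
        raise AssertionError(
            f"distance decompositions disagree: {direct} vs {via_score}")
    ops = {
        "matched": {(u, v) for u, v in mapping
                    if s.gamma(t1.label(u), t2.label(v)) == 0.0},
        "substituted": {(u, v) for u, v in mapping
                        if s.gamma(t1.label(u), t2.label(v)) > 0.0},
        "deleted": {u for u in t1.node_ids() if u not in m1},
        "inserted": {v for v in t2.node_ids() if v not in m2},
    }
    return TedResult(direct, score, mapping, ops, timed_out, solver)


def _clique_ted(t1: Tree, t2: Tree, s: CostScheme, mode: str,
                prune_zero: Optional[bool], timeout: Optional[float],
                weighted: bool = True,
                warm_start: bool = False) -> tuple[TedResult, AssociationGraph]:
    import time as _time

    d1, d2 = add_dummy_roots(t1, t2)
    if prune_zero is None:
        prune_zero = s.name == "lcs"
    g = build_association_graph(d1, d2, s, mode=mode, prune_zero=prune_zero)
    if weighted:
        initial: tuple = ()
        if warm_start and mode == "unordered":
            # the ordered optimum is a valid unordered mapping and usually a
            # near-optimal incumbent; its graph is sparser and solves fast
            start = _time.monotonic()
            go = build_association_graph(d1, d2, s, mode="ordered",
                                         prune_zero=prune_zero)
            ord_budget = None if timeout is None else timeout / 2
            seed_res = max_weight_clique(go.adj, go.weights,
                                         timeout=ord_budget)
            initial = tuple(seed_res.best_set)  # same vertex indexing
            if timeout is not None:
                timeout = max(0.0, timeout - (_time.monotonic() - start))
        res = max_weight_clique(g.adj, g.weights, timeout=timeout,
                                initial=initial)
        score = res.best_value
    else:
        res = max_clique(g.adj, timeout=timeout)
        score = sum(g.weights[i] for i in res.best_set)
    pairs = clique_to_mapping(g, res.best_set)
    pairs.discard((d1.root, d2.root))  # sentinel pair carries no information
    return _assemble(t1, t2, s, pairs, score, res.timed_out, res), g


def unordered_ted(t1: Tree, t2: Tree, s: CostScheme,
                  prune_zero: Optional[bool] = None,
                  timeout: Optional[float] = None,
                  warm_start: bool = True) -> TedResult:
    """Exact edit distance between rooted labelled unordered trees.

    Builds the association graph of the dummy-rooted trees and solves a
    maximum vertex-weighted clique; by default the search is warm-started
    from the ordered-mode optimum (a valid unordered mapping), which never
    changes the optimal value. On solver timeout the incumbent mapping is
    still valid, so the reported distance is an upper bound, flagged by
    ``timed_out``.
    """
    return _clique_ted(t1, t2, s, "unordered", prune_zero, timeout,
                       warm_start=warm_start)[0]


def ordered_ted(t1: Tree, t2: Tree, s: CostScheme, engine: str = "clique",
                timeout: Optional[float] = None) -> TedResult:
    """Edit distance with sibling order respected.

    ``engine="clique"`` restricts association-graph edges to order-consistent
    pairs; ``engine="dp"`` runs the keyroot dynamic program over ordered
    forests instead (distance only). Both must agree.
    """
    if engine == "clique":
        return _clique_ted(t1, t2, s, "ordered", None, timeout)[0]
    if engine == "dp":
        dist = _zhang_shasha(t1, t2, s)
        return TedResult(dist, _totals(t1, t2, s) - dist, None)
    raise ValueError(f"unknown engine {engine!r}")


def reversed_ordered_ted(t1: Tree, t2: Tree, s: CostScheme,
                         engine: str = "clique",
                         timeout: Optional[float] = None) -> TedResult:
    """Ordered distance after reversing every child sequence of the second
    tree; a control separating genuinely unordered similarity from sibling
    order agreement."""
    return ordered_ted(t1, reverse_children(t2), s, engine=engine,
                       timeout=timeout)


def largest_common_subtree(t1: Tree, t2: Tree,
                           timeout: Optional[float] = None
                           ) -> tuple[int, set[tuple[int, int]]]:
    """Largest tree obtainable from both inputs by deletions only.

    Under delete/insert cost 1 and mismatch cost 2, matching unequal labels
    gains nothing, so zero-gain vertices are pruned and an unweighted
    maximum clique over the label-matched pairs suffices. The returned size
    satisfies |V1| + |V2| - 2*size = edit distance under that scheme.
    """
    alphabet = t1.labels() | t2.labels()
    s = lcs_scheme(alphabet)
    res, _ = _clique_ted(t1, t2, s, "unordered", True, timeout, weighted=False)
    matched = {(u, v) for u, v in res.mapping
               if t1.label(u) == t2.label(v)}
    return len(matched), matched


# -- exhaustive oracle --------------------------------------------------------

def brute_force_ted(t1: Tree, t2: Tree, s: CostScheme) -> TedResult:
    """Minimise the cost decomposition over every valid mapping directly.

    Enumerates all one-to-one, ancestry-preserving node correspondences by
    recursion over the first tree's preorder (each node is left unmapped or
    paired with a compatible unused node), with no clique machinery. Guarded
    to |V1| * |V2| <= 64.
    """
    if t1.n * t2.n > 64:
        raise ValueError("brute force guarded to |V1|*|V2| <= 64")
    nodes1 = list(t1.preorder())
    nodes2 = list(t2.preorder())
    anc1 = {u: t1.ancestors(u) for u in nodes1}
    anc2 = {v: t2.ancestors(v) for v in nodes2}
    f = {(u, v): score_f(s, t1.label(u), t2.label(v))
         for u in nodes1 for v in nodes2}

    best_score = 0.0
    best_map: tuple = ()
    chosen: list[tuple[int, int]] = []
    used2: set[int] = set()

    def rec(i: int, score: float) -> None:
        nonlocal best_score, best_map
        if i == len(nodes1):
            if score > best_score:
                best_score = score
                best_map = tuple(chosen)
            return
        u = nodes1[i]
        rec(i + 1, score)  # u unmapped (deleted)
        for v in nodes2:
            if v in used2:
                continue
            ok = True
            for u2, v2 in chosen:
                if (u2 in anc1[u]) != (v2 in anc2[v]) or \
                   (u in anc1[u2]) != (v in anc2[v2]):
                    ok = False
                    break
            if ok:
                chosen.append((u, v))
                used2.add(v)
                rec(i + 1, score + f[(u, v)])
                chosen.pop()
                used2.remove(v)

    rec(0, 0.0)
    return _assemble(t1, t2, s, set(best_map), best_score, False, None)


# -- ordered-tree dynamic program --------------------------------------------

def _zhang_shasha(t1: Tree, t2: Tree, s: CostScheme) -> float:
    """Keyroot/forest dynamic program for the ordered edit distance.

    Classic O(n^2 * depth-ish) scheme: nodes in postorder, a forest-distance
    table per keyroot pair, subtree distances memoised in ``td``.
    """

    def arrays(t: Tree):
        po = list(t.postorder())
        idx = {v: i for i, v in enumerate(po)}
        lml = [0] * len(po)  # leftmost leaf descendant, postorder index
        for i, v in enumerate(po):
            ch = t.children(v)
            lml[i] = idx[ch[0]] if ch else i
            while ch:
                v2 = ch[0]
                lml[i] = lml[idx[v2]]
                ch = t.children(v2)
        labels = [t.label(v) for v in po]
        keyroots = sorted({max(i for i in range(len(po)) if lml[i] == lml[k])
                           for k in range(len(po))})
        return labels, lml, keyroots

    lab1, lml1, kr1 = arrays(t1)
    lab2, lml2, kr2 = arrays(t2)
    n1, n2 = len(lab1), len(lab2)
    td = [[0.0] * n2 for _ in range(n1)]

    for i in kr1:
        for j in kr2:
            # forest distance over postorder slices [lml(i)..i] x [lml(j)..j]
            li, lj = lml1[i], lml2[j]
            m, n = i - li + 2, j - lj + 2
            fd = [[0.0] * n for _ in range(m)]
            for x in range(1, m):
                fd[x][0] = fd[x - 1][0] + s.delete(lab1[li + x - 1])
            for y in range(1, n):
                fd[0][y] = fd[0][y - 1] + s.insert(lab2[lj + y - 1])
            for x in range(1, m):
                u = li + x - 1
                for y in range(1, n):
                    v = lj + y - 1
                    best = min(fd[x - 1][y] + s.delete(lab1[u]),
                               fd[x][y - 1] + s.insert(lab2[v]))
                    if lml1[u] == li and lml2[v] == lj:
                        # both slices are whole subtrees: substitution allowed
                        cand = fd[x - 1][y - 1] + s.gamma(lab1[u], lab2[v])
                        if cand < best:
                            best = cand
                        td[u][v] = best
                    else:
                        cand = fd[lml1[u] - li][lml2[v] - lj] + td[u][v]
                        if cand < best:
                            best = cand
                    fd[x][y] = best
    return td[n1 - 1][n2 - 1]
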