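"""Association graph linking two trees: cliques correspond to edit mappings.

Vertices are cross-tree node pairs (u, v) over the non-root nodes of both
(dummy-rooted) trees, weighted by the match gain f(u, v). Two vertices are
adjacent when the pairs are mutually compatible as mapping entries: distinct
nodes on both sides and the ancestor relation preserved in both directions.
Under that construction the cliques of the graph are exactly the valid edit
distance mappings (with root fixed to root), and a maximum-weight clique is
an optimal mapping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from .costs import CostScheme, score_f
from .tree import DUMMY_LABEL, Tree


@dataclass
class AssociationGraph:
    """Vertex-weighted undirected graph over node pairs of two trees."""

    t1: Tree
    t2: Tree
    vertices: list[tuple[int, int]]  # (node in t1, node in t2)
    weights: list[float]
    adj: list[int]  # bitmask adjacency, index-aligned with vertices
    mode: str  # "unordered" | "ordered"

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(m.bit_count() for m in self.adj) // 2

    def neighbours(self, i: int) -> list[int]:
        m = self.adj[i]
        out = []
        while m:
            low = m & -m
            out.append(low.bit_length() - 1)
            m ^= low
        return out


def _order_index(t: Tree) -> dict[int, int]:
    """Preorder position of each node; encodes left-to-right sibling order."""
    return {v: i for i, v in enumerate(t.preorder())}


def build_association_graph(t1: Tree, t2: Tree, s: CostScheme,
                            mode: str = "unordered",
                            prune_zero: bool = False) -> AssociationGraph:
    """Construct the vertex-weighted compatibility graph of two dummy-rooted trees.

    Both inputs must already carry sentinel dummy roots, which are excluded
    from the vertex set (root maps to root by construction). In ordered mode
    an edge additionally requires that pairs of nodes unrelated by ancestry
    appear in the same left-to-right order on both sides. With ``prune_zero``
    vertices of zero gain are dropped; since gains are non-negative this
    never changes the maximum-weight objective.
    """
    if t1.label(t1.root) != DUMMY_LABEL or t2.label(t2.root) != DUMMY_LABEL:
        raise ValueError("trees must be dummy-rooted (see add_dummy_roots)")
    if mode not in ("unordered", "ordered"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = (t1.labels() | t2.labels()) - {DUMMY_LABEL}
    missing = labels - set(s.alphabet)
    if missing:
        raise ValueError(f"labels not covered by the cost scheme: {sorted(missing)}")

    def keyed(t: Tree) -> list[int]:
        return sorted((v for v in t.node_ids() if v != t.root),
                      key=lambda v: (t.depth(v), v))

    nodes1, nodes2 = keyed(t1), keyed(t2)
    vertices: list[tuple[int, int]] = []
    weights: list[float] = []
    for u in nodes1:
        for v in nodes2:
            w = score_f(s, t1.label(u), t2.label(v))
            if prune_zero and w <= 0.0:
                continue
            vertices.append((u, v))
            weights.append(w)

    anc1 = {v: t1.ancestors(v) for v in nodes1}
    anc2 = {v: t2.ancestors(v) for v in nodes2}
    if mode == "ordered":
        pre1, pre2 = _order_index(t1), _order_index(t2)

    n = len(vertices)
    adj = [0] * n
    for i in range(n):
        u1, v1 = vertices[i]
        for j in range(i + 1, n):
            u2, v2 = vertices[j]
            if u1 == u2 or v1 == v2:
                continue
            u1_anc_u2 = u1 in anc1[u2]
            u2_anc_u1 = u2 in anc1[u1]
            if u1_anc_u2 != (v1 in anc2[v2]):
                continue
            if u2_anc_u1 != (v2 in anc2[v1]):
                continue
            if mode == "ordered" and not u1_anc_u2 and not u2_anc_u1:
                # unrelated pairs must keep their left-to-right order
                if (pre1[u1] < pre1[u2]) != (pre2[v1] < pre2[v2]):
                    continue
            adj[i] |= 1 << j
            adj[j] |= 1 << i
    return AssociationGraph(t1, t2, vertices, weights, adj, mode)


def clique_to_mapping(g: AssociationGraph, clique) -> set[tuple[int, int]]:
    """Turn a clique (vertex indices) into a mapping, adding the root pair."""
    clique = list(clique)
    for a in range(len(clique)):
        for b in range(a + 1, len(clique)):
            if not (g.adj[clique[a]] >> clique[b]) & 1:
                raise ValueError(
                    f"vertices {clique[a]} and {clique[b]} are not adjacent")
    pairs = {g.vertices[i] for i in clique}
    pairs.add((g.t1.root, g.t2.root))
    return pairs


def to_dimacs(g: AssociationGraph) -> tuple[str, str]:
    """Export as a DIMACS ascii clique instance plus a vertex-weight file.

    Vertices are numbered from 1 in stored order; the weight file has one
    ``<vertex> <weight>`` line per vertex.
    """
    buf = io.StringIO()
    buf.write(f"p edge {g.n_vertices} {g.n_edges}\n")
    for i in range(g.n_vertices):
        for j in g.neighbours(i):
            if j > i:
                buf.write(f"e {i + 1} {j + 1}\n")
    wbuf = io.StringIO()
    for i, w in enumerate(g.weights):
        wbuf.write(f"{i + 1} {w:g}\n")
    return buf.getvalue(), wbuf.getvalue()
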