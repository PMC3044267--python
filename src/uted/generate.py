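"""Seeded generators: random trees, random metric cost schemes, edit scripts.

Everything here is a pure function of its seed so fixtures never need to be
stored: identical parameters reproduce bit-identical trees and schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import EPSILON, CostScheme, unit_scheme
from .tree import Tree


def _symbols(alphabet_size: int) -> list[str]:
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be >= 1")
    base = "abcdefghijklmnopqrstuvwxyz"
    if alphabet_size <= len(base):
        return list(base[:alphabet_size])
    return [f"s{i}" for i in range(alphabet_size)]


@dataclass(frozen=True)
class GenSpec:
    """Parameters of a random tree draw.

    ``attachment='uniform-parent'`` picks each new node's parent uniformly
    among existing nodes (shallow, bushy trees); ``'preferential'`` weights
    parents by their current child count plus one, giving broader degree
    spread; ``'chain-biased'`` mostly extends a current leaf and only
    occasionally (p = 0.15) branches off a uniform node, emulating the
    narrow, chain-dominated topology of glycan structures.
    """

    n: int
    alphabet_size: int = 3
    attachment: str = "uniform-parent"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.attachment not in ("uniform-parent", "preferential",
                                   "chain-biased"):
            raise ValueError(f"unknown attachment {self.attachment!r}")


def random_tree(spec: GenSpec) -> Tree:
    """Grow a rooted tree node by node according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    syms = _symbols(spec.alphabet_size)
    labels = [syms[int(i)] for i in rng.integers(0, len(syms), size=spec.n)]
    records: list[tuple[int, str, int | None]] = [(0, labels[0], None)]
    child_count = np.zeros(spec.n)
    leaves = [0]
    for i in range(1, spec.n):
        if spec.attachment == "uniform-parent":
            parent = int(rng.integers(0, i))
        elif spec.attachment == "preferential":
            w = child_count[:i] + 1.0
            parent = int(rng.choice(i, p=w / w.sum()))
        else:  # chain-biased
            if rng.random() < 0.15:
                parent = int(rng.integers(0, i))
            else:
                parent = leaves[int(rng.integers(0, len(leaves)))]
        if parent in leaves:
            leaves.remove(parent)
        leaves.append(i)
        child_count[parent] += 1
        records.append((i, labels[i], parent))
    return Tree(records)


def random_valid_scheme(alphabet_size: int, seed: int = 0) -> CostScheme:
    """Draw a random cost scheme and repair it into a metric.

    Deletion/insertion costs are uniform in [0.5, 2]; each substitution cost
    is uniform in [0, del + ins]; a shortest-path closure over the extended
    alphabet then enforces the triangle inequality (costs can only shrink,
    never below 0, so the other axioms survive).
    """
    rng = np.random.default_rng(seed)
    syms = _symbols(alphabet_size)
    ext = syms + [EPSILON]
    k = len(ext)
    g = np.zeros((k, k))
    de = rng.uniform(0.5, 2.0, size=len(syms))
    for i in range(len(syms)):
        g[i, k - 1] = g[k - 1, i] = de[i]
    for i in range(len(syms)):
        for j in range(i + 1, len(syms)):
            g[i, j] = g[j, i] = rng.uniform(0.0, de[i] + de[j])
    # Floyd-Warshall closure: replace each cost by the cheapest edit chain
    for m in range(k):
        g = np.minimum(g, g[:, m:m + 1] + g[m:m + 1, :])
    table = {(ext[i], ext[j]): float(g[i, j])
             for i in range(k) for j in range(k) if i != j}
    return CostScheme(frozenset(syms), table, name=f"random-{seed}")


# -- edit-script perturbation --------------------------------------------------


def _mutable(t: Tree):
    labels = {v: t.label(v) for v in t.node_ids()}
    children = {v: t.children(v) for v in t.node_ids()}
    parent = {v: t.parent(v) for v in t.node_ids()}
    return labels, children, parent


def _freeze(labels, children, root) -> Tree:
    records = []
    stack = [(root, None)]
    while stack:
        v, p = stack.pop()
        records.append((v, labels[v], p))
        stack.extend((c, v) for c in reversed(children[v]))
    return Tree(records)


def perturb(t: Tree, k: int, seed: int = 0,
            scheme: CostScheme | None = None) -> tuple[Tree, float]:
    """Apply ``k`` random edit operations; return the result and the script cost.

    Deletion splices the victim's children into its parent's child sequence
    at the victim's position; insertion makes the new node the parent of a
    contiguous block of an existing node's children (so the operations are
    exact inverses and safe for ordered trees); substitution redraws a label.
    The true edit distance is bounded above by the returned cost.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    alphabet = sorted(t.labels())
    if scheme is None:
        scheme = unit_scheme(set(alphabet))
    labels, children, parent = _mutable(t)
    root = t.root
    next_id = max(labels) + 1
    cost = 0.0
    for _ in range(k):
        ops = ["insert", "substitute"]
        if len(labels) > 1:
            ops.append("delete")
        op = ops[int(rng.integers(0, len(ops)))]
        nodes = sorted(labels)
        if op == "delete":
            candidates = [v for v in nodes if v != root]
            v = candidates[int(rng.integers(0, len(candidates)))]
            u = parent[v]
            pos = children[u].index(v)
            children[u][pos:pos + 1] = children[v]
            for c in children[v]:
                parent[c] = u
            cost += scheme.delete(labels[v])
            del labels[v], children[v], parent[v]
        elif op == "insert":
            u = nodes[int(rng.integers(0, len(nodes)))]
            ch = children[u]
            i = int(rng.integers(0, len(ch) + 1))
            j = int(rng.integers(i, len(ch) + 1))
            v = next_id
            next_id += 1
            lab = alphabet[int(rng.integers(0, len(alphabet)))]
            block = ch[i:j]
            children[u][i:j] = [v]
            children[v] = block
            for c in block:
                parent[c] = v
            parent[v] = u
            labels[v] = lab
            cost += scheme.insert(lab)
        else:
            v = nodes[int(rng.integers(0, len(nodes)))]
            old = labels[v]
            others = [a for a in alphabet if a != old]
            new = others[int(rng.integers(0, len(others)))] if others else old
            labels[v] = new
            cost += scheme.gamma(old, new)
    return _freeze(labels, children, root), cost
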