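"""Rooted labelled trees and readers for bracket notation and KCF glycan records.

A tree is stored as a flat table of nodes with stable integer ids assigned in
input order. Child sequences are kept in order; the order is consulted only by
ordered-mode comparisons, everything else treats the tree as unordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

#: Reserved label for dummy roots; not permitted in input alphabets.
DUMMY_LABEL = "⊥"  # "⊥"


class TreeFormatError(ValueError):
    """Raised for malformed bracket or KCF input."""


@dataclass
class _Node:
    id: int
    label: str
    parent: Optional[int]
    children: list[int] = field(default_factory=list)


class Tree:
    """A rooted tree with string labels and ordered child sequences.

    Invariants: exactly one root, parent/child links consistent and acyclic,
    ids unique, labels non-empty.
    """

    def __init__(self, nodes: list[tuple[int, str, Optional[int]]]):
        """Build a tree from (id, label, parent-id-or-None) records.

        Children of each node are ordered by the record order of the input.
        """
        self._nodes: dict[int, _Node] = {}
        root = None
        for nid, label, parent in nodes:
            if nid in self._nodes:
                raise TreeFormatError(f"duplicate node id {nid}")
            if not label:
                raise TreeFormatError(f"empty label on node {nid}")
            self._nodes[nid] = _Node(nid, label, parent)
            if parent is None:
                if root is not None:
                    raise TreeFormatError("more than one root")
                root = nid
        if root is None:
            raise TreeFormatError("no root (empty tree or a cycle)")
        for node in self._nodes.values():
            if node.parent is not None:
                if node.parent not in self._nodes:
                    raise TreeFormatError(
                        f"node {node.id} has unknown parent {node.parent}")
                self._nodes[node.parent].children.append(node.id)
        self.root: int = root
        # reachability check doubles as the acyclicity check
        seen = set()
        stack = [root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeFormatError("cycle detected")
            seen.add(v)
            stack.extend(self._nodes[v].children)
        if len(seen) != len(self._nodes):
            raise TreeFormatError("nodes unreachable from the root")

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self._nodes)

    def node_ids(self) -> list[int]:
        return list(self._nodes)

    def label(self, v: int) -> str:
        return self._node(v).label

    def parent(self, v: int) -> Optional[int]:
        return self._node(v).parent

    def children(self, v: int) -> list[int]:
        return list(self._node(v).children)

    def labels(self) -> set[str]:
        return {nd.label for nd in self._nodes.values()}

    def _node(self, v: int) -> _Node:
        try:
            return self._nodes[v]
        except KeyError:
            raise KeyError(f"unknown node id {v}") from None

    def ancestors(self, v: int) -> set[int]:
        """Strict ancestors of v up to and including the root; empty for the root."""
        out = set()
        p = self._node(v).parent
        while p is not None:
            out.add(p)
            p = self._nodes[p].parent
        return out

    def depth(self, v: int) -> int:
        return len(self.ancestors(v))

    def preorder(self) -> Iterator[int]:
        """Node ids in preorder, children visited in stored order."""
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self._nodes[v].children))

    def postorder(self) -> Iterator[int]:
        out = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self._nodes[v].children)
        return iter(reversed(out))

    # -- transforms --------------------------------------------------------

    def records(self) -> list[tuple[int, str, Optional[int]]]:
        """Node records in preorder (a valid constructor argument)."""
        return [(v, self._nodes[v].label, self._nodes[v].parent)
                for v in self.preorder()]

    def relabelled(self, mapping: dict[int, str]) -> "Tree":
        recs = [(v, mapping.get(v, lab), p) for v, lab, p in self.records()]
        return Tree(recs)

    def __eq__(self, other: object) -> bool:
        """Ordered-tree equality: same shape, labels and child order (ids ignored)."""
        if not isinstance(other, Tree):
            return NotImplemented
        return _ordered_key(self, self.root) == _ordered_key(other, other.root)

    def __repr__(self) -> str:
        return f"Tree({write_bracket(self)!r})"


def _ordered_key(t: Tree, v: int):
    return (t.label(v), tuple(_ordered_key(t, c) for c in t.children(v)))


# -- bracket notation -------------------------------------------------------

def parse_bracket(text: str) -> Tree:
    """Parse ``label(child,child,...)`` notation into a Tree.

    Labels are alphanumeric tokens (``_`` allowed); whitespace is ignored.
    Children keep their written order.
    """
    s = "".join(text.split())
    pos = 0
    records: list[tuple[int, str, Optional[int]]] = []

    def fail(msg: str):
        raise TreeFormatError(f"{msg} at position {pos}")

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and (s[pos].isalnum() or s[pos] == "_"):
            pos += 1
        if pos == start:
            fail("expected a label")
        return s[start:pos]

    def read_node(parent: Optional[int]):
        nonlocal pos
        label = read_label()
        nid = len(records)
        records.append((nid, label, parent))
        if pos < len(s) and s[pos] == "(":
            pos += 1
            read_node(nid)
            while pos < len(s) and s[pos] == ",":
                pos += 1
                read_node(nid)
            if pos >= len(s) or s[pos] != ")":
                fail("expected ')' or ','")
            pos += 1

    read_node(None)
    if pos != len(s):
        fail("trailing input")
    return Tree(records)


def write_bracket(t: Tree) -> str:
    """Canonical bracket form: children in stored order, no whitespace."""

    def rec(v: int) -> str:
        ch = t.children(v)
        if not ch:
            return t.label(v)
        return t.label(v) + "(" + ",".join(rec(c) for c in ch) + ")"

    return rec(t.root)


# -- KCF glycan records ------------------------------------------------------

def parse_kcf(text: str) -> Tree:
    """Parse a single KCF glycan record into a rooted tree.

    KCF draws the reducing end rightmost, so the NODE with the largest
    x-coordinate is taken as the root (ties broken by smallest node index).
    EDGE lines are read as ``index  child[:anomer]  parent[:position]``;
    the anomer/position annotations after ``:`` are discarded. Children of
    each node are ordered by descending y-coordinate, ties by node index.
    """
    nodes: dict[int, tuple[str, float, float]] = {}
    edges: list[tuple[int, int]] = []
    section = None
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line.strip() or line.strip() == "///":
            continue
        head = line.split()[0]
        if head in ("ENTRY", "NODE", "EDGE", "BRACKET"):
            section = head
            rest = line.split()[1:]
            if section in ("ENTRY", "BRACKET"):
                continue
            # NODE/EDGE header lines carry only the count
            continue
        fields = line.split()
        if section == "NODE":
            if len(fields) < 4:
                raise TreeFormatError(f"short NODE line: {line!r}")
            idx = int(fields[0])
            nodes[idx] = (fields[1], float(fields[2]), float(fields[3]))
        elif section == "EDGE":
            if len(fields) < 3:
                raise TreeFormatError(f"short EDGE line: {line!r}")
            child = int(fields[1].split(":")[0])
            parent = int(fields[2].split(":")[0])
            edges.append((child, parent))
    if not nodes:
        raise TreeFormatError("missing NODE section")
    for c, p in edges:
        if c not in nodes or p not in nodes:
            raise TreeFormatError(f"EDGE references unknown node ({c},{p})")
    root = max(nodes, key=lambda i: (nodes[i][1], -i))
    parent_of: dict[int, Optional[int]] = {root: None}
    adj: dict[int, list[int]] = {i: [] for i in nodes}
    for c, p in edges:
        adj[c].append(p)
        adj[p].append(c)
    # orient edges away from the root; rejects cycles and disconnection
    order = [root]
    seen = {root}
    qi = 0
    while qi < len(order):
        v = order[qi]
        qi += 1
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                parent_of[w] = v
                order.append(w)
    if len(seen) != len(nodes):
        raise TreeFormatError("record is not a single connected tree")
    if len(edges) != len(nodes) - 1:
        raise TreeFormatError("record contains a cycle")
    # children sorted by descending y, tie -> node index
    by_parent: dict[int, list[int]] = {i: [] for i in nodes}
    for v in nodes:
        p = parent_of.get(v)
        if p is not None:
            by_parent[p].append(v)
    for p in by_parent:
        by_parent[p].sort(key=lambda i: (-nodes[i][2], i))
    records: list[tuple[int, str, Optional[int]]] = []
    stack = [root]
    while stack:
        v = stack.pop()
        records.append((v, nodes[v][0], parent_of[v]))
        stack.extend(reversed(by_parent[v]))
    return Tree(records)


def write_kcf(t: Tree, entry: str = "G00000") -> str:
    """Render a tree as a KCF record that :func:`parse_kcf` reads back.

    Coordinates are synthetic: x decreases with depth (so the root is the
    rightmost node) and y decreases in preorder (so the stored child order
    is recovered by the descending-y rule).
    """
    order = list(t.preorder())
    idx = {v: i + 1 for i, v in enumerate(order)}
    lines = [f"ENTRY     {entry}          Glycan", f"NODE      {t.n}"]
    for i, v in enumerate(order):
        x = -10 * t.depth(v)
        lines.append(f"            {idx[v]}   {t.label(v)}   {x}   {-i}")
    edges = [v for v in order if t.parent(v) is not None]
    lines.append(f"EDGE      {len(edges)}")
    for j, v in enumerate(edges, start=1):
        lines.append(f"            {j}   {idx[v]}   {idx[t.parent(v)]}")
    lines.append("///")
    return "\n".join(lines) + "\n"


def parse_kcf_file(text: str) -> list[Tree]:
    """Parse a multi-record KCF file (records separated by ``///``)."""
    out = []
    for chunk in text.split("///"):
        if chunk.strip():
            out.append(parse_kcf(chunk))
    return out


# -- structural utilities ----------------------------------------------------

def add_dummy_roots(t1: Tree, t2: Tree) -> tuple[Tree, Tree]:
    """Wrap both trees with a fresh sentinel-labelled root.

    The sentinel label lies outside any input alphabet, so the forced
    root-to-root match costs nothing while letting the old roots be deleted,
    inserted or substituted like any other node. Not idempotent: applying
    twice nests two dummies.
    """
    return _wrap(t1), _wrap(t2)


def _wrap(t: Tree) -> Tree:
    new_root = max(t.node_ids()) + 1
    recs: list[tuple[int, str, Optional[int]]] = [(new_root, DUMMY_LABEL, None)]
    for v, lab, p in t.records():
        recs.append((v, lab, new_root if p is None else p))
    return Tree(recs)


def reverse_children(t: Tree) -> Tree:
    """Reverse every node's child sequence; an involution on ordered trees."""
    recs: list[tuple[int, str, Optional[int]]] = []
    stack = [t.root]
    while stack:
        v = stack.pop()
        recs.append((v, t.label(v), t.parent(v)))
        stack.extend(t.children(v))  # pushing in order pops reversed
    return Tree(recs)
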