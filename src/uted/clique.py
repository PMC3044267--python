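"""Exact maximum clique and maximum vertex-weighted clique.

Branch-and-bound in the MCQ/MWCQ family: vertices are ordered once by
non-increasing degree, and at every search node the candidate set is greedily
colour-sorted. A clique holds at most one vertex per colour class, so the sum
over classes of the heaviest class member bounds the best attainable weight
(for unit weights this degenerates to the number of classes bounding the
clique size); branches whose bound cannot beat the incumbent are cut. The
search is deterministic: ties break by stable input order everywhere.

Graphs are plain bitset adjacency lists (``adj[i]`` has bit j set iff i~j),
which keeps the inner loops to integer AND/OR operations.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

#: absolute tolerance for float-weight comparisons during pruning
TOL = 1e-9


@dataclass
class SolveResult:
    best_set: frozenset[int]
    best_value: float
    nodes_explored: int
    timed_out: bool = False


class _Timeout(Exception):
    pass


def from_edges(n: int, edges) -> list[int]:
    """Bitset adjacency from an edge list over vertices 0..n-1."""
    adj = [0] * n
    for i, j in edges:
        if i == j:
            raise ValueError("self-loop")
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    return adj


def read_dimacs(text: str) -> list[int]:
    """Read a DIMACS ascii clique instance (``p edge`` / ``e i j`` lines)."""
    n = None
    edges = []
    for line in text.splitlines():
        parts = line.split()
        if not parts or parts[0] == "c":
            continue
        if parts[0] == "p":
            n = int(parts[2])
        elif parts[0] == "e":
            edges.append((int(parts[1]) - 1, int(parts[2]) - 1))
    if n is None:
        raise ValueError("missing 'p edge' line")
    return from_edges(n, edges)


class _Search:
    """One branch-and-bound run over a degree-reordered copy of the graph."""

    def __init__(self, adj: list[int], weights: list[float],
                 timeout: float | None, initial=()):
        n = len(adj)
        # non-increasing degree, ties by input order
        order = sorted(range(n), key=lambda v: (-adj[v].bit_count(), v))
        self.back = order  # internal index -> original vertex
        pos = {v: i for i, v in enumerate(order)}
        self.adj = [0] * n
        for v in range(n):
            m = adj[v]
            acc = 0
            while m:
                low = m & -m
                acc |= 1 << pos[low.bit_length() - 1]
                m ^= low
            self.adj[pos[v]] = acc
        self.w = [weights[v] for v in order]
        self.n = n
        self.deadline = None if timeout is None else time.monotonic() + timeout
        self.best = sum(self.w[pos[v]] for v in initial)
        self.best_set: tuple[int, ...] = tuple(pos[v] for v in initial)
        self.nodes = 0

    def run(self) -> SolveResult:
        timed_out = False
        try:
            if self.n:
                self._expand((1 << self.n) - 1, (), 0.0)
        except _Timeout:
            timed_out = True
        best = frozenset(self.back[i] for i in self.best_set)
        return SolveResult(best, self.best, self.nodes, timed_out)

    def _expand(self, cand: int, clique: tuple[int, ...], weight: float) -> None:
        self.nodes += 1
        if self.deadline is not None and self.nodes % 256 == 0:
            if time.monotonic() > self.deadline:
                raise _Timeout
        order, bounds = self._colour_sort(cand)
        adj = self.adj
        w = self.w
        for i in range(len(order) - 1, -1, -1):
            if weight + bounds[i] <= self.best + TOL:
                return
            v = order[i]
            sub = cand & adj[v]
            ext = clique + (v,)
            if sub:
                self._expand(sub, ext, weight + w[v])
            elif weight + w[v] > self.best + TOL:
                self.best = weight + w[v]
                self.best_set = ext
            cand &= ~(1 << v)

    def _colour_sort(self, cand: int) -> tuple[list[int], list[float]]:
        """Greedy sequential colouring; returns vertices grouped by colour
        class together with the cumulative per-class-maximum weight bound."""
        adj = self.adj
        w = self.w
        order: list[int] = []
        bounds: list[float] = []
        uncoloured = cand
        cum = 0.0
        while uncoloured:
            avail = uncoloured
            members = []
            cls_max = 0.0
            while avail:
                low = avail & -avail
                v = low.bit_length() - 1
                members.append(v)
                if w[v] > cls_max:
                    cls_max = w[v]
                avail &= ~adj[v]
                avail ^= low
            cum += cls_max
            for v in members:
                uncoloured &= ~(1 << v)
                order.append(v)
                bounds.append(cum)
        return order, bounds


def max_weight_clique(adj: list[int], weights, timeout: float | None = None,
                      engine: str = "compiled", initial=()) -> SolveResult:
    """Exact maximum vertex-weighted clique (weights must be >= 0).

    Two engines run the identical search (same vertex order, colouring,
    bound and tie-breaks, hence identical results): ``"compiled"`` (default)
    is the numba bitset kernel, ``"python"`` the plain reference
    implementation. ``initial`` optionally warm-starts the incumbent with a
    known clique (the optimum is returned regardless; a good start only
    prunes earlier). On timeout the incumbent (a valid clique, a lower
    bound on the optimum) is returned with ``timed_out=True``.
    """
    weights = [float(x) for x in weights]
    if len(weights) != len(adj):
        raise ValueError("weights/adjacency length mismatch")
    if any(x < 0 for x in weights):
        raise ValueError("negative vertex weight")
    initial = sorted(set(initial))
    for a in range(len(initial)):
        for b in range(a + 1, len(initial)):
            if not (adj[initial[a]] >> initial[b]) & 1:
                raise ValueError("initial vertices do not form a clique")
    if engine == "python":
        return _Search(adj, weights, timeout, initial).run()
    if engine != "compiled":
        raise ValueError(f"unknown engine {engine!r}")
    from ._bb import solve_numba

    # the kernel assumes the degree-sorted vertex order; remap around it
    n = len(adj)
    order = sorted(range(n), key=lambda v: (-adj[v].bit_count(), v))
    pos = {v: i for i, v in enumerate(order)}
    radj = [0] * n
    for v in range(n):
        m = adj[v]
        acc = 0
        while m:
            low = m & -m
            acc |= 1 << pos[low.bit_length() - 1]
            m ^= low
        radj[pos[v]] = acc
    rw = [weights[v] for v in order]
    best, value, nodes, timed_out = solve_numba(
        radj, rw, timeout, initial=[pos[v] for v in initial])
    return SolveResult(frozenset(order[i] for i in best), value, nodes,
                       timed_out)


def max_clique(adj: list[int], timeout: float | None = None,
               engine: str = "compiled") -> SolveResult:
    """Exact maximum (cardinality) clique via the same colour-bounded search."""
    res = max_weight_clique(adj, [1.0] * len(adj), timeout, engine=engine)
    return SolveResult(res.best_set, int(round(res.best_value)),
                       res.nodes_explored, res.timed_out)


def brute_force_clique(adj: list[int], weights=None) -> SolveResult:
    """Exhaustive clique enumeration; test oracle for graphs of <= 20 vertices."""
    n = len(adj)
    if n > 20:
        raise ValueError("brute force guarded to 20 vertices")
    if weights is None:
        weights = [1.0] * n
    weights = [float(x) for x in weights]
    best = 0.0
    best_set: tuple[int, ...] = ()
    count = 0

    # every clique extends lexicographically: recurse on candidates above v
    def rec(cand: int, clique: tuple[int, ...], weight: float) -> None:
        nonlocal best, best_set, count
        count += 1
        if weight > best:
            best = weight
            best_set = clique
        m = cand
        while m:
            low = m & -m
            v = low.bit_length() - 1
            m ^= low
            higher = ~((1 << (v + 1)) - 1)
            rec(cand & adj[v] & higher, clique + (v,), weight + weights[v])

    rec((1 << n) - 1 if n else 0, (), 0.0)
    return SolveResult(frozenset(best_set), best, count, False)
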