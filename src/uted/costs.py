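"""Edit-cost schemes over the extended alphabet and the derived score function.

A scheme assigns a cost gamma(a, b) to every pair of symbols from the input
alphabet extended with the empty symbol epsilon: gamma(a, eps) is the cost of
deleting an a-labelled node, gamma(eps, a) of inserting one, gamma(a, b) of a
label substitution. The edit distance is a metric exactly when the scheme
satisfies non-negativity, identity, symmetry and the triangle inequality over
the extended alphabet, and those four axioms also make the derived match gain

    f(u, v) = gamma(l(u), eps) + gamma(eps, l(v)) - gamma(l(u), l(v))

symmetric and non-negative, which the clique reduction relies on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

EPSILON = "-"  # written form of the empty symbol in cost tables


class InvalidSchemeError(ValueError):
    """Raised when a cost table violates the metric axioms (without override)."""


@dataclass(frozen=True)
class CostScheme:
    """An edit-cost function over ``alphabet | {epsilon}``.

    ``table`` maps ordered symbol pairs to costs; identical pairs default
    to 0 when absent. Symmetry is an axiom checked by
    :func:`validate_metric`, not a structural guarantee, so deliberately
    broken tables remain representable.
    """

    alphabet: frozenset[str]
    table: dict[tuple[str, str], float] = field(default_factory=dict)
    name: str = "custom"

    def gamma(self, a: str, b: str) -> float:
        for sym in (a, b):
            if sym != EPSILON and sym not in self.alphabet:
                raise KeyError(f"symbol {sym!r} not in scheme alphabet")
        if a == b:
            return self.table.get((a, b), 0.0)
        return self.table[(a, b)]

    def delete(self, a: str) -> float:
        return self.gamma(a, EPSILON)

    def insert(self, a: str) -> float:
        return self.gamma(EPSILON, a)

    def extended(self) -> list[str]:
        return sorted(self.alphabet) + [EPSILON]


def scheme_from_pairs(alphabet, pairs: dict[tuple[str, str], float],
                      name: str = "custom") -> CostScheme:
    """Build a scheme from costs given once per unordered pair (symmetrised)."""
    table = {}
    for (a, b), v in pairs.items():
        table[(a, b)] = v
        table[(b, a)] = v
    return CostScheme(frozenset(alphabet), table, name=name)


def unit_scheme(alphabet) -> CostScheme:
    """Unit costs: every deletion, insertion and mismatch costs 1."""
    syms = sorted(alphabet) + [EPSILON]
    pairs = {}
    for i, a in enumerate(syms):
        for b in syms[i + 1:]:
            pairs[(a, b)] = 1.0
    return scheme_from_pairs(alphabet, pairs, name="unit")


def lcs_scheme(alphabet) -> CostScheme:
    """Largest-common-subtree costs: delete/insert 1, mismatch 2, match 0.

    A mismatch costs exactly a deletion plus an insertion, so matching
    differently-labelled nodes never pays (f = 0) and an optimal mapping can
    pair identical labels only; its matched pairs form a largest common
    subtree.
    """
    syms = sorted(alphabet)
    pairs = {}
    for i, a in enumerate(syms):
        for b in syms[i + 1:]:
            pairs[(a, b)] = 2.0
        pairs[(a, EPSILON)] = 1.0
    return scheme_from_pairs(alphabet, pairs, name="lcs")


def score_f(s: CostScheme, a: str, b: str) -> float:
    """Gain of matching labels a and b instead of deleting a and inserting b."""
    if a not in s.alphabet:
        raise KeyError(f"symbol {a!r} not in scheme alphabet")
    if b not in s.alphabet:
        raise KeyError(f"symbol {b!r} not in scheme alphabet")
    return s.delete(a) + s.insert(b) - s.gamma(a, b)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.valid


def validate_metric(s: CostScheme) -> ValidationReport:
    """Check the four metric axioms exhaustively over the extended alphabet.

    The triangle inequality is checked over all ordered triples, with the
    empty symbol allowed in any position. Violations are report content,
    not exceptions.
    """
    rep = ValidationReport()
    syms = s.extended()
    g = {}
    for a in syms:
        for b in syms:
            if a == b:
                g[(a, b)] = s.table.get((a, b), 0.0)
            elif (a, b) in s.table:
                g[(a, b)] = s.table[(a, b)]
            else:
                rep.violations.append(f"missing cost for pair ({a},{b})")
                return rep
    for a in syms:
        if g[(a, a)] != 0.0:
            rep.violations.append(f"identity: gamma({a},{a}) = {g[(a, a)]} != 0")
        for b in syms:
            if g[(a, b)] < 0:
                rep.violations.append(f"negativity: gamma({a},{b}) = {g[(a, b)]} < 0")
            if a < b and g[(a, b)] != g[(b, a)]:
                rep.violations.append(f"symmetry: gamma({a},{b}) != gamma({b},{a})")
    tol = 1e-12
    for a in syms:
        for b in syms:
            for c in syms:
                if g[(a, c)] > g[(a, b)] + g[(b, c)] + tol:
                    rep.violations.append(
                        f"triangle: gamma({a},{c}) > gamma({a},{b}) + gamma({b},{c})")
    return rep


def load_cost_table(text: str, allow_invalid: bool = False) -> CostScheme:
    """Read a TSV cost table; the ``-`` column/row is the empty symbol.

    The first row lists the symbols; each body row starts with its symbol.
    Refuses tables failing :func:`validate_metric` unless ``allow_invalid``
    is set, in which case the scheme is returned as written.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0].strip() == "":
        header = header[1:]
    syms = [h.strip() for h in header]
    if EPSILON not in syms:
        raise InvalidSchemeError(f"cost table lacks a {EPSILON!r} column")
    table: dict[tuple[str, str], float] = {}
    seen_rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        row_sym = cells[0].strip()
        if row_sym not in syms:
            raise InvalidSchemeError(f"unknown row symbol {row_sym!r}")
        seen_rows.append(row_sym)
        for col_sym, cell in zip(syms, cells[1:]):
            try:
                table[(row_sym, col_sym)] = float(cell)
            except ValueError:
                raise InvalidSchemeError(
                    f"non-numeric cell {cell!r} at ({row_sym},{col_sym})") from None
    if set(seen_rows) != set(syms):
        raise InvalidSchemeError("row symbols do not match the header")
    scheme = CostScheme(frozenset(s for s in syms if s != EPSILON), table)
    report = validate_metric(scheme)
    if not report.valid and not allow_invalid:
        raise InvalidSchemeError(
            "cost table violates the metric axioms: "
            + "; ".join(report.violations[:5]))
    return scheme


def write_cost_table(s: CostScheme) -> str:
    syms = s.extended()
    buf = io.StringIO()
    buf.write("\t".join([""] + syms) + "\n")
    for a in syms:
        row = [a] + [f"{s.gamma(a, b):g}" for b in syms]
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()
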