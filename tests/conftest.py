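import pytest

from uted.costs import unit_scheme
from uted.generate import GenSpec, random_tree, random_valid_scheme
from uted.tree import parse_bracket

KCF_TWO_NODE = """\
ENTRY     G_test          Glycan
NODE      2
            1   Gal      10     0
            2   GlcNAc    0     0
EDGE      1
            1   2:b1    1:4
///
"""

KCF_STAR = """\
ENTRY     G_star          Glycan
NODE      4
            1   Man       0     5
            2   Gal      10     0
            3   Fuc       0    -5
            4   GlcNAc    0     0
EDGE      3
            1   1:a1    2:2
            2   3:a1    2:6
            3   4:b1    2:4
///
"""


@pytest.fixture
def chain_pair():
    return parse_bracket("a(b)"), parse_bracket("c(d)")


@pytest.fixture
def unit_abc():
    return unit_scheme({"a", "b", "c"})


def random_pair(i: int, lo: int = 4, hi: int = 7):
    """Deterministic random tree pair #i, node counts in [lo, hi]."""
    span = hi - lo + 1
    attach = ("uniform-parent", "preferential")[i % 2]
    t1 = random_tree(GenSpec(lo + i % span, 3, attach, seed=10_000 + i))
    t2 = random_tree(GenSpec(lo + (i // 2) % span, 3, attach, seed=20_000 + i))
    return t1, t2


def scheme_for(i: int):
    """Alternate unit and random metric schemes over the 3-letter alphabet."""
    if i % 2 == 0:
        return unit_scheme({"a", "b", "c"})
    return random_valid_scheme(3, seed=i)
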