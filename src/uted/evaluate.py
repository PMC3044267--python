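"""All-pairs distance matrices and ROC/AUC evaluation of similarity search.

A similarity search over a labelled collection is scored by treating every
unordered pair of items as a sample: a pair is a true relation when the two
items share a class annotation, and the search statistic (a distance, or an
alignment-like score) ranks the pairs. Sweeping a threshold over the
statistic traces a receiver operating characteristic; the area under it is 1
for a perfectly separating statistic and 0.5 for a class-independent one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .costs import CostScheme
from .ted import ordered_ted, reversed_ordered_ted, unordered_ted
from .tree import Tree

log = logging.getLogger(__name__)

_MODES = {
    "unordered": unordered_ted,
    "ordered": ordered_ted,
    "ordered-reversed": reversed_ordered_ted,
}


def pairwise_matrix(trees: dict[str, Tree], s: CostScheme,
                    mode: str = "unordered",
                    timeout: Optional[float] = None) -> pd.DataFrame:
    """Symmetric all-pairs edit-distance matrix with a zero diagonal.

    Pairs whose solve times out are recorded as NaN and logged rather than
    aborting the sweep.
    """
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    try:
        compute = _MODES[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}") from None
    ids = list(trees)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            res = compute(trees[a], trees[b], s, timeout=timeout)
            if res.timed_out:
                log.warning("pair (%s, %s) timed out; distance missing", a, b)
                val = np.nan
            else:
                val = res.distance
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat


@dataclass(frozen=True)
class PairSample:
    """One unordered pair of items with its search statistic and truth label."""

    id1: str
    id2: str
    statistic: float
    same_class: bool

    def __post_init__(self):
        if self.id1 == self.id2:
            raise ValueError("a pair must join two distinct items")


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (false positive rate, true positive rate)
    auc: float


def roc_from_pairs(samples: Sequence[PairSample],
                   polarity: str = "distance") -> RocCurve:
    """Threshold-sweep ROC over pair samples.

    ``polarity="distance"`` calls a pair positive when its statistic falls
    below the threshold; ``"score"`` when it rises above. All pairs tied at
    a threshold flip together (one sweep step). The curve runs from (0,0)
    to (1,1) and the AUC is its trapezoidal area.
    """
    if polarity not in ("distance", "score"):
        raise ValueError(f"unknown polarity {polarity!r}")
    y = np.array([p.same_class for p in samples], dtype=bool)
    stat = np.array([p.statistic for p in samples], dtype=float)
    if y.all() or not y.any():
        raise ValueError("need both same-class and different-class pairs")
    score = -stat if polarity == "distance" else stat
    fpr, tpr, _ = _sk_roc_curve(y, score, drop_intermediate=False)
    return RocCurve(list(zip(fpr.tolist(), tpr.tolist())),
                    float(_trapezoid_auc(fpr, tpr)))


def read_class_labels(text: str) -> dict[str, set[str]]:
    """Parse a TSV of (tree-id, class-label) rows; ids may repeat (multi-label)."""
    out: dict[str, set[str]] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ValueError(f"label line needs two columns: {ln!r}")
        out.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return out


def pairs_from_matrix(matrix: pd.DataFrame,
                      classes: dict[str, set[str]]) -> list[PairSample]:
    """Turn a distance matrix plus class annotations into pair samples.

    A pair is same-class when the two items share at least one annotation;
    NaN entries (timed-out solves) are skipped.
    """
    ids = list(matrix.index)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            val = matrix.loc[a, b]
            if np.isnan(val):
                continue
            same = bool(classes.get(a, set()) & classes.get(b, set()))
            out.append(PairSample(a, b, float(val), same))
    return out


def write_roc(curve: RocCurve) -> str:
    """TSV ROC points followed by a single-line AUC summary."""
    lines = ["fpr\ttpr"]
    lines += [f"{x:.6g}\t{y:.6g}" for x, y in curve.points]
    lines.append(f"# AUC\t{curve.auc:.6g}")
    return "\n".join(lines) + "\n"
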