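"""Benchmarking predictions against validation gene sets.

Confusion counts are formed over the *annotated* genes of the search
space (unannotated genes are unpredictable by construction and would
only pad the true-negative cell); the validation set is restricted to
that universe before counting.  From the counts come sensitivity,
specificity and the enrichment ratio — precision divided by validation
prevalence, i.e. the fold improvement over picking genes at random from
the search space.  Leave-one-out cross-validation withholds each seed
in turn and records the rank at which the seeded pipeline recovers it;
ROC points sweep the rank cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "loocv_ranks",
    "roc_points",
    "roc_auc",
    "NOT_PREDICTED",
]

NOT_PREDICTED = "not predicted"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN of a prediction set against a validation set."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    predicted: Iterable[str],
    validation: Iterable[str],
    universe: Iterable[str],
) -> ConfusionCounts:
    """Set arithmetic of predictions vs validation within a universe.

    Both gene sets are intersected with the universe first: validation
    genes outside the (annotated) search space are not scoreable.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    predicted = set(predicted) & universe
    validation = set(validation) & universe
    tp = len(predicted & validation)
    fp = len(predicted - validation)
    fn = len(validation - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity and enrichment ratio.

    enrichment_ratio = precision / prevalence
                     = (tp/(tp+fp)) / ((tp+fn)/universe).
    Components whose denominator is zero are reported as None, not 0.
    """
    n = c.universe_size
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    er: float | None = None
    if (c.tp + c.fp) and (c.tp + c.fn) and n:
        precision = c.tp / (c.tp + c.fp)
        prevalence = (c.tp + c.fn) / n
        er = precision / prevalence
    return {"sensitivity": sens, "specificity": spec, "enrichment_ratio": er}


def loocv_ranks(
    seeds: Iterable[str],
    predict_fn: Callable[[frozenset[str]], Mapping[str, int]],
    space_genes: Iterable[str],
) -> dict[str, int | str]:
    """Leave-one-out recovery ranks of the seed genes.

    For every seed located in the search space, the seeded pipeline is
    rerun with that gene withheld from the seed list (``predict_fn``
    maps a seed set to a gene→rank table); the withheld gene's rank, or
    ``"not predicted"``, is recorded.  Seeds outside the search space
    can never be recovered and are reported as not predicted.
    """
    seeds = sorted(set(seeds))
    space_genes = set(space_genes)
    out: dict[str, int | str] = {}
    for withheld in seeds:
        if withheld not in space_genes:
            out[withheld] = NOT_PREDICTED
            continue
        remaining = frozenset(s for s in seeds if s != withheld)
        if not remaining:
            out[withheld] = NOT_PREDICTED
            continue
        ranks = predict_fn(remaining)
        out[withheld] = ranks.get(withheld, NOT_PREDICTED)
    return out


def roc_points(
    ranked_predictions: Mapping[str, int],
    validation: Iterable[str],
    universe: Iterable[str],
) -> list[tuple[float, float]]:
    """ROC curve points from a gene→rank table.

    The rank cutoff k sweeps the distinct ranks; at each k the top-k
    predictions form the predicted set.  Points start at (0, 0) and are
    monotone non-decreasing in both coordinates.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    validation = set(validation) & universe
    positives = len(validation)
    negatives = len(universe) - positives
    points = [(0.0, 0.0)]
    ranked = [(r, g) for g, r in ranked_predictions.items() if g in universe]
    if not ranked:
        return points
    ranked.sort()
    tp = fp = 0
    i = 0
    while i < len(ranked):
        k = ranked[i][0]
        while i < len(ranked) and ranked[i][0] == k:
            if ranked[i][1] in validation:
                tp += 1
            else:
                fp += 1
            i += 1
        fpr = fp / negatives if negatives else 0.0
        tpr = tp / positives if positives else 0.0
        points.append((fpr, tpr))
    return points


def roc_auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under ROC points, closed at (1, 1)."""
    pts = list(points)
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, pts[-1][1]))
        pts.append((1.0, 1.0))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))
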