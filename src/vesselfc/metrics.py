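"""Voxelwise segmentation evaluation: accuracy, sensitivity, specificity, Dice."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import GridError
from .io_resample import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


class Scores(NamedTuple):
    """The four ratio scores; a score with zero denominator is None."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    dice: float | None


def confusion(
    pred: BinaryMask, gold: BinaryMask, region: BinaryMask | None = None
) -> ConfusionCounts:
    """Confusion counts of pred vs gold, restricted to ``region`` if given.

    Restricting to the liver mask avoids inflating specificity with trivial
    out-of-liver negatives.
    """
    if pred.shape != gold.shape:
        raise GridError(f"pred shape {pred.shape} != gold shape {gold.shape}")
    p = pred.astype_bool()
    g = gold.astype_bool()
    if region is not None:
        if region.shape != pred.shape:
            raise GridError(f"region shape {region.shape} != pred shape {pred.shape}")
        r = region.astype_bool()
        p, g = p[r], g[r]
    return ConfusionCounts(
        TP=int(np.count_nonzero(p & g)),
        TN=int(np.count_nonzero(~p & ~g)),
        FP=int(np.count_nonzero(p & ~g)),
        FN=int(np.count_nonzero(~p & g)),
    )


def scores(c: ConfusionCounts) -> Scores:
    """Accuracy, sensitivity, specificity, and Dice from confusion counts."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return Scores(
        accuracy=ratio(c.TP + c.TN, c.total),
        sensitivity=ratio(c.TP, c.TP + c.FN),
        specificity=ratio(c.TN, c.TN + c.FP),
        dice=ratio(2 * c.TP, 2 * c.TP + c.FN + c.FP),
    )


def evaluate(
    pred: BinaryMask, gold: BinaryMask, region: BinaryMask | None = None
) -> Scores:
    return scores(confusion(pred, gold, region))
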