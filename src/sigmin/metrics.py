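"""Scalar performance indices for binary endpoint classifiers.

The central index is the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

a correlation in [-1, 1] that stays informative under the class imbalance
typical of clinical endpoints.  Two auxiliary fitting indices are provided:

    index1 = TP*TN / ((TP+FP)(TN+FP))
    index2 = TN/(TN+FP) + TP/(TP+FP)     (= specificity + precision)

and the MCC-robustness weight, the mean cross-validated MCC divided by its
standard deviation across repeats — large when a classifier is both strong
and stable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies of a binary prediction."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSample:
    """Per-repeat values of one metric with their mean and sample SD (n-1)."""

    values: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1))


def confusion(
    truth: Sequence, pred: Sequence, positive=1
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN, treating ``positive`` as the positive class."""
    if len(truth) != len(pred):
        raise ValidationError(
            f"truth length {len(truth)} != prediction length {len(pred)}"
        )
    if len(truth) == 0:
        raise ValidationError("empty label vectors")
    tp = tn = fp = fn = 0
    for t, p in zip(truth, pred):
        t_pos = t == positive
        p_pos = p == positive
        if t_pos and p_pos:
            tp += 1
        elif t_pos:
            fn += 1
        elif p_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if c.total == 0:
        raise ValidationError("empty confusion counts")
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        # Standard convention for a degenerate marginal.
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def index1(c: ConfusionCounts, variant: str = "as-printed") -> float:
    """TP*TN over (TP+FP)(TN+FP); 0 when a denominator factor is empty.

    ``variant="fn"`` swaps the second factor to (TN+FN).
    """
    if variant == "as-printed":
        d = (c.TP + c.FP) * (c.TN + c.FP)
    elif variant == "fn":
        d = (c.TP + c.FP) * (c.TN + c.FN)
    else:
        raise ValueError(f"unknown index1 variant {variant!r}")
    if d == 0:
        warnings.warn("index1 denominator is 0; returning 0", stacklevel=2)
        return 0.0
    return (c.TP * c.TN) / d


def index2(c: ConfusionCounts) -> float:
    """Specificity + precision, each term 0 when its denominator is empty."""
    out = 0.0
    if c.TN + c.FP > 0:
        out += c.TN / (c.TN + c.FP)
    else:
        warnings.warn("index2: TN+FP is 0; term dropped", stacklevel=2)
    if c.TP + c.FP > 0:
        out += c.TP / (c.TP + c.FP)
    else:
        warnings.warn("index2: TP+FP is 0; term dropped", stacklevel=2)
    return out


def precision(c: ConfusionCounts) -> float:
    if c.TP + c.FP == 0:
        return 0.0
    return c.TP / (c.TP + c.FP)


def accuracy_sensitivity_specificity(
    c: ConfusionCounts,
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); an empty class yields rate 0."""
    if c.total == 0:
        raise ValidationError("empty confusion counts")
    acc = (c.TP + c.TN) / c.total
    if c.TP + c.FN > 0:
        sen = c.TP / (c.TP + c.FN)
    else:
        warnings.warn("no positive samples; sensitivity set to 0", stacklevel=2)
        sen = 0.0
    if c.TN + c.FP > 0:
        spe = c.TN / (c.TN + c.FP)
    else:
        warnings.warn("no negative samples; specificity set to 0", stacklevel=2)
        spe = 0.0
    return acc, sen, spe


def mcc_robustness(sample: MetricSample) -> float:
    """Mean MCC divided by its SD across CV repeats.

    Returns ``inf`` when the SD is exactly 0 (a perfectly stable classifier);
    callers comparing a batch of models resolve that sentinel with
    :func:`resolve_robustness_weights`.
    """
    if len(sample.values) < 2:
        raise ValidationError("MCC-robustness needs at least 2 repeat values")
    sd = sample.sd
    if sd == 0.0:
        return float("inf")
    return sample.mean / sd


def resolve_robustness_weights(
    raw: Sequence[float], zero_sd_policy: str = "smallest", cap: float = 1e6
) -> list[float]:
    """Turn raw MCC-robustness values into usable weights for one batch.

    Infinite values (zero SD) are assigned the smallest finite weight in the
    batch (``"smallest"`` policy) or a large finite ``cap`` (``"cap"``).
    """
    if zero_sd_policy not in ("smallest", "cap"):
        raise ValueError(f"unknown zero_sd_policy {zero_sd_policy!r}")
    finite = [w for w in raw if math.isfinite(w)]
    if zero_sd_policy == "smallest":
        fill = min(finite) if finite else 1.0
    else:
        fill = cap
    return [w if math.isfinite(w) else fill for w in raw]
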