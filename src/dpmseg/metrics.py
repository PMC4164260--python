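"""Segmentation accuracy: confusion counts and overlap scores.

With result set R and true set T (binary masks), the pixel counts are
TP = |R ∩ T|, TN = |complement(R ∪ T)|, FP = |R \\ T|, FN = |T \\ R|, and

    DSC   = 2 TP / ((FP + TP) + (TP + FN))
    Jacc  = TP / (FP + TP + FN)
    Sens  = TP / (TP + FN)
    Spec  = TN / (TN + FP)

A zero denominator yields NaN (with a warning) rather than a silent 0.
DSC and Jaccard satisfy DSC = 2 J / (1 + J).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

__all__ = ["MetricsReport", "confusion_counts", "evaluate"]


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus the four derived overlap scores.

    Scores lie in [0, 1]; an undefined score (zero denominator) is NaN.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    dsc: float
    jaccard: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _masks(result, truth, eval_mask):
    r = np.asarray(result, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: result {r.shape} vs truth {t.shape}")
    if eval_mask is None:
        m = np.ones(r.shape, dtype=bool)
    else:
        m = np.asarray(eval_mask, dtype=bool)
        if m.shape != r.shape:
            raise ValueError("eval_mask shape mismatch")
    return r, t, m


def confusion_counts(result, truth, eval_mask=None) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) pixel counts, restricted to ``eval_mask`` if given."""
    r, t, m = _masks(result, truth, eval_mask)
    tp = int(np.count_nonzero(r & t & m))
    tn = int(np.count_nonzero(~r & ~t & m))
    fp = int(np.count_nonzero(r & ~t & m))
    fn = int(np.count_nonzero(~r & t & m))
    return tp, tn, fp, fn


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return math.nan
    return num / den


def evaluate(result, truth, eval_mask=None) -> MetricsReport:
    """Full overlap report of a result mask against ground truth."""
    tp, tn, fp, fn = confusion_counts(result, truth, eval_mask)
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        dsc=_ratio(2.0 * tp, (fp + tp) + (tp + fn), "DSC"),
        jaccard=_ratio(float(tp), fp + tp + fn, "Jaccard"),
        sensitivity=_ratio(float(tp), tp + fn, "sensitivity"),
        specificity=_ratio(float(tn), tn + fp, "specificity"),
    )
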