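"""Threshold calibration on a training set and binary sample calls.

A sample is called positive when its max-VAF score *strictly* exceeds the
VAF threshold (a score exactly at the threshold is negative).  The
threshold is chosen on a training set of disease-free samples as the
smallest candidate whose training specificity reaches a target — keeping
sensitivity as high as the specificity requirement allows.

Thresholds are carried as exact rationals (:class:`fractions.Fraction`) so
that the boundary comparison at, say, 48/2400 vs 2% has no floating-point
ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence, Union

import pandas as pd

from .panel import Panel
from .quantify import MaxVafStat

__all__ = [
    "ThresholdCalibration",
    "SampleCall",
    "CalibrationError",
    "as_fraction",
    "training_specificity",
    "calibrate_threshold",
    "classify",
    "per_gene_calls",
]

ThresholdLike = Union[str, float, int, Fraction]


def as_fraction(threshold: ThresholdLike) -> Fraction:
    """Coerce a threshold to an exact fraction.

    Strings and Fractions are exact; floats go through their shortest
    decimal repr (so ``0.02`` means exactly 2/100, not the nearest double).
    """
    if isinstance(threshold, Fraction):
        return threshold
    if isinstance(threshold, int):
        return Fraction(threshold)
    if isinstance(threshold, float):
        return Fraction(repr(threshold))
    return Fraction(str(threshold))


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    positive: bool
    threshold: Fraction


@dataclass
class ThresholdCalibration:
    candidates: list[Fraction]
    specificities: list[float]  # training specificity per candidate
    selected: Fraction
    target_specificity: float


class CalibrationError(ValueError):
    def __init__(self, message: str, best_threshold: Fraction, best_specificity: float):
        super().__init__(message)
        self.best_threshold = best_threshold
        self.best_specificity = best_specificity


def _is_positive(stat: MaxVafStat, threshold: Fraction) -> bool:
    return stat.exact_vaf > threshold


def training_specificity(
    training: Sequence[MaxVafStat], threshold: ThresholdLike
) -> float:
    """Fraction of (disease-free) training samples called negative."""
    if not training:
        raise ValueError("empty training set")
    t = as_fraction(threshold)
    neg = sum(1 for s in training if not _is_positive(s, t))
    return neg / len(training)


def calibrate_threshold(
    training: Sequence[MaxVafStat],
    candidates: Sequence[ThresholdLike],
    target_specificity: float,
) -> ThresholdCalibration:
    """Pick the smallest candidate threshold meeting the target specificity.

    Raises :class:`CalibrationError` (carrying the best achievable
    candidate) when no candidate reaches the target.
    """
    if not candidates:
        raise ValueError("no candidate thresholds")
    cands = [as_fraction(c) for c in candidates]
    if sorted(cands) != cands:
        raise ValueError("candidate thresholds must be sorted ascending")
    specs = [training_specificity(training, c) for c in cands]
    for c, s in zip(cands, specs):
        if s >= target_specificity:
            return ThresholdCalibration(cands, specs, c, target_specificity)
    i_best = max(range(len(cands)), key=lambda i: (specs[i], -cands[i]))
    raise CalibrationError(
        f"no candidate reaches target specificity {target_specificity:.3f}; "
        f"best is {float(cands[i_best]):.4f} at {specs[i_best]:.3f}",
        best_threshold=cands[i_best],
        best_specificity=specs[i_best],
    )


def classify(stat: MaxVafStat, threshold: ThresholdLike) -> SampleCall:
    """Positive iff max_vaf strictly exceeds the threshold."""
    t = as_fraction(threshold)
    return SampleCall(stat.sample_id, _is_positive(stat, t), t)


def per_gene_calls(
    table: pd.DataFrame, panel: Panel, threshold: ThresholdLike
) -> dict[str, bool]:
    """Per-gene positive flags for one sample, plus an "Any" OR flag.

    A gene is positive when any of its non-excluded hotspots exceeds the
    threshold; "Any" equals the sample-level max-VAF call by construction
    (same sites, same strict inequality).
    """
    t = as_fraction(threshold)
    flags: dict[str, bool] = {g: False for g in panel.genes}
    active = {h.key: h for h in panel.active_hotspots()}
    for r in table.itertuples():
        key = (str(r.chrom), int(r.pos), str(r.alt))
        h = active.get(key)
        if h is None:
            continue
        d, a = int(r.depth), int(r.alt_count)
        if d > 0 and Fraction(a, d) > t:
            flags[h.gene] = True
    flags["Any"] = any(flags[g] for g in panel.genes)
    return flags
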