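"""Residue-level and interval-level evaluation.

Two complementary views of prediction quality:

* residue-level confusion counts against reference structured intervals,
  summarized as sensitivity, specificity, accuracy, balanced accuracy and
  precision (percentages, reported to two decimals with half-up rounding);
* interval-level benchmarking, where each reference construct is matched
  to its best-overlapping predicted unit by reciprocal overlap and counted
  as recovered when that overlap strictly exceeds a threshold
  (conventionally 70%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Interval, StructuredUnit, interval_overlap, reciprocal_overlap


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero (so 0.005 -> 0.01), unlike banker's
    rounding; applied only at the reporting layer."""
    factor = 10**decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Percentages, two decimals; precision is None when nothing was
    predicted positive."""

    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    precision: float | None


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Standard confusion-matrix metrics as percentages (2 decimals)."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("need at least one positive and one negative residue")
    sens = 100.0 * counts.tp / (counts.tp + counts.fn)
    spec = 100.0 * counts.tn / (counts.tn + counts.fp)
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    bal = (sens + spec) / 2
    prec = (
        100.0 * counts.tp / (counts.tp + counts.fp)
        if counts.tp + counts.fp > 0
        else None
    )
    return MetricsReport(
        sensitivity=round_half_up(sens),
        specificity=round_half_up(spec),
        accuracy=round_half_up(acc),
        balanced_accuracy=round_half_up(bal),
        precision=None if prec is None else round_half_up(prec),
    )


def proportion(successes: int, total: int) -> float:
    """Percentage successes/total to two decimals (half-up)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    return round_half_up(100.0 * successes / total)


def confusion_from_intervals(
    predicted: list[StructuredUnit] | list[Interval],
    reference: list[Interval],
    protein_length: int,
    mask: np.ndarray | None = None,
) -> ConfusionCounts:
    """Residue-level confusion counts for one protein.

    Masked residues (e.g. annotated domain regions excluded from scoring)
    are left out of all four cells.
    """

    def to_bool(intervals) -> np.ndarray:
        vec = np.zeros(protein_length, dtype=bool)
        for item in intervals:
            iv = item.interval if isinstance(item, StructuredUnit) else item
            if iv.end > protein_length:
                raise ValueError(
                    f"interval [{iv.start},{iv.end}] exceeds protein length"
                )
            vec[iv.start - 1 : iv.end] = True
        return vec

    pred = to_bool(predicted)
    ref = to_bool(reference)
    keep = (
        ~np.asarray(mask, dtype=bool)
        if mask is not None
        else np.ones(protein_length, dtype=bool)
    )
    return ConfusionCounts(
        tp=int((pred & ref & keep).sum()),
        fp=int((pred & ~ref & keep).sum()),
        fn=int((~pred & ref & keep).sum()),
        tn=int((~pred & ~ref & keep).sum()),
    )


@dataclass(frozen=True)
class OverlapBenchmark:
    best_overlaps: tuple  # per reference construct, in input order
    count_above: int
    mean: float
    sd: float


def overlap_benchmark(
    predictions: dict[str, list[StructuredUnit]],
    constructs: dict[str, list[Interval]],
    threshold: float = 70.0,
) -> OverlapBenchmark:
    """Best reciprocal overlap per reference construct.

    Each construct scores the best reciprocal overlap against any predicted
    unit of its protein (0 when the protein has no predictions).  Counting
    against the threshold is strict (> threshold); mean and standard
    deviation (sample, n-1 denominator) are over all constructs.
    """
    best = []
    for pid in constructs:
        preds = predictions.get(pid, [])
        for construct in constructs[pid]:
            overlaps = [
                reciprocal_overlap(construct, u.interval) for u in preds
            ]
            best.append(max(overlaps, default=0.0))
    arr = np.asarray(best)
    if arr.size == 0:
        raise ValueError("no reference constructs supplied")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return OverlapBenchmark(
        best_overlaps=tuple(best),
        count_above=int((arr > threshold).sum()),
        mean=float(arr.mean()),
        sd=sd,
    )
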