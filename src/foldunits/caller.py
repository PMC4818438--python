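"""Target scoring and density-grid unit calling.

The per-residue target score is a weighted combination of the five feature
tracks,

    score_i = (w_ord*order_i + w_ss*ss_i + w_cons*cons_i
               + w_ant*ant_i + w_hyd*hyd_i) / (w_ord + w_ss + w_cons + w_ant + w_hyd)

with the published default weights (0.8, 1.0, 0.6, 0.1, 0.1).  Dividing by
the weight sum keeps the score on [0, 1], where the default calling cutoff
0.52 is discriminative; set ``normalize=False`` for the raw weighted sum.
Residues inside annotated domains, trans-membrane segments or signal
peptides are masked and score exactly 0.

Putative structural units are then called by a 1-D density-grid clustering:
the protein is partitioned into consecutive grids of 5 residues (the last
grid may be shorter), the highest-mean grid above the cutoff seeds a
candidate, and the candidate grows one grid at a time — preferring the side
that keeps its mean higher — as long as the added grid's mean score exceeds
the cutoff and the growth stays clear of masked or previously claimed
residues.  Candidates longer than 40 residues are reported; either way
their residues are claimed and seeding repeats until no eligible grid
remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import consensus_domains
from .core import (
    DomainAnnotation,
    Interval,
    ProteinRecord,
    RegionMask,
    StructuredUnit,
    UnitKind,
)
from .features import FEATURE_NAMES, FeatureTrack


@dataclass(frozen=True)
class WeightVector:
    """Non-negative feature weights; order matches FEATURE_NAMES."""

    w_order: float = 0.8
    w_ss: float = 1.0
    w_cons: float = 0.6
    w_ant: float = 0.1
    w_hyd: float = 0.1

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise ValueError("weights must be non-negative")
        if sum(vals) <= 0:
            raise ValueError("at least one weight must be positive")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.w_order, self.w_ss, self.w_cons, self.w_ant, self.w_hyd)

    @property
    def total(self) -> float:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class CallerConfig:
    """Unit-calling parameters: grid width, score cutoff and the minimum
    acceptable unit length (41 residues, i.e. strictly more than 40)."""

    grid_size: int = 5
    score_cutoff: float = 0.52
    min_length: int = 41

    def __post_init__(self) -> None:
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        if not 0.0 <= self.score_cutoff <= 1.0:
            raise ValueError("score_cutoff must lie in [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class TargetScoreProfile:
    """Per-residue combined score plus the domain/TM/signal mask."""

    scores: np.ndarray
    masked: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        masked = np.asarray(self.masked, dtype=bool)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "masked", masked)
        if scores.shape != masked.shape or scores.ndim != 1:
            raise ValueError("scores and mask must be 1-D vectors of equal length")
        if np.any(scores[masked] != 0.0):
            raise ValueError("masked positions must score exactly 0")

    def __len__(self) -> int:
        return self.scores.size


def mask_vector(length: int, masks: list[RegionMask]) -> np.ndarray:
    """Boolean per-residue mask from region-mask interval lists."""
    vec = np.zeros(length, dtype=bool)
    for mask in masks:
        for iv in mask.intervals:
            if iv.end > length:
                raise ValueError(
                    f"mask interval [{iv.start},{iv.end}] exceeds length {length}"
                )
            vec[iv.start - 1 : iv.end] = True
    return vec


def target_score(
    tracks: dict[str, FeatureTrack],
    weights: WeightVector = WeightVector(),
    masks: list[RegionMask] | None = None,
    normalize: bool = True,
) -> TargetScoreProfile:
    """Combine the five feature tracks into the per-residue target score.

    ``tracks`` maps every feature name to its track; all tracks must share
    one length.  Masked residues are forced to exactly 0.
    """
    missing = set(FEATURE_NAMES) - set(tracks)
    if missing:
        raise ValueError(f"missing feature tracks: {sorted(missing)}")
    lengths = {len(tracks[name]) for name in FEATURE_NAMES}
    if len(lengths) != 1:
        raise ValueError(f"track length mismatch: {sorted(lengths)}")
    (n,) = lengths

    matrix = np.stack([tracks[name].values for name in FEATURE_NAMES])
    w = np.asarray(weights.as_tuple())
    scores = w @ matrix
    if normalize:
        scores = scores / weights.total
    masked = mask_vector(n, masks or [])
    scores[masked] = 0.0
    return TargetScoreProfile(scores, masked)


def grid_averages(
    profile: TargetScoreProfile, grid_size: int = 5
) -> list[tuple[Interval, float]]:
    """Partition the protein into consecutive grids and average the score
    in each (masked zeros included); the final grid may be shorter."""
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    n = len(profile)
    out = []
    for start in range(0, n, grid_size):
        end = min(start + grid_size, n)
        iv = Interval(start + 1, end)
        out.append((iv, float(profile.scores[start:end].mean())))
    return out


def call_units(
    profile: TargetScoreProfile, config: CallerConfig = CallerConfig()
) -> list[StructuredUnit]:
    """Call putative structural units from a score profile by iterative
    seed-and-grow over the score grids (see module docstring)."""
    n = len(profile)
    grids = grid_averages(profile, config.grid_size)
    blocked = profile.masked.copy()  # masked now, claimed as we go

    def grid_free(gi: int) -> bool:
        iv = grids[gi][0]
        return not blocked[iv.start - 1 : iv.end].any()

    units: list[StructuredUnit] = []
    while True:
        candidates = [
            gi
            for gi, (_, mean) in enumerate(grids)
            if mean > config.score_cutoff and grid_free(gi)
        ]
        if not candidates:
            break
        seed = max(candidates, key=lambda gi: (grids[gi][1], -gi))
        lo_grid = hi_grid = seed
        start, end = grids[seed][0].start, grids[seed][0].end

        def segment_sum(a: int, b: int) -> float:
            return float(profile.scores[a - 1 : b].sum())

        while True:
            options = []  # (resulting mean, side order: left first on ties)
            if lo_grid > 0 and grid_free(lo_grid - 1) and grids[lo_grid - 1][1] > config.score_cutoff:
                iv = grids[lo_grid - 1][0]
                new_mean = segment_sum(iv.start, end) / (end - iv.start + 1)
                if new_mean > config.score_cutoff:
                    options.append((new_mean, 0, "left"))
            if (
                hi_grid + 1 < len(grids)
                and grid_free(hi_grid + 1)
                and grids[hi_grid + 1][1] > config.score_cutoff
            ):
                iv = grids[hi_grid + 1][0]
                new_mean = segment_sum(start, iv.end) / (iv.end - start + 1)
                if new_mean > config.score_cutoff:
                    options.append((new_mean, 1, "right"))
            if not options:
                break
            _, _, side = max(options, key=lambda o: (o[0], -o[1]))
            if side == "left":
                lo_grid -= 1
                start = grids[lo_grid][0].start
            else:
                hi_grid += 1
                end = grids[hi_grid][0].end

        length = end - start + 1
        if length >= config.min_length:
            mean = segment_sum(start, end) / length
            units.append(
                StructuredUnit(
                    Interval(start, end),
                    UnitKind.PUTATIVE_UNIT,
                    mean_score=mean,
                    provenance="density_grid",
                )
            )
        # claim residues regardless so the region cannot re-seed
        blocked[start - 1 : end] = True

    units.sort(key=lambda u: u.interval)
    return units


def predict(
    protein: ProteinRecord,
    annotations: list[DomainAnnotation],
    tracks: dict[str, FeatureTrack],
    masks: list[RegionMask] | None = None,
    config: CallerConfig = CallerConfig(),
    weights: WeightVector = WeightVector(),
    normalize: bool = True,
) -> tuple[list[StructuredUnit], TargetScoreProfile]:
    """Full per-protein prediction: consensus domains plus putative units.

    Consensus-domain intervals join the mask before scoring, so putative
    units never overlap annotated domains.  Returns the combined sorted
    unit list and the score profile it was called from.
    """
    from .core import MaskKind

    domains = consensus_domains(protein, annotations)
    all_masks = list(masks or [])
    if domains:
        all_masks.append(
            RegionMask(
                MaskKind.CONSENSUS_DOMAIN,
                tuple(d.interval for d in domains),
            )
        )
    profile = target_score(tracks, weights, all_masks, normalize=normalize)
    units = [
        StructuredUnit(
            d.interval,
            UnitKind.CONSENSUS_DOMAIN,
            mean_score=0.0,
            provenance=d.rule_applied.value,
        )
        for d in domains
    ]
    units.extend(call_units(profile, config))
    units.sort(key=lambda u: u.interval)
    return units, profile
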