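"""Synthetic fixture generation.

Generates proteins with planted structured regions so every pipeline stage
is testable without external databases or predictors.  The generator
emulates the statistical structure the target score assumes: planted
regions carry high order, secondary-structure, conservation (and, by
default, antigenicity and hydrophobicity) signal, the rest of the chain
low signal, with truncated-Gaussian noise around those means.  Residue
composition is also skewed — order-promoting, hydrophobic letters inside
planted regions, disorder-promoting letters outside — so the built-in
sequence-only providers separate the classes too, not just imported
tracks.

Each protein draws from its own pseudo-random stream keyed by
``(seed, protein index)``, so adding or removing proteins never perturbs
the others' data.

Five named annotation scenarios with analytically known consensus outputs
(good_overlap, fragmented_structure, fragmented_sequence, sequence_only,
none) provide ground truth for the consensus-domain rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusDomain, ConsensusRule
from .core import (
    DomainAnnotation,
    Interval,
    ProteinRecord,
    SourceClass,
    union_span,
)
from .features import FEATURE_NAMES, FeatureTrack

#: Letters over-represented inside planted structured regions (ordered,
#: hydrophobic) and outside them (disorder promoting).
ORDERED_LETTERS = "ILVFWYMAC"
DISORDERED_LETTERS = "PESQKGRDNT"

SCENARIOS = (
    "good_overlap",
    "fragmented_structure",
    "fragmented_sequence",
    "sequence_only",
    "none",
)

#: Fixed annotation geometries per scenario (absolute coordinates; proteins
#: carrying a scenario must be at least 160 residues long).
_SCENARIO_ANNOTATIONS: dict[str, list[tuple[str, int, int]]] = {
    "good_overlap": [("sequence_based", 10, 100), ("structure_based", 50, 150)],
    "fragmented_structure": [
        ("sequence_based", 10, 150),
        ("structure_based", 20, 60),
        ("structure_based", 90, 140),
    ],
    "fragmented_sequence": [
        ("structure_based", 10, 150),
        ("sequence_based", 20, 60),
        ("sequence_based", 90, 140),
    ],
    "sequence_only": [("sequence_based", 30, 120)],
    "none": [],
}

SCENARIO_REGION_END = 160  # annotations never extend past this coordinate


def scenario_annotations(scenario: str) -> list[DomainAnnotation]:
    """The planted annotation set realizing one named scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    return [
        DomainAnnotation(
            Interval(start, end),
            SourceClass(cls),
            source_db="synthetic",
            accession=f"SYN_{scenario.upper()}_{k}",
        )
        for k, (cls, start, end) in enumerate(_SCENARIO_ANNOTATIONS[scenario])
    ]


def expected_consensus(scenario: str) -> list[ConsensusDomain]:
    """Analytically known consensus domains for a scenario's annotations."""
    anns = scenario_annotations(scenario)
    if scenario == "none":
        return []
    if scenario == "good_overlap":
        return [
            ConsensusDomain(
                union_span([a.interval for a in anns]),
                ConsensusRule.GOOD_OVERLAP,
                tuple(anns),
            )
        ]
    if scenario == "fragmented_structure":
        structs = [a for a in anns if a.source_class is SourceClass.STRUCTURE_BASED]
        return [
            ConsensusDomain(s.interval, ConsensusRule.FRAGMENTED_STRUCTURE, tuple(anns))
            for s in structs
        ]
    if scenario == "fragmented_sequence":
        struct = next(
            a for a in anns if a.source_class is SourceClass.STRUCTURE_BASED
        )
        return [
            ConsensusDomain(
                struct.interval, ConsensusRule.FRAGMENTED_SEQUENCE, tuple(anns)
            )
        ]
    # sequence_only
    return [
        ConsensusDomain(anns[0].interval, ConsensusRule.SEQUENCE_ONLY, tuple(anns))
    ]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 50
    length_range: tuple[int, int] = (220, 400)
    units_per_protein: tuple[int, int] = (1, 2)
    unit_length_range: tuple[int, int] = (50, 120)
    inside_mean: float = 0.9
    outside_mean: float = 0.1
    noise_sd: float = 0.05
    scenarios: tuple[str, ...] = ("none",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        if not 0 <= self.outside_mean <= 1 or not 0 <= self.inside_mean <= 1:
            raise ValueError("feature means must lie in [0, 1]")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        if self.unit_length_range[1] > self.length_range[0]:
            raise ValueError(
                "infeasible geometry: planted units may exceed protein length"
            )
        if set(self.scenarios) != {"none"} and self.length_range[0] < SCENARIO_REGION_END + 60:
            raise ValueError(
                "annotation scenarios need proteins of at least "
                f"{SCENARIO_REGION_END + 60} residues"
            )


@dataclass
class FixtureDataset:
    spec: FixtureSpec
    proteins: list[ProteinRecord]
    scenarios: dict[str, str]
    annotations: dict[str, list[DomainAnnotation]]
    tracks: dict[str, dict[str, FeatureTrack]]
    labels: dict[str, list[Interval]]  # planted structured units


def _place_units(
    rng: np.random.Generator,
    length: int,
    region_start: int,
    n_units: int,
    len_range: tuple[int, int],
    min_gap: int = 25,
    margin: int = 10,
) -> list[Interval]:
    """Place non-overlapping planted units in [region_start, length] with
    randomized gaps; drops units that no longer fit."""
    placed: list[Interval] = []
    while n_units > 0:
        lengths = rng.integers(len_range[0], len_range[1] + 1, size=n_units)
        needed = int(lengths.sum()) + (n_units - 1) * min_gap + 2 * margin
        available = length - region_start + 1
        if needed <= available:
            slack = available - needed
            extras = rng.multinomial(slack, np.full(n_units + 1, 1.0 / (n_units + 1)))
            cursor = region_start + margin - 1
            for k, ul in enumerate(lengths):
                cursor += int(extras[k])
                placed.append(Interval(cursor + 1, cursor + int(ul)))
                cursor += int(ul) + min_gap
            return placed
        n_units -= 1
    return placed


def generate(spec: FixtureSpec) -> FixtureDataset:
    """Generate a reproducible dataset of proteins, annotations, tracks
    and planted-unit labels under the given study conditions."""
    proteins: list[ProteinRecord] = []
    scenarios: dict[str, str] = {}
    annotations: dict[str, list[DomainAnnotation]] = {}
    tracks: dict[str, dict[str, FeatureTrack]] = {}
    labels: dict[str, list[Interval]] = {}

    for idx in range(spec.n_proteins):
        rng = np.random.default_rng([spec.seed, idx])
        pid = f"SYNP{idx:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        scenario = spec.scenarios[idx % len(spec.scenarios)]
        anns = scenario_annotations(scenario)

        # planted putative units live to the right of any scenario
        # annotations so domain masking never eats into them
        region_start = SCENARIO_REGION_END + 11 if anns else 1
        n_units = int(
            rng.integers(spec.units_per_protein[0], spec.units_per_protein[1] + 1)
        )
        units = _place_units(
            rng, length, region_start, n_units, spec.unit_length_range
        )

        structured = np.zeros(length, dtype=bool)
        for iv in units:
            structured[iv.start - 1 : iv.end] = True
        for ann in anns:
            structured[ann.interval.start - 1 : ann.interval.end] = True

        seq = np.where(
            structured,
            rng.choice(list(ORDERED_LETTERS), size=length),
            rng.choice(list(DISORDERED_LETTERS), size=length),
        )
        proteins.append(ProteinRecord(pid, "".join(seq)))
        scenarios[pid] = scenario
        annotations[pid] = anns
        labels[pid] = units

        means = np.where(structured, spec.inside_mean, spec.outside_mean)
        prot_tracks = {}
        for name in FEATURE_NAMES:
            values = np.clip(
                rng.normal(means, spec.noise_sd), 0.0, 1.0
            )
            prot_tracks[name] = FeatureTrack(name, values)
        tracks[pid] = prot_tracks

    return FixtureDataset(
        spec=spec,
        proteins=proteins,
        scenarios=scenarios,
        annotations=annotations,
        tracks=tracks,
        labels=labels,
    )
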