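"""Core domain types and interval algebra.

Coordinates follow the protein residue-numbering convention throughout:
1-based indices, inclusive at both ends, so an interval ``[start, end]``
has length ``end - start + 1``.  Every file format and report produced by
this package uses the same convention; nothing half-open ever leaks out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

logger = logging.getLogger("foldunits")

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Non-standard letters folded into X (selenocysteine, pyrrolysine,
#: ambiguity codes).  X receives scale value 0 in built-in feature providers.
NONSTANDARD_AA = {"B", "Z", "U", "O", "J"}


def sanitize_sequence(sequence: str) -> str:
    """Upper-case a sequence and map non-standard letters to ``X``.

    Letters outside the 20 standard codes (B, Z, U, O, J and anything else
    unrecognised) become ``X`` with a logged warning.
    """
    seq = sequence.upper()
    out = []
    replaced = set()
    for ch in seq:
        if ch in STANDARD_AA or ch == "X":
            out.append(ch)
        else:
            replaced.add(ch)
            out.append("X")
    if replaced:
        logger.warning(
            "non-standard residue letters mapped to X: %s",
            ",".join(sorted(replaced)),
        )
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier — the coordinate frame for
    every annotation, track and unit attached to it."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """A closed residue interval ``[start, end]``, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}]: need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class SourceClass(str, Enum):
    """Provenance class of a domain annotation: profile/motif databases
    (Pfam, SMART, PROSITE style) versus structure-derived ones (Gene3D
    style)."""

    SEQUENCE_BASED = "sequence_based"
    STRUCTURE_BASED = "structure_based"


@dataclass(frozen=True)
class DomainAnnotation:
    """One database domain hit on a protein."""

    interval: Interval
    source_class: SourceClass
    source_db: str = ""
    accession: str = ""


class UnitKind(str, Enum):
    CONSENSUS_DOMAIN = "consensus_domain"
    PUTATIVE_UNIT = "putative_unit"


@dataclass(frozen=True)
class StructuredUnit:
    """A called structured region: either a consensus domain (mean_score 0)
    or a putative structural unit with its mean target score."""

    interval: Interval
    kind: UnitKind
    mean_score: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_score <= 1.0:
            raise ValueError(f"mean_score {self.mean_score} outside [0, 1]")


class MaskKind(str, Enum):
    CONSENSUS_DOMAIN = "consensus_domain"
    TRANSMEMBRANE = "transmembrane"
    SIGNAL_PEPTIDE = "signal_peptide"


@dataclass(frozen=True)
class RegionMask:
    """Residue regions excluded from target scoring (annotated domains,
    trans-membrane segments, signal peptides)."""

    mask_kind: MaskKind
    intervals: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def interval_overlap(a: Interval, b: Interval) -> int:
    """Number of residues shared by two intervals (0 if disjoint)."""
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """Reciprocal overlap of two intervals as a percentage in [0, 100].

    The shared residue count is measured against the length of *each*
    interval and the smaller fraction is kept — a conservative score that
    reaches 100 only when the intervals coincide exactly.  Used at a 70%
    threshold to declare a predicted unit a recovery of a reference
    construct.
    """
    ov = interval_overlap(a, b)
    return 100.0 * min(ov / a.length, ov / b.length)


def union_span(intervals) -> Interval:
    """Smallest single interval covering every input interval."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("union_span of empty interval list")
    return Interval(min(i.start for i in intervals), max(i.end for i in intervals))


def merge_intervals(intervals) -> list[Interval]:
    """Merge overlapping (not merely adjacent) intervals into disjoint spans."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            merged[-1] = Interval(merged[-1].start, max(merged[-1].end, iv.end))
        else:
            merged.append(iv)
    return merged
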