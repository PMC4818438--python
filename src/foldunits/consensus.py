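"""Consensus-domain construction.

Sequence-based domain hits (Pfam/SMART/PROSITE style) and structure-based
hits (Gene3D style) on one protein are reconciled into consensus domains
by a three-case rule set:

* **good overlap** — one sequence-based and one structure-based hit where
  the sequence-based hit covers more than 50% of the structure-based hit:
  the consensus is the span covering both.
* **fragmented** — several hits of one class overlap a single hit of the
  other class: the structure-based hit(s) win and each becomes its own
  consensus domain.
* **single class** — an isolated hit becomes a consensus domain as-is.

A 1:1 pair that fails the 50% test also falls back to keeping the
structure-based hit, consistent with the fragmented cases' preference for
structural evidence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .core import (
    DomainAnnotation,
    Interval,
    ProteinRecord,
    SourceClass,
    interval_overlap,
    union_span,
)

logger = logging.getLogger("foldunits")


class ConsensusRule(str, Enum):
    GOOD_OVERLAP = "good_overlap"
    FRAGMENTED_STRUCTURE = "fragmented_structure"
    FRAGMENTED_SEQUENCE = "fragmented_sequence"
    SEQUENCE_ONLY = "sequence_only"
    STRUCTURE_ONLY = "structure_only"


#: Precedence used when merged consensus domains carry different rules.
_RULE_PRIORITY = {
    ConsensusRule.GOOD_OVERLAP: 0,
    ConsensusRule.FRAGMENTED_STRUCTURE: 1,
    ConsensusRule.FRAGMENTED_SEQUENCE: 2,
    ConsensusRule.STRUCTURE_ONLY: 3,
    ConsensusRule.SEQUENCE_ONLY: 4,
}


@dataclass(frozen=True)
class ConsensusDomain:
    interval: Interval
    rule_applied: ConsensusRule
    members: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError("consensus domain must have contributing members")


def build_components(
    annotations: list[DomainAnnotation],
) -> list[list[DomainAnnotation]]:
    """Group annotations into connected components of the cross-class
    overlap graph.

    An edge joins a sequence-based and a structure-based annotation that
    share at least one residue; annotations of the same class end up in one
    component only through a shared cross-class partner.  Output components
    are ordered by their leftmost member; members keep input order.
    """
    n = len(annotations)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = annotations[i], annotations[j]
            if a.source_class == b.source_class:
                continue
            if interval_overlap(a.interval, b.interval) >= 1:
                union(i, j)

    groups: dict[int, list[DomainAnnotation]] = {}
    for i, ann in enumerate(annotations):
        groups.setdefault(find(i), []).append(ann)
    return sorted(
        groups.values(), key=lambda g: min(a.interval.start for a in g)
    )


def resolve_component(group: list[DomainAnnotation]) -> list[ConsensusDomain]:
    """Apply the consensus rules to one overlap component."""
    seq = [a for a in group if a.source_class is SourceClass.SEQUENCE_BASED]
    struct = [a for a in group if a.source_class is SourceClass.STRUCTURE_BASED]

    if not struct:
        # isolated sequence-based hit(s); components without a cross-class
        # partner are always singletons
        return [
            ConsensusDomain(a.interval, ConsensusRule.SEQUENCE_ONLY, (a,))
            for a in seq
        ]
    if not seq:
        return [
            ConsensusDomain(a.interval, ConsensusRule.STRUCTURE_ONLY, (a,))
            for a in struct
        ]

    if len(seq) == 1 and len(struct) == 1:
        s, t = seq[0], struct[0]
        ov = interval_overlap(s.interval, t.interval)
        if ov / t.interval.length > 0.5:
            return [
                ConsensusDomain(
                    union_span([s.interval, t.interval]),
                    ConsensusRule.GOOD_OVERLAP,
                    (s, t),
                )
            ]
        # weak 1:1 overlap: keep the structural evidence
        return [ConsensusDomain(t.interval, ConsensusRule.STRUCTURE_ONLY, (t,))]

    # fragmented: one class has several members against the other; the
    # structure-based member(s) win either way
    rule = (
        ConsensusRule.FRAGMENTED_SEQUENCE
        if len(struct) == 1
        else ConsensusRule.FRAGMENTED_STRUCTURE
    )
    return [
        ConsensusDomain(t.interval, rule, tuple(group))
        for t in sorted(struct, key=lambda a: a.interval)
    ]


def consensus_domains(
    protein: ProteinRecord, annotations: list[DomainAnnotation]
) -> list[ConsensusDomain]:
    """Full consensus pipeline for one protein.

    Annotations extending past the protein are dropped with a warning.
    Consensus outputs from different components that nevertheless overlap
    are merged to their union span, recording the dominant contributing
    rule.
    """
    kept = []
    for ann in annotations:
        if ann.interval.end > len(protein):
            logger.warning(
                "protein %s: annotation %s [%d,%d] exceeds length %d; dropped",
                protein.id,
                ann.accession or ann.source_db,
                ann.interval.start,
                ann.interval.end,
                len(protein),
            )
            continue
        kept.append(ann)

    out: list[ConsensusDomain] = []
    for group in build_components(kept):
        out.extend(resolve_component(group))
    out.sort(key=lambda c: c.interval)

    merged: list[ConsensusDomain] = []
    for cd in out:
        if merged and cd.interval.start <= merged[-1].interval.end:
            prev = merged[-1]
            members = prev.members + cd.members
            rules = Counter(
                [prev.rule_applied] * (len(prev.members) or 1)
                + [cd.rule_applied] * (len(cd.members) or 1)
            )
            best = min(
                rules.items(), key=lambda kv: (-kv[1], _RULE_PRIORITY[kv[0]])
            )[0]
            merged[-1] = ConsensusDomain(
                union_span([prev.interval, cd.interval]), best, members
            )
        else:
            merged.append(cd)
    return merged
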