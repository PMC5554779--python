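"""Peptide -> transcript allocation strategies.

Three ways to resolve peptides that are shared between isoforms, all gated on
the upstream differential-transcript-usage (DTU) calls:

* ``unique_only``   — keep only peptides that map to a single isoform, and
  only when that isoform is a DTU transcript.
* ``major_guided``  — use transcript abundance: per gene, candidate targets
  are the condition majors (one, or two for a switch gene); a peptide is
  allocated to a major it maps to, and for a switch gene only when it maps to
  exactly one of the two majors (a peptide in the region shared by both majors
  is flagged, reported, and excluded from per-isoform fold changes).
* ``expression_agnostic`` — ignore abundance: a peptide is allocated iff
  exactly one of its mapped transcripts is a DTU transcript; peptides touching
  two or more DTU transcripts are ambiguous.

Multi-gene peptides must be removed before any strategy runs.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .peptide_layer import PeptideRecord, Uniqueness
from .transcript_layer import DifferentialCalls, GeneIsoformProfile

logger = logging.getLogger(__name__)


class Strategy(str, enum.Enum):
    UNIQUE_ONLY = "unique_only"
    MAJOR_GUIDED = "major_guided"
    EXPRESSION_AGNOSTIC = "expression_agnostic"


class DiscardReason(str, enum.Enum):
    MULTI_GENE = "multi_gene"
    NOT_UNIQUE = "not_unique"                  # shared peptide under unique_only
    NO_DTU_TARGET = "no_dtu_target"
    NOT_ON_MAJOR = "not_on_major"
    AMBIGUOUS_MULTI_DTU = "ambiguous_multi_dtu"


@dataclass
class AssignmentResult:
    strategy: Strategy
    allocations: dict[str, str] = field(default_factory=dict)
    discarded: dict[str, DiscardReason] = field(default_factory=dict)
    #: switch-gene peptides lying in the region shared by both majors;
    #: reported but excluded from per-isoform fold-change aggregation
    shared_between_majors: dict[str, tuple[str, str]] = field(default_factory=dict)
    unique_peptides_only: bool = False

    def __post_init__(self) -> None:
        overlap = set(self.allocations) & set(self.discarded)
        if overlap:
            raise ValueError(f"peptides both allocated and discarded: {sorted(overlap)[:3]}")

    @property
    def n_allocated(self) -> int:
        return len(self.allocations)

    def transcripts(self) -> set[str]:
        return set(self.allocations.values())

    def peptides_of_transcript(self, transcript_id: str) -> list[str]:
        return sorted(p for p, t in self.allocations.items() if t == transcript_id)


def _check_multi_gene_removed(peptides: Iterable[PeptideRecord]) -> None:
    for p in peptides:
        if p.uniqueness is Uniqueness.MULTI_GENE:
            raise ValueError(f"multi-gene peptide {p.sequence!r} not removed upstream")


def assign_unique_only(
    peptides: Iterable[PeptideRecord], calls: DifferentialCalls
) -> AssignmentResult:
    """Allocate exactly the uniquely mapping peptides whose isoform is DTU."""
    peptides = list(peptides)
    _check_multi_gene_removed(peptides)
    res = AssignmentResult(Strategy.UNIQUE_ONLY, unique_peptides_only=True)
    for p in peptides:
        if p.uniqueness is not Uniqueness.UNIQUE_TRANSCRIPT:
            res.discarded[p.sequence] = DiscardReason.NOT_UNIQUE
            continue
        (target,) = p.mapped_transcripts
        if target in calls.dtu_transcripts:
            res.allocations[p.sequence] = target
        else:
            res.discarded[p.sequence] = DiscardReason.NO_DTU_TARGET
    return res


def assign_major_guided(
    peptides: Iterable[PeptideRecord],
    profiles: Mapping[str, GeneIsoformProfile],
    calls: DifferentialCalls,
    unique_peptides_only: bool = False,
) -> AssignmentResult:
    """Abundance-guided allocation to condition-major transcripts.

    A gene is retained only when at least one of its condition majors is a DTU
    transcript.  With a single major (no switch) a peptide must map to that
    major; additionally mapping to minor isoforms does not disqualify it.
    With two majors (switch) the peptide must lie in the region distinguishing
    them, i.e. map to exactly one of the two.
    """
    peptides = list(peptides)
    _check_multi_gene_removed(peptides)
    res = AssignmentResult(Strategy.MAJOR_GUIDED, unique_peptides_only=unique_peptides_only)
    for p in peptides:
        if unique_peptides_only and p.uniqueness is not Uniqueness.UNIQUE_TRANSCRIPT:
            res.discarded[p.sequence] = DiscardReason.NOT_UNIQUE
            continue
        prof = profiles.get(p.gene_id)
        if prof is None:
            res.discarded[p.sequence] = DiscardReason.NOT_ON_MAJOR
            continue
        majors = sorted({m for m in prof.major_transcript.values() if m is not None})
        if not majors or not any(m in calls.dtu_transcripts for m in majors):
            res.discarded[p.sequence] = DiscardReason.NO_DTU_TARGET
            continue
        on_majors = sorted(p.mapped_transcripts & set(majors))
        if not on_majors:
            res.discarded[p.sequence] = DiscardReason.NOT_ON_MAJOR
        elif len(majors) == 2 and len(on_majors) == 2:
            res.shared_between_majors[p.sequence] = (majors[0], majors[1])
        else:
            res.allocations[p.sequence] = on_majors[0]
    return res


def assign_expression_agnostic(
    peptides: Iterable[PeptideRecord], calls: DifferentialCalls
) -> AssignmentResult:
    """Allocate a peptide iff exactly one of its isoforms is a DTU transcript."""
    peptides = list(peptides)
    _check_multi_gene_removed(peptides)
    res = AssignmentResult(Strategy.EXPRESSION_AGNOSTIC)
    for p in peptides:
        dtu_hits = sorted(p.mapped_transcripts & calls.dtu_transcripts)
        if not dtu_hits:
            res.discarded[p.sequence] = DiscardReason.NO_DTU_TARGET
        elif len(dtu_hits) > 1:
            res.discarded[p.sequence] = DiscardReason.AMBIGUOUS_MULTI_DTU
        else:
            res.allocations[p.sequence] = dtu_hits[0]
    return res


def dtu_major_genes(
    profiles: Mapping[str, GeneIsoformProfile], calls: DifferentialCalls
) -> set[str]:
    """DTU genes with at least one condition major that is itself a DTU
    transcript (the "DTU major transcripts" gene set)."""
    out = set()
    for gene_id in calls.dtu_genes:
        prof = profiles.get(gene_id)
        if prof is None:
            continue
        majors = {m for m in prof.major_transcript.values() if m is not None}
        if majors & calls.dtu_transcripts:
            out.add(gene_id)
    return out
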