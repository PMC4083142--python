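"""Sharing analysis over post-cascade retained variants.

Within a family, a retained variant is "shared" when carried by two or
more affected members (obligate carriers count as affected) and
"individual" when carried by exactly one.  Family-level unique counts are
taken over the union of member sets.  Note the two accountings are not
additive: per-member totals sum carrier-variant pairs, unique subtotals
count distinct variants.

Across families (or probands) the analysis reduces to pairwise
intersection cardinalities of family-level unique sets, and within the
proband cohort to the multiplicity spectrum of each variant over probands.
Candidates are ranked by affected-carrier count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .io_formats import Family, variant_sort_key
from .variant_core import AnnotatedVariant, DomainError, VariantKey

MemberSets = Dict[str, Set[VariantKey]]


def round_half_up(x: float) -> int:
    """Round half away from zero (display convention for integer percents;
    Python's builtin rounds half to even)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _pct(part: int, whole: int) -> int:
    return round_half_up(100.0 * part / whole) if whole else 0


# ---------------------------------------------------------------------------
# Within-family sharing
# ---------------------------------------------------------------------------


@dataclass
class MemberCounts:
    sample_id: str
    total: int
    individual: int
    shared: int


@dataclass
class SharingSummary:
    """Per-family sharing partition in the shape of the per-member /
    subtotal report rows."""

    family_id: str
    member_counts: List[MemberCounts]
    total_unique: int
    individual_unique: int
    shared_unique: int

    @property
    def individual_pct(self) -> int:
        return _pct(self.individual_unique, self.total_unique)

    @property
    def shared_pct(self) -> int:
        return _pct(self.shared_unique, self.total_unique)


def partition_sharing(family: Family, retained: MemberSets) -> SharingSummary:
    """Partition a family's retained variants into individual-specific vs
    shared, counting carriers among affected-or-obligate members only."""
    affected_ids = [m.sample_id for m in family.affected]
    carrier_count: Dict[VariantKey, int] = {}
    for sid in affected_ids:
        for k in retained.get(sid, set()):
            carrier_count[k] = carrier_count.get(k, 0) + 1
    shared_keys = {k for k, n in carrier_count.items() if n >= 2}
    members = []
    for sid in affected_ids:
        keys = retained.get(sid, set())
        n_shared = sum(1 for k in keys if k in shared_keys)
        members.append(
            MemberCounts(
                sample_id=sid,
                total=len(keys),
                individual=len(keys) - n_shared,
                shared=n_shared,
            )
        )
    total_unique = len(carrier_count)
    shared_unique = len(shared_keys)
    return SharingSummary(
        family_id=family.family_id,
        member_counts=members,
        total_unique=total_unique,
        individual_unique=total_unique - shared_unique,
        shared_unique=shared_unique,
    )


@dataclass
class AggregateSummary:
    grand_total: int
    grand_individual: int
    grand_shared: int
    n_families: int

    @property
    def average_per_family(self) -> int:
        return round_half_up(self.grand_total / self.n_families)

    @property
    def individual_pct(self) -> int:
        return _pct(self.grand_individual, self.grand_total)

    @property
    def shared_pct(self) -> int:
        return _pct(self.grand_shared, self.grand_total)


def summarize_counts(
    subtotals: Sequence[Tuple[int, int, int]]
) -> AggregateSummary:
    """Aggregate per-family (total, individual, shared) unique-count
    triples into grand totals, the per-family average (rounded to the
    nearest integer) and aggregate integer percents."""
    for i, (t, ind, sh) in enumerate(subtotals):
        if t != ind + sh:
            raise DomainError(
                f"inconsistent subtotal triple for family #{i + 1}: "
                f"{t} != {ind} + {sh}"
            )
    return AggregateSummary(
        grand_total=sum(t for t, _, _ in subtotals),
        grand_individual=sum(i for _, i, _ in subtotals),
        grand_shared=sum(s for _, _, s in subtotals),
        n_families=len(subtotals),
    )


# ---------------------------------------------------------------------------
# Cross-family / cross-proband overlap
# ---------------------------------------------------------------------------


@dataclass
class CrossFamilyOverlap:
    """Symmetric matrix of pairwise |retained(Fi) ∩ retained(Fj)| over
    family-level unique retained sets; the diagonal holds each family's
    own unique total."""

    family_ids: List[str]
    matrix: np.ndarray

    def pair(self, fam_a: str, fam_b: str) -> int:
        i, j = self.family_ids.index(fam_a), self.family_ids.index(fam_b)
        return int(self.matrix[i, j])


def cross_overlap(
    family_unions: Mapping[str, Set[VariantKey]]
) -> CrossFamilyOverlap:
    if len(family_unions) < 2:
        raise DomainError("cross-family overlap requires at least 2 families")
    ids = list(family_unions)
    n = len(ids)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            m[i, j] = len(family_unions[ids[i]] & family_unions[ids[j]])
    return CrossFamilyOverlap(family_ids=ids, matrix=m)


@dataclass
class ProbandSharing:
    total_unique: int
    specific: int  # carried by exactly one proband
    shared: int    # carried by >= 2 probands

    @property
    def specific_pct(self) -> int:
        return _pct(self.specific, self.total_unique)

    @property
    def shared_pct(self) -> int:
        return _pct(self.shared, self.total_unique)

    @classmethod
    def from_counts(cls, total: int, specific: int, shared: int) -> "ProbandSharing":
        if total != specific + shared:
            raise DomainError(
                f"inconsistent proband counts: {total} != {specific} + {shared}"
            )
        return cls(total_unique=total, specific=specific, shared=shared)


def proband_sharing(proband_sets: Sequence[Set[VariantKey]]) -> ProbandSharing:
    """Classify each unique variant in the proband cohort by how many
    probands carry it: exactly one (proband-specific) vs two or more."""
    if len(proband_sets) < 2:
        raise DomainError("proband sharing requires at least 2 probands")
    multiplicity: Dict[VariantKey, int] = {}
    for s in proband_sets:
        for k in s:
            multiplicity[k] = multiplicity.get(k, 0) + 1
    shared = sum(1 for n in multiplicity.values() if n >= 2)
    return ProbandSharing.from_counts(
        total=len(multiplicity),
        specific=len(multiplicity) - shared,
        shared=shared,
    )


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------


@dataclass
class Candidate:
    variant: AnnotatedVariant
    carrier_count: int
    #: "+"/"-" per affected-or-obligate member, in family member order
    carrier_pattern: str
    carriers: List[str] = field(default_factory=list)


@dataclass
class CandidateRanking:
    family_id: str
    affected_ids: List[str]
    candidates: List[Candidate]


def rank_candidates(
    family: Family,
    retained: MemberSets,
    annotations: Mapping[VariantKey, AnnotatedVariant],
) -> CandidateRanking:
    """Rank retained variants by affected-carrier count, descending; ties
    break by genomic coordinate.  The +/− pattern spans the affected
    (incl. obligate-carrier) members in pedigree order."""
    affected_ids = [m.sample_id for m in family.affected]
    carriers_of: Dict[VariantKey, List[str]] = {}
    for sid in affected_ids:
        for k in retained.get(sid, set()):
            carriers_of.setdefault(k, []).append(sid)
    order = sorted(
        carriers_of,
        key=lambda k: (-len(carriers_of[k]), variant_sort_key(k)),
    )
    candidates = []
    for k in order:
        carrier_set = set(carriers_of[k])
        av = annotations.get(k)
        if av is None:
            raise DomainError(f"retained variant {k} has no annotation")
        candidates.append(
            Candidate(
                variant=av,
                carrier_count=len(carrier_set),
                carrier_pattern="".join(
                    "+" if sid in carrier_set else "-" for sid in affected_ids
                ),
                carriers=sorted(carrier_set),
            )
        )
    return CandidateRanking(
        family_id=family.family_id, affected_ids=affected_ids, candidates=candidates
    )
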