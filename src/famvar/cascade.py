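"""The variant-reduction cascade.

Raw per-member callsets are reduced to family-specific, novel, deleterious
candidates by five fixed stages:

    quality gate  ->  known-variant removal  ->  family-normal removal
                  ->  synonymous removal     ->  benign removal

Proband mode (single affected individuals without sequenced relatives)
skips the family-normal stage: probands are filtered against population
databases and annotation classes only.

Every stage is a pure set subtraction or predicate, so the final retained
set is order-independent; the :class:`FilterTrace` attributes each removal
to the first applicable stage in the fixed order and telescopes exactly:
the output count of stage k is the input count of stage k+1, and no
variant call is double-removed or lost.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple

from .io_formats import Callset, Family, GenotypeCall, PopulationDatabase, Status
from .variant_core import (
    AnnotatedVariant,
    ContractError,
    DomainError,
    DeleteriousnessBin,
    VariantKey,
    is_retained_class,
)

#: per-member variant sets, keyed by sample id
MemberSets = Dict[str, Set[VariantKey]]


class Mode(enum.Enum):
    FAMILY = "family"
    PROBAND = "proband"


class Disposition(str, enum.Enum):
    REMOVED_QUALITY = "removed_quality"
    REMOVED_KNOWN = "removed_known"
    REMOVED_FAMILY_NORMAL = "removed_family_normal"
    REMOVED_SYNONYMOUS = "removed_synonymous"
    REMOVED_BENIGN = "removed_benign"
    RETAINED = "retained"


@dataclass
class CascadeConfig:
    """Quality-gate thresholds and run mode.

    ``min_depth`` defaults to 10 reads, matching the caller-side minimum;
    the base-quality criterion arrives as a per-call boolean flag.
    """

    min_depth: int = 10
    require_qual_pass: bool = True
    mode: Mode = Mode.FAMILY

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise DomainError(f"min_depth must be >= 0, got {self.min_depth}")
        if isinstance(self.mode, str):
            self.mode = Mode(self.mode)


@dataclass
class FilterTrace:
    """Audit ledger: one disposition per (sample, variant) call that
    asserted a variant, plus telescoping per-stage counts.

    hom-ref and missing-genotype calls carry no variant; they are counted
    in ``n_nonvariant_calls`` and excluded from the traced universe.
    """

    unit_id: str
    records: Dict[Tuple[str, VariantKey], str] = field(default_factory=dict)
    stage_counts: List[Tuple[str, int, int, int]] = field(default_factory=list)
    n_nonvariant_calls: int = 0

    def mark(self, sample: str, key: VariantKey, disposition: Disposition) -> None:
        pair = (sample, key)
        if pair in self.records:
            raise ContractError(
                f"duplicate trace entry for {sample} {key}: "
                f"{self.records[pair]} then {disposition.value}"
            )
        self.records[pair] = disposition.value

    def add_stage(self, stage: str, n_in: int, n_removed: int) -> None:
        self.stage_counts.append((stage, n_in, n_removed, n_in - n_removed))

    def check_telescoping(self) -> None:
        """Assert per-stage counts chain and partition the input."""
        for (s0, _, _, out0), (s1, in1, _, _) in zip(
            self.stage_counts, self.stage_counts[1:]
        ):
            if out0 != in1:
                raise ContractError(
                    f"trace does not telescope: {s0} out={out0} != {s1} in={in1}"
                )
        if self.stage_counts:
            n_input = self.stage_counts[0][1]
            if n_input != len(self.records):
                raise ContractError(
                    f"trace covers {len(self.records)} calls but stage input is {n_input}"
                )
            n_removed = sum(c[2] for c in self.stage_counts)
            n_retained = sum(
                1 for d in self.records.values() if d == Disposition.RETAINED.value
            )
            if n_removed + n_retained != n_input:
                raise ContractError("removed + retained != input in trace")

    def retained_sets(self) -> MemberSets:
        out: MemberSets = {}
        for (sample, key), disp in self.records.items():
            if disp == Disposition.RETAINED.value:
                out.setdefault(sample, set()).add(key)
        return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def quality_gate(
    calls: Callset, cfg: CascadeConfig, trace: FilterTrace
) -> MemberSets:
    """Stage 1: drop calls below the depth threshold or failing the
    base-quality criterion.  Only variant-asserting calls (het/hom-alt)
    enter the traced universe; hom-ref and missing calls are tallied as
    non-variant."""
    out: MemberSets = {s: set() for s in calls}
    n_in = 0
    n_removed = 0
    for sample, sample_calls in calls.items():
        for c in sample_calls:
            if not c.carries_variant:
                trace.n_nonvariant_calls += 1
                continue
            n_in += 1
            if c.depth < cfg.min_depth or (cfg.require_qual_pass and not c.qual_pass):
                trace.mark(sample, c.key, Disposition.REMOVED_QUALITY)
                n_removed += 1
            else:
                out[sample].add(c.key)
    trace.add_stage("quality", n_in, n_removed)
    return out


def _subtract(
    sets: MemberSets,
    remove_if,
    disposition: Disposition,
    stage: str,
    trace: FilterTrace,
) -> MemberSets:
    out: MemberSets = {}
    n_in = sum(len(s) for s in sets.values())
    n_removed = 0
    for sample, keys in sets.items():
        kept = set()
        for k in keys:
            if remove_if(k):
                trace.mark(sample, k, disposition)
                n_removed += 1
            else:
                kept.add(k)
        out[sample] = kept
    trace.add_stage(stage, n_in, n_removed)
    return out


def filter_known(
    sets: MemberSets, db: PopulationDatabase, trace: FilterTrace
) -> MemberSets:
    """Stage 2: remove variants present in the population databases
    (membership-based, frequency-blind)."""
    return _subtract(sets, lambda k: k in db, Disposition.REMOVED_KNOWN, "known", trace)


def filter_family_normal(
    family: Family,
    sets: MemberSets,
    trace: FilterTrace,
    *,
    mode: Mode = Mode.FAMILY,
) -> MemberSets:
    """Stage 3: remove, family-wide, every variant carried by at least one
    unaffected member — such variants are family-specific normal
    polymorphisms, not candidates.  Obligate carriers count as affected:
    their variants are never subtracted.

    Raises
    ------
    ContractError
        If invoked in proband mode; the stage must be skipped upstream,
        never silently no-op'd.
    """
    if mode == Mode.PROBAND:
        raise ContractError("family-normal filtering has no meaning in proband mode")
    normal: Set[VariantKey] = set()
    for member in family.members:
        if member.status == Status.UNAFFECTED:
            normal |= sets.get(member.sample_id, set())
    return _subtract(
        sets, lambda k: k in normal, Disposition.REMOVED_FAMILY_NORMAL,
        "family_normal", trace,
    )


def filter_functional(
    sets: MemberSets,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    trace: FilterTrace,
) -> MemberSets:
    """Stage 4: remove synonymous (and unclassifiable) variants.  Every
    surviving key must be annotated — missing annotations are an error,
    not a silent drop."""
    missing = sorted(
        {k for s in sets.values() for k in s if k not in annotations},
        key=lambda k: (k.chrom, k.pos),
    )
    if missing:
        raise DomainError(
            "unannotated variants reached the functional filter: "
            + ", ".join(str(k) for k in missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    return _subtract(
        sets,
        lambda k: not is_retained_class(annotations[k].functional_class),
        Disposition.REMOVED_SYNONYMOUS,
        "functional",
        trace,
    )


def filter_benign(
    sets: MemberSets,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    trace: FilterTrace,
) -> MemberSets:
    """Stage 5: remove variants binned benign.  Probably/possibly damaging
    and unscored (splicing, stop gain/loss) variants are retained."""
    return _subtract(
        sets,
        lambda k: annotations[k].bin == DeleteriousnessBin.BENIGN,
        Disposition.REMOVED_BENIGN,
        "benign",
        trace,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_cascade(
    calls: Callset,
    family: Family,
    db: PopulationDatabase,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    cfg: CascadeConfig | None = None,
) -> Tuple[MemberSets, FilterTrace]:
    """Run the full cascade for one family (or one proband).

    Stage order is fixed: quality → known → family-normal (family mode
    only) → functional → benign.  Returns the per-member retained sets and
    the complete, telescoping :class:`FilterTrace`.
    """
    cfg = cfg or CascadeConfig()
    if cfg.mode == Mode.PROBAND and len(family.members) > 1:
        raise ContractError(
            f"proband mode requires a single-member family, "
            f"got {len(family.members)} members in {family.family_id}"
        )
    trace = FilterTrace(unit_id=family.family_id)
    sets = quality_gate(calls, cfg, trace)
    sets = filter_known(sets, db, trace)
    if cfg.mode == Mode.FAMILY:
        sets = filter_family_normal(family, sets, trace)
    sets = filter_functional(sets, annotations, trace)
    sets = filter_benign(sets, annotations, trace)
    for sample, keys in sets.items():
        for k in keys:
            trace.mark(sample, k, Disposition.RETAINED)
    trace.check_telescoping()
    return sets, trace
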