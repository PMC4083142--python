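"""Core domain types for single-nucleotide germline variants.

Variant identity, functional classification and deleteriousness binning are
the vocabulary every downstream stage (filtering, sharing analysis,
reporting) speaks.  The scope is deliberately SNV-only: indels are rejected
at parse time rather than silently dropped, so that audit traces account for
every input record.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

_BASES = frozenset("ACGT")

#: Deleteriousness-score bin boundaries (PolyPhen-2 HumVar convention):
#: benign 0–0.446, possibly damaging 0.447–0.908, probably damaging 0.909–1.
#: Scores are compared at 3-decimal precision so the printed inclusive
#: ranges are exhaustive.
BENIGN_MAX = 0.446
POSSIBLY_MAX = 0.908


class FamvarError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(FamvarError, ValueError):
    """A value violates a domain precondition (range, allele syntax...)."""


class FormatError(FamvarError, ValueError):
    """An input file violates its accepted dialect."""


class ContractError(FamvarError, RuntimeError):
    """An operation was invoked outside its contract (caller bug)."""


class FunctionalClass(enum.Enum):
    """Functional consequence of a coding SNV.

    Only nonsynonymous, splicing and stop gain/loss variants are candidate
    material; synonymous changes and anything else are removed by the
    cascade's functional filter.
    """

    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    SYNONYMOUS_SNV = "synonymous_snv"
    SPLICING = "splicing"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    OTHER = "other"


#: Classes retained by the functional filter.
RETAINED_CLASSES = frozenset(
    {
        FunctionalClass.NONSYNONYMOUS_SNV,
        FunctionalClass.SPLICING,
        FunctionalClass.STOPGAIN,
        FunctionalClass.STOPLOSS,
    }
)


class DeleteriousnessBin(enum.Enum):
    """Missense deleteriousness bin; NOT_APPLICABLE for unscored variants
    (splicing, stop gain/loss have no missense score)."""

    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    NOT_APPLICABLE = "not_applicable"

    @property
    def letter(self) -> str:
        """One-letter display code (D/P/B/NA) used in candidate tables."""
        return {
            DeleteriousnessBin.PROBABLY_DAMAGING: "D",
            DeleteriousnessBin.POSSIBLY_DAMAGING: "P",
            DeleteriousnessBin.BENIGN: "B",
            DeleteriousnessBin.NOT_APPLICABLE: "NA",
        }[self]


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of an SNV: (chrom, 1-based pos, ref, alt).

    Equality over the four fields is the identity used by every set
    operation in the pipeline.  Chromosome names are normalized to the
    leading-"chr" dialect by :func:`parse_variant_key`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # "chr1:20972051 A>G"
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"


def parse_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build a canonical :class:`VariantKey`, normalizing the chromosome
    dialect and enforcing the SNV-only scope.

    Raises
    ------
    DomainError
        For non-positive positions, non-ACGT alleles, multi-base alleles
        (indels are out of scope and must not be silently dropped), or
        ref == alt.
    """
    chrom = str(chrom).strip()
    if not chrom:
        raise DomainError("empty chromosome name")
    if not chrom.lower().startswith("chr"):
        chrom = "chr" + chrom
    else:
        chrom = "chr" + chrom[3:]
    pos = int(pos)
    if pos < 1:
        raise DomainError(f"position must be >= 1, got {pos}")
    ref = str(ref).upper()
    alt = str(alt).upper()
    if len(ref) != 1 or len(alt) != 1:
        raise DomainError(
            f"only single-base SNVs are in scope, got ref={ref!r} alt={alt!r} "
            f"at {chrom}:{pos}"
        )
    if ref not in _BASES or alt not in _BASES:
        raise DomainError(f"alleles must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise DomainError(f"ref == alt ({ref}) at {chrom}:{pos} is not a variant")
    return VariantKey(chrom, pos, ref, alt)


def classify_deleteriousness(score: Optional[float]) -> DeleteriousnessBin:
    """Bin a deleteriousness score on [0, 1] into benign / possibly /
    probably damaging; a missing score maps to NOT_APPLICABLE.

    The printed bin ranges (0–0.446, 0.447–0.908, 0.909–1) are inclusive
    decimal intervals, so scores are rounded to 3 decimals before
    comparison: 0.4464 → benign, 0.4465 → possibly damaging.
    """
    if score is None:
        return DeleteriousnessBin.NOT_APPLICABLE
    score = float(score)
    if not (0.0 <= score <= 1.0):
        raise DomainError(f"deleteriousness score must lie in [0, 1], got {score}")
    r = round(score, 3)
    if r <= BENIGN_MAX:
        return DeleteriousnessBin.BENIGN
    if r <= POSSIBLY_MAX:
        return DeleteriousnessBin.POSSIBLY_DAMAGING
    return DeleteriousnessBin.PROBABLY_DAMAGING


def is_retained_class(fc: FunctionalClass) -> bool:
    """True for the functional classes the cascade keeps (nonsynonymous,
    splicing, stop gain/loss); False for synonymous and other."""
    if not isinstance(fc, FunctionalClass):
        raise DomainError(f"not a FunctionalClass: {fc!r}")
    return fc in RETAINED_CLASSES


@dataclass(frozen=True)
class AnnotatedVariant:
    """A :class:`VariantKey` plus gene-level annotation.

    ``cdna_change`` / ``protein_change`` are carried as opaque HGVS-like
    labels.  The bin is always re-derivable from the score: construction
    enforces consistency.
    """

    key: VariantKey
    gene: str
    functional_class: FunctionalClass
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    score: Optional[float] = None
    bin: DeleteriousnessBin = DeleteriousnessBin.NOT_APPLICABLE

    def __post_init__(self) -> None:
        expected = classify_deleteriousness(self.score)
        if self.bin != expected:
            # normalize rather than error: the score is authoritative
            object.__setattr__(self, "bin", expected)

    @classmethod
    def make(
        cls,
        key: VariantKey,
        gene: str,
        functional_class: FunctionalClass,
        cdna_change: Optional[str] = None,
        protein_change: Optional[str] = None,
        score: Optional[float] = None,
    ) -> "AnnotatedVariant":
        return cls(
            key=key,
            gene=gene,
            functional_class=functional_class,
            cdna_change=cdna_change,
            protein_change=protein_change,
            score=score,
            bin=classify_deleteriousness(score),
        )
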