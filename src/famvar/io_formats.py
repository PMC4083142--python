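"""Readers and writers for every external format the pipeline touches.

VCF goes through pysam; the tabular sidecar files (PED, population-variant
table, annotation table, retained-variant tables) through pandas.  The
filter-trace log is a line-delimited TSV of our own, since no standard
format exists for a per-variant audit ledger.

Conventions: coordinates are 1-based, inclusive, VCF-style everywhere; all
readers are strict on their accepted dialects and fail loudly, with the
single documented exception of missing-genotype calls, which are counted
and logged rather than erroring.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import pandas as pd
import pysam

from .variant_core import (
    AnnotatedVariant,
    DomainError,
    FormatError,
    FunctionalClass,
    VariantKey,
    parse_variant_key,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class Zygosity(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Status(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    OBLIGATE_CARRIER = "obligate_carrier"


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one variant: zygosity, read depth and whether
    the call met the base-quality criterion (sourced from the VCF FILTER
    column; absent annotation defaults to passing)."""

    sample_id: str
    key: VariantKey
    zygosity: Zygosity
    depth: int
    qual_pass: bool = True

    @property
    def carries_variant(self) -> bool:
        return self.zygosity in (Zygosity.HET, Zygosity.HOM_ALT)


@dataclass(frozen=True)
class Individual:
    sample_id: str
    family_id: str
    sex: Sex = Sex.UNKNOWN
    status: Status = Status.UNAFFECTED
    is_proband: bool = False
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    @property
    def counts_as_affected(self) -> bool:
        """Obligate carriers are treated as affected for filtering and
        sharing purposes: their variants are candidate material."""
        return self.status in (Status.AFFECTED, Status.OBLIGATE_CARRIER)


@dataclass
class Family:
    family_id: str
    members: List[Individual]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(
                f"duplicate sample ids in family {self.family_id}: {dupes}"
            )
        if not any(m.counts_as_affected for m in self.members):
            raise FormatError(
                f"family {self.family_id} has no affected or obligate-carrier member"
            )

    @property
    def sample_ids(self) -> List[str]:
        return [m.sample_id for m in self.members]

    @property
    def affected(self) -> List[Individual]:
        """Affected plus obligate-carrier members."""
        return [m for m in self.members if m.counts_as_affected]

    @property
    def unaffected(self) -> List[Individual]:
        return [m for m in self.members if m.status == Status.UNAFFECTED]

    @property
    def is_proband_family(self) -> bool:
        return len(self.members) == 1 and self.members[0].is_proband


@dataclass
class PopulationDatabase:
    """Exact-membership set of known population variants (dbSNP/ESP/1000G
    style).  Allele frequencies, when present, are carried for reporting
    but never thresholded on: removal is membership-based."""

    entries: Dict[VariantKey, Optional[float]] = field(default_factory=dict)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, key: VariantKey, af: Optional[float] = None) -> None:
        if af is not None and not (0.0 <= af <= 1.0):
            raise DomainError(f"allele frequency must lie in [0,1], got {af}")
        self.entries[key] = af


#: Per-sample callsets: sample id -> list of calls.
Callset = Dict[str, List[GenotypeCall]]

# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

_CHROM_RE = re.compile(r"^chr(\d+|[XYM]T?)$", re.IGNORECASE)


def chrom_sort_key(chrom: str):
    """Natural ordering: chr1..chr22, chrX, chrY, chrM, then others."""
    m = _CHROM_RE.match(chrom)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (0, int(tok), "")
        return (1, {"X": 0, "Y": 1, "M": 2, "MT": 2}[tok], "")
    return (2, 0, chrom)


def variant_sort_key(key: VariantKey):
    return (chrom_sort_key(key.chrom), key.pos, key.ref, key.alt)


def _is_snv_allele(a: Optional[str]) -> bool:
    return a is not None and len(a) == 1 and a.upper() in "ACGT"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(
    path: Union[str, Path],
    pedigree: Union[Family, Sequence[Family]],
) -> Callset:
    """Read a multi-sample VCF into per-sample :class:`GenotypeCall` lists.

    Only SNV records are ingested (non-SNV alts are skipped and counted);
    multi-allelic records are decomposed into one key per alternate allele.
    Depth precedence per call: per-sample DP, else record-level INFO/DP,
    else 0.  ``qual_pass`` reflects the record FILTER column (PASS or
    unset → True).

    Raises
    ------
    FormatError
        If a pedigree sample is absent from the VCF header.
    """
    families = [pedigree] if isinstance(pedigree, Family) else list(pedigree)
    wanted = [s for fam in families for s in fam.sample_ids]

    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        missing = sorted(set(wanted) - set(header_samples))
        if missing:
            raise FormatError(
                f"pedigree samples missing from VCF {path}: {', '.join(missing)}"
            )
        calls: Callset = {s: [] for s in wanted}
        n_missing_gt = 0
        n_non_snv = 0
        for rec in vcf:
            alts = rec.alts or ()
            if not _is_snv_allele(rec.ref):
                n_non_snv += len(alts) or 1
                continue
            filters = list(rec.filter.keys())
            qual_pass = (not filters) or filters == ["PASS"]
            rec_dp = rec.info.get("DP") if "DP" in rec.info else None
            for alt_idx, alt in enumerate(alts, start=1):
                if not _is_snv_allele(alt):
                    n_non_snv += 1
                    continue
                key = parse_variant_key(rec.chrom, rec.pos, rec.ref, alt)
                for sample in wanted:
                    sc = rec.samples[sample]
                    gt = sc.get("GT")
                    if gt is None or all(a is None for a in gt):
                        n_missing_gt += 1
                        continue
                    n_alt = sum(1 for a in gt if a == alt_idx)
                    n_called = sum(1 for a in gt if a is not None)
                    if n_alt == 0:
                        zyg = Zygosity.HOM_REF
                    elif n_alt >= n_called:
                        zyg = Zygosity.HOM_ALT
                    else:
                        zyg = Zygosity.HET
                    dp = sc.get("DP")
                    if dp is None:
                        dp = rec_dp
                    depth = int(dp) if dp is not None else 0
                    calls[sample].append(
                        GenotypeCall(sample, key, zyg, depth, qual_pass)
                    )
    if n_missing_gt:
        logger.info("%s: %d missing-GT sample calls skipped", path, n_missing_gt)
    if n_non_snv:
        logger.info("%s: %d non-SNV alleles skipped (SNV-only scope)", path, n_non_snv)
    return calls


def write_vcf(calls: Callset, path: Union[str, Path]) -> None:
    """Write per-sample calls back out as an uncompressed multi-sample VCF.

    Samples without a call at a site are emitted as ``./.``; a record is
    FILTER=PASS iff every contributing call passed the quality criterion,
    else ``q30_fail`` (the criterion is record-level on read, so
    round-trips are exact on generator output).
    """
    samples = list(calls.keys())
    # key -> {sample: call}
    by_key: Dict[VariantKey, Dict[str, GenotypeCall]] = {}
    for sample, sample_calls in calls.items():
        for c in sample_calls:
            by_key.setdefault(c.key, {})[sample] = c
    keys = sorted(by_key, key=variant_sort_key)

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FILTER=<ID=q30_fail,Description="Base quality below 30">')
    contigs = sorted({k.chrom for k in keys}, key=chrom_sort_key)
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    for s in samples:
        header.add_sample(s)

    gt_map = {Zygosity.HOM_REF: (0, 0), Zygosity.HET: (0, 1), Zygosity.HOM_ALT: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in keys:
            per_sample = by_key[key]
            rec = out.new_record(
                contig=key.chrom,
                start=key.pos - 1,
                stop=key.pos,
                alleles=(key.ref, key.alt),
            )
            all_pass = all(c.qual_pass for c in per_sample.values())
            rec.filter.add("PASS" if all_pass else "q30_fail")
            for s in samples:
                c = per_sample.get(s)
                if c is None or c.zygosity == Zygosity.MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = gt_map[c.zygosity]
                    rec.samples[s]["DP"] = c.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}


def read_ped(path: Union[str, Path]) -> List[Family]:
    """Read a 6-column PED (family, individual, father, mother, sex,
    phenotype) with an optional 7th ``carrier`` column (0/1) flagging
    obligate carriers.

    Phenotype codes: 1=unaffected, 2=affected.  Parent ids must name an
    in-family member or be "0" (founder).  A single-member affected family
    is a proband.
    """
    rows: List[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (6, 7):
                raise FormatError(
                    f"{path}:{lineno}: expected 6 or 7 columns, got {len(parts)}"
                )
            rows.append((lineno, parts))

    fam_rows: Dict[str, List[tuple]] = {}
    for lineno, parts in rows:
        fam_rows.setdefault(parts[0], []).append((lineno, parts))

    families: List[Family] = []
    for fam_id, members_rows in fam_rows.items():
        ids = [p[1][1] for p in members_rows]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise FormatError(f"{path}: duplicate individual ids in family {fam_id}: {dupes}")
        id_set = set(ids)
        members: List[Individual] = []
        for lineno, parts in members_rows:
            _, ind_id, father, mother, sex_code, pheno = parts[:6]
            carrier = parts[6] if len(parts) == 7 else "0"
            for parent, role in ((father, "father"), (mother, "mother")):
                if parent != "0" and parent not in id_set:
                    raise FormatError(
                        f"{path}:{lineno}: {role} id {parent!r} of {ind_id} "
                        f"not found in family {fam_id}"
                    )
            if pheno == "2":
                status = Status.AFFECTED
            elif pheno == "1":
                status = (
                    Status.OBLIGATE_CARRIER if carrier == "1" else Status.UNAFFECTED
                )
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown phenotype code {pheno!r} "
                    "(expected 1=unaffected or 2=affected)"
                )
            members.append(
                Individual(
                    sample_id=ind_id,
                    family_id=fam_id,
                    sex=_SEX_CODES.get(sex_code, Sex.UNKNOWN),
                    status=status,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                )
            )
        if len(members) == 1 and members[0].counts_as_affected:
            members = [
                Individual(
                    sample_id=members[0].sample_id,
                    family_id=fam_id,
                    sex=members[0].sex,
                    status=members[0].status,
                    is_proband=True,
                )
            ]
        families.append(Family(family_id=fam_id, members=members))
    return families


def write_ped(families: Iterable[Family], path: Union[str, Path]) -> None:
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for fam in families:
            for m in fam.members:
                pheno = "2" if m.status == Status.AFFECTED else "1"
                carrier = "1" if m.status == Status.OBLIGATE_CARRIER else "0"
                fh.write(
                    "\t".join(
                        [
                            fam.family_id,
                            m.sample_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_out[m.sex],
                            pheno,
                            carrier,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Population-variant table
# ---------------------------------------------------------------------------


def read_population_table(path: Union[str, Path]) -> PopulationDatabase:
    """TSV with columns chrom, pos, ref, alt and optional af; duplicate
    rows collapse to one entry (set semantics)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: population table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    has_af = "af" in df.columns
    db = PopulationDatabase()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            key = parse_variant_key(row.chrom, row.pos, row.ref, row.alt)
        except DomainError as e:
            raise FormatError(f"{path}: row {i}: {e}") from e
        af = None
        if has_af and pd.notna(row.af):
            af = float(row.af)
        db.add(key, af)
    return db


def write_population_table(db: PopulationDatabase, path: Union[str, Path]) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt,
         "af": "" if af is None else af}
        for k, af in sorted(db.entries.items(), key=lambda kv: variant_sort_key(kv[0]))
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

#: ANNOVAR-dialect functional-class strings.
_TYPE_MAP = {
    "nonsynonymous snv": FunctionalClass.NONSYNONYMOUS_SNV,
    "synonymous snv": FunctionalClass.SYNONYMOUS_SNV,
    "splicing": FunctionalClass.SPLICING,
    "stopgain": FunctionalClass.STOPGAIN,
    "stopgain snv": FunctionalClass.STOPGAIN,
    "stoploss": FunctionalClass.STOPLOSS,
    "stoploss snv": FunctionalClass.STOPLOSS,
}

_TYPE_OUT = {
    FunctionalClass.NONSYNONYMOUS_SNV: "nonsynonymous SNV",
    FunctionalClass.SYNONYMOUS_SNV: "synonymous SNV",
    FunctionalClass.SPLICING: "splicing",
    FunctionalClass.STOPGAIN: "stopgain",
    FunctionalClass.STOPLOSS: "stoploss",
    FunctionalClass.OTHER: "other",
}


def read_annotation_table(
    path: Union[str, Path]
) -> Dict[VariantKey, AnnotatedVariant]:
    """TSV with columns chrom, pos, ref, alt, gene, type, cdna, protein,
    score.  Unmappable type strings map to ``other`` with a warning; a
    blank score means unscored.  Identical duplicate rows collapse;
    conflicting annotations for one key are an error."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str, "gene": str,
               "type": str, "cdna": str, "protein": str},
    )
    required = {"chrom", "pos", "ref", "alt", "gene", "type"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: annotation table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    annotations: Dict[VariantKey, AnnotatedVariant] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            key = parse_variant_key(row.chrom, row.pos, row.ref, row.alt)
        except DomainError as e:
            raise FormatError(f"{path}: row {i}: {e}") from e
        type_str = str(row.type).strip()
        fc = _TYPE_MAP.get(type_str.lower())
        if fc is None:
            logger.warning(
                "%s: row %d: unmappable type %r mapped to 'other'", path, i, type_str
            )
            fc = FunctionalClass.OTHER
        cdna = getattr(row, "cdna", None)
        protein = getattr(row, "protein", None)
        score = getattr(row, "score", None)
        av = AnnotatedVariant.make(
            key=key,
            gene=str(row.gene),
            functional_class=fc,
            cdna_change=None if pd.isna(cdna) else str(cdna),
            protein_change=None if pd.isna(protein) else str(protein),
            score=None if score is None or pd.isna(score) else float(score),
        )
        prev = annotations.get(key)
        if prev is not None and prev != av:
            raise FormatError(
                f"{path}: row {i}: conflicting annotations for {key}"
            )
        annotations[key] = av
    return annotations


def write_annotation_table(
    annotations: Mapping[VariantKey, AnnotatedVariant], path: Union[str, Path]
) -> None:
    rows = []
    for key in sorted(annotations, key=variant_sort_key):
        av = annotations[key]
        rows.append(
            {
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "gene": av.gene,
                "type": _TYPE_OUT[av.functional_class],
                "cdna": av.cdna_change or "",
                "protein": av.protein_change or "",
                "score": "" if av.score is None else av.score,
            }
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "type", "cdna", "protein", "score"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filter trace log
# ---------------------------------------------------------------------------

_TRACE_MAGIC = "#famvar-trace\tv1"


def write_trace(trace, path: Union[str, Path]) -> None:
    """Write a :class:`~famvar.cascade.FilterTrace` as a line-delimited TSV:
    a commented header carrying stage counts, then one record per
    sample×variant call with its disposition, sorted by coordinate."""
    with open(path, "w") as fh:
        fh.write(_TRACE_MAGIC + "\n")
        fh.write(f"#unit\t{trace.unit_id}\n")
        fh.write(f"#nonvariant_calls\t{trace.n_nonvariant_calls}\n")
        for stage, n_in, n_removed, n_out in trace.stage_counts:
            fh.write(f"#stage\t{stage}\t{n_in}\t{n_removed}\t{n_out}\n")
        fh.write("chrom\tpos\tref\talt\tsample\tdisposition\n")
        items = sorted(
            trace.records.items(),
            key=lambda kv: (variant_sort_key(kv[0][1]), kv[0][0]),
        )
        for (sample, key), disp in items:
            fh.write(
                f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{sample}\t{disp}\n"
            )


def read_trace(path: Union[str, Path]):
    """Re-read a trace log written by :func:`write_trace`."""
    from .cascade import FilterTrace  # local import avoids a module cycle

    trace = FilterTrace(unit_id="")
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _TRACE_MAGIC:
            raise FormatError(f"{path}: not a famvar trace file")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#unit\t"):
                trace.unit_id = line.split("\t", 1)[1]
            elif line.startswith("#nonvariant_calls\t"):
                trace.n_nonvariant_calls = int(line.split("\t")[1])
            elif line.startswith("#stage\t"):
                _, stage, n_in, n_rm, n_out = line.split("\t")
                trace.stage_counts.append((stage, int(n_in), int(n_rm), int(n_out)))
            elif line.startswith("chrom\t") or not line:
                continue
            else:
                chrom, pos, ref, alt, sample, disp = line.split("\t")
                key = parse_variant_key(chrom, int(pos), ref, alt)
                trace.records[(sample, key)] = disp
    return trace


# ---------------------------------------------------------------------------
# Retained-variant tables
# ---------------------------------------------------------------------------


def write_retained(
    retained: Mapping[str, Set[VariantKey]],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    path: Union[str, Path],
) -> None:
    """Write post-cascade retained variants as a TSV with one row per
    unique variant and its carrier sample list."""
    union: Dict[VariantKey, List[str]] = {}
    for sample, keys in retained.items():
        for k in keys:
            union.setdefault(k, []).append(sample)
    rows = []
    for key in sorted(union, key=variant_sort_key):
        av = annotations.get(key)
        rows.append(
            {
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "gene": av.gene if av else "",
                "class": _TYPE_OUT[av.functional_class] if av else "",
                "score": "" if av is None or av.score is None else av.score,
                "carriers": ",".join(sorted(union[key])),
            }
        )
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "class", "score", "carriers"]
    ).to_csv(path, sep="\t", index=False)


def read_retained(path: Union[str, Path]) -> Dict[str, Set[VariantKey]]:
    """Invert a retained-variant table back into per-sample key sets."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    retained: Dict[str, Set[VariantKey]] = {}
    for row in df.itertuples(index=False):
        key = parse_variant_key(row.chrom, row.pos, row.ref, row.alt)
        if pd.isna(row.carriers):
            continue
        for sample in str(row.carriers).split(","):
            retained.setdefault(sample, set()).add(key)
    return retained
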