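"""Seeded generator of pedigree cohorts and annotated callsets.

The generator emulates the variant-class structure the filtering cascade
assumes, with a ground-truth ledger so every downstream claim is checkable:

* ``common_known`` — population polymorphisms present in the population
  table, genotyped per individual under Hardy-Weinberg at a sampled allele
  frequency (Beta-shaped, skewed toward rare).
* ``family_private_benign`` — novel variants segregating in one family,
  carried by at least one unaffected member AND scored benign, so the
  family-normal and benign filters are each sufficient to remove them
  (a config switch restricts them to affected members to exercise the
  benign filter alone).
* ``planted_predisposition`` — the family's causal variant: heterozygous
  in one founder and transmitted Mendelianly (independent fair coin per
  heterozygous parent), annotated probably-damaging missense or unscored
  splicing.
* ``sporadic_deleterious`` — novel deleterious variants private to single
  affected individuals; these legitimately survive the cascade.
* ``recurrent_deleterious`` — a cohort-level pool shared between probands
  so the proband sharing analysis has nonzero shared counts.
* ``synonymous_novel`` — novel synonymous variants, removed by the
  functional filter.

Affection status is sampled with configurable penetrance (carriers) and
phenocopy rate (non-carriers).  Unaffected carriers that sit on the
transmission path between affected carriers are flagged obligate carriers.
A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import yaml

from .io_formats import (
    Callset,
    Family,
    GenotypeCall,
    Individual,
    PopulationDatabase,
    Sex,
    Status,
    Zygosity,
    write_annotation_table,
    write_ped,
    write_population_table,
    write_vcf,
)
from .variant_core import (
    AnnotatedVariant,
    DomainError,
    FunctionalClass,
    VariantKey,
)

_BASES = "ACGT"

TRUTH_LABELS = (
    "common_known",
    "family_private_benign",
    "planted_predisposition",
    "sporadic_deleterious",
    "recurrent_deleterious",
    "synonymous_novel",
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSpec:
    """Three-generation pedigree: a founder couple, their children, one
    married-in spouse per child, and grandchildren per couple.  The
    default (2 children, 1 grandchild each) gives 8 members."""

    n_children: int = 2
    n_grandchildren_per_child: int = 1

    @property
    def n_members(self) -> int:
        return 2 + self.n_children * (2 + self.n_grandchildren_per_child)


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings.

    Defaults mirror the study design the pipeline targets: 3 multiplex
    families of 8, a 22-proband cohort, a fully penetrant dominant
    predisposition with no phenocopies, 8000 known population variants
    with rare-skewed allele frequencies (≈1.9k known variants carried per
    member), and read depth negative-binomial around a 63x exome mean.
    """

    n_families: int = 3
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)
    n_probands: int = 22
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    n_common: int = 8000
    common_af_shape: Tuple[float, float] = (0.5, 3.0)
    n_family_private_benign: int = 60
    n_planted_predisposition: int = 1
    n_sporadic_deleterious: int = 8     # per affected member (and per proband)
    n_synonymous_novel: int = 30        # per member
    n_proband_recurrent: int = 40
    benign_affected_only: bool = False
    genotyping_error: float = 0.0
    depth_mean: float = 63.0
    depth_dispersion: float = 20.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate", "genotyping_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must lie in [0,1], got {v}")
        for name in (
            "n_families", "n_probands", "n_common", "n_family_private_benign",
            "n_planted_predisposition", "n_sporadic_deleterious",
            "n_synonymous_novel", "n_proband_recurrent",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise DomainError("depth model parameters must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["common_af_shape"] = list(self.common_af_shape)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "pedigree" in d and isinstance(d["pedigree"], Mapping):
            d["pedigree"] = PedigreeSpec(**d["pedigree"])
        if "common_af_shape" in d:
            d["common_af_shape"] = tuple(d["common_af_shape"])
        return cls(**d)

    @property
    def run_id(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return f"{self.seed}-{hashlib.md5(blob).hexdigest()[:8]}"


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Label ledger for a generated cohort; the acceptance oracle for the
    cascade.  ``mechanism`` per individual is "carrier", "phenocopy" or
    "none" (unaffected non-carrier)."""

    run_id: str
    labels: Dict[VariantKey, str] = field(default_factory=dict)
    planted: Dict[str, Set[VariantKey]] = field(default_factory=dict)
    carriers: Dict[Tuple[str, str], bool] = field(default_factory=dict)
    mechanism: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def label_counts(self) -> Dict[str, int]:
        out = {lab: 0 for lab in TRUTH_LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out


@dataclass
class RecoveryReport:
    """Per-family recovery of the planted predisposition.

    ``sensitivity`` is the fraction of planted variants retained anywhere
    in their family; ``false_candidates`` counts retained variants in
    classes the cascade must remove (common/known, family-private benign,
    synonymous) — sporadic and recurrent deleterious variants are
    legitimate survivors, not false calls.
    """

    sensitivity: Dict[str, float]
    false_candidates: Dict[str, int]

    @property
    def overall_sensitivity(self) -> float:
        vals = list(self.sensitivity.values())
        return float(np.mean(vals)) if vals else float("nan")


def recovery_report(
    truth: GroundTruth,
    retained_unions: Mapping[str, Set[VariantKey]],
    run_id: Optional[str] = None,
) -> RecoveryReport:
    if run_id is not None and run_id != truth.run_id:
        raise DomainError(
            f"run id mismatch: retained sets from {run_id!r}, truth from "
            f"{truth.run_id!r}"
        )
    must_remove = {"common_known", "family_private_benign", "synonymous_novel"}
    sensitivity: Dict[str, float] = {}
    false_candidates: Dict[str, int] = {}
    for unit_id, retained in retained_unions.items():
        planted = truth.planted.get(unit_id, set())
        if planted:
            sensitivity[unit_id] = len(planted & retained) / len(planted)
        false_candidates[unit_id] = sum(
            1 for k in retained if truth.labels.get(k) in must_remove
        )
    return RecoveryReport(sensitivity=sensitivity, false_candidates=false_candidates)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def _stream(cfg_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=key))


@dataclass
class PedigreeSim:
    family: Family
    carriers: Set[str]                 # sample ids heterozygous at the planted locus
    mechanism: Dict[str, str]          # sample id -> carrier / phenocopy / none


def simulate_pedigree(cfg: SyntheticConfig, family_index: int) -> PedigreeSim:
    """Simulate one family: Mendelian transmission of a single dominant
    predisposition from a heterozygous founder, then affection status by
    penetrance/phenocopy.  Families with no affected member are resampled
    wholesale (deterministically, by advancing the stream)."""
    fam_id = f"F{family_index + 1}"
    spec = cfg.pedigree
    for attempt in range(10_000):
        rng = _stream(cfg.seed, 1, family_index, attempt)
        sid = lambda i: f"{fam_id}-{i}"
        # layout: 1 founder-carrier (F), 2 founder spouse (M); per child j:
        # child, married-in spouse, grandchildren
        parents: Dict[str, Tuple[Optional[str], Optional[str]]] = {
            sid(1): (None, None), sid(2): (None, None)
        }
        sexes = {sid(1): Sex.FEMALE, sid(2): Sex.MALE}
        carrier = {sid(1): True, sid(2): False}
        order = [sid(1), sid(2)]
        nxt = 3
        for _ in range(spec.n_children):
            child = sid(nxt); nxt += 1
            child_sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
            parents[child] = (sid(2), sid(1))  # (father, mother)
            sexes[child] = child_sex
            carrier[child] = bool(rng.random() < 0.5)  # het parent transmits 1/2
            order.append(child)
            spouse = sid(nxt); nxt += 1
            parents[spouse] = (None, None)
            sexes[spouse] = Sex.MALE if child_sex == Sex.FEMALE else Sex.FEMALE
            carrier[spouse] = False
            order.append(spouse)
            for _ in range(spec.n_grandchildren_per_child):
                gc = sid(nxt); nxt += 1
                father, mother = (
                    (child, spouse) if sexes[child] == Sex.MALE else (spouse, child)
                )
                parents[gc] = (father, mother)
                sexes[gc] = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
                carrier[gc] = bool(carrier[child] and rng.random() < 0.5)
                order.append(gc)

        affected: Dict[str, bool] = {}
        mechanism: Dict[str, str] = {}
        for s in order:
            if carrier[s]:
                affected[s] = bool(rng.random() < cfg.penetrance)
                mechanism[s] = "carrier"
            else:
                affected[s] = bool(rng.random() < cfg.phenocopy_rate)
                mechanism[s] = "phenocopy" if affected[s] else "none"
        if not any(affected.values()):
            continue

        # obligate carriers: unaffected carriers linking affected carriers
        children_of: Dict[str, List[str]] = {s: [] for s in order}
        for s, (fa, mo) in parents.items():
            for p in (fa, mo):
                if p is not None:
                    children_of[p].append(s)

        def has_affected_carrier_descendant(s: str) -> bool:
            stack = list(children_of[s])
            while stack:
                c = stack.pop()
                if carrier[c] and affected[c]:
                    return True
                stack.extend(children_of[c])
            return False

        def has_affected_carrier_ancestor(s: str) -> bool:
            stack = [p for p in parents[s] if p is not None]
            while stack:
                a = stack.pop()
                if carrier[a] and affected[a]:
                    return True
                stack.extend(p for p in parents[a] if p is not None)
            return False

        members = []
        for s in order:
            if affected[s]:
                status = Status.AFFECTED
            elif (
                carrier[s]
                and has_affected_carrier_descendant(s)
                and has_affected_carrier_ancestor(s)
            ):
                status = Status.OBLIGATE_CARRIER
            else:
                status = Status.UNAFFECTED
            fa, mo = parents[s]
            members.append(
                Individual(
                    sample_id=s, family_id=fam_id, sex=sexes[s], status=status,
                    father_id=fa, mother_id=mo,
                )
            )
        family = Family(family_id=fam_id, members=members)
        return PedigreeSim(
            family=family,
            carriers={s for s in order if carrier[s]},
            mechanism=mechanism,
        )
    raise DomainError(
        "could not simulate a family with at least one affected member; "
        "penetrance/phenocopy settings too extreme"
    )


# ---------------------------------------------------------------------------
# Variant universe
# ---------------------------------------------------------------------------


class _KeyFactory:
    """Allocates globally unique SNV keys across chr1..chr22."""

    def __init__(self, rng: np.random.Generator) -> None:
        self._i = 0
        self._rng = rng

    def new(self) -> VariantKey:
        i = self._i
        self._i += 1
        chrom = f"chr{i % 22 + 1}"
        pos = 1_000_000 + i
        ref_i = int(self._rng.integers(4))
        alt_i = (ref_i + 1 + int(self._rng.integers(3))) % 4
        return VariantKey(chrom, pos, _BASES[ref_i], _BASES[alt_i])


@dataclass
class SyntheticCohort:
    """In-memory product of :func:`generate_callsets`."""

    config: SyntheticConfig
    families: List[Family]
    probands: List[Family]
    family_calls: Dict[str, Callset]
    proband_calls: Callset
    population: PopulationDatabase
    annotations: Dict[VariantKey, AnnotatedVariant]
    truth: GroundTruth
    mechanisms: Dict[str, Dict[str, str]] = field(default_factory=dict)

    @property
    def run_id(self) -> str:
        return self.config.run_id


def _hwe_zygosity(rng: np.random.Generator, afs: np.ndarray, n_samples: int) -> np.ndarray:
    """(n_samples, n_variants) int8 matrix of allele counts under HWE."""
    u = rng.random((n_samples, afs.size))
    p_hom = afs**2
    p_het = 2 * afs * (1 - afs)
    g = np.zeros_like(u, dtype=np.int8)
    g[u < p_hom] = 2
    g[(u >= p_hom) & (u < p_hom + p_het)] = 1
    return g


def _apply_error(rng: np.random.Generator, g: np.ndarray, rate: float) -> np.ndarray:
    """Per-call carrier-status flips: carrier -> hom-ref, non-carrier -> het."""
    if rate <= 0.0:
        return g
    flip = rng.random(g.shape) < rate
    out = g.copy()
    out[flip & (g > 0)] = 0
    out[flip & (g == 0)] = 1
    return out


def _depths(rng: np.random.Generator, shape, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=shape)


_ZYG = {0: Zygosity.HOM_REF, 1: Zygosity.HET, 2: Zygosity.HOM_ALT}


def _build_callset(
    sample_ids: Sequence[str],
    keys: Sequence[VariantKey],
    g: np.ndarray,
    depth: np.ndarray,
) -> Callset:
    calls: Callset = {s: [] for s in sample_ids}
    for si, s in enumerate(sample_ids):
        row_g = g[si]
        row_d = depth[si]
        calls[s] = [
            GenotypeCall(s, keys[vi], _ZYG[int(row_g[vi])], int(row_d[vi]), True)
            for vi in range(len(keys))
        ]
    return calls


def generate_callsets(cfg: SyntheticConfig) -> SyntheticCohort:
    """Generate the full cohort: families, probands, population table,
    annotation table and ground-truth ledger.  Deterministic in the seed."""
    truth = GroundTruth(run_id=cfg.run_id)
    annotations: Dict[VariantKey, AnnotatedVariant] = {}
    keyfac = _KeyFactory(_stream(cfg.seed, 0, 0))

    def annotate(
        key: VariantKey, rng: np.random.Generator, fc: FunctionalClass,
        score_range: Optional[Tuple[float, float]],
    ) -> None:
        score = None
        cdna = protein = None
        if score_range is not None:
            lo, hi = score_range
            score = round(float(rng.uniform(lo, hi)), 3)
        gene = f"GENE{int(hashlib.md5(str(key).encode()).hexdigest()[:6], 16) % 5000:04d}"
        if fc in (FunctionalClass.NONSYNONYMOUS_SNV, FunctionalClass.SYNONYMOUS_SNV,
                  FunctionalClass.STOPGAIN, FunctionalClass.STOPLOSS):
            cdna = f"c.{key.pos % 9000 + 1}{key.ref}>{key.alt}"
            protein = f"p.X{key.pos % 999 + 1}Y"
        annotations[key] = AnnotatedVariant.make(
            key=key, gene=gene, functional_class=fc,
            cdna_change=cdna, protein_change=protein, score=score,
        )

    # --- common known variants -------------------------------------------
    rng_common = _stream(cfg.seed, 0, 1)
    a, b = cfg.common_af_shape
    afs = rng_common.beta(a, b, size=cfg.n_common)
    common_keys = [keyfac.new() for _ in range(cfg.n_common)]
    population = PopulationDatabase()
    for k, af in zip(common_keys, afs):
        population.add(k, float(af))
        truth.labels[k] = "common_known"
    # realistic annotation mix for known variants (removed at the known stage)
    fc_draw = rng_common.random(cfg.n_common)
    for k, u in zip(common_keys, fc_draw):
        if u < 0.55:
            annotate(k, rng_common, FunctionalClass.NONSYNONYMOUS_SNV, (0.0, 1.0))
        elif u < 0.85:
            annotate(k, rng_common, FunctionalClass.SYNONYMOUS_SNV, None)
        elif u < 0.95:
            annotate(k, rng_common, FunctionalClass.SPLICING, None)
        else:
            annotate(k, rng_common, FunctionalClass.STOPGAIN, None)

    families: List[Family] = []
    family_calls: Dict[str, Callset] = {}
    mechanisms: Dict[str, Dict[str, str]] = {}

    # --- families ---------------------------------------------------------
    for fi in range(cfg.n_families):
        sim = simulate_pedigree(cfg, fi)
        fam = sim.family
        families.append(fam)
        mechanisms[fam.family_id] = sim.mechanism
        for s in fam.sample_ids:
            truth.carriers[(fam.family_id, s)] = s in sim.carriers
            truth.mechanism[(fam.family_id, s)] = sim.mechanism[s]
        rng_fam = _stream(cfg.seed, 2, fi)
        samples = fam.sample_ids
        s_index = {s: i for i, s in enumerate(samples)}
        affected_ids = [m.sample_id for m in fam.affected]
        unaffected_ids = [
            m.sample_id for m in fam.members if m.status == Status.UNAFFECTED
        ]

        novel_keys: List[VariantKey] = []
        novel_carriers: List[List[str]] = []

        def add_novel(key: VariantKey, carriers: List[str], label: str) -> None:
            novel_keys.append(key)
            novel_carriers.append(carriers)
            truth.labels[key] = label

        # planted predisposition(s): carried by the carrier lineage
        truth.planted[fam.family_id] = set()
        lineage = [s for s in samples if s in sim.carriers]
        for _ in range(cfg.n_planted_predisposition):
            k = keyfac.new()
            if rng_fam.random() < 0.2:
                annotate(k, rng_fam, FunctionalClass.SPLICING, None)
            else:
                annotate(k, rng_fam, FunctionalClass.NONSYNONYMOUS_SNV, (0.909, 1.0))
            add_novel(k, lineage, "planted_predisposition")
            truth.planted[fam.family_id].add(k)

        # family-private benign variants
        for _ in range(cfg.n_family_private_benign):
            k = keyfac.new()
            annotate(k, rng_fam, FunctionalClass.NONSYNONYMOUS_SNV, (0.0, 0.446))
            if cfg.benign_affected_only or not unaffected_ids:
                pool = affected_ids
                base = [pool[int(rng_fam.integers(len(pool)))]]
                extra = [s for s in pool if rng_fam.random() < 0.3 and s not in base]
            else:
                base = [unaffected_ids[int(rng_fam.integers(len(unaffected_ids)))]]
                extra = [s for s in affected_ids if rng_fam.random() < 0.5]
            add_novel(k, sorted(set(base + extra)), "family_private_benign")

        # sporadic deleterious: private to single affected members
        for s in affected_ids:
            for _ in range(cfg.n_sporadic_deleterious):
                k = keyfac.new()
                u = rng_fam.random()
                if u < 0.8:
                    annotate(k, rng_fam, FunctionalClass.NONSYNONYMOUS_SNV, (0.447, 1.0))
                elif u < 0.9:
                    annotate(k, rng_fam, FunctionalClass.STOPGAIN, None)
                else:
                    annotate(k, rng_fam, FunctionalClass.STOPLOSS, None)
                add_novel(k, [s], "sporadic_deleterious")

        # novel synonymous: private per member
        for s in samples:
            for _ in range(cfg.n_synonymous_novel):
                k = keyfac.new()
                annotate(k, rng_fam, FunctionalClass.SYNONYMOUS_SNV, None)
                add_novel(k, [s], "synonymous_novel")

        # genotype matrix: common (HWE) then novel (het in listed carriers)
        rng_geno = _stream(cfg.seed, 3, fi)
        g_common = _hwe_zygosity(rng_geno, afs, len(samples))
        g_novel = np.zeros((len(samples), len(novel_keys)), dtype=np.int8)
        for vi, carriers in enumerate(novel_carriers):
            for s in carriers:
                g_novel[s_index[s], vi] = 1
        g = np.concatenate([g_common, g_novel], axis=1)
        g = _apply_error(rng_geno, g, cfg.genotyping_error)
        depth = _depths(rng_geno, g.shape, cfg.depth_mean, cfg.depth_dispersion)
        keys = common_keys + novel_keys
        family_calls[fam.family_id] = _build_callset(samples, keys, g, depth)

    # --- probands ---------------------------------------------------------
    rng_pro = _stream(cfg.seed, 4, 0)
    proband_ids = [f"P{i + 1}" for i in range(cfg.n_probands)]
    probands = [
        Family(
            family_id=pid,
            members=[
                Individual(
                    sample_id=pid, family_id=pid, sex=Sex.FEMALE,
                    status=Status.AFFECTED, is_proband=True,
                )
            ],
        )
        for pid in proband_ids
    ]
    pro_novel_keys: List[VariantKey] = []
    pro_novel_carriers: List[List[str]] = []

    def add_pro(key: VariantKey, carriers: List[str], label: str) -> None:
        pro_novel_keys.append(key)
        pro_novel_carriers.append(carriers)
        truth.labels[key] = label

    for pid in proband_ids:
        truth.carriers[(pid, pid)] = False
        truth.mechanism[(pid, pid)] = "none"
        for _ in range(cfg.n_sporadic_deleterious):
            k = keyfac.new()
            annotate(k, rng_pro, FunctionalClass.NONSYNONYMOUS_SNV, (0.447, 1.0))
            add_pro(k, [pid], "sporadic_deleterious")
        for _ in range(cfg.n_synonymous_novel):
            k = keyfac.new()
            annotate(k, rng_pro, FunctionalClass.SYNONYMOUS_SNV, None)
            add_pro(k, [pid], "synonymous_novel")
    if cfg.n_probands >= 2:
        for _ in range(cfg.n_proband_recurrent):
            k = keyfac.new()
            annotate(k, rng_pro, FunctionalClass.NONSYNONYMOUS_SNV, (0.447, 1.0))
            n_carry = int(rng_pro.integers(2, max(3, cfg.n_probands // 3 + 1)))
            chosen = sorted(
                rng_pro.choice(cfg.n_probands, size=n_carry, replace=False).tolist()
            )
            add_pro(k, [proband_ids[i] for i in chosen], "recurrent_deleterious")

    proband_calls: Callset = {}
    if cfg.n_probands:
        rng_pg = _stream(cfg.seed, 4, 1)
        g_common = _hwe_zygosity(rng_pg, afs, cfg.n_probands)
        g_novel = np.zeros((cfg.n_probands, len(pro_novel_keys)), dtype=np.int8)
        p_index = {pid: i for i, pid in enumerate(proband_ids)}
        for vi, carriers in enumerate(pro_novel_carriers):
            for pid in carriers:
                g_novel[p_index[pid], vi] = 1
        g = np.concatenate([g_common, g_novel], axis=1)
        g = _apply_error(rng_pg, g, cfg.genotyping_error)
        depth = _depths(rng_pg, g.shape, cfg.depth_mean, cfg.depth_dispersion)
        keys = common_keys + pro_novel_keys
        proband_calls = _build_callset(proband_ids, keys, g, depth)

    return SyntheticCohort(
        config=cfg,
        families=families,
        probands=probands,
        family_calls=family_calls,
        proband_calls=proband_calls,
        population=population,
        annotations=annotations,
        truth=truth,
        mechanisms=mechanisms,
    )


# ---------------------------------------------------------------------------
# Run-directory serialization
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    """Ground-truth ledger: variant labels, planted assignments and
    per-individual carrier status, as sectioned TSV."""
    with open(path, "w") as fh:
        fh.write(f"#famvar-truth\tv1\trun_id={truth.run_id}\n")
        fh.write("#section\tvariants\n")
        fh.write("chrom\tpos\tref\talt\tlabel\tplanted_in\n")
        planted_in = {
            k: fam for fam, keys in truth.planted.items() for k in keys
        }
        for k in sorted(truth.labels, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
            fh.write(
                f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\t{truth.labels[k]}\t"
                f"{planted_in.get(k, '')}\n"
            )
        fh.write("#section\tindividuals\n")
        fh.write("family_id\tsample_id\tcarrier\tmechanism\n")
        for (fam, s) in sorted(truth.carriers):
            fh.write(
                f"{fam}\t{s}\t{int(truth.carriers[(fam, s)])}\t"
                f"{truth.mechanism[(fam, s)]}\n"
            )


def read_truth(path: Union[str, Path]) -> GroundTruth:
    from .variant_core import parse_variant_key

    truth = GroundTruth(run_id="")
    section = None
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#famvar-truth"):
            raise DomainError(f"{path}: not a famvar truth ledger")
        truth.run_id = header.split("run_id=")[1]
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#section"):
                section = line.split("\t")[1]
            elif not line or "\t" not in line:
                continue
            elif section == "variants":
                if line.startswith("chrom\t"):
                    continue
                chrom, pos, ref, alt, label, planted_in = line.split("\t")
                k = parse_variant_key(chrom, int(pos), ref, alt)
                truth.labels[k] = label
                if planted_in:
                    truth.planted.setdefault(planted_in, set()).add(k)
            elif section == "individuals":
                if line.startswith("family_id\t"):
                    continue
                fam, s, carrier, mech = line.split("\t")
                truth.carriers[(fam, s)] = bool(int(carrier))
                truth.mechanism[(fam, s)] = mech
    return truth


def write_run(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> Path:
    """Serialize a cohort into a run directory: one VCF per family, one
    multi-sample VCF for the proband cohort, a combined PED, the
    population and annotation tables, the truth ledger and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for fam in cohort.families:
        p = out / f"family_{fam.family_id}.vcf"
        write_vcf(cohort.family_calls[fam.family_id], p)
        files[f"vcf_{fam.family_id}"] = p.name
    if cohort.probands:
        p = out / "probands.vcf"
        write_vcf(cohort.proband_calls, p)
        files["vcf_probands"] = p.name
    write_ped(cohort.families + cohort.probands, out / "cohort.ped")
    write_population_table(cohort.population, out / "population.tsv")
    write_annotation_table(cohort.annotations, out / "annotations.tsv")
    write_truth(cohort.truth, out / "truth.tsv")
    files.update(
        ped="cohort.ped", population="population.tsv",
        annotations="annotations.tsv", truth="truth.tsv",
    )
    manifest = {
        "run_id": cohort.run_id,
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "files": files,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
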