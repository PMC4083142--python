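# Methods

## Problem and model

`famvar` implements a family-focused strategy for finding candidate
germline predispositions in multiplex disease families (the motivating
setting is BRCA1/BRCA2-negative familial breast cancer, an autosomal
dominant disease). The working assumption is that each disease-prone
family transmits its own predisposing variant across generations, so the
causal variant should be (i) absent from population variant databases,
(ii) absent from unaffected relatives, (iii) protein-altering, and
(iv) predicted deleterious. The pipeline encodes those four expectations
as a fixed filtering cascade over single-nucleotide variants:

1. **Quality gate** — a variant-asserting call (het or hom-alt) survives
   only with read depth ≥ `min_depth` (default 10) and a passing
   base-quality flag. hom-ref and missing-genotype calls carry no variant;
   they are counted separately and never enter the cascade.
2. **Known-variant removal** — exact-membership lookup against a
   population table (dbSNP/ESP/1000G-style). Removal is deliberately
   frequency-blind: any database match removes the variant, with no minor
   allele frequency threshold. This trades sensitivity for specificity of
   the "novel" label.
3. **Family-normal removal** — any variant carried by at least one
   *unaffected* family member is removed from every member's set
   (family-wide). Obligate carriers — unaffected individuals who must
   carry the predisposition by pedigree logic — count as affected here:
   their variants are never subtracted. Probands (single affected
   individuals without sequenced relatives) skip this stage entirely.
4. **Synonymous removal** — only nonsynonymous, splice-site and stop
   gain/loss variants remain candidate material.
5. **Benign removal** — variants with a missense deleteriousness score
   binned *benign* are removed; *possibly damaging*, *probably damaging*
   and unscored variants (splicing, stop gain/loss, which missense
   predictors do not score) are retained.

All five stages are pure predicates or set subtractions, so the final
retained set is order-independent; the per-variant audit trace attributes
each removal to the first applicable stage in the fixed order and its
per-stage counts telescope exactly (output of stage k = input of
stage k+1).

### Score binning

PolyPhen-2 HumVar-convention bins: benign 0–0.446, possibly damaging
0.447–0.908, probably damaging 0.909–1. Published scores carry 2–3
decimals, so scores are rounded to 3 decimals before comparison; this
makes the printed inclusive decimal ranges an exhaustive partition of
[0, 1] (effective boundaries 0.4465 and 0.9085).

### Sharing analysis and ranking

Within a family, a retained variant is *shared* when ≥ 2
affected-or-obligate members carry it and *individual* when exactly one
does. Family-level unique counts are taken over the union of member
sets; per-member counts are carried-variant counts. The two accountings
are intentionally not additive (a shared variant appears in several
members' counts but once in the unique subtotal). Integer percents use
round-half-away-from-zero. Cross-family comparison is the pairwise
intersection cardinality of family-level unique sets; proband sharing
classifies each unique variant by the number of probands carrying it
(1 vs ≥ 2). Candidates are ranked by affected-carrier count, ties broken
by genomic coordinate, and displayed with a +/− carrier pattern across
the affected members.

## Power calculation

The paired t-test power module computes, for n pairs and standardized
effect size d, power from the noncentral t distribution with df = n − 1
and noncentrality λ = d·√n: with t* the (1 − α/2) central-t quantile,
power = P(T′ > t*) + P(T′ < −t*). The opposite-tail term is negligible
at moderate d but kept for correctness. The reference design d = 0.67,
n = 20, α = 0.05 gives 0.811 (81%). Genetic design parameters (genetic
relative risk, prevalence, locus frequency, sib recurrence ratio) can be
attached as metadata for reporting but never enter the computation: no
closed-form mapping from them to a standardized effect size is assumed.

Numerical note: scipy's noncentral-t CDF can return NaN at extreme
noncentrality (λ ≳ 11 at df = 1). When that happens the module falls back
to direct quadrature over the chi-square mixing variable,
P(T′ > t) = E_V[Φ(λ − t·√(V/df))], V ~ χ²(df). Sample-size solving uses a
doubling bracket plus bisection, valid because power is strictly
increasing in n; the search floor is n = 2, though at n = 2 (df = 1) the
heavy t tails cap achievable power — e.g. d = 5 yields only 0.42 power,
so the minimal n there is 3, not 2.

## Synthetic cohort generator

The generator produces pedigrees, multi-sample VCFs, a population table,
an annotation table and a ground-truth ledger with the statistical
structure the cascade assumes. Defaults are the study conditions the
pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_families` | 3 | multiplex families |
| `pedigree` | 2 children, 1 grandchild each | 8-member, 3-generation family |
| `n_probands` | 22 | single-member affected families |
| `penetrance` | 1.0 | P(affected \| carrier) |
| `phenocopy_rate` | 0.0 | P(affected \| non-carrier) |
| `n_common` | 8000 | known population variants, AF ~ Beta(0.5, 3) |
| `n_family_private_benign` | 60 / family | ≥1 unaffected carrier, score U[0, 0.446] |
| `n_planted_predisposition` | 1 / family | score U[0.909, 1] missense, or unscored splicing (p = 0.2) |
| `n_sporadic_deleterious` | 8 / affected member | private, score U[0.447, 1] or unscored stop gain/loss |
| `n_synonymous_novel` | 30 / member | private synonymous variants |
| `n_proband_recurrent` | 40 | deleterious pool shared by 2+ probands |
| `depth_mean`, `depth_dispersion` | 63, 20 | negative-binomial read depth (63x exome mean) |
| `genotyping_error` | 0.0 | per-call carrier-status flip probability |

The Beta(0.5, 3) allele-frequency shape gives a mean carrier probability
of ≈ 0.24 under Hardy-Weinberg, so each member carries ≈ 1.9k known
variants — about 2,000 variants per member including the novel classes, a
deliberately desk-scale stand-in for the ~140k raw calls of a real exome.
Frequencies only matter for realism: the known-variant filter is
membership-based.

One founder per family is heterozygous for the planted predisposition;
transmission to each offspring is an independent fair coin per
heterozygous parent. Families with no affected member are resampled
wholesale by advancing the seeded stream. Unaffected carriers with both
an affected-carrier ancestor and an affected-carrier descendant are
flagged obligate carriers. Family-private benign variants are forced to
include at least one unaffected carrier *and* a benign score, so the
family-normal and benign filters are each independently exercised; the
`benign_affected_only` switch generates affected-only benign variants to
verify the benign filter removes them alone.

Determinism: every random stream is spawned from the config seed with a
fixed spawn key, and all writers emit coordinate-sorted records, so a
fixed seed yields byte-identical output files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and recombination,
indels and multi-nucleotide variants, sequencing-level artifacts beyond a
symmetric per-call miscall, population stratification of allele
frequencies, within-family sharing of non-causal deleterious variants
(real relatives share many rare variants by descent, so real shared
fractions are far higher than the generator's), and incomplete database
coverage of truly common variants. The generator validates the
*logic* of the cascade against a known ground truth, not its
*yield* on real exomes.

## File formats and conventions

VCF 4.x read/write goes through pysam (GT required; per-sample DP
preferred, record-level DP as fallback, else 0; multi-allelic records are
decomposed per alternate allele; non-SNV alleles are skipped and
counted). The base-quality criterion has no standard per-sample VCF
encoding, so `qual_pass` is sourced from the record FILTER column
(PASS/unset → pass); files without quality annotation therefore default
to passing. PED is the 6-column dialect plus an optional 7th
`carrier` column (0/1) marking obligate carriers, which standard PED
cannot express. Coordinates are 1-based, inclusive, VCF-style
everywhere. Chromosome names are normalized to the leading-`chr`
dialect at parse time. Indels are rejected at parse time rather than
silently dropped so the audit trace accounts for every record.

## Degenerate inputs and tie-breaks

* A family with no unaffected members makes the family-normal stage an
  identity (empty subtrahend); invoking it in proband mode is a contract
  error, not a silent no-op.
* Scores exactly at bin boundaries are resolved by the 3-decimal
  rounding rule above.
* Ranking ties at equal carrier count are broken by (chromosome,
  position) in natural chromosome order.
* An unannotated variant reaching the functional filter is an error that
  names the offending keys; annotation completeness is a precondition.

## Problem sizes

The test suite exercises the full default cohort (3 × 8-member families,
22 probands, ≈ 8,400 variants per family) once, end to end; randomized
cascade-vs-oracle checks use 40-to-50-variant problems where exhaustive
first-principles re-derivation is easy to read and obviously correct;
Monte-Carlo power checks use 200,000 replicates per grid point. These
sizes make the whole suite run in seconds while keeping every claim
computed, not assumed.

## Known limitations

* SNV-only scope; indels, CNVs and structural variants are out of scope.
* The known-variant filter cannot distinguish a truly novel variant from
  one merely absent from the provided table; specificity is bounded by
  database completeness.
* Candidate ranking implements only the computable part of candidate
  selection (carrier frequency + deleteriousness); gene-function and
  literature evidence are inherently manual and out of scope.
* Autosomal dominant model only; no X-linked or recessive transmission.
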