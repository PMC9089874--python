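# Methods

`famvar` reimplements, as a tested and reusable pipeline, the analysis
design used in family-based exome studies of psychiatric disorders: take a
small cohort of multiplex families (several affected members per family),
sequence affected and — where available — unaffected members, and retain
rare, protein-altering variants whose within-family genotype pattern
matches an inheritance model. Because individual rare variants in a cohort
of this size carry little statistical power, the end point is a gene list
fed into gene-set over-representation analysis.

## Pipeline model

The pipeline consumes an annotated multi-sample VCF (upstream read
alignment, variant calling and functional annotation are out of scope) and
proceeds through five deterministic stages.

**1. Quality control.** Per-call thresholds: read depth DP ≥ 10, genotype
quality GQ ≥ 20, and — for calls asserting an alternate allele — an
alternative allele ratio AAR = AD_alt / (AD_ref + AD_alt) ≥ 0.25. All
boundaries are inclusive; an undefined ratio (missing AD or zero
denominator) fails. Failing calls are demoted to missing rather than
removing the site: this is deliberate, because a low-quality parental call
must be able to veto a de novo call downstream (a missing parent means
"no de novo", never "parent is reference"). Site-level rules: the VQSR
FILTER column must be PASS and the site must not lie in a segmental
duplication. Finally, variants detected in ≥ 20 carriers of a large
in-house exome cohort (consumed as a precomputed detection-count table)
are removed as platform-specific artefacts; a variant absent from the
table counts zero detections. QC rules are applied uniformly to SNVs and
indels. `apply_qc` is idempotent and monotone in every threshold; both
properties are asserted by tests.

**2. Relatedness verification.** Pairwise kinship over QC-passed,
pre-rarity-filter autosomal genotypes (common variants are required for a
stable estimate; X sites are excluded) with the KING-robust estimator:

    phi = (N_het,het − 2·N_AA,aa) / (N_het,i + N_het,j)

over co-called sites, where N_het,het counts double heterozygotes and
N_AA,aa opposite homozygotes. A zero denominator yields an undefined phi,
reported with degree "unrelated" and treated as a mismatch whenever
relatedness was expected. Degrees follow the standard cutpoints
(> 0.354 duplicate/MZ; (0.177, 0.354] first; (0.0884, 0.177] second;
(0.0442, 0.0884] third; else unrelated). Observed degrees are compared
with pedigree-expected ones computed from the recursive kinship
coefficient (founders assumed unrelated and non-inbred); the report is
informational and does not gate the pipeline, since a label swap is
something an analyst must inspect, not something to silently drop.

**3. Rare-variant filters.** Three conjunctive predicates:
(i) protein-altering consequence (missense, nonsense, stop-loss,
frameshift or in-frame indel, canonical splicing), plus synonymous
variants flagged as splice-site; (ii) allele frequency ≤ 1% in each of
five population databases (1000 Genomes, ExAC all and East-Asian, HGVD,
jMorp) — a null entry means "never observed" and passes, matching how
absence is printed as 0 in variant tables; (iii) at least one overlapped
gene with RVIS percentile ≤ 25 and brain normalized expression ≥ 1.
Variants overlapping several genes pass if ANY gene passes and are then
attributed to the passing genes only in gene-level outputs. Conjunction
makes application order irrelevant and thresholds monotone; both are
asserted on randomized fixtures.

**4. Segregation classification.** Genotypes are first recoded
sex-aware: male calls on non-pseudoautosomal X (GRCh37 PARs
X:60001–2,699,520 and X:154,931,044–155,260,560) carrying any alternate
allele become hemizygous-alt, accommodating callers that emit diploid-coded
male X genotypes. Four classes per (variant, family), with fixed
precedence de_novo > hemizygous_x > homozygous_recessive > shared_het so
at most one class is assigned:

- *shared_het*: ≥ 2 affected carriers and (by default) every affected
  member with a usable call carries the allele. The default demands full
  segregation ("shared only among patients"); a minimum-two-carriers
  relaxation is a first-class config switch since small sibships with one
  missing call would otherwise be lost.
- *de_novo*: an affected carrier whose parents are both sequenced,
  unaffected and confidently homozygous-reference. Carriers whose own
  parent is affected are ineligible: transmission from an affected parent
  is indistinguishable from sharing. The rule is evaluated per carrier,
  not per family, so an affected parent elsewhere in an extended pedigree
  does not block a grandparental trio.
- *homozygous_recessive*: ≥ 2 affected members (or all, per sharing mode)
  homozygous-alt, with no sequenced unaffected member homozygous-alt.
  A family's consanguinity flag is recorded but not required.
- *hemizygous_x*: every usable affected male hemizygous (at least one),
  every usable affected female a heterozygous carrier, and no unaffected
  male hemizygous. Unaffected females may carry heterozygously — the
  obligate-carrier-mother constellation.

Two candidate sets are built: the *all* set over every pedigree, and the
*strict* set restricted to pedigrees with sequenced unaffected members,
additionally excluding shared variants carried by any control. The class
predicates for de novo / homozygous / hemizygous candidates already
encode their control constraints, so strictness only tightens the shared
class. Variant counts deduplicate on (chrom, pos, ref, alt) across
families; gene counts are the union of candidates' gene sets.

**5. Enrichment.** Candidate genes are tested for over-representation
against GMT gene sets with the exact one-sided hypergeometric tail
P(X ≥ k) for X ~ Hypergeometric(N, K, n), followed by Benjamini–Hochberg
step-up Q-values; a set is significant when q < α (strict inequality,
default α = 0.05). The universe defaults to the genes bearing both RVIS
and expression annotations — i.e. the space the filters could have chosen
from — and is overridable. The original analysis used a network-based
enrichment engine whose internals and annotation version are not
recoverable, so its printed Q-values are not reproduction targets here;
the published significant-set gene lists ship as a GMT fixture so the
coverage (k/K) bookkeeping is testable.

## Multiallelic and missing-data conventions

Multiallelic sites are split into one record per ALT allele. AD
decomposition keeps the REF depth and the allele's own depth. A genotype
composed of this allele plus a *different* ALT (e.g. 1/2), or of other
ALTs only, is recoded homozygous-reference for the kept record and
flagged: such a call is never counted as a carrier of either allele.
Coordinates are 1-based VCF throughout; null database frequencies mean
"not observed".

## Synthetic cohort generator

The simulator emulates the targeted study design so every stage is
exercisable without access data: 14 families with 39 sequenced members —
30 affected (one of them carrying a non-schizophrenia psychiatric
diagnosis, coded affected) and 9 unaffected — exactly one consanguineous
family, and seven families with sequenced controls. Background sites
(default 20,000, autosomal, MAF uniform on [0.05, 0.5]) get founder
genotypes in Hardy–Weinberg proportions and offspring genotypes by
Mendelian transmission of independent sites. Read depths are a shifted
negative binomial (minimum 10, overdispersed mean 60) with binomial
allele-depth draws, so allele-ratio boundary cases arise naturally at
background heterozygotes; planted sites use confident draws (DP 40–80,
GQ 80–99, het AAR 0.4–0.6) so a planted pattern stands or falls on the
segregation rules, not on sampling accidents.

Planted variants realise each class: 11 shared (one transmitted through a
sequenced carrier control, which the strict set must reject), 3 de novo
(only in families with both parents sequenced and unaffected), 1
homozygous pair in the consanguineous family, 1 X-linked hemizygous pair
of brothers with a heterozygous carrier mother. Eight decoys each violate
exactly one rule (common frequency, non-splice synonymous, tolerant gene,
non-brain gene, segmental duplication, VQSR failure, low depth, in-house
common). A truth table records every planted variant's intended class and
fate, and whether it belongs in the all and strict sets.

What the simulator does **not** model — and hence what passing tests do
not show about real data: linkage disequilibrium and recombination,
population structure and true consanguineous founder relatedness (the
consanguinity flag is metadata only; the consanguineous spouses are
simulated unrelated), mosaicism, indel-alignment ambiguity, batch effects,
and realistic mutation-rate or site-frequency spectra. Database
frequencies of background sites equal their simulated MAF, which makes
the rarity filter's behaviour on them exact rather than noisy.

The optional noise channel perturbs per-call fields (depth collapse,
quality collapse, genotype flips, allele-ratio skew) at a configurable
per-call rate and records every touched call in a ledger; tests assert
that every end-to-end false negative under noise maps to a ledger entry
at that variant's site for a member of the affected family.

## Numerical and design choices

- All thresholds are inclusive at their printed boundaries (DP ≥ 10,
  GQ ≥ 20, AAR ≥ 0.25, AF ≤ 0.01, RVIS ≤ 25, NX ≥ 1, in-house < 20).
- In-house detections are counted as carriers, not alleles.
- Hom-ref calls pass the allele-ratio check vacuously; the ratio is a
  property of calls asserting an alternate allele.
- Unknown affection (PED code 0) is excluded from both the affected and
  control sets.
- Unknown sex on non-PAR X recodes to missing with a warning rather than
  guessing a ploidy.
- The kinship degree for an undefined phi is "unrelated" (vcftools prints
  NaN in the same situation); verification treats it as a mismatch when
  relatedness was expected.
- BH q-values are computed by the step-up definition
  q(i) = min_{j≥i} p(j)·m/j capped at 1, returned in input order; ties and
  permutations are covered by property tests against a quadratic-time
  reference and an independent implementation.
- Reports embed a hash of the analysis parameters (thresholds, modes,
  seed — deliberately not file paths) so stage-wise runs compose to
  byte-identical outputs.

## Problem sizes used in tests and the acceptance script

Unit tests run on a 2,000-site bundle; kinship verification uses 12,000
sites because cross-family phi noise at 2,000 sites approaches the
third-degree cutpoint (0.0442). The acceptance script pools 20 cohorts at
the default 20,000 sites for recovery, 20 replicates of 10,000 sites for
kinship calibration, a full exhaustive hypergeometric sweep for universe
sizes up to 12, 200 randomized vectors for BH, and 1,000 null replicates
(20 sets of 50 genes, queries of 190 from a 2,000-gene universe) for the
type-I calibration. These sizes were chosen as the smallest at which the
estimators are stable.

## Known limitations

- Compound heterozygotes, parametric linkage, phasing and IBD segments
  are out of scope by design.
- The shared-variant rule treats a family with exactly one usable
  affected call as non-segregating (carriers must number ≥ 2), so heavily
  missing families contribute nothing rather than weak candidates.
- Visual review of candidate calls (IGV-style) is replaced by the
  deterministic QC rules; borderline alignment artefacts that a human
  would catch are not modelled.
- The hypergeometric universe is a modelling choice; published
  denominators from network-based engines cannot be reconstructed, so
  cross-study Q-value comparisons are not meaningful.
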