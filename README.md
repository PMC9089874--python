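# famvar

Pedigree-aware rare-variant filtering and segregation analysis for
multiplex-family exome studies.

## The problem

Multiplex families — families with more than one member affected by a
disorder — concentrate inherited risk variants that case-control designs
dilute. Exome studies of such cohorts (here modelled on a
schizophrenia-family design: ~14 families, ~39 sequenced members,
affected and unaffected relatives) search for rare, protein-altering
variants whose genotypes *segregate* with disease inside each family:
shared heterozygous variants carried by all affected members, de novo
variants in offspring of unaffected parents, homozygous recessive
variants (especially in consanguineous families), and X-linked hemizygous
variants transmitted from carrier mothers to affected sons. Because a
small cohort cannot power single-variant association, the candidate gene
list is then tested for gene-set over-representation.

`famvar` implements that full design as a library plus CLI:

- **QC** — per-call DP ≥ 10, GQ ≥ 20, alternative allele ratio ≥ 25%
  (failing calls demoted to missing, never silently dropped sites);
  VQSR-pass and segmental-duplication site filters; exclusion of variants
  seen ≥ 20 times in an in-house exome cohort.
- **Relatedness verification** — KING-robust kinship
  φ = (N_het,het − 2·N_AA,aa)/(N_het,i + N_het,j) over co-called
  autosomal sites, checked against pedigree-expected relationship degrees.
- **Rare-variant filters** — protein-altering or splice-site consequence;
  allele frequency ≤ 1% in five population databases (null = never
  observed = passes); gene constraints RVIS percentile ≤ 25 and brain
  normalized expression ≥ 1.
- **Segregation** — per-(variant, family) classification into
  shared_het / de_novo / homozygous_recessive / hemizygous_x with fixed
  precedence, building an *all* candidate set and a *strict* set
  restricted to control-bearing families with control-carrier exclusion.
- **Enrichment** — exact hypergeometric over-representation of candidate
  genes against GMT gene sets with Benjamini–Hochberg Q-values
  (significant at q < 0.05).
- **Synthetic cohorts** — a ground-truthed generator (VCF + PED + sidecar
  + annotation TSVs + in-house counts + GMT) that emulates the study
  design, plants variants of every class plus rule-violating decoys, and
  supports seeded genotype noise with a perturbation ledger.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate a cohort and run the pipeline end to end:

```
$ famvar simulate --out bundle --seed 1
bundle written to bundle

$ famvar run-all --vcf bundle/cohort.vcf --ped bundle/cohort.ped \
    --sidecar bundle/sidecar.tsv --annotations bundle/variant_annotations.tsv \
    --genes bundle/gene_annotations.tsv --inhouse bundle/inhouse_counts.tsv \
    --gmt bundle/gene_sets.gmt --out results_demo
all-set: 16 variants / 16 genes; strict-set: 9 variants / 9 genes
```

The 16 all-set candidates are exactly the planted truth
(`bundle/truth.tsv`): 11 shared heterozygous, 3 de novo, 1 homozygous
recessive in the consanguineous family, 1 X-linked hemizygous; the 8
decoys (each violating exactly one QC or filter rule) are all rejected.
The strict set keeps the 9 candidates from control-bearing families whose
controls carry no candidate allele. `results_demo/` contains
`qc_report.tsv`, `kinship.tsv` (+ a pedigree-mismatch report),
`candidates_all.tsv`, `candidates_strict.tsv`, `summary.json` and
`enrichment_{all,strict}.tsv`; every report embeds the analysis-parameter
hash and seed.

Stages can equally be run one at a time (`famvar qc`, `famvar filter`,
`famvar segregate`, `famvar enrich`, each consuming the previous stage's
outputs) and compose to byte-identical results.

Library use mirrors the CLI:

```python
from famvar import pipeline as pl
from famvar.simulate import SimConfig, simulate_cohort

bundle = simulate_cohort(SimConfig(seed=1), "bundle")
report = pl.run_all(pl.config_for_bundle(bundle, "results_demo"))
print(report.summary_all["per_class"])
# {'de_novo': 3, 'hemizygous_x': 1, 'homozygous_recessive': 1, 'shared_het': 11}
```

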