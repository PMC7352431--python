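# famprio

Family-based germline variant prioritization for dominant disease in
small pedigrees, plus quantification of the telomere assays commonly
used to validate candidates.

The core is a filtering cascade over an annotated multi-sample variant
table:

1. **quality** — caller QUAL > 20, per-member depth > 5, caller-internal
   filters passed;
2. **rarity** — every available population frequency (1000 Genomes,
   non-TCGA ExAC) ≤ 0.1 %; novel variants survive;
3. **segregation** — under a dominant model, every genotyped case
   carries the alternate allele and no genotyped control does; members
   with an intermediate phenotype ("potential carrier") are
   unconstrained, as are missing genotypes;
4. **cadd** — scaled PHRED-like CADD score > 10;
5. **conservation** — GERP > 2.0, PhastCons > 0.3, PhyloP ≥ 3.0 over the
   available scores;
6. **vote** — at least 60 % of the non-missing calls from ten
   deleteriousness predictors (SIFT, PolyPhen2 HDIV/HVAR, LRT,
   MutationTaster, MutationAssessor, FATHMM, MetaSVM, MetaLR, PROVEAN)
   are "deleterious", restricted to missense/nonsense/splice variants.

Protein-altering variants in a user-supplied cancer-gene list are
handled leniently: they bypass the CADD/conservation/vote gates (never
quality, rarity or segregation) and are flagged as rescued. Surviving
candidates are *ranked* — never filtered — by gene-level intolerance
evidence (three intolerance percentiles, pLI for truncating variants,
missense Z for missense). A separate engine combines ACMG/AMP evidence
codes into the five-tier classification using a packaged rule table.

`famprio.assays` implements qPCR relative telomere length
(T/S = 2^−ΔCt against an albumin single-copy control, RTL against a
reference DNA pool), ChIP dot-blot enrichment normalized to total input
chromatin, and the two-tailed equal-variance t-test for group
comparisons.

`famprio.simulate` generates a two-generation synthetic family (by
default 11 members, 9 with samples: 4 cases, 3 carriers, 2 controls
among the genotyped), one planted heterozygous causal variant
transmitted from an untyped founder that passes every gate by
construction, and background variants with role-independent
Hardy–Weinberg genotypes (Mendelian-consistent gene drop within trios)
and annotation scores from configurable null/deleterious mixtures, so
the whole funnel is testable offline.

## CLI

```sh
# generate a synthetic dataset (TSV or VCF dialect + extended PED)
famprio simulate --seed 7 --n-background 1000 --out sim/

# run the cascade; writes funnel.tsv, candidates.tsv, summary.json,
# run.log and a manifest
famprio prioritize --variants sim/variants.tsv --ped sim/family.ped \
    --rescue src/famprio/data/rescue_genes.txt --out report/

# combine ACMG evidence codes
famprio classify --codes PM2,PP1,PP3

# T/S and relative telomere length from a long-format Ct table
famprio telomere --ct ct.tsv --reference pool --out rtl.tsv
```

`prioritize --config thresholds.yaml` accepts a YAML file mirroring
`FilterConfig` field-for-field (thresholds, stage order, rescue genes,
missing-data policies).

## File formats

* **Pedigree**: tab-separated PED (family, id, father, mother, sex,
  phenotype) extended with a role column (`case` / `carrier` /
  `control` / `unknown`) and an optional sample-availability flag.
  `src/famprio/data/family5.ped` is a packaged example with its
  co-segregating missense variant in `family5_pot1.tsv`.
* **Variants**: VCF 4.x with INFO keys `MAF_1KG`, `MAF_EXAC_NONTCGA`,
  `CADD_PHRED`, `GERP`, `PHASTCONS`, `PHYLOP`, `GENE`, `CSQ_CLASS` and
  one D/T key per predictor, or an equivalent flat TSV with `gt_<id>` /
  `dp_<id>` columns (`.` = missing). The two dialects are
  interconvertible and round-trip exactly.
* **Intolerance reference**: TSV with gene, three percentile columns,
  pli, mis_z (see `data/intolerance_example.tsv`; the values there are
  synthetic).

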