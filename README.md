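# cageqtl

Mapping genetic variants to **promoter usage** and **enhancer activity** from
CAGE 5′-tag data.

CAGE (Cap Analysis of Gene Expression) sequences the 5′ ends of capped RNAs,
giving single-base transcription start site positions and counts. Quantifying
each CAGE peak of a gene separately turns "which promoter does this gene use,
and how much?" into a molecular phenotype that can be tested against nearby
genetic variants — a **puQTL** (promoter-usage QTL). The same data measure
enhancer output: active enhancers produce short, balanced bidirectional
transcripts (eRNAs), so summing the two strands' tags around an enhancer
midpoint yields a per-sample activity phenotype for **eaQTL** mapping.
Connecting the two maps with total-mRNA eQTLs, GWAS hits, and causal
mediation tests shows *how* regulatory variants act: promoter shifts that
leave total mRNA unchanged, or enhancer activation that propagates to the
target gene.

The package is aimed at statistical/regulatory genomicists who want a tested,
reusable implementation of this analysis chain, together with a synthetic
cohort generator that plants known effects so every stage can be validated
end to end.

## The statistics in brief

* **Quantification**: tag counts per feature → tags per million (TPM) →
  between-sample relative log expression (RLE, median-of-ratios size factors)
  → mean ≥ 0.5 RLE-TPM filter.
* **cis mapping**: for phenotype *y* and dosage *g* within the phenotype's
  TAD, fit *y* = α + β·g after removing covariate PCs (3 genotype + 20/12
  expression). The best in-window nominal p is adjusted with 1000 phenotype
  permutations (Beta-approximated tail), and genome-wide significance uses
  Storey q-values, q < 0.05 ⇔ 5% FDR.
* **Gene groups**: per gene, peaks < 200 nt apart collapse into promoter
  units; units responding to the lead variant (p < 0.05) sort the gene into
  groups 1–5 by count, slope signs, and effect-size ratio
  ER = |max β| / |min β| (group 5 when ER > 2).
* **Enhancers**: density clustering of pooled CTSS (≥ 5 tags, max/min
  density ≥ 2, ≤ 200 nt), bidirectionality within ±400 nt of the midpoint,
  directionality D = (F − R)/(F + R) with |D| < 0.8, activity = F + R per
  sample.
* **Integration**: π1 = 1 − π̂0 replication, dosage LD (r², Spearman ρ),
  RTC = (N − rank)/N concordance with GWAS hits, MAF/TSS-distance-matched
  permutation enrichment, and a four-component causal inference test with
  omnibus p = max(p1…p4) per direction, 5% FDR.

`docs/methods.md` documents every model, default, and numerical choice.

## Worked example

Run the full pipeline on a synthetic cohort at study scale (150 samples,
~2000 CAGE peaks, 100 enhancers, ~20k variants; about a minute on one CPU):

```bash
cageqtl run-all --out-dir run --seed 7
cageqtl report run
```

which prints (output from this exact command):

```
pipeline run report
===================

        peaks_kept: 1823
            puqtls: 667
  classified_genes: 452
    enhancers_kept: 81
            eaqtls: 46
          triplets: 12
       group sizes: 1:175, 2:69, 3:73, 4:61, 5:74
        pi1 (mRNA): 0.919
   GWAS overlap OR: 6.230 (CI 4.37-9.67, p=0.000999)
```

Reading the numbers: of 1823 CAGE peaks passing the expression filter, 667
have a puQTL at 5% FDR, belonging to 452 genes spread over the five
promoter-usage groups (175 single-promoter genes, 69 single-responding-unit
genes, 73 with opposite-sign effects, 61/74 with concordant effects split at
ER = 2). Of 100 simulated enhancers, 81 pass the bidirectionality and |D|
filters and 46 carry an eaQTL, yielding 12 (variant, enhancer, promoter)
triplets for causal testing. π1 = 0.92 of puQTLs replicate in the synthetic
mRNA totals, and puQTL variants overlap the (planted-QTL-derived) GWAS
catalog far more than matched random variants (OR 6.2). Stage outputs land in
`run/` as TSV/BED/VCF files; `manifest.json` hashes every file, and rerunning
with the same seed reproduces them byte for byte.

Each stage is also a library call (`cageqtl.cis_qtl.map_cis`,
`cageqtl.enhancers.paraclu_cluster`, `cageqtl.integration.cit_test`, …) and a
separate CLI subcommand (`simulate`, `normalize`, `map-puqtl`, `classify`,
`enhancers`, `map-eaqtl`, `integrate`, `report`).

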