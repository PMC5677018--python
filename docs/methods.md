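# Methods

`cageqtl` maps genetic variants to two CAGE-derived molecular phenotypes —
promoter usage (expression of individual CAGE peaks) and enhancer activity
(bidirectional eRNA output) — and integrates the two QTL maps with a
total-mRNA eQTL pass, GWAS hits, and causal mediation tests. This note
documents the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic cohort does and does not emulate.

## Quantification and normalization

CAGE 5′-tag counts are aggregated per feature (CAGE peak on the gene strand;
enhancer flanking windows per strand), scaled within samples to tags per
million mapped reads (TPM), and normalized between samples by relative log
expression (RLE). The RLE estimator is the median of ratios to the
per-feature geometric mean, restricted to features nonzero in every sample,
with size factors rescaled to geometric mean 1; the estimator is undefined
(and signalled) when no feature is expressed everywhere. Features with mean
expression below 0.5 RLE-TPM across the cohort are removed.

Covariates for QTL mapping are principal components: 3 from centered,
unscaled genotype dosages and 20 from the centered, unit-scaled promoter
expression matrix (12 for enhancer activity), the counts used in the original
design at n = 154; they are configurable and clamped with a warning when a
small cohort cannot support them. Phenotypes are rank-based
inverse-normal transformed before mapping (`rank_transform`, on by default) to
guard the linear model against residual count skew; whether the original
analysis transformed phenotypes is not documented, so the switch is exposed.

## cis-QTL mapping

Each phenotype is tested against all variants inside its topologically
associating domain (TAD); the anchor is the stranded 5′ end for CAGE peaks
and the midpoint for enhancers. Anchors outside every TAD fall back to a
±1 Mb window (logged). Covariates are regressed out once by OLS; the
per-variant statistic is the correlation of the residuals with dosage, with
degrees of freedom n − 2 − (number of covariates) to account for the prior
residualization. The lead variant is the smallest p, ties broken by genomic
position.

Multiplicity within a window is handled by permutation: the residualized
phenotype is shuffled across samples (covariates are not re-fit per
permutation, the QTLtools convention) and the best in-window p recorded.
Three adjustment modes:

* `empirical`: (1 + #{permutation best p ≤ observed}) / (1 + n_perm);
* `beta` (default, 1000 permutations): a Beta(a, b) distribution is fitted to
  the permutation best-p values by maximum likelihood and the adjusted p is
  its CDF at the observed best p; with fewer than 100 permutations the code
  warns and falls back to `empirical`;
* `exhaustive`: full enumeration of all n! sample permutations (n ≤ 9),
  used as an exactness oracle in the tests.

Permutation seeds are derived per phenotype from the root seed (CRC32 of the
phenotype id mixed into a `SeedSequence`), so results do not depend on scan
order.

Genome-wide significance uses Storey q-values over the adjusted p-values:
π̂0(λ) = #{p > λ}/(m(1 − λ)) on λ ∈ {0.05, …, 0.95}, smoothed by a cubic
polynomial weighted by each point's precision (the variance of π̂0(λ) grows
like 1/(1 − λ), so the noisy high-λ end is down-weighted) and evaluated at
λ = 0.95, clipped to (0, 1]. With fewer than 100 tests the smoother is
unstable and the single-point λ = 0.5 estimator is used instead. QTLs are
called at q < 0.05 (5% FDR).

## Promoter-usage classification

For every gene with a genome-wide-significant puQTL, all of its CAGE peaks
are re-tested against the gene's single lead variant (the variant of its most
significant peak; the variant-sharing rule is implied but not stated in the
original description). Peaks under 200 nt apart collapse by single linkage
into promoter units (pairwise distance, so a 0/150/300 chain is one unit);
each unit carries its most significant peak's slope and p. Groups:

1. one unit; 2. exactly one unit with p < 0.05; 3. two or more responding
units with opposite slope signs; 4./5. concordant signs split by the
effect-size ratio ER = |max β|/|min β| over responding units, group 5 when
ER > 2 (strictly; ER = 2 stays in group 4).

Per-peak slopes for classification are estimated on log(1 + RLE-TPM), not on
the rank-transformed scale: the inverse-normal transform standardizes each
peak by its own total variance, which compresses between-peak effect-size
ratios and erases the group-4/5 distinction. On log expression the slope is
the per-allele log fold change, directly comparable across peaks.

If no unit passes p < 0.05 despite genome-wide significance (possible after
re-testing against a shared lead variant), the inconsistency is logged and
the best unit is treated as the single responder (group 2).

## Enhancer activity

CTSS records are pooled across the cohort (clustering sample-wise patterns
cohort-wide is the only reading consistent with selecting enhancers
"characterized with bidirectional transcription patterns in our samples") and
clustered per strand by recursive maximal-density segmentation: a segment's
candidate interval is [detachment density, break density), where the break
density is the weakest prefix/suffix boundary density and the detachment
density is the running maximum of break densities along its ancestor chain
(a segment is maximal for a density d only if d exceeds every split that
separates it from the root). Emitted clusters must hold ≥ 5 tags, span
≤ 200 nt, and have max/min density ≥ 2; single-position clusters have
infinite maximum density and pass the ratio by construction, since the
ratio constraint targets diffuse clusters.

An enhancer is retained when at least one plus- and one minus-strand cluster
overlap the ±400 nt window around its midpoint. Expression of the two
200 nt flanking windows (R = minus strand [mid−200, mid), F = plus strand
[mid, mid+200)) is normalized TPM→RLE jointly over all windows; the
directionality score D = (F − R)/(F + R) uses the across-sample sums (one
cohort-level D per enhancer), and per-sample activity is F_s + R_s.
Enhancers with |D| ≥ 0.8 (promoter-like) or with zero activity in more than
a 50/154 fraction of samples are dropped; F + R = 0 makes D undefined and
drops the enhancer with a log entry.

## Integration statistics

**π1.** The replication statistic is 1 − π̂0 over the nominal p-values of one
QTL set's lead variants re-tested in another phenotype (here, per-gene mRNA
totals). A bootstrap standard error (100 resamples) accompanies the point
estimate.

**RTC.** For a QTL and a GWAS variant sharing an interval (the TAD set by
default; the original used recombination-hotspot intervals), the phenotype is
residualized on each interval variant in turn and the QTL variant re-tested
against each set of residuals. The GWAS variant is ranked by how strongly its
correction extinguishes the QTL association (rank 0 = corrected p largest,
ties by position); RTC = (N − rank)/N, with RTC > 0.9 flagged high
confidence. Shared signals give RTC near 1; unrelated variants rank among
the interval background.

**GWAS overlap enrichment.** A QTL variant overlaps when it matches a catalog
variant or lies within ±500 kb of one with dosage r² > 0.5. The null redraws,
per QTL variant, a random non-QTL variant from the same MAF decile and
TSS-distance bin (10 log-spaced bins; empty bins widen to the MAF bin, then
to all non-QTL variants, logged), 1000 permutations. The odds ratio compares
observed odds to the permutation mean with a Haldane correction at the
boundaries; the CI is the 2.5/97.5 percentile of per-permutation odds ratios
(the original interval construction is not described); the empirical p has a
1/(n_perm + 1) floor.

**Annotation enrichment.** Observed QTLs inside functional annotations are
compared with permutations that keep each QTL's signed offset to its
phenotype anchor but re-draw the anchor uniformly from the landscape of all
tested phenotypes.

**Causal inference test.** For triplets (variant L, enhancer activity M,
promoter expression T), four component tests per direction: (1) T ~ L;
(2) M ~ L | T; (3) T ~ M | L; (4) an equivalence test of conditional
independence L ⊥ T | M. For (4) the no-mediation reference distribution is
built by regressing M on L and permuting the residuals (preserving the L–M
association while severing M–T beyond L); the F statistics for L in
T ~ M* + L across 500 permutations yield a method-of-moments noncentrality,
and p4 is the lower tail of the noncentral F at the observed statistic.
The omnibus p is the maximum of the four; both causal directions are tested
(the two directions share a permutation stream, so relabeling mediator and
outcome swaps the results exactly), and triplet-level calls use Storey
q-values at 5% FDR. Triplets pair each eaQTL's enhancer with its linked
promoters; a triplet is "shared" when the eaQTL variant is a puQTL variant or
has |Spearman ρ| > 0.8 with one.

**TSS annotation.** (1) peaks whose stranded 5′ end is within 500 nt upstream
of an annotated TSS or inside a same-strand 5′-UTR first exon/intron are
"Annotated gene"; (2) otherwise the chromatin state decides: enhancer states
are "eRNA/enhancer", promoter states go on, anything else is "other";
(3) promoter-state peaks overlapping a gene body on the opposite strand are
"Antisense promoter", the rest "Putative promoter" (intragenic/intergenic
recorded). Antisense is defined as opposite-strand overlap with a gene body;
the original boundary ("based on genomic localization") is under-specified.

## Synthetic cohort

The generator's defaults are the study conditions: 150 unrelated samples,
sequencing depth 16.2 × 10⁶ ± 4.3 × 10⁶ tags, TAD-partitioned genome,
multi-promoter genes (1–7 peaks, mean ≈ 2.3, with inter-peak gaps drawn on
both sides of the 200 nt collapsing cutoff), enhancer midpoints ≥ 1 kb from
promoters, and planted per-allele log-scale slopes of 0.5–1.0 covering all
five promoter-usage groups, enhancer-activity effects, and
variant→enhancer→promoter mediation chains.

Genotypes are diploid dosages from copy-with-mutation haplotype chains within
LD blocks (allele copied from the previous variant, redrawn from the block
frequency with probability 0.15, giving immediate-neighbor r² ≈ 0.7);
variants with alternative-allele count < 10 are removed, mirroring the real
genotype filter. Counts are negative binomial with a log link (dispersion
0.05; the generative model is the package's choice — NB matches CAGE
overdispersion); promoter tags sit at the peak's stranded 5′ end, enhancer
tags are spread divergently over three positions per 200 nt flank with a
per-enhancer F/R balance inside the |D| < 0.8 region for "bidirectional"
elements, fully one-sided for "unidirectional" ones, and near-zero expression
for "silent" ones. Mediated effects flow through a latent per-sample
activity (slope × dosage + N(0, 0.3)) shared by the enhancer and its paired
promoter. The GWAS catalog mixes LD partners of planted QTL variants with
random null variants.

The cohort emulates the statistical structure the pipeline consumes, not
sequence-level reality: there are no reads or mapping artifacts, no
population structure or batch effects, variant positions are uniform within
TADs (so QTLs are not positionally enriched near promoters, unlike real
data), library composition is dominated by the simulated features, and LD
decays geometrically rather than following recombination maps. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under a faithful effect-size/noise regime — not performance under
real-data confounding.

## Calibration experiments and problem sizes

`cageqtl.experiments` packages the validation runs used by the tests and the
acceptance script; sizes are chosen to characterize each statistic at the
study's n = 150 within minutes on one CPU:

* FDR/power: 200 phenotypes per replicate (10% alternatives, slopes 0.5–1.0),
  1000 permutations, 10 replicates;
* slope recovery: the mapper's estimate at the causal variant, 50 replicates
  × 10 phenotypes, unlinked variants with MAF ≥ 0.3 so the error reflects
  estimation noise rather than LD attenuation or lead mis-selection;
* π1 recovery: m = 5000 per cohort, 10 cohorts averaged per grid point
  (the single-cohort smoother has endpoint noise of ~±0.05);
* RTC separation: two-block intervals (~60 variants) with slow within-block
  LD decay (switch probability 0.02), 50 simulations per condition;
* CIT operating characteristics: 100 replicates per topology, 200
  permutations for component 4;
* enhancer filters and classifier recovery: full tag-level simulations.

## Numerical choices and degenerate inputs

Missing genotypes are mean-imputed per variant (flag kept). Monomorphic
variants are skipped in scans and signalled in LD computations. Constant
phenotypes are skipped with a log entry. Beta fits clip permutation p-values
to [1e-12, 1 − 1e-12] and fall back to the empirical estimate if the fit
fails. Odds ratios use a 0.5 Haldane correction at 0 or full overlap. All
permutation p-values respect the 1/(n_perm + 1) floor. Coordinates are
0-based half-open everywhere; VCF positions convert on read/write. Lead and
rank ties break by genomic position for reproducibility; all randomness
derives from one root seed, and rerunning a pipeline configuration
reproduces byte-identical outputs (hashed into `manifest.json`).

## Known limitations

Single independent signal per phenotype (no conditional mapping); no
trans-QTLs; TADs as RTC intervals instead of recombination hotspots;
cohort-level directionality only (per-sample D is diagnostic); the CIT, like
all mediation tests, is sensitive to measurement noise in the mediator; the
synthetic generator's simplifications listed above.
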