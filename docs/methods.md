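# Methods

This note records the models behind each stage, the defaults and why they
were chosen, the numerical conventions, and what the synthetic data does and
does not emulate.

## RIAIL simulation

A recombinant inbred advanced intercross line is modelled as a homozygous
mosaic of two parental genomes. Per chromosome and line, the starting allele
is Bernoulli(1/2); the number of crossovers is Poisson with mean
`map_expansion × length_cM / 100`; breakpoints are uniform in genetic
distance and alleles alternate at each breakpoint. This is the Haldane
(no-interference) model — the simplest crossover process consistent with a
genetic map in centimorgans. Crossover interference, genotyping error,
residual heterozygosity and segregation distortion are *not* modelled;
passing tests therefore demonstrate the statistics' behaviour under clean
mosaic genotypes, not robustness to those artifacts.

`map_expansion` (default 4) is a single scalar absorbing the map-expanding
effect of the intercross generations that precede inbreeding in an advanced
intercross design; the breeding design itself is not simulated because the
scans only require mosaics with realistically dense breakpoints. The default
panel is 300 lines × 600 markers on 6 chromosomes of 50 cM, with physical
positions tied to genetic positions at a constant 40,000 bp/cM
(`bp = round(cM × 40000) + 1`, 1-based), so both the 1-Mb local-eQTL rule
and the 5-cM hotspot bins are exercised on compatible scales.

Genotypes are coded 0 (parent A) / 1 (parent B) with −1 as the missing
sentinel. The correlation-based LOD is invariant to affine recoding, so the
coding choice is cosmetic; 0/1 matches homozygous inbred biology.

Quantitative traits are additive: `y = Σ βk·gk + ε`, with Gaussian noise
scaled against the realized genetic variance on the panel so the expected
heritability equals the target. Expression probes come in three classes —
local (driven by a marker within 0.5 Mb of the probe start), hotspot (driven
by one designated locus, probe placed on another chromosome so its eQTL is
distant), and null — with unit-variance Gaussian noise and configurable
effect sizes of random sign. Mediated traits follow the linear structural
model `m = a·g + ε`, `y = b·m + c′·g + ε`, so the true indirect effect is
`a·b`.

## Linkage mapping

The per-marker statistic is `LOD = −n·ln(1−R²)/(2·ln10)` with `R` the
Pearson correlation of genotype and trait over the `n` lines complete at
that marker (pairwise-complete: `n` may differ across markers). `1−R²` is
floored at 1e−16, capping a perfectly correlated marker at a finite LOD
(≈3.47·n) instead of emitting infinity. Markers monomorphic among complete
pairs, or with fewer than 3 complete pairs, report NaN.

The genome-wide threshold permutes trait values across lines (breaking
genotype–phenotype linkage while preserving both marginals), records each
permutation's genome-max LOD, and takes the empirical 95th percentile using
the *order-statistic* (`method="higher"`) convention: with the observed
trait exchangeable with its permutations, the test then has exact level
50/1001 ≈ 5% at 1000 permutations. Default 1000 permutations, α = 0.05.

Forward search: scan; if the max LOD exceeds the threshold, record the peak
(ties broken toward the lowest genomic coordinate), residualize the
*original* trait on the genotype columns of all recorded peaks (OLS with
intercept, duplicate columns dropped with a warning), rescan the residuals;
stop at no exceedance or `max_qtl`. The threshold is computed once on the
original trait and reused across iterations — one genome-wide error rate per
trait; `recompute_threshold=True` re-permutes each residualized trait
instead, for users who prefer per-iteration calibration.

QTL annotation: the 95% confidence interval walks outward from the peak; on
each side the bound is the *first* marker whose LOD falls strictly below
`peak − 1.5` (that marker included — the "proximal" convention; the
alternative, last-marker-above, gives intervals one marker narrower), or the
terminal marker if the chromosome end is reached. Variance explained is
`1 − 10^(−2·LOD/n)`, the exact inverse of the LOD form, so it round-trips
the peak R². The allelic effect is `mean(y | allele B) − mean(y | allele A)`.

## eQTL mapping and hotspots

The panel scan standardizes the genotype matrix once and computes
marker × probe correlations as one matrix product per block of 512 probes;
with missing genotypes it falls back to pairwise-complete per-probe scans.
The block path is tested against the per-probe loop to 1e−10.

The FDR threshold searches the grid 2–10 (step 0.01): for each threshold
`t`, `FDR(t)` = (mean over 10 permutations of the number of probes with max
LOD > `t`) / (number observed > `t`); the chosen threshold is the smallest
`t` with FDR < 0.05 — the most permissive threshold that still controls the
rate. Line labels of the whole expression matrix are permuted jointly,
preserving inter-probe correlation (per-probe independent shuffling is an
option). Where the observed count is zero the FDR is 0 if the permuted mean
is also zero, else +∞. Counting uses strict `>` on both sides of the ratio.

Local/distant: an eQTL is local iff its peak marker lies on the probe's
chromosome within 1,000,000 bp (inclusive) of the probe's start.

Hotspots: each chromosome is cut into half-open 5-cM bins `[iw, (i+1)w)`
with the final partial bin kept; distant eQTL are assigned by their peak
marker's genetic position. With λ = counted eQTL / total bins, the critical
count is the smallest `k` with Poisson CDF(k; λ) ≥ 1 − 0.01/n_bins
(Bonferroni-corrected 99th percentile), and a bin is significant when its
count strictly exceeds `k`. λ defaults to the *distant* count (the quantity
being binned); `lambda_all=True` uses all passing eQTL instead, since either
reading of "total QTL / total bins" is defensible. An optional strict LOD
floor (`lod > floor`, e.g. 5 or 6) re-runs detection on high-confidence eQTL
only, and `hotspot_permutation_check` scatters the counted eQTL uniformly
over bins to measure the spurious-hotspot rate (expected < 1 per dataset
under the correction).

## Mediation

Three OLS fits on the common sample give slopes `a` (mediator on genotype),
`b, c′` (phenotype on mediator + genotype) and `c` (phenotype on genotype);
`c = c′ + a·b` holds algebraically and is asserted to 1e−8. The mediation
score is the indirect effect `a·b`; the direct effect, the expression slope
`b`, and the mediated proportion `a·b/c` are all reported, but the
proportion is never used for ranking because inconsistent mediation (direct
and indirect effects of opposite sign) pushes it outside [0, 1], where the
`proportion_interpretable` flag is set False.

Inference is a nonparametric percentile bootstrap: lines resampled with
replacement (observation resampling, not residual resampling), default 1000
resamples; degenerate resamples (a single genotype class) are dropped from
the bootstrap distribution. The two-sided p-value is
`2·min((#{≤0}+½)/(B+1), (#{≥0}+½)/(B+1))`, the sign-based bootstrap p with a
half-count continuity correction so it is never exactly 0.

`mediate_panel` ranks candidates by |indirect effect| (absolute value, so
resistance- and sensitivity-direction mediators compare on one scale).
Percentile ranks use the mean-rank convention, under which exactly
⌈0.1·n⌉ candidates sit at or above the 90th percentile when scores are
distinct; per-probe bootstrap seeds derive from the master seed and a CRC32
hash of the probe id, making results independent of candidate order.

## Phenotype processing

Drug-condition replicates are regressed on their strain's mean
control-condition value with a single pooled OLS line; the residuals are the
mapped trait (variation attributable to the drug, net of baseline growth).
If all control means coincide the design collapses and residuals revert to
deviations from the drug mean. A `group_by`-style per-batch fit is left to
the caller by subsetting, since pooling matches the single-model
description. The derived trait `median.norm.EXT = median.EXT / median.TOF`
normalizes optical density by animal length; 0–1 normalization is affine
min–max, refused on constant input.

Broad-sense heritability is the intraclass correlation of
`phenotype ~ 1 + (1|strain)`: REML via statsmodels MixedLM by default, with
the one-way ANOVA method-of-moments estimator as an explicit option and as
automatic fallback (identical expectation for balanced designs; also used
when REML cannot converge, e.g. noise-free data). Negative variance
components are truncated at zero before forming H². Pairwise strain
contrasts use the Tukey HSD studentized-range test on `phenotype ~ strain`.

## Problem sizes and determinism

Default analysis conditions — 300 lines, 600 markers, 500 probes, 1000
linkage permutations, 10 FDR permutations, 1000 bootstrap resamples — are
the package's standard study scale; the calibration script measures the
genome-wide error rate over 500 null traits and the realized eQTL FDR over
20 replicate panels at exactly this scale. Every stochastic routine takes a
seed; the pipeline expands one master seed into per-stage seeds through
fixed counters (`SeedSequence([master, counter])`), so adding a stage never
perturbs earlier streams and reruns are byte-identical.

## Known limitations

* Marker regression only: no interval mapping between markers, no
  Haley–Knott regression, no mixed-model association; resolution is limited
  to the marker grid.
* The permutation FDR is an expected-proportion estimate, not an FDR-adjusted
  per-probe q-value.
* Mediation assumes the linear structural model with no confounding of the
  mediator–outcome path (sequential ignorability); no sensitivity analysis
  or multi-mediator models are provided.
* The hotspot test treats bins as exchangeable Poisson draws; long-range
  linkage disequilibrium between adjacent bins is ignored.
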