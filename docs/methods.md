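# Methods

This note records the statistical models implemented by `recdiff`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that matter for reproducing
results.

## Coordinates and containers

All coordinates are 0-based half-open (BED convention); VCF positions are
converted on read and write.  Recombination maps are piecewise-constant
per-base per-generation rates; binned tracks tile chromosomes at a fixed
width with the final bin kept short and flagged by its true extent.
Bin-averaging uses the length-weighted mean over covered bases only
(bedtools `map -o mean` semantics), leaving uncovered bins explicitly
missing rather than zero.

## Landscape divergence

**Correlation panel.**  Each replicate map is averaged into 2 kb bins and
every pair of replicates is Spearman-correlated inside non-overlapping 5 Mb
windows.  Non-overlapping windows (rather than a sliding step) keep window
values independent for the pooled medians; the step is configurable.  Pairs
with fewer than 10 jointly non-missing bins in a window yield no value.

**me, ms and PRDI.**  `me` is the lowest of the two within-population
median correlations minus the between-population median, with medians
pooled over all windows and pairs.  Pooling (instead of per-window medians
first) was an open choice; pooled medians are used because they weight
windows by their available pair count, and the per-window contrast is still
available through `prdi_profile`.  `ms` applies the same contrast to maps
inferred from neutral data generated under one shared landscape, so
`PRDI = me − ms` isolates divergence beyond what demography and estimation
noise produce.  Because the statistic is rank-based it is invariant to any
strictly monotone transform of the rates.

**Δr.**  For every complete 100 kb window of fifty 2 kb bins,
`Δr = ln(mean |r_A − r_B| + ε)` with a natural log and `ε = 1e-12`
(configurable).  The log base is a monotone choice that does not move the
SD-rule flags except at the ε floor; windows missing any bin, or short at a
chromosome end, are dropped so every Δr summarises exactly fifty bins.
Outlier windows are those whose median between-population Δr exceeds the
genome-wide mean of the per-window median within-population Δr by three of
its SDs — both sides of the rule use the same per-window-median granularity
so the null comparison is exchangeable.

**Hotspots and coldspots.**  Per 2 kb bin, the log rate is compared with
the mean and sample SD (ddof = 1) of the bins within ±20 kb, excluding the
focal bin; |z| > 3 calls a hotspot (above) or coldspot (below).  Excluding
the focal bin keeps a single extreme bin from inflating its own background.
At chromosome ends the truncated neighbourhood is used with at least five
background bins.  Zero rates are floored at the smallest positive rate
×1e-3 before the log (LD-based estimators can emit exact zeros).  A
background flatter than 1e-7 log units is treated as zero-SD: the bin is
called only if it deviates beyond that tolerance, which keeps cumulative-sum
rounding from manufacturing infinite z-scores.  Calls of the same kind merge
at gaps ≤1 kb (below the 2 kb bin width, so only adjacent significant bins
merge) and merged hotspots longer than 5 kb are removed as artefact-prone.
Sharing between call sets counts ≥1 bp overlap; percentages are reported
rounded to integers from each set's own denominator, since no single
convention reproduces every published rounding.

In the pipeline, spots are called per population on the replicate-averaged
track (geometric mean of rates, i.e. mean log rate), which suppresses
replicate estimation noise by √k before thresholding.

## Differentiation scan

**Weir–Cockerham θ̂.**  The two-population per-locus estimator
θ̂ = a/(a+b+c) with the standard variance components, computed from called
diploid counts, alt-allele counts and heterozygote counts; missing genotypes
simply reduce the per-population sample size.  Loci monomorphic across both
populations are undefined (NaN).  The estimator may be negative in finite
samples; that is expected behaviour, not an error.

**Recombination bins.**  100 kb windows take quintile labels (20th/40th/
60th/80th percentile edges, linear-interpolation quantiles) of the
genome-wide pedigree-map cM/Mb distribution.  The pedigree map is used
instead of the LD-based map to avoid circularity: selection inflates LD,
which depresses LD-based rate estimates exactly where F_ST is interesting.
Windows without a linkage value are excluded from the scan.  Outlier SNPs
strictly exceed the 99th percentile of F_ST within their bin ("exceeding"
reads as strict, so threshold ties are not outliers).

**Window enrichment.**  Windows with <10 SNPs are removed first; the
genome-wide outlier proportion p₀ is computed after that filter (both
counts are logged).  The window statistic is the exact binomial upper tail
P(X ≥ k | n, p₀).  Linked SNPs violate the independence assumption, so this
is an enrichment score rather than a calibrated P-value; no multiple-testing
correction is applied, matching the raw 0.05 cut the score is used with.
Adjacent enriched windows (zero gap on the tiling) merge; both pre- and
post-merge counts are reported.  Two controls are attached: a χ² test of
uniform representation of enriched windows across the five bins, and the
Pearson correlation of the window P with its SNP count.

**Candidate-region overlap.**  The observed statistic is the Pearson χ²
(no continuity correction; zero-expected cells contribute zero, so a
degenerate margin gives χ² = 0 rather than an error) of enriched/background
× overlap/no-overlap.  The null repositions each enriched window uniformly
within its own chromosome, preserving its size and allowing permuted
windows to overlap each other — the minimal null that respects chromosome
identity and window size.  The empirical P is the fraction of permuted χ²
at or above the observed, reported as "< 1/n_perm" when none reach it.

## Diversity and residuals

Windowed π sums, over variant sites, 2·c_alt·(n − c_alt)/(n(n−1)) with n
the called alleles at the site, and divides by the full window length —
positions without a variant record are treated as genotyped monomorphic
sites.  This matches the missing-data-aware convention of modern π
estimators at the resolution available from a variants-only input; windows
with no variant records therefore read π = 0, not missing.  Population mean
π is compared by a Welch t-test (unequal variances; category sizes in this
pipeline are very unequal, and Welch reduces to Student when variances
match).

Windowed F_ST for the models is the ratio of summed variance components
Σa/Σ(a+b+c), the standard multi-locus combination.  The model
log F_ST ~ cM/Mb + π + cM/Mb:π is fitted by OLS per population; windows
with non-positive F_ST are dropped before the log and counted.  A
rank-deficient design raises rather than silently dropping a term.

The map-residual analysis regresses log(mean LD-based rate per 100 kb
window) on pedigree cM/Mb by OLS and keeps the residuals: negative values
mark windows with less effective recombination (more LD) than their meiotic
rate predicts.  Residuals are correlated with π and with both raw and log
F_ST (both are reported because the published choice of scale is ambiguous),
and compared across window categories (background / enriched / enriched ∩
candidate) by Welch t-tests, skipping categories with fewer than two
windows.  If the LD rate is an exact monotone function of cM/Mb the
residuals vanish and the analysis flags itself degenerate instead of
reporting spurious correlations.

## Structural variants

Reference spans follow VCF semantics: deletions and inversions occupy
[pos, pos+len), insertions anchor at pos with a 1 bp span.  Per-SV F_ST is
the same Weir–Cockerham operation applied to SV genotypes.  Outliers
strictly exceed the 99th percentile of the SV F_ST distribution, so a
degenerate all-equal distribution flags nothing.

The Fisher overlap test is two-sided, run overall and stratified into
small (<1 kb) and large (≥1 kb) SVs.  SV density per 100 kb window counts
deletions and insertions as 1 bp and inversions at their length (the
published density rule states the 1 bp convention for deletions; insertions
are also 1 bp on the reference by construction), and is Spearman-correlated
with −log₁₀ of the window P as a confounding control.

**LD features.**  For each SV, the flanking pair is the nearest SNP
strictly left of the span start and the nearest strictly right of the span
end, each within 5 kb of its breakend (breakends, not the midpoint — a
declared choice where the source convention is unstated).  SVs lacking a
flank, an r² record, or whose pair spans more than 35 kb (the typical
pairwise-LD computation window) are dropped and counted.  `proportion
covered = |SV length| / (pos₂ − pos₁)` and may exceed 1 for insertions,
whose length does not exist on the reference.  The inverse
frequency-weighted distance is implemented as
1/((pos₂ − pos₁)·MAF₁·MAF₂); the literature formula is undefined, so this
stand-in is isolated behind the feature builder and documented as
provisional.  The model r² ~ scaled(distance) + scaled(proportion covered)
+ SV type with a chromosome random intercept is fitted by REML
(`statsmodels` MixedLM); with a single chromosome it falls back to OLS with
a warning.  Marginal means per type are fixed-effect predictions at
covariate means (the random intercept has mean zero), and pairwise type
contrasts use the fixed-effect covariance with normal-theory P values.

**Spot enrichment.**  SV counts in hot/coldspot categories are compared
with 10,000 shuffles that reposition each region uniformly within its
chromosome, preserving lengths; the one-sided P is the fraction of shuffles
with at least the observed count and the ratio divides the observed count by
the shuffled mean.

## Synthetic data

The generators produce every pipeline input with planted, returned truth:

* **Landscapes** — a shared Gaussian log-rate field per chromosome
  (moving-average-smoothed white noise, standardised per chromosome), mean
  ln(1e-8) ≈ −18.4 and SD 1 in natural-log units, autocorrelation length
  50 kb.  Hotspots (+4 SD, 3 kb) and coldspots (−4 SD, 4 kb) shift the
  field in proportion to each bin's covered fraction, matching what
  bin-averaging of a per-base shift would produce; coldspots are kept
  narrower than half the ±20 kb calling background so a planted spot does
  not dominate its own background estimate.  Divergence segments add a
  log-rate shift to population 2 only.  Each of the six replicate subsets
  per population (matching the replicate-subset design of LD-based map
  studies) adds iid N(0, 0.33) log noise per bin, chosen so that
  within-population replicate Spearman correlations land near 0.9 at 2 kb
  resolution, the consistency level typical of resampled LD-based maps.
* **Linkage map** — the noise-free population-averaged rate per 100 kb,
  converted at 1e-8 per bp per generation = 1 cM/Mb with log-normal noise
  (SD 0.1), emulating an independent meiotic map that tracks the landscape
  imperfectly.
* **Genotypes** — Balding–Nichols: ancestral frequencies uniform on
  (0.05, 0.95), population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with
  F = 0.02 background and 0.4 in planted 100 kb windows, 40 diploids per
  population, binomial genotypes, optional missingness, and a pooled
  MAF ≥ 0.05 filter applied to the realized sample, mirroring the standard
  SNP filter.  With these settings the realized mean per-SNP θ̂ sits within
  a few percent of F (verified by a Monte-Carlo test at ±20% tolerance).
* **SVs** — per-type counts at catalogue-like proportions
  (DEL ≈ INS ≫ INV), log-normal lengths with medians ~0.2/0.25/2.5 kb,
  Balding–Nichols frequencies, optional placement inside supplied
  coldspots, and optional planted outliers with a fixed between-population
  frequency gap.
* **LD records** — r² for the flanking pair of each SV from a linear model
  with a proportion-covered slope, per-type shifts, a chromosome intercept
  and Gaussian noise, clipped to [0, 1].

Everything is deterministic given the seed.  What the generators do *not*
emulate: coalescent gene genealogies and linkage between SNPs (sites are
independent given frequencies, so the binomial enrichment score is better
calibrated here than on real, linked data), demography beyond what the F
parameter absorbs, sequence context, SV genotyping error, and the
correlation between diversity, recombination and differentiation that linked
selection produces in real genomes.  Passing recovery tests therefore
demonstrates that the estimators and decision rules do what they claim on
data satisfying their assumptions — not that real data meet those
assumptions.

## Problem sizes

Tests and the acceptance script run on a four-chromosome, 10 Mb-per-
chromosome genome with ~20,000 SNPs, 6 replicate maps per population and
~400–500 SVs — sizes chosen so the full validation suite completes in well
under a minute while every window-level statistic still has hundreds of
windows behind it.  All analysis tunables keep their study-scale defaults
(2 kb bins, 5 Mb correlation windows, 100 kb scan windows, 500/10,000
permutations), so scaling up is a config change, not a code change.

## Known limitations

* The binomial window score inherits SNP non-independence on real data; it
  ranks windows sensibly but its P is not calibrated there (hence the χ²
  uniformity and SNP-count controls).
* π from a variants-only input cannot distinguish "no variant" from "no
  data"; fully untyped windows read 0 rather than missing.
* The inverse frequency-weighted distance is a declared stand-in; swap it
  behind `build_ld_features` if a canonical definition emerges.
* Hotspot calling with a local-background z-rule is biased against broad
  features by construction; features wider than roughly half the background
  window suppress their own contrast.  This matches the published rule and
  is why the generator's spots are narrow.
* `spot_enrichment` shuffles regions, not SVs, so clustered SVs inflate the
  variance of the null counts; with the region counts used here the test is
  slightly conservative.
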