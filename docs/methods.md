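# Methods

## Scope and model

`ffpeqc` implements sample-level quality control for bulk RNA-seq of
FFPE tissue. The package has two halves: (i) deterministic statistics
computed on a real or synthetic cohort — normalization, the three QC
metrics, replicate reproducibility, threshold derivation, and the QC
predictor — and (ii) a generative model of an FFPE cohort used to test
everything end to end. Nothing in the package depends on external data.

## Synthetic cohort model

**Gene catalog.** Exonic lengths are log-normal (median 1.5 kb, log-sd
1.0) clipped to [200, 100000] bp — heavy-tailed, like real exonic
lengths. GC fractions are Beta(5,5) rescaled to [0.3, 0.7]; base
expression is log-normal with log-sd 1.5 (≈3 orders of magnitude).

**Counts.** For sample *s* with latent quality `q ∈ [0,1]` and gene
*g*, the expected count is

```
mu_gs = depth · p_g · bio_g · exp(−dropout_strength · (1−q) · w_g)
```

with `p_g ∝ base_mean_g · length_g` (reads scale with transcript
abundance times length), `bio_g` a specimen-level log-normal biological
factor (log-sd 0.5) shared by all replicates of one specimen, and `w_g`
a degradation weight increasing with GC and decreasing with log length
(z-scored combination, min–max normalized to [0,2] so its mean is ≈1
and `dropout_strength` keeps an interpretable scale). Counts are
negative binomial (gamma–Poisson) around `mu_gs`. Degraded samples
additionally receive multiplicative log-normal noise with
`sd = degradation_noise_sd · (1−q) · w_g` (mean-corrected), which is
what produces the higher replicate variability of degraded samples and
its concentration in short, GC-rich genes.

Defaults (all implementer-chosen; the emulated study design publishes
no generative parameters): `dispersion = 0.02` (technical-replicate
scale — replicate libraries of one specimen differ by counting noise
plus a small overdispersion, not by biological variation),
`dropout_strength = 2.0`, `degradation_noise_sd = 1.0` (at the worst
simulated quality, the most susceptible genes gain ≈1 log2-unit of
replicate noise, enough to push replicate FPR from a few percent to
tens of percent, the range reported for degraded material),
`mean_depth = 2.5e6` for the desk-scale default of 2000 genes, i.e.
≈1250 expected reads per gene — the same per-gene depth as 25M reads
over 20k genes.

**Cohort design.** Study samples draw quality ~ U(0.15, 0.95) and are
grouped into batches by quality (mirroring the practice of sequencing
similar-quality samples together). Every batch carries one FFPE
technical control; all controls are replicates of one fixed
good-quality specimen (quality ≈ 0.8, drawn once). The first
`n_replicate_groups` study samples are duplicated into a neighboring
batch as study replicates.

**Lab metrics.** RNA concentration is `5 + 55·q` ng/ul plus Gaussian
noise (sd 3, truncated at 0); pre-capture library concentration is
`0.2 + 7.8·q` plus noise (sd 0.3). Both are calibrated so the 25 and
1.7 ng/ul decision cutoffs fall mid-range. DV50/100/200 are logistic
functions of quality with staggered midpoints (DV200 saturates first,
DV50 last), emitted for completeness but unused by the default
predictor. In *planted-rule* mode the labels are recomputed as PASS iff
RNA ≥ 25 and library ≥ 1.7, then flipped independently with probability
`label_noise`; the predictor-benchmark cohort
(`planted_rule_cohort`) instead draws the two concentrations as
independent uniforms (U(5,60) and U(0.2,8)) so both cutoffs are
identifiable — when both metrics are monotone in one latent quality
they are nearly collinear and the second split carries little signal.

**What the generator does not emulate:** isoform structure, GC-content
amplification bias beyond the degradation weight, batch effects other
than quality grouping, ambient/contaminating reads, and variant-level
data (SNP sets are consumed as abstract position sets). Passing tests
therefore demonstrate correctness of the statistics and recoverability
of planted structure, not performance on any particular real cohort.

## Deterministic statistics

**Normalization.** FPKM divides counts by length (kb) and library size
(millions); TPM renormalizes FPKM columns to 1e6. TMM factors follow
the published trimmed-mean-of-M-values procedure: reference = sample
whose upper-quartile count fraction is closest to the cohort mean;
genes with zero counts in either member of a pair are excluded; 30%
two-sided trim on M, 5% on A; precision-weighted mean of the surviving
M values; factors normalized to geometric mean 1. log2 CPM uses
effective library sizes and a pseudocount of 1 on the CPM scale
(configurable).

**QC metrics.** The correlation matrix is Spearman (average ranks,
computed as rank-then-Pearson); constant samples give NaN pairs with a
warning and are excluded from medians — they will fail the
detected-gene criterion anyway. The correlation input layer is log2
TMM-CPM on all genes by default (configurable to TPM; which layer the
metric is "supposed" to use is genuinely underdetermined, and the
rank correlation makes the choice mild). Flagging uses strict
inequalities — a sample exactly at a cutoff passes, reading the
criteria as "smaller than"/"less than". Batch propagation appends a
dedicated reason code so original failure causes stay visible.

**Replicate statistics.** MAD over a group of more than two replicates
is the maximum pairwise absolute difference (= max − min). The TPM > 4
expression filter requires the gene to pass in *all* replicates of the
group (conservative; configurable to *any*). Substitution categories
collapse to pyrimidine reference (G>A ≡ C>T). Variant keys are exact
(chrom, 1-based pos, ref, alt) tuples; inputs are assumed normalized.
The default lfc grid is {0.5, 1, 1.5, 2}.

**Loess.** Locally weighted polynomial regression, degree 2, tricube
weights over the `ceil(span·n)` nearest neighbors, evaluated on an even
grid of ≥ 100 points; exact for polynomials of degree ≤ 2;
rank-deficient local fits (too few distinct x) fall back to lower
degree, then to a weighted mean. Default span 0.75. No installed Python
package provides degree-2 loess (statsmodels lowess is degree 1), so it
is implemented here.

**Knee finding.** "Inflection point" is operationalized as the grid
point maximizing the absolute second difference of the smoothed curve —
where the curve bends hardest. For a knee-shaped (hinge-like) curve
this is the knee; for a smooth logistic it is a curvature shoulder, not
the center. A numerically straight line (max |Δ²y| ≤ 1e−8 of the y
range) raises a no-inflection error. Because the choice of a cutoff
"near the knee" is ultimately a judgement call, the derivation
accepts an explicit override.

**Saturation.** The plateau is the maximum of the loess fit; the depth
cutoff is the smallest grid x whose fit reaches `fraction` of the
plateau. Default fraction 0.85 with the resulting (25M reads, 11,400
genes) pairing; 0.80 (giving ≈20M / 10,400) is supported via the same
parameter, since both conventions appear in practice. The saturation
fit uses a tighter default span (0.5) because an exponential-saturation
curve bends sharply at low depth and a wide window underfits the knee
region.

**Local failure rate.** Quantile windows (equal occupancy) rather than
equal width, to stabilize rates in sparse tails; tied windows merge
with a warning. The occupancy-weighted mean of window rates equals the
overall failure rate exactly, by construction.

**CART.** Exhaustive split search over midpoints of consecutive
distinct sorted feature values; left branch takes `value < threshold`;
ties break toward the earlier feature and the smallest threshold (for
reproducibility). Impurity is Gini. Pruning removes any split whose
size-weighted impurity improvement (relative to the root sample count)
is below `cp ×` root impurity. The cp grid is 10 log-spaced values in
[1e−4, 0.5]; cp is selected by 10-fold × 3-repeat stratified CV on
accuracy, ties resolved toward the largest cp (simplest tree). Feature
importance is the per-feature sum of weighted Gini improvements,
normalized to 1. No surrogate splits; missing feature values are an
error at prediction time.

**Logistic.** IRLS (Newton) with convergence at max coefficient change
< 1e−8 or 100 iterations; linear predictors are clipped at ±30 inside
the link for numerical stability. Complete separation (diverging or
non-finite updates) is detected, warned about, and the last stable
iterate returned.

**F score.** F1 of a designated positive class; default positive class
is PASS (exposed as a flag — the natural question for a sequencing core
is "will this sample be usable", and both orientations are one flag
away).

**Split.** Stratified 7:3 with largest-remainder allocation of the
train quota across classes, guaranteeing both classes in both sets
whenever class sizes allow; deterministic per seed.

## Problem sizes

Tests and the acceptance script run cohorts of 200 samples × 2
features for the predictor benchmarks (20 seeds), 120–250 points for
the threshold-derivation curves, and 500–2000 genes × 2–36 samples for
expression matrices. These sizes were chosen so each planted parameter
is comfortably identifiable while the whole suite runs in a few
seconds; all statistics are vectorized and scale to cohort sizes two
orders of magnitude larger.

## Known limitations

* The decision model consumes two features by default; DV50/100/200 are
  simulated and carried through metadata but excluded from the default
  model (an optional feature column at most).
* SNP confirmation assumes normalized, comparable variant keys; no
  left-alignment is performed, and RNA-editing and allele-specific
  expression are ignored (the statistic is precision, not recall).
* The knee of a smooth curve is span-dependent; derived thresholds
  should be read as "around the knee", and the override used when a
  cohort's curve is flat or multi-kneed.
* No confidence intervals on derived thresholds.
* The pipeline is single-machine, in-memory; matrices of ~60k genes ×
  thousands of samples are fine, but nothing is chunked or sparse-aware
  beyond MTX input.
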