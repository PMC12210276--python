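# Methods

This note documents the statistical procedures implemented in `chromcal`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Data model and conventions

Regions follow the BED convention on disk (0-based, half-open); genotype
positions are VCF 1-based. Genotype calls are coded by ALT allele count
(0/1/2), "/" and "|" separators are equivalent, and `./.` is missing —
excluded from every MAF and heterozygosity denominator. Event tables are in
seconds; internal sample indices are `round(t · rate)` with half-up rounding
and half-open windows on the right. All pseudoautosomal (PAR) intervals are
configuration, defaulting to hg19-like coordinates.

## Normalization

Filtering keeps a region when its CPM reaches `cpm_threshold` (default 1) in
at least `ceil(min_fraction · n_samples)` samples (default 10%; the ceiling
matters for small cohorts where 10% is not integral). Filtering is
idempotent.

TMM scaling factors are computed against a reference sample (the one whose
75th-percentile CPM is closest to the cohort mean of those percentiles — the
method's customary choice). M- and A-values are computed on regions nonzero
in both samples, the M tails are trimmed by 30% and the A tails by 5%
(rank-based), and the trimmed mean is weighted by inverse delta-method
variances. Factors are rescaled to geometric mean 1; effective library size
is `library_size · factor`. The implementation agrees with the standard
R implementation (edgeR `calcNormFactors`) to ~1e-10 on random matrices, and
that agreement is pinned by a test.

Log2 CPM uses a prior count of 0.5 (not dictated by the procedure's sources;
any small positive constant works, 0.5 is the common default).

Quantile normalization is applied within groups of samples of the same cell
type, mapping every column to the cross-sample mean of order statistics.
Tie policy: the default (`ties="order"`) breaks tied values by original row
order, so per-group distributions agree bit-for-bit — the property the rest
of the pipeline assumes. A rank-average policy (`ties="average"`) is
provided; note the two goals (tie symmetry vs. exactly identical
distributions) are mutually exclusive on count data, where low counts tie
heavily. Whether quantile normalization should act on counts or log-CPM is
underdetermined; it acts on log-CPM here, after TMM.

## Covariate ledger

Candidates (technical metrics such as FRiP deviations, insert sizes, peak
counts) are median-centered within cell type, then screened one at a time:
per region, ΔBIC = BIC(base) − BIC(base + candidate) from plain OLS fits
under a Gaussian likelihood (BIC = n·ln(RSS/n) + k·ln n, k counting
coefficients plus the variance; the variance parameter cancels in ΔBIC
except through RSS). A candidate is included when at least `min_fraction`
(default 5%) of regions have ΔBIC ≥ `delta_bic` (default 4, the conventional
"positive evidence" step); improved-minus-worse counts and a sensitivity
grid over ΔBIC ∈ {2, 4, 10} × fraction ∈ {2%, 5%} are reported alongside.

Two deliberate simplifications: the subject random intercept is absent from
ledger fits (the ledger is a screening heuristic, not the inference model),
and a candidate that is collinear with the base design is reported
(`collinear=True`, never included) rather than fitted.

Small-cohort caveat: at ~20 samples, ΔBIC ≥ 4 corresponds to a per-region
F-tail of roughly 2.5%, and region-level improvements are correlated across
regions (they share samples), so the 5%-fraction criterion admits a
pure-noise covariate in a nontrivial share of tiny simulated cohorts. At 40
samples (the scale the screen is meant for) false inclusion is rare; the
test suite quantifies this (49–50 of 50 seeds correct).

## Differential testing

The base design is a cell-means coding of cell type × diagnosis (four
indicators, no intercept) plus a sex indicator; the contrast of interest is
case − control within one cell type. Fitting is generalized least squares
per region with three variance components estimated from the data:

- **Observation weights.** A lowess curve (span 0.5) of √(residual SD)
  against mean log2 abundance, evaluated at fitted values; weights are
  trend⁻⁴, floored at a small positive value. On homoscedastic data the
  weights are flat; on count-like data they increase with abundance.
- **Sample weights.** Inverse mean squared standardized residual per sample,
  rescaled to geometric mean 1 — a simplified array-quality weight that
  sends the noisiest library to the smallest weight.
- **Block correlation.** Residuals standardized per region; the mean pairwise
  within-subject product estimates the intra-subject correlation per region,
  combined by the median on the atanh scale. The fit then uses an
  exchangeable within-subject correlation shared by all regions. This is the
  standard practical reading of a subject random intercept inside a weighted
  least-squares framework; a true per-region mixed model is out of scope.

Residual variances are moderated: the prior (d₀, s₀²) is estimated by method
of moments on log variances (digamma/trigamma matching of a scaled-F model);
posterior variances are the usual weighted combination, t statistics use
df = residual + prior df. Setting `prior_df=0` recovers ordinary t
statistics exactly (tested against hand OLS to 1e-9); `prior_df=inf` forces
complete shrinkage. FDR control is Benjamini–Hochberg.

On a 2,000-region global-null simulation the fraction of regions with
p < 0.05 is within [0.04, 0.06], pinned by a test.

## Validation of the differential set

**Permutation.** Diagnosis labels are permuted at the subject level (both of
a subject's libraries flip together), the full pipeline — weights, block
correlation, fit — is rerun per permutation with identical settings, and the
count of regions significant at the stated FDR is recorded (default 100
permutations). The report carries two empirical p-values: the add-one
`(1 + #{perm ≥ obs}) / (n + 1)` convention, and a tie-randomized version
`(#{perm > obs} + U·(1 + #{perm = obs})) / (n + 1)` with U ~ Uniform(0,1).
The latter is exactly uniform under exchangeability even when most permuted
counts tie (the typical situation at a stringent FDR under the null, where
observed and permuted counts are all zero) and is the right quantity for
calibration checks; the former is never smaller and is the conventional
summary. Permutations that make sex collinear with diagnosis (possible in
tiny cohorts) are redrawn. A one-sample KS distance of the observed p-values
against Uniform(0,1) accompanies the report: valid null p-values should be
uniform, which is how "well-behaved p-value rankings" is operationalized
here.

**Classifier check.** Six classifier families (Gaussian naive Bayes, random
forest, k-nearest neighbors, logistic regression, linear-kernel SVM,
polynomial-kernel SVM) predict case/control status by repeated stratified
5-fold cross-validation (10 repeats) on (a) the differential-region feature
matrix and (b) ten equally sized random region draws; the report gives each
classifier's accuracy and the differential-minus-random delta. The
differential regions are selected on the full data before the CV loop — by
design, mirroring the validation protocol — and the report says so
explicitly: the absolute accuracies are optimistic, only the delta against
random sets is meaningful.

## Sample QC

Genetic sex combines three metrics by majority vote: chrX non-PAR
heterozygosity (MAF ≥ 5%; high → female, and high rates in annotated males
indicate contamination), summed CPM over female-marker regions (peaks near
genes such as XIST/FIRRE; high → female), and summed CPM over non-PAR chrY
regions (high → male). No numeric cutoffs are inherited from the source
procedure, so each metric is binarized at a data-driven exact two-means
split of the cohort values (overridable); a metric that does not separate
abstains, and unresolved samples are `ambiguous` rather than guessed.
Disagreement with annotated sex raises a mismatch flag (an exclusion
candidate, not an automatic exclusion).

Sample identity uses the fraction of concordant genotype calls over variants
with MAF ≥ 25%, restricted to calls nonmissing in both samples. Kinship
coefficients are deliberately not reimplemented; the concordance fraction
alone separates same-subject pairs (~1.0) from unrelated pairs (near the
HWE random-match expectation). PBC (non-redundant / uniquely mapped reads)
and FRiP (reads in peaks / total) are direct ratios with validated
preconditions.

## Peri-event statistics

Occupancy intervals closer than 2 s are merged transitively into bouts;
bout entries are the events. The per-cell statistic averages, over events,
the difference between the post-entry window mean ((1, 3) s) and the
pre-entry window mean ((−3, −1) s — the mirror image of the post window; the
source procedure states only "before and after"). The null applies one
uniform circular offset to all event times per shuffle, preserving
inter-event structure and the trace's autocorrelation (the trace itself is
never touched). Within the null, windows wrap modulo the recording length so
every shuffle keeps all events; observed statistics use the same convention
(identical for in-bounds events), which keeps observed and null
exchangeable — the property behind the calibration target. Bootstrap
probabilities use the add-one mid-tie convention (see README); labels are
up (p < α/2), down (p > 1 − α/2), else non, with α = 0.05 and 1000 shuffles
by default.

Mean in-zone activity, in-zone pairwise Pearson synchrony (zero-variance
cells are reported and masked as undefined), and the paired pre/post change
(sessions z-scored independently, per-registered-neuron difference of
in-zone means) complete the module. Whether per-event baselines should be
subtracted before averaging is undetermined in the source; raw window means
are used.

## Gene-set statistics

Overlap of two gene lists over a universe is the 2×2 cross-product odds
ratio ad/bc (infinite when bc = 0 and ad > 0; no Haldane correction) with a
two-sided Fisher exact p. "Rescue": a stress DEG (q < 0.1) counts as rescued
when the intervention contrast shows an opposite-sign effect significant at
the same FDR; a sign-only mode is exposed because the stricter reading is
an interpretation, not a stated rule. Jaccard pruning iteratively removes
the smaller member of the most-similar pair with J ≥ 0.5 until no pair
reaches the threshold; ties on size drop the lexicographically later name,
making the procedure deterministic and idempotent.

## Synthetic data

The ATAC simulator draws counts NB(mean, dispersion) with
mean = library_size × region_weight × 2^(design effects): log-normal region
weights (σ = 1.5, normalized to sum 1), libraries uniform in a configurable
range, paired libraries (one per cell type) per subject, a planted
case/control log2 effect in one cell type on ⌊frac · n_regions⌋ regions
(half up, half down), per-sample Gaussian covariates acting on random region
subsets, female-marker regions depleted ~10× in males and chrY regions
~100× in females. Dispersion is constant across regions (0.1 by default —
a typical bulk-ATAC scale) — rich enough for the filter/normalization/
differential tests, though real data show abundance-dependent dispersion,
GC/length biases and batch structure that are not emulated; passing tests
demonstrate correctness of the machinery, not performance on real cohorts.
No subject random intercept is planted by default, so the consensus
correlation on simulated data is near zero unless tests plant one directly.

The genotype simulator covers autosomal, chrX (PAR and non-PAR) and chrY
variants with MAF ~ U(0.05, 0.5) (so downstream MAF filters retain variants),
HWE sampling, male hemizygosity coded as homozygous diploid calls, 1%
missingness, and duplicate pairs copied with a 0.2% flip rate. The calcium
simulator produces stationary AR(1) noise with unit marginal SD (so
`transient_amplitude` is in noise-SD units) and exponentially decaying
event transients (τ = 1.5 s) at events spaced > 6 s — wider than the whole
peri-event window, so windows never overlap. Gene-set simulation solves
|A∩B| = round(J(|A|+|B|)/(1+J)) per constrained pair and rejects infeasible
profiles.

## Numerical choices and degenerate inputs

RSS is floored at 1e-12 in BIC computations (perfect fits); lowess trends
and weights are floored at small positive values; variances in weight
estimation at 1e-12. Empty filters, all-zero samples, constant traces,
zero-variance cells, rank-deficient designs, missing samples and malformed
events each raise a named `ValidationError` rather than propagating NaNs.
Every simulator and every pipeline run is bit-reproducible given its seed;
per-cell shuffle streams are spawned from a single seed sequence.

## Problem sizes in the test suite

The suite runs at desk scale by design: cohorts of 8–21 subjects (16–42
libraries), 120–2,000 regions, 50-seed replicate loops for the ledger and
permutation-calibration properties, 400 cells × 1000 shuffles for classifier
calibration. These sizes give the properties under test comfortable
statistical resolution (e.g. binomial CIs of ±0.01–0.02 on calibration
fractions) while keeping the full suite around a minute.
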