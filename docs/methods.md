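# Methods

## Arm-level CNA quantification

A sample's segmentation (chromosome, start, end, probe count, mean
log-intensity per segment) is reduced to per-arm alteration fractions on a
fixed grid: points every 30,000 bp from the arm start (the final partial
interval gets no point beyond the arm end), each point classified from the
covering segment's mean intensity — lost below −0.1, gained above 0.15,
neutral otherwise. Points not covered by any segment are neutral and stay
in the denominator: absence of a segment is absence of evidence for
alteration, and a constant denominator keeps fractions comparable across
samples. Disjoint altered runs all contribute ("nonconsecutive" summing),
so a fragmented arm scores the same total fraction as one contiguous event
of equal extent.

Coordinates are 0-based half-open internally; SEG input is treated as
1-based inclusive and converted on read. Within a sample and chromosome,
overlapping segments are repaired by truncating the earlier segment at the
later one's start (deterministic repair beats rejection for what should be
disjoint segmentation output), and segments straddling the centromere are
split at arm boundaries, with probe counts apportioned by overlap length.
Sex chromosomes and the p-arms of the acrocentric chromosomes (13p, 14p,
15p, 21p, 22p) are excluded, leaving 39 autosomal arms and 78
(arm, direction) features.

The intensity cutoffs (−0.1 / +0.15) are the conventional values for
log-ratio segment means; `intensity_sensitivity` re-runs the whole
threshold sweep on 0.05-spaced cutoff grids and flags any pair that
improves a feature's maximum AUC by more than a configurable margin
(default 0.02).

## Survival statistics

**Cox models** are fit by Newton–Raphson on the partial likelihood with
Efron tie handling (Breslow is available, and is what the coordinate-
descent penalized fits use). Convergence requires max |score| < 1e−9
within 50 iterations, with step-halving; monotone-likelihood separation
(|β| > 15) is flagged non-converged rather than raised, since downstream
sweeps must tolerate degenerate thresholds. Standard errors come from the
inverse observed information. The implementation agrees with
statsmodels' PHReg to ~1e−6 on censored data with ties and is checked in
the tests against a brute-force maximizer of the explicit partial
likelihood.

**Time-dependent ROC AUC** uses the Kaplan–Meier cumulative/dynamic
estimator (non-nearest-neighbor variant): cases are samples with an
observed event by the 5-year horizon, controls are samples observed beyond
it, and for each marker cutpoint c

    sens(c) = [1 − S_{X>c}(t*)] · P(X>c) / [1 − S(t*)]
    spec(c) = S_{X≤c}(t*) · P(X≤c) / S(t*)

with subgroup and overall survival estimated by Kaplan–Meier (events
precede censorings at tied times). The AUC integrates the (FPR, TPR) path
over all unique cutpoints by trapezoid, so tied marker comparisons
contribute 1/2. Sensitivity and specificity are clipped to [0, 1] — the
naive KM variant is not guaranteed monotone under censoring, which also
means the estimator is not exactly symmetric under marker negation; this
is a known property of the variant, not an implementation artifact. In the
no-censoring limit with the horizon inside the observation span, the
estimator equals the empirical Mann–Whitney concordance exactly, which the
acceptance suite verifies to 1e−10. Samples censored before the horizon
enter only through the KM estimates; nothing is imputed. An AUC whose
marker has an empty class is undefined (flagged), never set to 0.5 — that
would deflate the SD criterion below.

For the sweep's binary markers a vectorized closed form evaluates all 99
thresholds of a feature in one pass (the ROC has a single interior point),
which is what makes the permutation null affordable.

## The size-threshold sweep

For each feature and threshold T ∈ {1, …, 99}% (step configurable), the
binary call 1{100·f ≥ T} — the comparison is ≥, a fraction exactly at
threshold counts as present — is scored by td-AUC per endpoint. Thresholds
where either call class is empty are undefined and excluded from the
maximum and the SD. The optimal threshold is the argmax with ties broken
toward the smallest threshold (more sensitive, and deterministic). The SD
of the curve is the sample standard deviation (ddof = 1) over defined
thresholds, per endpoint. A feature is size-dependent when, for at least
one endpoint, max AUC ≥ 0.60, SD ≥ 0.01 and prevalence at the optimal
threshold ≥ 2.5% — all three comparisons inclusive. Criteria are evaluated
per endpoint and OR-combined.

The SD cutoff's false-discovery rate is estimated by scrambling the
sample↔fraction pairing within each feature — permutation without
replacement or bootstrap with replacement, preserving each arm's
background fraction distribution — re-running the sweep, and pooling the
(replicate × feature) SDs. The reported "FDR" is the null-tail proportion
at the cutoff, i.e. a per-test false-positive rate used as an FDR proxy;
the output labels it as such. The calibration check uses 100 replicates
(the full protocol uses 500) to stay within desktop runtimes.

The composite sweep refits a multivariable Cox model on all member calls
at each uniform threshold and reports the linear predictor's td-AUC,
marking thresholds undefined where the fit fails or every call is
constant.

## Focal windows

Arms are tiled with 200 kb bins (last bin short). A bin's intensity is the
weighted mean of overlapping segment means with weight = overlap length ×
segment probe density — the estimated probe count inside the overlap,
which honors both stated weighting factors with one formula. Bins with no
overlap are missing: they count as unaltered for pileup proportions (a
cohort-level statement) but are excluded from AUC medians (which need
defined markers). Bin calls use the same intensity cutoffs as arm calling;
loss and gain are independent tracks. Focal prognostic regions are maximal
runs of contiguous defined bins whose AUC is at least 0.04 above the
median of that arm's defined bin AUCs — the reference is the median of the
per-bin AUC track (not the whole-arm CNA's AUC), which makes the criterion
self-contained per track and invariant to adding a constant to the
profile; an undefined bin breaks a run, and arms with fewer than 3 defined
bins are skipped.

## Co-occurrence, burden and clustering

Pair (order-2; triplets on request) indicators are products of member
calls at their optimal thresholds; a tuple must contain at least one
size-dependent CNA and appear in ≥ 2.5% of the cohort (the same prevalence
floor as the single-feature criterion). Selection uses coordinate-descent
elastic-net Cox regression (scikit-survival's Coxnet, Breslow ties) with
the mixing grid α ∈ {0.05, …, 0.95, 1.0}, a per-α regularization path fit
on the full data, and 10-fold cross-validation with event-stratified,
seeded folds scored by Harrell's c-index. The selected model is the
sparsest (fewest nonzero coefficients, then heaviest penalty) whose mean
cross-validated c-index is within one standard error of the best.

The burden-adjusted pair model is a bivariate Cox fit on (pair, burden)
with Wald p-values; constant burden falls back to the univariate model
with a warning, and exact pair/burden collinearity is an error.

CNA clustering groups features by their prevalence-by-burden profiles:
burden bins are the integer burden values top-coded at the 95th
percentile, the feature × bin prevalence matrix is clustered with Ward
agglomerative clustering, and the number of clusters (2–6) maximizes the
k-means silhouette.

Burden partitioning is a 1-D survival tree: candidate splits are the
unique burden values, the split maximizing the two-sample log-rank
statistic is taken, and recursion stops at min-leaf 20, depth 3, or when
the best split's log-rank p — Bonferroni-corrected for the number of
candidate cutpoints, since the statistic is a maximum — is ≥ 0.05. Without
the correction the null no-split behavior the tree is supposed to have
would be lost to selection bias.

## Boosted risk score

The booster is linear steepest-ascent boosting of the Cox partial
likelihood: each round evaluates the score-space gradient g (Breslow
baseline) at the current additive score and adds rate · Xᵀg to the
coefficient vector; with rate 1 and one round this is exactly one gradient
step from zero, which the tests pin against a hand-coded oracle. Defaults:
rate 0.009, 2 rounds. The configuration this mirrors names a linear
booster with a tree depth, which is vacuous for a linear learner; depth is
therefore ignored and the model card records the booster as linear. Scores
are cut at the training distribution's 25th and 50th percentiles
(linear-interpolation percentiles; a score exactly at a cutpoint goes to
the upper group) into low/intermediate/high risk groups, and the cutpoints
are frozen from training for application to new samples.

## Synthetic cohorts

The generator emulates SEG-style tumor profiles with two endpoints
(recurrence-type and overall survival). Per sample and (arm, direction),
an alteration occurs with a configurable probability (default 0.10); it is
broad with probability 0.5 — covering a Beta(1, 2)-distributed fraction of
the arm, anchored at the telomeric end, reflecting that partial-arm events
outnumber whole-arm ones and that distal losses dominate — otherwise focal
with width uniform on 0.2–5 Mb at a uniform position. Intensities are
Gaussian: loss −0.45 ± 0.10, gain +0.30 ± 0.10, neutral 0 ± 0.05; probe
counts follow 3 probes / 10 kb. Losses take precedence where a drawn gain
overlaps a drawn loss. Survival times are Weibull proportional hazards
(shape 1.2; scale 12 y recurrence, 18 y OS) with uniform censoring on
[0, 12] y — roughly 30% 5-year baseline event probability and a censoring
fraction near 55%, in the range of retrospective tumor cohorts. The linear
predictor sums planted arm effects (active iff the true altered fraction
reaches the activation fraction, default 0.25), focal-locus effects, pair
interactions (both members active) and burden terms (linear and/or a step
at a burden threshold). True burden counts events at the activation scale,
mirroring how the pipeline counts calls. Everything is reproducible from
one seed, and the truth ledger records fractions, active indicators and
linear predictors per sample.

What the generator does **not** emulate: probe-level noise and uneven
probe spacing, copy-neutral LOH, whole-genome doubling, subclonality,
correlated co-alteration structure beyond planted pairs, and non-uniform
censoring. Passing recovery tests therefore demonstrate that the
statistical machinery identifies the planted signal classes under
idealized segmentations, not that any specific cohort's biology is
captured.

## Validation experiments and problem sizes

The acceptance suite and `scripts/acceptance.py` run planted-truth
experiments at the package's validation sizes: 400-sample cohorts for
threshold recovery (20 replicates; the script uses 10), FDR calibration
(78 features, 100 permutation replicates), focal localization (10
replicates on a compact 8-arm genome) and pair selection (lasso, 10-fold
CV, 20/10 replicates); 500 samples for burden partitioning; 300 for the
end-to-end run. The threshold-recovery background deliberately places
appreciable alteration mass below the activation fraction — without
sub-activation events, all thresholds below the activation yield identical
calls and the optimum is unidentifiable there.

## Known limitations

- The KM-based td-ROC variant can produce locally non-monotone ROC paths
  under heavy censoring; values are clipped but not isotonized.
- The FDR construction is a per-test null tail proportion, not a
  Benjamini–Hochberg-style procedure.
- The focal criterion is the automated rule only; pileup tracks are
  emitted for the manual inspection such analyses typically add.
- The burden tree splits on a single variable; no surrogate splits or
  pruning beyond the corrected log-rank stop.
- Arm coordinates bundled for simulation are approximate (rounded hg38
  boundaries); real analyses should load a cytoBand file.
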