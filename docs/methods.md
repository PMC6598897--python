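# Methods

## The two-stage procedure

Stage 1 models the continuous marker panel; stage 2 classifies diagnoses
from the (observed or forecast) panel.  The split reflects a modelling
stance: continuous markers are stochastic longitudinal processes worth a
generative model, while diagnosis is treated as a deterministic — if
noisy — categorization of the clinical presentation, best estimated by a
flexible classifier.

### Percentile transform

All markers are mapped to a common [0, 1] scale by a weighted empirical
CDF fitted on training data only (fitting on pooled data would leak test
information; the cost is a small train/test distribution mismatch).  Each
training observation is weighted by the inverse proportion of its
diagnosis category among that marker's observations, so that rare disease
stages shape the reference distribution as strongly as common ones.  The
category attached to an observation is the diagnosis at the same visit
(falling back to the most recent prior record); weighting by baseline
diagnosis instead is available behind a flag.  Conventions: the forward
map is the right-continuous "proportion ≤ value" ECDF; values are clamped
to [ε, 1−ε] with ε = 1/(2n) so downstream models never see exact 0/1; the
inverse interpolates linearly between reference order statistics; ties
collapse to one step with summed weight.  Both directions share one knot
set, making the round trip exact on every distinct training value — a
property the test suite checks exhaustively.

### Stage-1 families

On the percentile scale, subject i, marker k, time t (years from
baseline):

* **IMM** — per-marker linear mixed models with correlated random
  intercept and slope (2×2 covariance per marker), no cross-marker
  correlation; fitted independently per marker.
* **JMM** — one 2p-dimensional random-effect vector per subject with
  unstructured covariance D = VΩV, Ω = LL′; the cross-marker correlations
  are the model's point.
* **LTJMM** — adds γ_k(t + δ_i) with γ_k > 0 and δ_i ~ N(0, σ_δ²): a
  subject-level shift along "long-term disease time".  Here the per-marker
  random-effect blocks are *independent across markers* and the shared δ_i
  carries the cross-marker correlation.  This is not an arbitrary
  restriction: with a fully unstructured D the shift contributes a rank-1
  intercept covariance σ_δ²γγ′ that D absorbs exactly, leaving σ_δ
  identified only by its prior.  Simulation confirms both halves: under
  the block constraint the generating σ_δ = 0.5 is recovered to ±0.05 at
  n = 150, while under a free D the σ_δ posterior simply drifts.  Baseline
  diagnosis is excluded from the LTJMM covariates (the shift already
  encodes disease stage, and conditioning on baseline diagnosis would make
  it uninterpretable); it is included for IMM and JMM.

Remaining LTJMM caveats we accept and document rather than patch: γ_k·t is
confounded with the mean of the random slopes, and γ_k·δ_i with the
intercepts, so individual δ_i are weakly identified even when σ_δ is well
identified; a sum-to-zero constraint on δ is deliberately not imposed to
keep the model as declared.

### Priors and sampling

β ~ N(0, 10²); half-Cauchy(0, 2.5) on every scale (diagonal of V, σ_k,
γ_k, σ_δ); LKJ(η = 1) on L, i.e. uniform over correlation matrices (the
shape parameter is not otherwise pinned down; η = 1 is the least
informative choice).  Random effects are stored standardized,
α = V·L·z with z ~ N(0, I).

No probabilistic-programming backend is used; the sampler is a blocked
Gibbs scheme written directly for this likelihood:

* β_k, random effects u_i, and δ_i have exact Gaussian conditionals
  (the per-subject precision assembles from per-marker 2×2 blocks plus
  D⁻¹; a batched Cholesky over subjects keeps iterations cheap).
* σ_k, diag(V), γ_k, σ_δ are updated by componentwise random-walk
  Metropolis on the log scale; L by componentwise Metropolis on
  tanh-transformed canonical partial correlations (the LTJMM block
  constraint is imposed by freeing only the within-marker entries).
  Proposal scales adapt toward 0.44 acceptance during warmup only, so the
  retained chain is a valid Markov chain.

Defaults: 5000 iterations per chain, 2500 warmup, 2 chains, thinning 5 →
1000 retained draws.  A reduced preset (`ci_profile`: 500/250/1/1, 250
draws) is used throughout the test suite; on a 150-subject, 4-marker,
6-visit cohort a JMM fit takes a few seconds and recovers β and diag(V) to
within ±0.05 and an intercept correlation of 0.8 to within ±0.05.
Convergence is summarized by split-R̂ over all β and σ draws; a fit whose
maximum exceeds 1.05 completes but is flagged with a warning (short test
chains trip this routinely; the recovery checks are the operative
guarantee there).

### Prediction, information criteria, averaging

Trajectory forecasts evaluate the subject-specific posterior mean per draw
on the percentile scale, back-transform each draw, and summarize with the
pointwise mean and central 95% interval (the credible level is a
parameter; intervals are mean-trajectory by default, with residual noise
behind a flag).  Because the inverse percentile transform is nonlinear,
linear percentile-scale trajectories are sensibly nonlinear on raw scales.
Back-transformed draws are clipped into [0, 1] before inversion.

WAIC is −2(lppd − p_waic) with p_waic the summed posterior variance of the
pointwise log-likelihood (1/(S−1) convention); LOOIC uses PSIS-smoothed
importance sampling (via arviz) with Pareto-k diagnostics.  Exact
posterior model probabilities would need marginal likelihoods that are
intractable here, so model weights default to pseudo-BMA — a softmax over
total PSIS-LOO elpd — with stacking and equal weights as alternatives.
The model-averaged predictive is the weight-proportional mixture of the
per-model draw sets; its mean is the weighted mean and its intervals are
weighted quantiles over pooled draws, so degenerate weights reproduce a
single model bit for bit.

### Stage 2

Feature rows are one per (subject, time): the marker panel (observed for
training, stage-1 posterior means for forecasting), years from baseline,
age supplied time-varying as baseline age + time, sex, APOE e4, education,
marital status, and baseline diagnosis (included by default; a
reduced feature set without it is a config flag, since either choice is
defensible).  Incomplete rows are completed by a MissForest-style
iterative imputer written on scikit-learn forests: initialize missing
cells at column means/modes, revisit variables in increasing-missingness
order fitting a random forest of each on the rest, stop when the change
statistic first increases, return the last-improving completion; observed
cells are never altered.  The imputer fitted on training rows is frozen
and reused at prediction time.

The classifier is a scikit-learn random forest: 100 trees, bootstrap per
tree, √(feature count) candidate features per split, out-of-bag error from
out-of-bootstrap votes, mean-decrease-in-Gini importances (one-hot encoded
categoricals are summed back to their parent feature).  Vote ties break
toward the less severe class (CN < MCI < Dementia), a conservative and
deterministic rule.

Amyloid utilities: elevated iff PET SUVR > 1.10 or CSF Aβ42 < 909.6 pg/ml
(strict inequalities; either modality suffices when both are present).
`derive_csf_cutoff` reproduces the quantile-matching construction of such
a CSF threshold: the sample value whose "fraction below" best matches the
SUVR-positive fraction, ties toward the lower quantile.

### Metrics

MAE and WES for continuous forecasts (WES weights each absolute residual
by the inverse credible-interval width — models are held to their own
claimed precision); confusion matrices with per-class error, overall
error, row percentages; one-vs-rest balanced class accuracy, its
unweighted mean over classes, and a data-weighted aggregate over time
points.  The TN/FP bookkeeping follows the one-vs-rest reduction of the
multiclass confusion matrix — the displayed BCA formula, not the looser
prose gloss sometimes attached to it.  Report rounding is 3 decimals for
error rates and 2 for percentages; internal values are never rounded.

## Synthetic cohorts

The generator emulates the *structure* of a multi-cohort AD observational
study, not any real cohort's marginals: 12 default markers (8
cognitive/functional, 4 imaging), visits at 0, 0.5, 1, 1.5, 2, 3, 4, 5
years, ~200 subjects by default.  Covariates: age ~ N(73.5, 7²) clipped to
[55, 92]; 44.9% female; 46% APOE e4 carriers; education ~ N(16, 2.6²);
marital status (married 75%, widowed 10%, divorced 10%, never 5%).
Trajectories are simulated natively on the percentile scale from the same
families stage 1 fits — so parameter recovery is directly checkable — and
mapped outward through monotone per-marker affine links with plausible
ranges and directions (e.g. MMSE decreasing 30→0, ventricles increasing).
Default truth: intercepts 0.05–0.15 plus small age/sex/APOE effects (age
0.004/year), random-effect SDs 0.15 (intercepts) and 0.05 (slopes),
one-factor correlation (0.6 among intercepts, 0.4 among slopes) for JMM,
residual SD 0.07.  For LTJMM cohorts γ_k defaults to 0.2/year: the
latent-shift signal scales with γ·σ_δ, and a slope that small relative to
the intercept SD would make the shift decorative rather than testable.
Mean time trends are zero under IMM/JMM (random slopes have mean zero, as
in the fitted model); progression enters through slope heterogeneity and,
for LTJMM, through γ.

Per-visit diagnoses threshold the anchor marker (CDRSB) percentile at
(1/3, 2/3) — noiseless by default, so labels are a deterministic function
of the latent state.  Missingness: per-observation MCAR at 10% plus
monotone attrition with exponential dropout times at annual hazard 0.12;
baseline visits are never dropped.  Everything is reproducible bitwise
from one seed.

What passing tests on these cohorts show: the samplers, transforms,
splits, imputation and metrics are correct, and each family recovers its
own generating process.  What they do not show: performance on real
cohort data, whose missingness is informative, whose diagnoses are noisy
human judgements, and whose marker distributions are nothing like affine
images of a percentile process.

## Numerical choices and degenerate inputs

* Forecast percentile draws are clipped to [0, 1] before back-transform.
* WES refuses non-positive interval widths; the pipeline floors widths at
  1e-9 before scoring model-averaged predictions.
* Weighted quantiles take the first draw whose cumulative weight reaches
  the target (lower order statistic on ties).
* Transforms refuse markers with fewer than two distinct training values.
* Per-time BCA reports NaN for classes absent at a time point and averages
  the defined classes; fully empty joins are errors, not silent zeros.
* Baseline = a subject's minimum observed time, not literally t = 0.
* Problem sizes in the test and acceptance runs (≤ 150 subjects, ≤ 4
  markers, reduced MCMC preset) are chosen so the whole suite exercises
  every stage in well under an hour on one core; the paper-scale preset
  remains the documented default for real fits.

## Known limitations

* Linear time trends only; no nonlinear mean structure.
* The latent-time variance is homogeneous across subjects.
* Stage 2 offers no alternative classifiers and no probability
  calibration; stage 1 credible intervals are not calibrated against
  empirical coverage.
* Pseudo-BMA weights are a surrogate for posterior model probabilities;
  with very similar models they can be unstable at small n (stacking is
  available when that matters).
* The Gibbs sampler's componentwise correlation updates mix more slowly
  than gradient-based samplers on large panels; for p ≫ 10 expect to raise
  the iteration count.
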