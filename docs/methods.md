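# Methods

This note documents the statistical models implemented in `qcscore`, the
assumptions behind them, the defaults of the synthetic cohort generator, and
the numerical choices that matter for reproducing results.

## Data model

The unit of observation is one blinded quality judgment: a rater assigns an
integer score 1–4 to one *item*, an (image, slice, contour type, cardiac
phase, segmentation method) tuple. Datasets are long-format CSV, one row per
judgment, with slice level (apical/basal/mid) and pathology carried as
stratification metadata. The (item, rater) key is unique; partial rater
coverage is represented simply by absent rows. ED/ES phase is carried but
pooled by default — the analyses treat each phase's contour as its own item,
and nothing downstream conditions on phase unless asked to.

Paired views (for signed-rank tests) keep only items scored under **both**
methods by the same rater; unpaired ratings are excluded from pairing but
retained for the agreement and regression stages, which tolerate
missingness. This matters because one emulated rater completes only ~17% of
items: dropping their unpaired data globally would discard information the
mixed model can use.

## Inter-rater agreement: Gwet's AC2

Reliability is estimated with the weighted second-order chance-corrected
agreement coefficient (formulas in the README). Design points:

* **Ordinal weights.** `w_kl = 1 − C(|k−l|+1, 2) / max`, i.e. the penalty is
  the number of category pairs an error spans, normalized so exact agreement
  has weight 1 and confusing the scale extremes weight 0. For the 4-point
  rubric the off-diagonal weights are 5/6, 1/2, 0. Identity, linear and
  quadratic families are available; identity weights reduce AC2 to the
  unweighted first-order coefficient.
* **Subjects** default to presented items, so agreement is "did the raters
  give this very contour the same score". Subjects rated by a single rater
  still inform the marginal propensities π_k but not percent agreement.
* **Uncertainty.** Variance by Gwet-style subject-level linearization
  (influence values κ*_i); confidence intervals use a Student-t quantile on
  n−1 degrees of freedom, truncated to [−1, 1]. The finite-population
  correction defaults to 0 (subjects sampled from an infinite population).
* **Benchmarking.** The normal-approximation membership probability of each
  interval of a reliability scale (default: very good (0.8,1.0],
  substantial (0.6,0.8], moderate, fair, poor) is accumulated from the best
  interval down; the label is the first with cumulative membership > 0.95.
  The outermost intervals are open-ended (±∞) so memberships sum to one;
  for any realistically precise estimate this is numerically
  indistinguishable from truncating at ±1. With `se = 0` the membership is
  a point mass in the containing interval.
* **Comparing two coefficients.** Default is the independent two-sample
  z-test on the difference (SEs combined in quadrature). A paired variant —
  empirical variance of per-subject differences of the influence values —
  is available and is the stricter choice when both coefficients are
  computed on the same subjects; the package asserts subject alignment
  before using it.

## Method comparison: random-intercept proportional odds

Scores are ordinal; the model is cumulative-logit with proportional odds
and an image-level normal random intercept. Assumptions worth stating:

* proportional odds — each covariate shifts all three cumulative log-odds
  equally; `exp(β)` is then a single odds ratio of a better score;
* a single random intercept per image — ratings of the same image are
  exchangeable given the image effect (no extra slice- or rater-level random
  effects: rater is a fixed effect);
* missing ratings are missing at random given the modelled covariates.

**Estimation.** Maximum likelihood with the intercept integrated out by
adaptive Gauss–Hermite quadrature (15 nodes by default). Each group's
integrand is recentred at its conditional mode with curvature rescaling
(Newton iterations on a strictly log-concave objective), followed by one
moment-matching refinement of the centering; with dozens-to-hundreds of
ratings per image the integrand is extremely sharp and a non-adaptive rule
would be badly inaccurate, whereas the adaptive 15-node rule matches dense
numerical integration to ≈1e−9 even at σ_u = 3 on tiny groups (and 15 vs 31
nodes move the study-scale estimates by ~1e−5). Cutpoints are optimized as
(τ₁, log-gaps) and σ_u on the log scale, so ordering and positivity are
structural. The optimizer alternates freezing the quadrature grid with an
exact inner L-BFGS on an analytic gradient (warm-started from a plain
ordered-logit fit) until parameters stop moving; the reported covariance is
the inverse observed information via central finite differences of the
analytic score, delta-transformed to the natural scale.

**Inference.** Wald tests and 95% CIs for single terms (symmetric on the
log-odds scale); likelihood-ratio χ² tests for interaction blocks, with
degrees of freedom equal to the number of added dummy products. An empty
block (a factor with one observed level) gives a well-defined null test
(statistic 0, p = 1). Reference levels default to manual method, LV
epicardial contour, mid slice, healthy pathology, first rater — so subgroup
odds ratios are directionally comparable across reports.

**Degenerate inputs.** Rank-deficient designs and single-category outcomes
are rejected with diagnostics rather than fitted; datasets with fewer than
two images cannot identify the random intercept and must be fitted with
`random_intercept=None` (the pipeline falls back automatically below a
configurable image count and records the fallback in the report).

## Paired tests

Per rater, the Wilcoxon signed-rank statistic uses tie-averaged ranks of
|automated − manual|. Zero differences are dropped by default (classic
Wilcoxon); Pratt handling (rank zeros, then discard) is available because
zeros dominate a 4-point scale and the choice should be explicit and
reportable. Exact two-sided p-values enumerate the sign-flip null (as a
convolution over the doubled-rank lattice, identical to full enumeration)
for up to 25 nonzero differences; beyond that a normal approximation with
tie-corrected variance Σr²/4 and continuity correction 0.5 is used. On
untied ranks at n = 12 the approximation stays within 0.02 of the exact
p-value over the whole rejection-relevant range; with heavy ties the exact
null lattice is coarse and no continuous approximation tracks it that
closely, which is why the exact mode is the default whenever feasible.

## Synthetic cohort generator

The generator is the model's probabilistic twin: latent propensity
η = method effect + rater leniency + contour/slice/pathology effects
(+ method interactions) + u_image, scores drawn from the implied 4-category
proportional-odds distribution. Defaults emulate the structure of a
217-subject clinical scoring study:

| quantity | default | rationale |
| --- | --- | --- |
| images | 217, pathology mix DCM 33 / HTN 107 / HCM 13 / IHD 10+5 / LVNC 6 / myocarditis 1 / healthy 42 | published cohort composition (IHD split into normal/reduced EF is not published; 10/5 chosen) |
| slices × phases | 5 (1 apical, 3 mid, 1 basal) × 2 | reproduces the published total of ≈39k scores and per-contour n ≈ 6.2k at 217 images; the published mid-slice share (~81%) cannot hold simultaneously with those totals, and the totals were preferred as the more precisely printed quantity |
| raters | completion (1.0, 0.69, 1.0, 0.17), leniency (+1.0, −0.7, +0.2, −0.6) | mirrors the published per-rater pair counts and mean-score ordering; completion applies per item (a partial rater skips whole items, so pair counts scale linearly with completion) |
| method effect | 0.844 at the reference cell | the default method×factor interactions average to −0.687 over the design, putting the design-averaged automated-vs-manual log-odds at log(1.17), the overall odds ratio being emulated, with near-equal marginal means |
| interactions | contour −0.8/−1.3, slice −1.1/−0.4, pathology DCM −0.7 / HTN +0.85 (on automated) | signs and rough magnitudes of the published subgroup contrasts (epicardial and basal worse; manual contour gaps larger; automated basal drop larger) |
| σ_image | 1.0 | substantial within-image clustering, matching what the emulated analysis assumes |
| cutpoints | calibrated | see below |

**Cutpoint calibration.** Cutpoints are solved numerically so that the
*marginal* score distribution — integrating the random intercept (21-node
Gauss–Hermite) and averaging over the completion-weighted design mix — hits
(0.01, 0.02, 0.15, 0.82), i.e. P(score = 4) ≈ 0.82 and mean ≈ 3.78.
Calibrating conditional probabilities at η = 0 instead would miss these
targets once σ = 1 heterogeneity is integrated. Each cumulative target is a
monotone scalar equation solved by bracketed root-finding.

Scores are drawn by comparing one uniform variate per row against the
cumulative probabilities, so increasing any effect moves that row's score
weakly upward *pathwise* at a fixed seed — a property the tests exploit.
A `rater_threshold_scale` flag compresses/stretches a rater's cutpoints
about their mean, providing a controlled violation of proportional odds for
robustness checks.

**What the generator does not emulate:** image pixels and actual contour
geometry; rater drift or learning over a session; correlation between
neighbouring slices beyond the shared image intercept; non-proportional
rater behaviour (except behind the flag above); selection of which images
enter the study. Passing recovery tests therefore demonstrate that the
estimators are correct *under the assumed model*, not that the model
captures every feature of real rating data.

## Scoring sessions

The blinded workflow is headless: a coordinator manifest knows each
contour's source; rater-facing session files contain a seeded random
permutation of blinded item views and simply have no method field, so no
serialization path can leak the source (tests scan the bytes). State is
written atomically (temp file + rename) for crash-safe resumption; scoring
is forward-only with an explicit opt-in step-back. Merging unblinds via the
manifest and rejects conflicting duplicate scores.

## Pipeline report and problem sizes

`run_analysis` emits CSV tables only — every number is produced by one
library operation, the orchestrator computes nothing itself. Subgroup
p-values are reported raw (as in the emulated analysis); an optional Holm
adjustment column can be switched on. The acceptance script's recovery
target uses 100 replicates of the full 217-image design (~37k ratings each);
the test suite's statistical checks use 25 replicates at the same size for
recovery and 200 smaller cohorts (40 images, ~640 ratings) for null
coverage, sizes at which the Monte-Carlo error of each check is several
times smaller than the tolerance it enforces.

## Known limitations

* The proportional-odds assumption is untested within the package (no
  Brant-style diagnostics); misspecification shows up only through the
  generator's violation flag.
* The AC2 comparison p-value treats the two method subsets as independent
  in its default mode; the paired mode is provided but the two modes can
  disagree when the subsets share images.
* Wald intervals for σ_u near 0 are unreliable (boundary); the package
  reports them but interaction and method inference rests on the fixed
  effects, which are well-behaved.
* Exact Wilcoxon mode is capped at 25 nonzero differences; beyond that the
  normal approximation's accuracy depends on the tie structure (see above).
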