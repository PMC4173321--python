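# Methods

## The model

`avotraj` models heterogeneity in signaled active avoidance (AA) learning.
In the paradigm a rat is trained over `D` daily sessions of 30 tone (CS)
trials; shuttling during the tone (an avoidance response) terminates it and
omits the footshock.  Each session is summarised into three 10-trial bins,
so an animal carries `T = 3D` avoidance scores, each an integer count in
[0, 10].  Scores are stored as counts out of 10 rather than means: the
published class estimates (intercepts up to 4.15, asymptotes near 8) are on
the 0–10 scale, and the 0–10 count convention keeps every quantity on that
scale.

Learning trajectories are modelled as a finite mixture of piecewise-linear
growth curves.  With loading matrix `Λ` (`T × (1 + D)`: an intercept column
of ones, and per day `d` a slope column that steps 0, 1, 2 within the day
and is then held at 2), class `k` generates

    y_i | class k  ~  N( Λ μ_k ,  Λ_r V Λ_rᵀ + σ² I )

* `μ_k` — class growth-factor means: the intercept (expected score on the
  first 10 trials) and one slope per day (expected increment per 10-trial
  bin step within that day).  A printed "day-d slope" therefore contributes
  `2 × slope_d` to the day's total gain.
* `V` — covariance of the growth factors given subject-level (random)
  variation, shared across classes.  An empty random set is latent class
  growth analysis (LCGA, `V = 0`), used for the 3-day cohort; the 5-day
  cohort frees the intercept and day-1 slope.
* `σ²` — residual variance, shared across classes and bins (parsimony, and
  the convention of the standard growth-mixture software; class-specific
  variances are out of scope).

The within-day slope coding (0, 1, 2, then held) is the unique
nondecreasing coding under which the published class means stay within the
0–10 score range and reproduce the described convergence of the Modal and
Rapid classes near 8/10; e.g. the Rapid 5-day class implies day-1 bins
(4.15, 5.77, 7.39) and the Modal class reaches
1.39 + 2(0.43 + 2.14 + 0.70) = 7.93 by the end of day 3.

The outcome is treated as Gaussian at the bin level even though scores are
counts — deliberately reproducing the original analysis convention; the
generator's binomial mode (below) quantifies how the Gaussian fit behaves
under the true count noise.

## Estimation

Maximum likelihood by EM.  The E-step computes responsibilities
`p_ik ∝ π_k φ(y_i; Λμ_k, Σ)`.  The M-step is a generalized (ECM) sweep:

1. `π_k` = mean responsibility.
2. `μ_k` by exact weighted GLS under the current `Σ` (this maximizes the
   mixture bound over the means exactly).
3. `V` and `σ²` by one EM step on the latent random effects: with
   `C = (Λ_rᵀΛ_r/σ² + V⁻¹)⁻¹` and posterior mean `m_ik = C Λ_rᵀ (y_i −
   Λμ_k)/σ²`, update `V = Σ_ik p_ik (m_ik m_ikᵀ + C)/n` and `σ²` from the
   residuals plus the trace correction.

Every sweep is monotone in the observed log-likelihood; the implementation
asserts this on each iteration and treats a decrease beyond 1e-6 relative
as an estimation failure.  Convergence is a relative log-likelihood change
below `tol = 1e-7` (default), capped at 500 iterations.  Numerical guards:
`σ² ≥ 1e-3` (variance floor against degenerate spikes), eigenvalues of `V`
floored at 1e-6 to keep it invertible, and a warning when a mixing
proportion collapses below `0.5/n`.

Mixture likelihoods are multimodal, so `fit_multistart` runs `n_starts`
(default 50) short EM passes (30 iterations, loose tolerance) from
perturbed k-means initializations — the hard k-means partition mixed with
Dirichlet noise at a random weight per start — then refines the best
`n_final_starts` (default 5) to full convergence and keeps the best
log-likelihood, ties broken toward the lowest start index.  Agreement of
the top two refined log-likelihoods within 1e-3 is reported as the
"replicated best log-likelihood" (global-solution) diagnostic.  Classes are
canonically ordered by ascending end-of-training implied mean so that
seeded runs are reproducible and label-permutation invariant.

Standard errors of the class means come from the inverse observed
information: a central-difference numerical Hessian of the log-likelihood
over the free parameters (means; mixing-weight logits; the Cholesky of the
free block of `V`; `log σ²`), with Wald z and two-sided p-values.  For a
single flat class this reproduces `σ/√(nT)` to numerical precision.

## Class enumeration

`enumerate_classes` fits K = 1..K_max and tabulates, per K: log-likelihood,
free parameter count, AIC (`−2LL + 2p`), BIC (`−2LL + p ln n`), SSBIC
(`−2LL + p ln((n+2)/24)`), normalized entropy
(`1 − Σ −p_ik ln p_ik / (n ln K)`), the smallest class proportion, the
replicated-LL flag, and two K-vs-(K−1) tests:

* **BLRT** (primary): parametric bootstrap likelihood ratio test.  `B`
  datasets are simulated from the fitted (K−1)-class model, both models are
  refit to each with a reduced multistart budget (10 starts — a deliberate
  runtime/accuracy trade-off versus the 50-start main fits), and
  `p = (1 + #{LR* ≥ LR}) / (B + 1)`.
* **LMR-style analytic test** (secondary): `2ΔLL` referred to a chi-square
  with df equal to the parameter difference, reported both unadjusted and
  with the ad-hoc shrinkage `c = 1 + 1/(df ln n)`.  The exact weighted
  chi-square reference of the original test requires information-matrix
  eigenweights that the published material does not determine, so the
  chi-square approximation is used and clearly labelled; it carries no
  weight in retention.

Retention is an explicit codification of the usual informal reasoning
("IC reductions + LRT + parsimony"): the retained K is the largest K whose
BIC improves on K−1 by more than 6, whose BLRT rejects at α = 0.05, and
whose smallest class holds at least 5% of the sample; K = 1 otherwise.  All
three thresholds are arguments.  The rationale string records which
criterion bounded the choice.

## Phenotype labels and the acquisition rule

Acquisition of AA within a day is defined as a day-end bin score ≥ 5
(avoiding on at least 50% of the day's last 10 trials) maintained through
every subsequent day.  Applied to each fitted class's model-implied mean
trajectory this yields the label map: first acquisition on day 1 → Rapid
Avoider, days 2–3 → Modal, day ≥ 4 → Slow, never → Non-Avoider.  In the
3-day solution the Slow class never meets the criterion, colliding with
the Non class; collisions are resolved by ordering classes on (acquisition
day, then descending end-of-training mean) and assigning Rapid/Modal/
Slow/Non in that order, with a log record — the class that never acquires
but ends markedly higher is Slow, not Non.  Hard (modal) assignments come
with a warning when entropy falls below 0.6 (an operational cutoff for
"low"; configurable), since saved assignments are then unreliable.

## The synthetic cohort generator

The generator is the package's test bed: it emulates the two study designs
with the published four-class solutions as generating truth, so recovery
experiments have a known target.

* `study1_config` — n = 81, D = 3, proportions 20/21/37/22%
  (Non/Slow/Modal/Rapid) with the published intercepts and day slopes; no
  subject-level variation (pure LCGA).
* `study2_config` — n = 186, D = 5, proportions 16/9/50/25% with the
  published growth-factor means; subject-level SDs 0.8 (intercept) and 0.2
  (day-1 slope) supply the free-effect variation.  These SDs are not
  published; they are package defaults chosen to give visible but
  non-degenerate subject scatter, and are configurable.

Each animal draws a class, subject deviations, and then per-bin scores —
Binomial(10, mean/10) by default (the natural model for a count of 10
Bernoulli trials; implied means are clipped to [0, 10] first), or a
rounded, clipped Gaussian to match the fitted model's own assumptions for
calibration work.  Trial-level logs (30 Bernoulli trials per session) can
be generated instead; binning them reproduces the binomial bin law exactly.

Per-day inter-trial crossing (ITR) counts are Poisson with class-specific
day means.  Only the qualitative ordering of those means is published
(Rapid high from day 1; Non-Avoiders near zero until day 3; Modal and Slow
intermediate), so the defaults are illustrative encodings of that ordering,
not estimates.  The Poisson form itself is an assumption.  Baseline
(habituation-hour) crossings are Poisson(20) for every class — matching the
finding of no class differences at baseline.

What the generator does not emulate: within-session dynamics finer than
the three bins, escape/latency structure, autocorrelated residuals,
overdispersed ITRs, and any covariate structure.  Passing recovery tests
therefore show that the pipeline recovers the published solution under its
own assumptions plus count noise — not that real cohorts are this clean.

## Post-hoc analyses

`rm_manova` forms `days − 1` successive-difference scores per animal and
tests the within-subject time effect and the time-by-class interaction on
an effects-coded linear model, via Wilks' λ from the hypothesis and error
cross-product matrices with Rao's F approximation (exact for the
single-df time effect).  Animals missing any ITR day are dropped
(complete-case, logged).  `lsd_pairwise` runs Fisher's LSD per day with the
pooled within-group error term and uncorrected p-values;  `oneway_anova`
handles the baseline-crossings comparison.  Both tests hold their nominal
5% type-I error on class-free Poisson ITR data in the packaged calibration
checks.

## Problem sizes and numerical choices in the shipped checks

Recovery experiments use 20 seeded replicates at the study sample sizes
(n = 186 and n = 81) with 50-start fits; class enumeration uses 5 seeded
cohorts with BLRT B = 49 draws; the post-hoc calibration uses 1000 null
replicates.  Sub-seeds are derived deterministically from one master seed.
All randomness flows through `numpy.random.default_rng`.

## Known limitations

* The Gaussian trajectory likelihood ignores the count nature and
  mean-dependent variance of bin scores; recovered variance components are
  accordingly not interpretable as the generating subject-level variances
  (the class means and proportions are what recovery targets).
* The analytic LMR-style test is a labelled chi-square approximation, not
  the original weighted-chi-square reference distribution.
* With the study sample sizes, fitted mixing proportions track the realized
  class draw of the cohort at hand; across replicates they scatter around
  the generating proportions with the full multinomial sampling SD (about
  3.7 points for a 50% class at n = 186).  Seed-averaged recovery is
  correspondingly much tighter than any single cohort.
* Retention thresholds (BIC drop 6, α = 0.05, 5% minimum class) are
  conventional defaults, not optimized quantities.
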