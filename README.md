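# avotraj

Trajectory phenotyping of signaled active avoidance (AA) learning with
piecewise latent growth mixture models.

## The problem

In two-way shuttle-box AA training, a rat hears a tone (CS) that predicts a
footshock (US); shuttling to the other compartment during the tone cancels
the shock.  Cohorts trained this way are strikingly heterogeneous: some
animals avoid almost from the first trials, a modal group acquires the
response in step-like jumps over about three days, some acquire late, and
some never do.  Averaging the cohort hides all of this — the grand mean
looks like smooth, gradual learning that no individual animal shows.

`avotraj` is for behavioral neuroscientists and biostatisticians who want
to disaggregate such cohorts instead of averaging them.  It provides the
full analysis pipeline as a tested Python library:

* trial-level session logs → three 10-trial avoidance bins per day
  (integer scores 0–10);
* a four-class **piecewise growth mixture model** — per class `k`, binned
  trajectories `y_i ~ N(Λ μ_k, Λ_r V Λ_rᵀ + σ² I)` with loading matrix `Λ`
  carrying an intercept plus one linear slope per training day, optional
  random growth factors `V` (empty = LCGA), fit by multi-start EM;
* class enumeration by AIC/BIC/SSBIC, entropy, an analytic LMR-style test
  and the parametric bootstrap likelihood ratio test (BLRT), with an
  explicit retention rule;
* phenotype labels (Rapid / Modal / Slow / Non-Avoider) from the
  acquisition criterion — avoiding ≥ 50% of a day's last 10 trials,
  maintained thereafter;
* post-hoc analyses of inter-trial crossings (ITRs): repeated-measures
  MANOVA (Wilks' λ), Fisher's LSD, one-way ANOVA on baseline crossings;
* a synthetic cohort generator whose packaged configurations carry the
  published four-class solutions of a 3-day (n = 81) and a 5-day (n = 186)
  study as generating truth, so every stage is testable end to end without
  any data download.

See `docs/methods.md` for the model, estimation details and assumptions.

## Worked example

```python
import numpy as np
from avotraj import (simulate_cohort, study2_config, to_matrix,
                     PiecewiseGrowthMixture, assign_phenotypes, rm_manova)

cohort = simulate_cohort(study2_config(), seed=7)   # 186 rats x 5 days
Y, ids = to_matrix(cohort)                          # 186 x 15 bin scores

model = PiecewiseGrowthMixture(
    n_classes=4, random_factors=(0, 1), random_state=7
).fit(Y)

table = assign_phenotypes(model.fit_result_, cohort)
print("entropy:", round(model.entropy(), 3))
for label, grp in table.groupby("label"):
    k = grp["modal_class"].iloc[0]
    print(f"{label:>5}: {100 * model.proportions_[k]:4.1f}%  "
          f"intercept {model.means_[k, 0]:.2f}  "
          f"day slopes {np.round(model.means_[k, 1:], 2)}")

itr = rm_manova(cohort.itr_matrix, table["label"].to_numpy())
res = itr["time_by_group"]
print(f"time x class: Wilks lambda = {res.wilks_lambda:.2f}, "
      f"F({res.df1:.0f}, {res.df2:.1f}) = {res.F:.2f}, p = {res.p:.2g}")
```

Output:

```
entropy: 0.996
Modal: 48.6%  intercept 1.43  day slopes [0.3  2.15 0.7  0.14 0.03]
  Non: 14.5%  intercept 0.62  day slopes [ 0.03  0.41 -0.01 -0.12 -0.33]
Rapid: 27.4%  intercept 4.21  day slopes [ 1.57  0.24  0.14  0.17 -0.02]
 Slow:  9.4%  intercept 0.66  day slopes [0.53 0.22 0.3  2.23 0.74]
time x class: Wilks lambda = 0.55, F(12, 473.9) = 9.94, p = 1.8e-17
```

Reading this: the fit cleanly separates the four phenotypes (entropy 0.996,
so hard assignments are safe).  The Modal class (48.6% of the cohort; the
generating truth is 50%) starts near 1.4 avoidances per 10 trials and makes
its big gain on day 2 (slope 2.15 per bin step); Rapid Avoiders start high
(4.21) and are near asymptote within day 1; Slow Avoiders stay low until a
day-4 jump (2.23); Non-Avoiders stay flat near zero.  The recovered
intercepts and slopes sit within sampling error of the generating values
(e.g. Rapid intercept 4.21 vs 4.15 generating).  The MANOVA confirms that
ITR trajectories differ by phenotype — the time-by-class interaction the
class-linked generator builds in.

Class enumeration (how many trajectory classes does the data support?) is
one call:

```python
from avotraj import ModelSpec, build_design, enumerate_classes
report = enumerate_classes(Y, build_design(5),
                           ModelSpec(K=4, random_factors=(0, 1)),
                           K_max=5, B=49, seed=7)
print(report)   # per-K IC/entropy/LMR/BLRT table + retained K and rationale
```

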