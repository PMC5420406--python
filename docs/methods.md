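# Methods

This note documents the statistical procedures implemented in `phenocut`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic cohorts do and do not establish about real data.

## Behavioral readouts and their marginal models

Two readouts drive everything: the sucrose preference rate (a proportion
in [0, 1]; low = anhedonia-like) and forced-swim immobility time
(seconds; high = despair-like). In naive rats both are skewed, so the
package models the preference rate with a Beta(α, β) law and immobility
with a Gamma(shape k, rate λ) law.

* **Method of moments.** Beta: with sample mean m and variance v,
  c = m(1−m)/v − 1, α = mc, β = (1−m)c (infeasible when v ≥ m(1−m), which
  is reported as an error, not silently patched). Gamma: k = (m/s)²,
  λ = m/s². The Gamma shape identity is exact by construction and is
  asserted as a property.
* **Maximum likelihood** starts from the moments fit and maximizes the
  family likelihood with location (and for Beta, scale) fixed — the
  standard constrained `scipy.stats` fit.
* **Boundary handling.** Preference rates of exactly 0 or 1 occur in
  practice and make the Beta likelihood undefined; such values are nudged
  by 1e−6 into the open interval with a warning. The nudge is far below
  measurement precision of a weighed-bottle assay.
* **Fit adjudication.** "Which family fits better" is decided by AIC,
  with the Kolmogorov–Smirnov distance to the fitted law reported
  alongside; the package does not claim one criterion is canonical, it
  reports both. The Gaussian family is always available as the
  reference candidate.
* **Default parameters.** The reference naive population is emulated
  with Beta(2.53, 1.08) and Gamma(2.29, rate 0.0264). The rate deserves
  a note: the published scale value of 0.03 only makes sense as a
  rounded *rate*, because shape 2.29 equals (mean/SD)² of the published
  moments (86.76, 57.28) and mean/SD² = 0.0264 ≈ 0.03 recovers the
  published mean (2.29/0.0264 ≈ 86.7 s), whereas a scipy-style scale of
  0.03 would give a mean below 0.1 s.

## Latent profile analysis

The profile model is a K-class mixture of bivariate Gaussians with
diagonal covariance on the raw indicator scales (proportion; seconds).
Two structural choices are derived, not guessed:

* **Class-invariant variances (default).** The published fit table's
  BIC − AIC gaps equal p(ln 309 − 2) exactly for p = 3K + 1 =
  2K (means) + 2 (shared variances) + (K − 1) (weights), which pins the
  variance structure the original analysis used. Class-varying variances
  (p = 5K − 1) are available behind `variance_structure="varying"`.
* **Raw scales, no standardization.** The 1-class log-likelihood
  back-derived from the published AIC (≈ −1649.1) matches the closed-form
  Gaussian log-likelihood of the published raw-scale moments, not the
  standardized ones.

**EM.** E and M steps are the textbook diagonal-Gaussian updates with a
log-sum-exp E-step. Convergence: relative log-likelihood change < 1e−8
or 500 iterations. Variance floor 1e−8 (absolute; both indicator
variances are far above it). A class whose weight falls below 1/(10n)
aborts the start rather than continuing degenerately. Monotonicity of
the log-likelihood across iterations is asserted in tests on every
fitted path.

**Initialization.** Each restart (default 50; pipeline default 30) draws
K distinct observations as initial means with the data's column
variances and uniform weights, then proceeds from the implied
responsibilities. Soft random-responsibility starts were rejected during
design: they place every initial mean near the grand mean and routinely
lose small outlying classes (the 4% class of the emulated population is
exactly such a class). Ties between equal-likelihood starts resolve to
the lowest start index.

**Class enumeration.**

* AIC = −2logL + 2p, BIC = −2logL + p ln n, and the sample-size-adjusted
  BIC = −2logL + p ln((n+2)/24); lower is better.
* Standardized entropy E = 1 − Σᵢₖ(−p̂ᵢₖ ln p̂ᵢₖ)/(n ln K); undefined at
  K = 1.
* **LMR-adjusted LRT.** The adjusted statistic divides 2ΔlogL by
  1 + 1/(d ln n) with d = p_K − p_{K−1}. This exact form reproduces all
  four published adjusted statistics from log-likelihoods back-derived
  from the published AICs, which is how the variant was identified. The
  p-value is approximated with a chi-square on 2d degrees of freedom:
  mixture LRTs violate the regularity conditions behind the naive
  chi-square(d) reference, which is grossly anti-conservative for
  spurious class splits; doubling the degrees of freedom is the
  classical rule of thumb for component-count tests in normal mixtures
  and is, if anything, slightly conservative in the package's own
  calibration tests. The reference distribution the original software
  used is not published; treat the p-values as approximate and prefer
  the bootstrap when a decision matters.
* **Bootstrap LRT.** Parametric bootstrap of 2ΔlogL under the fitted
  (K−1)-class model, p = (1 + #{boot ≥ observed})/(B + 1), minimum
  B = 19. Failed replicates are redrawn up to a cap.
* **Selection rule.** Prefer the smallest set of classes justified by
  the tests: a K qualifies when its LMR test is significant (α = 0.05)
  and the K+1 test is not (or K is the largest fitted); among several
  qualifying K the higher entropy wins; with no significant test K = 1
  is retained. The rationale string always records where each
  information criterion attains its minimum, because the "lower is
  better" evidence can keep decreasing past the chosen K — the emulated
  study shows exactly that conflict.

## Percentile cutoffs and classification

Percentiles use the (n+1)-based weighted-average rule: h = (n+1)p,
linear interpolation between adjacent order statistics, clamped to the
extremes — the convention of the mainstream statistics packages used for
reference-limit work (`numpy`'s "weibull" method). The estimator name is
recorded in the cutoff table for provenance; alternates are selectable
for sensitivity analysis.

A low-is-pathological index gets (P5, P10) as (severe, mild) cutoffs; a
high-is-pathological index the mirrored (P95, P85). Classification is
three-level per index: strictly beyond the severe cutoff → *affected*;
strictly on the healthy side of the mild cutoff → *resilient*; the
closed interval between → *sub*. Boundary ties therefore go to the less
severe adjacent category, following the strict-inequality wording of
the operational definitions ("lower than 0.28", "higher than 0.41").
Joint *stress-resilience* is defined as resilient on both indices — the
source never defines it formally, so this conjunction is an interpretation,
documented as such. Recovery is scored per index, only for indices
non-resilient pre-treatment: recovered iff the post value is strictly
past the mild cutoff on the resilient side; otherwise
treatment-resilient.

Cutoff construction warns below a reference size of 100, where tail
percentiles are unreliable.

## Synthetic cohorts

The generators emulate the *summary structure* of the modelled study;
they are first-class, tested code, not throwaway fixtures.

* **Naive marginal cohort:** i.i.d. Beta × Gamma draws, independent
  across indices.
* **Naive mixture cohort:** the published four-class profile (weights
  44/100/153/12 of 309 — the published class-4 percentage is a typo and
  the count is used; class-wise means/SDs as published), sampled with
  truncation of the preference rate to [0, 1] and immobility to [0, ∞)
  by redraw.
* **Stressed cohorts:** for each animal and each index independently, a
  category is drawn from the published incidence, then the readout from
  a normal law with the published category-conditional moments,
  truncated to the category's cutoff interval by rejection (cap 10⁶,
  explicit failure). The rejection predicate reuses the classifier
  itself, so re-classification reproduces the sampled category with
  probability 1 — the closed loop the tests exploit. Category-conditional
  truncated normals are used rather than slicing one global law because
  the study reports per-category moments that are nearly identical
  across stress models, which this reproduces directly.
* **Treatment response:** every animal non-resilient on at least one
  index receives the antidepressant arm; each scored index recovers with
  its category's published recovery probability; post readouts are drawn
  past the mild cutoff (recovered) or inside the pre-treatment category
  interval (not recovered).
* The two indices are independent within category; no joint distribution
  was published, so the joint stress-resilience rate is an emergent
  quantity of the simulation, not a calibrated one.

What the generators do **not** emulate: within-animal correlation
between the two indices, repeated-measure dynamics across the test
weeks, litter effects, or any mechanistic stress biology. Passing tests
therefore demonstrate that the *procedures* behave correctly on data
with the published marginal and conditional structure — not that the
biological conclusions generalize.

## Contingency statistics

Every published incidence comparison is a Pearson chi-square on a
*category-vs-rest* dichotomy (groups × 2), a construction verified by
recomputation: it reproduces all ten published statistics from the
published counts to two decimals (three of the printed values are
double-rounded — e.g. 1.635 printed as 1.64 — so exact recomputation
sits within 0.006 of print). No continuity correction and no exact test
are applied by default, matching the emulated analysis even where
expected counts fall below 5; such cells trigger recorded warnings.
Pairwise group comparisons default to Bonferroni adjustment, with
`adjust="none"` available to mirror the original unadjusted reporting.
Recovery-table denominators follow the published percentages (which
equal the incidence counts, except one group's sub-despair denominator,
where the percentage implies 7).

One-way ANOVA is computed from summary statistics (n, mean, SD per
group) or raw values; the two routes agree exactly when summaries come
from the raw data, which is asserted as a property. Published F values
cannot be reproduced exactly from 2-dp rounded summaries and are not
asserted. Post-hoc comparisons use Tukey HSD.

## Pipeline

`run_pipeline` chains simulate → describe/fit → LPA → cutoffs →
classify/treat → stats, writing every intermediate artifact plus a
manifest with sha256 checksums; a fixed (config, seed) pair is
byte-reproducible. The top-level seed fans out to stage seeds via
`numpy.random.SeedSequence.spawn`. Stressed cohorts are generated and
classified against the published reference cutoffs (so incidences track
their published targets), while the percentile cutoffs *built* from the
simulated naive cohort are reported alongside as the method's output.

## Problem sizes used in the test suite

The suite exercises the stochastic claims at sizes chosen to make the
checks sharp but cheap: marginal-law means at n = 10⁴, law-of-large-
numbers class means at n = 5×10⁴, the four-class selection study at 100
replicates of n = 309 (the emulated cohort size), LMR calibration at 60
null replicates, bootstrap checks at n ≈ 200 with B = 19–39, and the
classifier closed loop at n = 10⁴ per group with a Bonferroni-adjusted
99% binomial band across the 24 incidence comparisons.

## Known limitations

* The LMR p-value reference is approximate (see above); only the
  statistic itself is exact to the published variant.
* Exact published values that depend on the unavailable raw per-animal
  data (empirical percentiles, absolute information criteria, posterior
  matrices, ANOVA F values) are approximated qualitatively by the
  generators, not reproduced.
* The percentile method itself assumes the reference cohort is drawn
  from the population of interest; no covariate adjustment is offered.
* Only the two-indicator profile model is implemented — no covariates,
  ordinal indicators, or latent-class regression.
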