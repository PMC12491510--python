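# Methods

## Model

The package implements the Hui–Walter latent class model for two binary
diagnostic tests applied to K ≥ 2 populations. Each individual in
population *k* carries a latent binary status with prevalence *P₍ₖ₎*.
Conditional on status, test *i* is positive with probability *Seᵢ* (latent
positives) or *1 − Spᵢ* (latent negatives). Two assumptions make the base
model identifiable from the K 2×2 cross-classifications: accuracies are
shared across populations, and prevalences differ between populations.
With two populations the independence model has six parameters against six
observed degrees of freedom (just identified); the dependence model below
adds two more and is identified only through the prior — its posterior is
proper but data-dominated asymmetries should not be over-interpreted.

Conditional dependence between the tests is modeled by within-class
covariance terms: among latent positives the joint cell probabilities are
`Se₁Se₂ + c₊`, `Se₁(1−Se₂) − c₊`, `(1−Se₁)Se₂ − c₊`, `(1−Se₁)(1−Se₂) + c₊`,
and analogously among negatives with `1 − Spᵢ` and `c₋`. Non-negativity of
the four cells confines each covariance to

```
max(−(1−a)(1−b), −ab)  ≤  c  ≤  min(a, b) − ab
```

with (a, b) the within-class success probabilities. The interval always
contains 0 and is invariant under complementing both margins, so the
negative-class bounds may equivalently be written on the specificities.

## Priors

Every probability parameter takes a Beta(α, β) prior; "minimally
informative" is Beta(1, 1). The covariance terms take a prior that is flat
over the feasible region jointly with the accuracies — i.e. the
unnormalized indicator of the bounds, not the width-normalized uniform.
This choice avoids a 1/width tilt in the accuracy conditionals and makes
the dependence sampler collapse exactly onto the independence sampler when
the covariances are zero.

`elicit_beta` converts a (mode, percentile) specification into shapes with
α, β ≥ 1, solving the mode relation β = 1 + (α−1)(1−m)/m and root-finding
the CDF constraint in α. Along a constant-mode family the CDF at a fixed
point is *not* monotone in α (it can dip before the distribution
concentrates), so the solver brackets sign changes on a geometric grid of
α ∈ [1, 10⁹] before Brent refinement; when a dip produces two roots the
smaller α — the less informative prior — is returned. Constraint pairs
with no root raise an error; notable infeasible requests are those asking
for more tail mass beyond the percentile value than the uniform limit
allows (e.g. an interior mode at 0.5 with the 95th percentile above 0.95).

## Samplers

**Independence model** (`gibbs_independence`): data-augmentation Gibbs.
For population *k* and observed cell *c* with count *n₍kc₎*, the latent
true-positive count is Binomial(*n₍kc₎*, *w₍kc₎*) with
*w₍kc₎ = P₍ₖ₎a₍c₎ / (P₍ₖ₎a₍c₎ + (1−P₍ₖ₎)b₍c₎)*, where *a₍c₎*, *b₍c₎* are the
within-class cell probabilities. Given the augmented counts, prevalences
and accuracies have conjugate beta full conditionals.

Plain data augmentation mixes slowly when populations are large — at
n = 5000 per population the lag-1 autocorrelation approaches 0.93 and
20,000 retained draws are worth only ~300 effective ones. Each iteration
therefore appends `n_collapsed_sweeps` (default 2) collapsed
slice-sampling sweeps: univariate slice updates (Neal's stepping-out and
shrinkage, width 0.1) of every free parameter against the observed-data
multinomial likelihood with the latent counts integrated out. Both
component kernels leave the posterior invariant, so the composition does
too; the sweeps only reduce autocorrelation (to roughly the level implied
by the posterior's parameter-parameter correlations, ~0.8 at worst here).
`n_collapsed_sweeps=0` restores the pure augmented sampler.

**Dependence model** (`mwg_dependence`): Metropolis-within-Gibbs on top of
the same augmentation. Prevalences keep their exact beta conditionals.
Accuracies are proposed from the independence-model beta conditionals and
corrected by a Metropolis–Hastings ratio against the exact augmented
within-class likelihood — the acceptance probability is exactly 1 when the
covariances are zero, so the sampler reduces to the independence kernel in
that case. The covariances are updated by a Gaussian random walk
(`proposal_sd`, default 0.05) reflected into their feasibility bounds at
the current accuracies; the flat-over-region prior cancels from the
acceptance ratio. The collapsed sweeps include the covariance terms
(slice updates inside their bounds), gated on `proposal_sd > 0` so that
the degenerate `proposal_sd = 0` configuration pins both covariances at
zero exactly. Acceptance rates are recorded and a warning fires if a
covariance acceptance rate leaves [0.1, 0.6].

**Chains and seeding.** Defaults follow the study protocol: two chains,
burn-in 5000, 10,000 retained iterations, no thinning. Chain *c* uses
`numpy.random.default_rng(seed + c)` and initializes all probability
parameters by drawing from their priors (overdispersed starts for the
Gelman–Rubin diagnostic); covariances start at 0. Identical inputs give
bit-identical draws.

**Label switching.** Latent class models are invariant under relabeling
the classes, which maps (Seᵢ, Spᵢ) → (1−Spᵢ, 1−Seᵢ), P → 1−P and swaps
c₊ ↔ c₋ (an involution that flips the sign of both Youden indices and
leaves the likelihood unchanged). When `enforce_identifiability` is on
(default), any state in which *both* tests have Se + Sp < 1 is mapped to
its mirror after each scan; the fraction of relabeled iterations is
reported. States where only one test is uninformative are left alone: the
constraint cannot decide them and the posterior mass there is negligible
in well-identified problems. The relabeling step is skipped when
accuracies are pinned via `fixed=` (the mirror would contradict the pin).

## Diagnostics and summaries

* **psrf** — the classic two-stage Gelman–Rubin statistic
  √(((n−1)/n·W + B/n)/W) without the sampling-variability df correction,
  chosen because it is hand-checkable (two identical chains give exactly
  √((n−1)/n)). Degenerate cases are fixed by definition: all draws
  identical → 1; distinct constant chains → ∞.
* **ESS** — N/(1 + 2Σρₜ) with autocovariances averaged across chains
  (each chain demeaned by its own mean) and the sum truncated by Geyer's
  initial monotone positive sequence rule on lag pairs. Constant chains
  give 0; estimates are capped at 1.5× the number of draws (mild
  antithetic super-efficiency is allowed, more is estimator noise). The
  estimator agrees with arviz's on autocorrelated test chains.
* **Summaries** — pooled-chain median (the default point estimate;
  `point="mean"` switches) and equal-tailed 2.5%/97.5% quantiles with
  linear interpolation of order statistics.
* **Model selection** — independence is retained iff both covariance 95%
  intervals contain 0, with inclusive endpoints (an interval touching 0
  counts as containing it).
* **Convergence thresholds** — psrf < 1.05 and ESS > 1000 per parameter,
  both configurable; the pipeline's exit status reflects them.

Predictive values are computed from the selected model's posterior point
estimates (matching how the study reports them), for the user-designated
test (the clinician-completed instrument by default).

## Synthetic data

`ScenarioSpec` defaults encode the study design: populations of 100
("Belgian") and 42 ("Swiss"), prevalences 0.518 and 0.817, accuracies
Se₁ 0.905 / Sp₁ 0.822 and Se₂ 0.730 / Sp₂ 0.726, zero covariances. Each
individual draws a latent status from Bernoulli(P₍ₖ₎) and a joint test
pattern from the within-class bivariate Bernoulli; OLBI total scores, when
requested, are uniform on the stratum consistent with the binary result
(45–64 for positives, 16–44 for negatives) — only the dichotomy enters the
model, so the stratum distribution is a neutral choice and is configurable
in principle by rescoring records.

What the generator does *not* emulate: item-level responses, missing data,
covariate structure, population heterogeneity in accuracies, and any
departure of real scoring distributions from uniformity within strata.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the model, not robustness of the model to real-data
violations of its assumptions.

## Test-suite design and problem sizes

Stochastic checks are sized to balance power against runtime: conjugate
and reduction checks use 2×4–5k draws; the full-protocol recovery check
runs the study's chain settings on two populations of 5000; the
covariance behaviour check uses 20 replicates of 300/300 at reduced chains
(burn-in 300, 1200 iterations) plus one strong-dependence fit at
2000/2000 (covariances at 80% of their upper bound); interval coverage
uses 50 replicates of 1000/1000 with 2000 retained draws. The near-prior
check (n = 1 per population, relabeling off) asserts a Kolmogorov–Smirnov
distance below 0.1 from the uniform prior; the measured distance for the
correct sampler is ~0.02, so the threshold separates correct from broken
implementations without flakiness. All stochastic tests are seeded.

## Known limitations

* Two tests only; random-effects (latent-trait) dependence models are out
  of scope.
* The dependence model with two populations is prior-identified; its
  covariance estimates are shrunk toward the prior and its accuracy
  estimates inherit extra uncertainty.
* The psrf variant omits the df correction; values marginally below 1 are
  possible for short, well-mixed chains.
* Predictive values are plug-in transforms of point estimates; full
  posterior distributions of PPV/NPV can be obtained by transforming the
  draws but are not part of the standard report.
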