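# Methods

## Model

For one infant-occasion, trial difference scores `d_t ∈ [−130, 130]`
(integer video-frame counts, 130 frames per trial) are modelled as i.i.d.
draws from

    u_mix(d) = π u(a, f) + (1 − π) [ λ u(a, b) + (1 − λ) u(e, f) ],
    a ≤ b < 0 < e ≤ f,   π, λ ∈ [0, 1],

where `u(α, β)` is the uniform density on the closed interval `[α, β]`.
The short component spans the whole response range; the two long bands hug
its boundaries. `x = 0` always lies in the open gap `(b, e)`, so an
exactly-even trial is structurally a short look. Zero-width components are
treated as point masses; they arise only for degenerate data. A band with
no observations on its side is dropped (`λ` pinned to 0 or 1).

Closed forms used throughout: a uniform on `[α, β]` has mean `(α + β)/2`
and second moment `(α² + αβ + β²)/3`; mixture moments are the
weight-averaged component moments with weights `π`, `(1 − π)λ`,
`(1 − π)(1 − λ)`.

## Likelihood convention for integer scores

Scores are frame counts, so each uniform component contributes a discrete
mass `1/(width + 1)` per integer point of its support. This matters: under
a continuous-density likelihood the band endpoints are scale parameters
with an unbounded profile likelihood (a band shrunk onto one or two
boundary observations has arbitrarily large density), the classic
degeneracy of location–scale mixtures. The unit-bin convention bounds the
likelihood (a point mass contributes at most mass 1) without affecting
wide components.

## Estimation

Outer endpoints are set to the observed extremes, `â = min d`,
`f̂ = max d` — the maximum-likelihood choice for uniform supports. Inner
endpoints only matter through which observations they cover, so the
distinct negative values (for `b`) and distinct positive values (for `e`)
form an exhaustive candidate grid. Two layers run over it:

**Likelihood layer (EM).** For each candidate pair, EM maximises over
`(π, λ)`: E-step responsibilities
`r_t = π u_s(d_t) / [π u_s(d_t) + (1 − π) u_long(d_t)]`, M-step
`π ← mean(r_t)` and `λ ←` long mass on the negative side over total long
mass (zero scores are ignored in the `λ` step — they carry no long
information). All trials in one region (negative band, gap, positive band)
share a responsibility, so iterations cost O(1). Convergence: relative
log-likelihood change below 1e−8 or 500 iterations. Initial values:
`π₀ = max(1/2, gap-count/T)` (observations in the open gap force `π > 0`),
`λ₀ =` the negative fraction clipped to [0.05, 0.95]. The best candidate's
log-likelihood is reported (`FitResult.loglik`) and is verified in tests
against an exhaustive `(b, e) × (π, λ)` grid search. The alternative
reading of `λ` as the raw fraction of negative responses is available as
`lam_rule="all"`.

**Posterior layer (candidate averaging).** At 24 trials the profile
likelihood over `(b, e)` is typically a plateau: candidates that disagree
about whether a handful of intermediate scores belong to a band or to the
gap fit almost equally well, yet imply `π̂` anywhere from ~0.27 to ~0.5 on
the same data. Trusting the argmax makes the estimate a near-arbitrary
function of likelihood ties; instead the reported `π̂` is the average over
trials of the per-trial posterior short-look probabilities, themselves
averaged over `(π, λ)` (flat prior, 48×48 midpoint grid) and over
candidates with flat-prior marginal-likelihood weights. The prior on
`(b, e)` is uniform over the continuous admissible rectangle
`[a, 0) × (0, f]`; each candidate's weight integrates the likelihood over
its equivalence cell in closed form (the band mass decays as a power of
the width within a cell). This is an Occam average: near-zero-width
"spike" candidates carry almost no prior mass and drop out, wide sloppy
candidates are damped by their poorer fit. `pi_hat` always equals the mean
of the reported posteriors by construction. `FitResult.model` carries the
maximum-weight candidate's bands with `pi = pi_hat` and the
posterior-mean `λ`.

**Structure selection.** Three structures compete by marginal likelihood:
short-only (`π = 1`; 2 free parameters `a, f`), long-only (`π = 0`;
feasible only when both sides are occupied and no score is zero; 5
parameters), and the full mixture (6 parameters; 4 for one-sided data).
Prior odds follow Jeffreys' simplicity postulate, `P(M) ∝ 2^(−k)` for `k`
parameters. Consequences that match the intended phenomenology: scores
drawn from a single flat uniform select short-only and return exactly
`π̂ = 1` (the long bands vanish); scores clustered entirely at the range
boundaries select long-only and return exactly `π̂ = 0`. When `π̂ = 1` the
bands are not identified; the profile-ML values are still reported with
`bands_identified = False`. Constant series short-circuit to a degenerate
`π̂ = 1` point-mass fit. Fitting refuses series with fewer than 4 trials
(6 parameters would be vacuous).

**Estimator properties (measured by the test suite).** With
well-separated narrow bands (widths ~12 frames at the range boundaries,
`λ = 1/2`, T = 24), the mean of `π̂` over 500 replicates is within ~0.01
of the truth at `π ∈ {0, 0.25, 0.5, 1}`. At `π = 0.75` the estimator is
biased upward by ≈ +0.10: the expected ~6 long looks split over two bands
carry only ~7 nats of evidence for the mixture, below the parsimony cost
that keeps the false-mixture rate on purely uniform data near 1–2%, so a
substantial fraction of replicates collapse to `π̂ = 1`. This is a genuine
small-T identifiability limit, not a tuning artifact: any estimator that
returns exactly 1 on featureless uniform data must trade power against
weak mixtures at T = 24.

**Classification.** Weak criterion: SL iff `π̂ > 1/2`, LL iff `< 1/2`,
indeterminate at exactly 1/2 (such rows are excluded from style-
conditioned analyses and counted). Strong criterion: SL iff
`π̂ ≥ 1 − 1e−6`, LL iff `≤ 1e−6` — estimates rarely hit the boundary
bit-exactly outside fully degenerate fits.

**Uncertainty.** Nonparametric bootstrap over trials (default B = 1000,
refused below 100): standard errors and 2.5/97.5 percentile intervals for
`π̂` and `d̄`.

## Diagnostics

`ecdf_vs_model` reports the two-sided KS discrepancy between the
right-continuous ECDF and the fitted CDF, evaluated at the observed points
and their left limits, with no p-value (estimated parameters invalidate
the reference distribution; the statistic is descriptive).
`cohort_variance_ratio` aggregates mean model variance over mean sample
variance per occasion. `serial_correlation_check` tests the i.i.d.
assumption via the Pearson correlation of `(d_t, t)` with a permutation
null by default (the sharp null for "order is irrelevant"); a bootstrap
null is available as an option. All resampling p-values use the add-one
convention `(k + 1)/(B + 1)`.

## Preference analyses

The cohort table has one row per infant-occasion: `π̂`, the mean score
`d̄`, the weak label, and the preference label (ORP if `d̄ < 0`, SRP if
`d̄ > 0`, none at exactly 0 — excluded from ORP/SRP counts).

* **Transitions**: `P(label₂ | label₁)` over infants seen at both
  occasions, by direct counting; zero conditioning counts yield undefined
  (NaN), never 0.
* **Conditional means**: per-cell one-sample two-sided t-tests against 0,
  suppressed for single-row or zero-variance cells (the mean is still
  reported); SL vs LL compared with Welch's unequal-variance t and
  Welch–Satterthwaite df (reported to one decimal in the CLI; a
  zero-variance group collapses the df toward the other group's `n − 1`).
* **δ-curves**: inclusive thresholds on both sides
  (`π̂ ≤ δ` and `π̂ ≥ δ`, δ = 0, 0.1, …, 1); the `≥` curve at δ = 0 and
  the `≤` curve at δ = 1 equal the unconditional mean identically. Empty
  cells are flagged, not fabricated; SEs suppressed below n = 2.
* **Independence test**: n-weighted OLS slope of each δ-curve against δ;
  the null resamples the pairing of `(π̂, d̄)` (permutation by default,
  independent bootstrap as an option) and recomputes the slope, which is a
  fixed linear functional of the per-δ means, so the null distribution is
  computed by matrix multiplication. Requires ≥ 10 rows and ≥ 3 defined
  grid points.
* **Precedence**: `P1 = P(SL | ORP)` vs `P2 = P(ORP | SL)`; if ORP
  develops after SL, `P1 > P2` (the event conditioned on in the larger
  probability is the later one). Bootstrap resamples infants — the unit of
  the contingency counts — via the equivalent multinomial over the four
  SL×ORP cells; two-sided achieved significance
  `2 · min(P(diff ≤ 0), P(diff ≥ 0))` with add-one smoothing.
* **Trajectories**: for infants observed at all requested occasions,
  per-infant OLS of `π̂` on age; the prediction at the target age (default
  0.25 months ≈ one week) is clamped to [0, 1]. The OLS intercept itself
  is left unconstrained: clamping the prediction is what keeps the
  reported quantity a probability, and it reproduces the intended
  step-trajectory behaviour (e.g. trajectory 0, 1, 1 extrapolates below 0
  and clamps to 0).
* **Sampling calculator**: `P(Binomial(n, p_SL) ≥ m)^k` for `k`
  independent cohorts — closed form via the binomial survival function.

## Synthetic cohorts

The generator emulates the longitudinal design the analyses assume: 74
infants at 3/6/9 months (46 complete, 21 at two adjacent ages, 7 once →
per-occasion occupancy near 58/67/62), 24 integer trials per session.
Looking style matures via a per-infant logistic in age (midpoint
N(4.5, 1.5) months, scale U(0.8, 2)); 15% of infants are "special" —
always-SL or step-like (LL at the first age, SL after) — matching the
qualitatively discrete trajectories real cohorts show. Band widths are
U(8, 25) frames, anchored at the range boundaries.

Preference is induced through the only mechanisms the mixture offers
(mixture mean `π(a+f)/2 + (1−π)[λ(a+b)/2 + (1−λ)(e+f)/2]`): `λ` is
centred at 0.55, giving long looks a mild negative (other-stimulus) lean,
and the short-component midpoint is offset by `π ·` (+12 frames at the
first occasion, −10 later), so short-lookers lean positive early and
mildly negative later while long-lookers' bands stay anchored at ±130.
The offset scales with `π` because the preference signal is meant to
*track* looking style continuously — the pattern the δ-curve and
independence analyses measure.

What the generator does not emulate: serial dependence within a session
(the model assumes exchangeable trials, and the order check is there to
probe that), stimulus-identity effects, measurement error in frame
coding, and any between-infant correlation structure. Passing tests on
these cohorts validate the machinery under the model's own assumptions,
not the model's adequacy for any particular real dataset.

## Numerical choices

* Likelihood/EM tolerance 1e−8 (relative), max 500 iterations; the EM
  trace is exposed and asserted non-decreasing in tests.
* `(π, λ)` integration: 48×48 midpoint grid on (0, 1)²; band-cell
  integrals in closed form; structure marginals via logsumexp.
* Ties and boundaries: `d = 0` is always a gap point (posterior 1 whenever
  `π > 0`); closed intervals everywhere (integer data make half-open
  conventions immaterial).
* Bootstrap/permutation p-values: add-one convention; all randomness
  flows through `numpy.random.Generator` seeds — fixed seeds give
  byte-identical outputs.
* Problem sizes in the test suite: 1000 random series for EM
  monotonicity, 50 twelve-trial series against the 201×201 exhaustive
  grid, 500 replicates per recovery point, 200 null cohorts of 60 infants
  (B = 199) for the type-I check.

## Known limitations

* Per-infant `π̂` at T = 24 has wide uncertainty (bootstrap SEs ≈ 0.15 for
  mixed lookers); cohort-level conclusions are the intended use.
* The `π = 0.75` upward bias described above; more trials per session is
  the only clean remedy.
* One infant's model is fit independently per occasion; no pooling or
  hierarchical shrinkage across infants or ages (deliberately — each
  infant has their own response population).
* Exactly two long bands; no continuous-time gaze modelling.
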