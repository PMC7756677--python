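# Methods

## Model and assumptions

All intervals assume the paired differences `D_i = X_i − Y_i` are iid
Normal(μ, σ²) on the analysis scale. The sufficient statistics are the
subject count n, the mean difference `D̄` and the sample standard deviation
`S` with divisor n−1 (required for the t-based prediction interval to be
exact). A Shapiro–Wilk p-value on the differences is reported as an
advisory check; it never blocks the computation. When a trend between the
per-subject means and differences is strong (|r| > 0.7) a warning is
logged, since horizontal tolerance limits presuppose no pattern in the
mean-difference plot; regression-based alternatives are out of scope.

Log-normal data are handled by analysing `log10` (or `ln`) measurements:
the normal model then applies to log-differences, and exponentiating the
bounds yields fold-change (ratio) intervals around the geometric mean
ratio. An absolute acceptance band is not meaningful on the log scale, so
the equivalence decision for log analyses is deferred to the
back-transformed ratio scale, where a tolerated relative difference f
defines the band `(1−f, 1/(1−f))` — asymmetric around 1 but symmetric in
log units.

## Interval families and their guarantees

| kind | formula | guarantee |
|---|---|---|
| AI | `D̄ ± z_(1+β)/2 · S` | approximate; true content < β for every finite n |
| AI with CIs | each AI bound ± `t_(1+γ)/2,n−1 · S·√(1/n + z²/(2(n−1)))` | descriptive only |
| βTI (= PI) | `D̄ ± t_(1+β)/2,n−1 · S·√(1+1/n)` | mean content exactly β at every n |
| βγTI approx | `D̄ ± z_(1+β)/2 · √(1+1/n) · √((n−1)/χ²_(1−γ),n−1) · S` | content ≥ β with confidence ≈ γ |
| βγTI exact | `D̄ ± k·S`, k from the integral equation below | content ≥ β with confidence = γ |
| bootstrap-t PI | t-quantiles replaced by resampled pivot quantiles | asymptotic; slightly anti-conservative at small n |

The exact two-sided factor k solves

```
√(2n/π) ∫₀^∞ P( χ²_{n−1} > (n−1)·χ²_{1,β,z²} / k² ) e^{−n z²/2} dz = γ,
```

with `χ²_{1,β,z²}` the β-quantile of the noncentral χ²(1 df, ncp z²). The
closed-form factor is its first-order approximation (the Student quantile
of the βTI replaced by a normal quantile, and S by the upper bound of its
one-sided γ confidence interval); the two agree within 1% relative for
n ≥ 10 at β=0.95, γ ∈ {0.8, 0.9, 0.95}.

### Numerics of the exact factor

The integrand weight is the half-normal density of `z ~ |N(0, 1/n)|`, so we
substitute `u = √n·z` and integrate u over [0, 12] with 128-node
Gauss–Legendre quadrature; the discarded half-normal tail mass is < 1e-30,
and the integrand is smooth. The noncentral-χ² quantiles at the nodes
depend only on (n, β), never on k, so they are computed once (and cached
per (n, β)), making each evaluation of the left-hand side a vectorised
`chi2.sf` call. k is found by Brent's method with relative tolerance 1e-10,
bracketed at the closed-form approximation × [0.8, 1.3] and expanded
outward on sign failure (the left-hand side is strictly increasing in k).
The returned root satisfies the equation to ~1e-12; an independent check
with adaptive quadrature in the untransformed variable agrees to 1e-11.

### Interval ordering

`width(AI) < width(βTI)` always. `width(βTI) < width(βγTI(γ))` holds
exactly when γ exceeds the βTI's own effective confidence level at that n
(≈0.74 at n=5, ≈0.61 at n=20, decreasing towards ~0.5 as n grows) — a
"γ > 0.5 for any n" rule is almost but not exactly right, matching the
observation that a βTI resembles a βγTI at 50% confidence without equating
it. At the confidence levels used in practice here (0.8, 0.9, 0.95) the
nesting AI ⊂ βTI ⊂ βγTI holds for every n ≥ 4.

### Bootstrap-t prediction interval

The analytic prediction pivot `(d_future − D̄)/(S·√(1+1/n))` is exactly
t_{n−1}. Each bootstrap iteration resamples the n differences with
replacement, computes `D̄*`, `S*`, draws one further resampled future
difference `d*`, and forms `r = (d* − D̄*)/(S*·√(1+1/n))`; the empirical
((1−β)/2, (1+β)/2) quantiles of r replace the t-quantiles. Resamples with
S* = 0 are skipped and counted. The interval is deterministic given the
seed and need not be symmetric; its coverage runs slightly below nominal
at small n because the empirical tails under-represent the population
tails.

## Coverage simulation

The study design: two devices measure the same truth with independent
Gaussian errors of unit SD each (both SDs configurable), so differences are
Normal(0, √(sd_x²+sd_y²)) — √2 by default. For each n in the grid, `reps`
experiments are simulated; every interval is a multiple `c·S` of the sample
SD with c depending only on (n, β, γ), so c is computed once per n and the
whole grid is vectorised. The *effective predictive level* of one computed
interval is its exact content `Φ((upper−μ)/σ) − Φ((lower−μ)/σ)` — no inner
simulation — and the *effective confidence level* is the fraction of
replicates whose content reaches at least β, with no discretisation. Both
come with Monte-Carlo standard errors (SD of the content / √reps, and
√(p(1−p)/reps)).

Defaults: n grid {5, 10, 20, 50, 100}, reps 10⁵, β=0.95,
γ ∈ {0.8, 0.9, 0.95}. 10⁵ replicates put the MC standard error on a level
near 0.8–0.95 at ~0.1 percentage point while a full grid runs in seconds on
one CPU; reps is a plain knob for sharper runs. Reproducibility: one
`SeedSequence` child per sample size spawned from the master seed, each
consumed by a single vectorised draw, so results are bit-identical for a
given config regardless of grid order.

`expected_content(multiplier, n)` computes the mean effective predictive
level analytically — a 200-node Gauss–Legendre quadrature in both
probability coordinates of the independent sampling laws `D̄ ~ N(0, σ²/n)`
and `(n−1)S²/σ² ~ χ²_{n−1}` (σ cancels). It reproduces β exactly for the
prediction multiplier (to ~2e-6 quadrature error) and provides a
simulation-free check of the Monte-Carlo engine. On this scale the AI's
level deficit is < 0.1% of β by n = 10³ and the βγTI(0.8) excess < 0.5% of
β by n = 10⁴; the corresponding width ratios converge more slowly (0.17%
and 0.59% at those n, like 1/n and 1/√n).

## Synthetic data

`generate_fixture` emulates an unreplicated comparison: subject truths are
Normal(base_level, between_subject_sd²), device Y reads the truth, device X
adds a systematic bias and Normal(0, sd_diff²) noise, so differences are
exactly Normal(bias, sd_diff²). `calibrate_to_summary` affinely rescales
the differences to hit a target (mean, SD) exactly — this is how analyses
published only as summary statistics are reproduced; the per-subject means
are preserved up to the implied shift. `lognormal_fixture` exponentiates
such a sample so the X/Y ratio is log-normal.

What these fixtures do not emulate: heteroscedastic or proportional error,
non-Gaussian tails, trends of the difference with the mean, outliers, or
replicate-level variance structure. Passing tests therefore certify the
intervals under the normal model they assume, not robustness to its
violations.

## Design choices

- **Repeated measures** are averaged per subject per method before
  differencing; the tolerance intervals then describe differences of
  per-subject means (stated in reports). No replicate-variance inflation is
  attempted.
- **Two-threshold acceptance bands**: Δ₁ applies strictly below the
  threshold, Δ₂ at or above it. Percentage bands are evaluated pointwise at
  every observed per-subject mean; equivalence requires the tolerance
  interval inside the band at each of them.
- **Decision rule**: every tolerance interval attached to the result (βTI
  and, when γ is supplied, βγTI) must lie inside the band; the AI is never
  part of the decision. No γ supplied means no βγTI — the confidence level
  is a study-design quantity to fix a priori, not a default.
- **Degenerate spread** (S = 0, possible with tied assay readings) yields a
  degenerate point interval plus a warning rather than an error.
- **Subjects with missing replicates** on either method are dropped with a
  logged count: the paired design requires complete pairs.
- **Precision**: all values are carried at full double precision; 3-decimal
  rounding in printed reports is presentation only.

## Limitations

- Normality of differences on the analysis scale is assumed, not enforced.
- One-sided tolerance bounds (noncentral-t based), Bayesian tolerance
  intervals, multivariate tolerance regions, and errors-in-variables
  regression for trending mean-difference plots are not implemented.
- The equivalence decision is binary interval-inclusion; no p-value or TOST
  machinery is provided.
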