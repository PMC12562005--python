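# Methods

## The model

The transformed inverse Weibull distribution (TIWD) has CDF

    F(x; α, β) = exp(α (1 − e^(x^(-β)))),   x > 0,  α, β > 0,

derived from the inverse Weibull CDF `G(x) = exp(-λ x^(-β))` with the scale
fixed at λ = 1 through `F = exp(α (1 − 1/G))`. Both parameters act as shape
parameters; there is no scale parameter, so the family is *not* closed under
rescaling of the data (a deliberate property of the transform; fits are
unit-dependent). A three-parameter extension with free λ is out of scope.

Key analytic facts the implementation leans on:

* Tail: expanding `e^(x^(-β)) ≈ 1 + x^(-β)` gives `S(x) ~ α x^(-β)`, i.e.
  Pareto-type algebraic decay. Hence `e^(tx) S(x) → ∞` for all `t > 0`
  (heavy tail in the strict sense) and `E[X^r] < ∞` iff `r < β`. Moment
  routines raise `InfiniteMomentError` at `r ≥ β` rather than returning a
  truncation-dependent number.
* Quantile: `ρ(w) = [log1p(−ln(w)/α)]^(-1/β)`, exact and monotone; sampling
  is inverse-transform.
* Along the substitution `x = ρ(w)`:
  `log f(ρ(w)) = log(αβ) + ((β+1)/β) ln u + ln w + u` with
  `u = log1p(−ln(w)/α)`. This identity is exact algebra and never
  exponentiates `x^(-β)`, so every tail-sensitive integral (normalization,
  moments, entropies, mean residual life) is computed on the bounded domain
  `w ∈ (0, 1)`. With β < 1 the raw x-domain carries mass to astronomically
  large x and fixed-upper-limit quadrature silently loses it — this is why
  entropy tables computed by naive truncated quadrature cannot be
  reproduced and are not targeted (see "Known discrepancies").

## Numerical hygiene

* `1 − e^(x^(-β))` is always `−expm1(x^(-β))`; `F` near 0/1 and the hazard
  near sf-underflow are computed in log space (`log_sf` uses
  `log(−expm1(log F))`); the reversed hazard uses its analytically cancelled
  form `αβ x^(-β-1) e^(x^(-β))`.
* `e^(x^(-β))` terms in the likelihood machinery switch to a max-shifted
  evaluation once `x^(-β) > 500`, so profile and score functions stay usable
  over the full root bracket even when observations lie below 1; where the
  score genuinely diverges (some `xᵢ < 1`, β → ∞) it returns −∞, which the
  bracketing logic treats as a sign.
* Mean residual life integrates `E[(X − x)⁺] = ∫ (ρ(w) − x) dw` after the
  further change `1 − w = v^(β/(β−1))`, which removes the `(1−w)^(-1/β)`
  endpoint singularity exactly (the plain substitution integral's QAGS error
  estimate is optimistic near that singularity).
* Entropy quadratures (`scipy.integrate.quad`, limit 400) are rejected with
  `EntropyDivergenceError` when the reported error exceeds
  `max(1e-6, 1e-4·|value|)` — a divergent power integral (e.g. Rényi order
  at or below `1/(β+1)`) raises instead of returning a finite artifact.

## Maximum likelihood

The α score has the closed-form root `α(β) = n / Σ expm1(xᵢ^(-β))` and is
strictly decreasing in α, so α profiles out exactly. The profiled β score
changes sign exactly once on (0, ∞); we bracket on [1e-3, 64] with geometric
expansion (up to 2¹⁰ upward, 1e-8 downward) and solve by Brent/bisection to
machine tolerance. Observed Fisher information uses the three analytic
second derivatives (`−n/α²`; `Σ e^t t ln x`; `−n/β² − α Σ e^t t (ln x)²(t+1)
+ Σ t (ln x)²`, with `t = x^(-β)`); asymptotic intervals are
`estimate ± z_(θ/2) √var` and are *not* truncated at zero — coverage is
computed against the raw interval.

## Minimum-distance estimators

Anderson–Darling `A = −n − (1/n) Σ (2i−1)[ln F(x₍ᵢ₎) + ln S(x₍ₙ₊₁₋ᵢ₎)]`,
Cramér–von Mises `C = 1/(12n) + Σ [F(x₍ᵢ₎) − (2i−1)/(2n)]²`, and least
squares `L = Σ [F(x₍ᵢ₎) − pᵢ]²` are minimized by multistart Nelder–Mead on
`(ln α, ln β)` (positivity without constraints), started at the ML estimate
plus eight perturbed points; the analytic gradient (via `∂F/∂α = F(1−e^t)`,
`∂F/∂β = α t e^t F ln x`) is recorded as a stationarity certificate. The
default plotting position is the standard `pᵢ = i/(n+1)`; `pᵢ = i/(n+i)`
(a plausible literal reading of one published rendering) is available via
`plotting_position="paper"`. Ties are handled by stable sorting with F
evaluated at each order statistic independently.

## Bayesian estimation

Independent Gamma(η₁, ψ₁), Gamma(η₂, ψ₂) priors (defaults all 1) or the
non-informative prior 1/(αβ) (equivalent to zero hyperparameters in the
conditionals). One MH update of α given β and one of β given α per Gibbs
sweep; normal random-walk proposals whose nonpositive draws are resampled.
Two deliberate choices where the published procedure is silent or loose:

* **Proposal scales.** Unstated in the source; default is 0.3 × the ML
  asymptotic standard errors, giving high acceptance (~0.9) but fast,
  reproducible chains whose 4500 retained draws estimate posterior first
  and second moments accurately at these data sizes. An optional
  pre-burn-in adaptive phase (`adapt=True`) tunes toward 25–45% acceptance
  and freezes the scales before any retained draw, keeping the kept chain
  Markov.
* **Truncation correction.** Resampling nonpositive proposals makes the
  proposal a zero-truncated normal; the published acceptance ratio ignores
  the Hastings correction `Φ(current/sd)/Φ(proposal/sd)`. The default
  follows that procedure verbatim (the bias is negligible whenever the
  chain sits several proposal sd above zero, as here);
  `truncation_correction=True` applies the exact factor.

Chains start at the ML estimate (existence/uniqueness guaranteed). The
precautionary-loss point estimate is the coordinatewise root of the
posterior mean square, `sqrt(mean of squared retained draws)` — the Bayes
rule for `L(θ̂, θ) = (θ̂ − θ)²/θ̂`.

## Goodness of fit

Two KS conventions are exposed. `two_sided` (default) is the standard
`D = max_i max(i/n − F(x₍ᵢ₎), F(x₍ᵢ₎) − (i−1)/n)` on the sorted sample.
`upper_step` is `max_i |F(xᵢ) − i/n|` over the data in stored order; this is
the convention that reproduces the published D values for both packaged
datasets to four decimals (including the effect of one out-of-order pair in
the printed survival data), and it is what the comparison-table
reproduction uses. p-values come from the asymptotic Kolmogorov series in
either mode; published p-values for these tables follow no standard formula
we could identify and are not targeted. Parameters are estimated on the
same data before KS is computed (no Lilliefors-style correction), matching
the published procedure.

Rival families use standard textbook parameterizations and a generic
multistart MLE, and are flagged `best_effort` in output.

## Monte Carlo harness

AE = mean of estimates, MSE = mean squared deviation from truth,
CV = sample standard deviation (n−1 denominator) / AE. Replicate streams
are split with `SeedSequence(seed, spawn_key=(n_index, rep))`, so results
are identical under any execution order. Replicates whose fit fails are
excluded and counted (never substituted); a warning fires above 5%
failures. The Bayes arms default to M = 5000 iterations with M₀ = 500
burn-in and η = ψ = 1. Full-size studies use 1000 replicates; the Bayesian
acceptance run uses 250 replicates, which this package treats as its
standard desk-scale setting (the Monte Carlo standard error it yields,
~0.007 on the average α estimate, is well below the effects of interest).

## What the synthetic generator does and does not emulate

Synthetic studies draw i.i.d. complete samples from the TIWD itself by
inverse transform — the same design as the published simulations. They
exercise estimator behaviour under correct specification only: no
censoring, no covariates, no contamination, no measurement rounding.
Passing simulation tests therefore demonstrates internal correctness and
estimator calibration, not robustness of the TIWD on misspecified real
data; the real-data evidence comes from the two packaged datasets.

## Known discrepancies with the published tables

Documented here because the package intentionally does not chase them:

* **Entropy tables.** Several printed entropy values sit at parameter/order
  combinations where the defining integral diverges (e.g. Rényi order 0.9
  at β = 0.025; the convergence boundary is order > 1/(β+1)). Where the
  integral does converge, some printed values still disagree with
  substitution quadrature (Shannon at (1, 0.025): ≈ 40.9 here vs 21.2
  printed) while others agree (Rényi 1.1 at (1, 0.025): 8.4716 vs 8.4718).
  The pattern is consistent with truncated x-domain quadrature in the
  source. The Tsallis/Mathai–Haubold column interchange between the two
  printed tables is the exact identity `H_M(ς) = H_T(2−ς)`, which holds
  here to machine precision.
* **Rival model-comparison rows.** The published Weibull row's parameters
  reproduce its printed AIC exactly under the standard shape/scale form, but
  are not the ML optimum (true Weibull MLE improves AIC by ~50 on the
  fatigue data, confirmed against `scipy.stats.weibull_min.fit`). With all
  rivals honestly refit, the generalized inverse exponential and
  exponentiated Pareto families come within ~0.5 AIC of (and slightly
  ahead of) the TIWD on both datasets. The comparison table reports honest
  refits.
* **Coverage table.** The published interval widths are ~1.5× those implied
  by the printed Fisher matrix, which is why the published coverage is
  ~0.99. The implementation follows the printed matrix and obtains
  near-nominal (~0.95) coverage with correspondingly narrower intervals.
* **Published distance-estimator fits on the real data** are implausible
  (e.g. an Anderson–Darling β̂ of 7.46 with KS ≈ 0.98, an essentially
  non-fitting solution); the optimizers here report their own verified
  minima (grid-search-certified) instead.

## Degenerate inputs and edge behaviour

Construction rejects nonpositive or non-finite parameters and observations
(with the offending row index). `n = 1` supports profiling but not full ML
(`n ≥ 2`). Quantile orders outside (0,1), order-statistic indices outside
[1, n], moment orders `r ≥ β`, and AICc with `n ≤ k+1` raise immediately.
Proposal sd of exactly zero leaves an MCMC chain at its initial state (the
identity move is accepted).
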