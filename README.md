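# tiwd — the transformed inverse Weibull distribution

A toolkit for modelling heavy-tailed lifetime data — fatigue lives of
components, patient survival times — with the **transformed inverse Weibull
distribution (TIWD)**, a two-parameter family obtained from the inverse
Weibull CDF `G(x) = exp(-x^(-β))` through the transform `F = exp(α(1 − 1/G))`:

```
F(x; α, β) = exp(α (1 − e^(x^(-β)))),                        x > 0, α, β > 0
f(x; α, β) = α β x^(-β-1) exp(α (1 − e^(x^(-β)))) e^(x^(-β))
```

The survival function decays algebraically, `S(x) ~ α x^(-β)` as `x → ∞`, so
the family is genuinely heavy tailed: `e^(tx) S(x) → ∞` for every `t > 0`,
and the `r`-th moment exists iff `r < β`. The hazard is unimodal
("inverted bathtub"). This makes the TIWD a candidate whenever empirical
log-log survival plots straighten out in the tail.

The package is aimed at reliability engineers and biostatisticians and
provides:

* **Distribution machinery** — pdf/cdf/sf, quantile function
  `ρ(w) = [ln(1 − ln(w)/α)]^(-1/β)`, inverse-transform sampling, hazard /
  cumulative hazard / reversed hazard, raw and incomplete moments, Lorenz and
  Bonferroni curves, order-statistic densities, mean residual life, Bowley
  skewness / Moors kurtosis, and tail diagnostics.
* **Entropies** — Shannon, Rényi, Tsallis and Mathai–Haubold model entropies
  by substitution quadrature with divergence diagnostics.
* **Five estimators** — maximum likelihood (profile of α via the closed form
  `α(β) = n / Σ(e^(xᵢ^(-β)) − 1)` plus 1-D root finding of the profiled
  score), minimum Anderson–Darling, Cramér–von Mises and least-squares
  distance estimators, and MH-within-Gibbs Bayesian estimation under
  precautionary loss `L(θ̂, θ) = (θ̂ − θ)²/θ̂` with gamma or non-informative
  priors. ML fits come with Fisher-information asymptotic confidence
  intervals.
* **Model comparison** — KS statistic, AIC/AICc/BIC, and a comparison table
  against six classical lifetime families (Weibull, weighted exponential,
  exponentiated Pareto, flexible Weibull, generalized exponential,
  generalized inverse exponential).
* **A Monte Carlo harness** — AE/MSE/CV estimator studies and CP/AW coverage
  studies, fully seeded and reproducible.
* **Two packaged datasets** — fatigue lives of 46 metal components (cycles)
  and survival times of 44 head-and-neck cancer patients.

Estimators follow scikit-learn conventions (`TIWDFitter`, `TIWDBayesFitter`
with `fit`, `get_params`, trailing-underscore attributes), so they compose
with sklearn tooling; plain functions (`ml_fit`, `ad_fit`, …) wrap them.

## Worked example

```python
import tiwd

sample = tiwd.load_builtin_dataset("metal_fatigue")   # n = 46 fatigue lives
fit = tiwd.ml_fit(sample)
print(fit.alpha, fit.beta)        # 1074.853  1.190816
ic = tiwd.information_criteria(fit.loglik, k=2, n=sample.n)
print(ic)                         # aic 715.3629, aicc 715.6420, bic 719.0202
ks = tiwd.ks_statistic(sample, fit.distribution().cdf, mode="upper_step")
print(ks["d"])                    # 0.10056
```

The same fit from the shell:

```sh
$ tiwd fit --dataset metal_fatigue --method ml
{
  "method": "ml",
  "n": 46,
  "alpha": 1074.8530478710964,
  "beta": 1.1908158614913649,
  "loglik": -355.68144231322117,
  ...
  "gof": { "ks_d": 0.1223, "ks_p": 0.497, "aic": 715.3629, "aicc": 715.6420, "bic": 719.0202 }
}
```

Read: the fitted transform parameter α̂ ≈ 1075 and shape β̂ ≈ 1.19 say the
fatigue lives are heavy tailed with barely more than one finite moment
(mean exists, variance does not). The AIC of 715.36 beats the two-parameter
Weibull refit (726.12) by more than ten units on these data. The default
`ks_d` is the standard two-sided statistic (0.1223 here); the `upper_step`
mode (0.1006) is the convention used in published comparison tables for
these datasets — see `docs/methods.md`.

Model comparison, simulation and entropy are one call each:

```sh
tiwd gof --dataset head_neck_cancer
tiwd simulate --alpha 0.5 --beta 1 --n 100 --reps 1000 --seed 1
tiwd entropy --alpha 1 --beta 3 --kind shannon     # -> 0.50145
```

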