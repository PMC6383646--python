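# anyprev

Bayesian multivariate meta-analysis of the prevalence of a **superordinate
category of disorders** — "any anxiety disorder", "any cardiac disorder" —
from studies that each measured only part of the disorder panel.

## Why

Primary studies rarely assess every disorder in a category. A study that
measured only generalized anxiety disorder reports an "any disorder"
prevalence for a *smaller* category than a study that measured all six
anxiety disorders, so pooling those numbers with an ordinary random-effects
meta-analysis mixes apples and oranges and can understate the category
prevalence severely (in the bundled case study: 9% pooled naively versus
about 20% from the joint model). `anyprev` instead models the constituent
disorders jointly and derives the category prevalence from the posterior.

## The model

For disorder `d` in study `s`, let `mu_{s,d}` be the probit-transformed
prevalence. The hierarchy is

    mu_{s,*}  ~ MVN(theta, Sigma_B),   Sigma_B[d,d'] = tau_d omega_B[d,d'] tau_d'
    n_{s,d}   ~ Binomial(N_s, Phi(mu_{s,d}))                      (aggregate data)
    y_{s,d,i} = 1{ytilde_{s,d,i} > 0},  ytilde_{s,*,i} ~ MVN(mu_{s,*}, omega_C)   (IPD)

with priors `theta_d ~ N(-1.88, 0.30^2)`, `tau_d ~ half-N(0.25)`, and LKJ(2)
on the Cholesky factors of both correlation matrices. `omega_C` is the
latent (tetrachoric) comorbidity correlation: estimated from
individual-participant data when available (Model 2), supplied as a known
matrix otherwise (Model 1). The category prevalence
P(at least k disorders) is computed from the posterior by simulating
hypothetical participants from hypothetical new studies.

Frequentist comparators (REML logit random-effects pooling and
meta-regression on the number of measured disorders), a synthetic-data
generator, and a coverage/bias evaluation harness are included. Sampling is
by a built-in No-U-Turn sampler; see `docs/methods.md` for the full account.

## Worked example

Fit the bundled case study — 20 samples, 10,033 peripartum participants,
six anxiety and related disorders — assuming a moderate exchangeable
comorbidity (`rho = 0.3`, Model 1, since the raw IPD are not
redistributable):

```python
import anyprev as ap

data = ap.case_study_table1()
model = ap.PrevalenceModel(data, omega_C=ap.exchangeable_corr(6, 0.3))
res = model.fit(chains=2, iterations=1200, warmup=600, seed=2024)
print(res.summary().round(3).to_string())
print(res.category_report(ks=(1, 2, 3, 4), n_inner=1000, seed=0))
```

which prints

```
                 prevalence  prev_hdi_low  prev_hdi_high    tau  tau_hdi_low  tau_hdi_high
disorder
panic                 0.019         0.010          0.029  0.252        0.067         0.477
ocd                   0.028         0.011          0.048  0.486        0.298         0.737
gad                   0.035         0.017          0.056  0.426        0.254         0.617
social_phobia         0.031         0.022          0.040  0.123        0.000         0.296
specific_phobia       0.056         0.023          0.090  0.384        0.187         0.602
ptsd                  0.016         0.006          0.031  0.483        0.283         0.714

Probability of having at least k disorders

k    prevalence [95% HDI]      95% PI
1+     20% (15%, 25%)      (6%, 35%)
2+      4% (2%, 6%)      (0%, 10%)
3+      1% (0%, 2%)      (0%, 2%)
4+      0% (0%, 0%)      (0%, 1%)
```

Reading the output: each disorder's population mean prevalence (`Phi(theta_d)`)
comes with a 95% highest-density interval, and `tau` is its between-study SD
on the probit scale (e.g. OCD prevalences vary a lot across studies, social
phobia hardly at all). One in five participants is estimated to have at
least one of the six disorders — far above the 9% obtained by naively
pooling the studies' own "any disorder" numbers — with a 95% HDI of 15–25%;
the prediction interval (6%, 35%) is the range expected for a single new
study, wider because it includes between-study heterogeneity.

The comparator table the model is judged against:

```bash
anyprev table2
```

```
method  k_samples  prevalence_pct  ci_low_pct  ci_high_pct  tau_probit  tau_logit
   FRE         17               9           6           13        0.48       0.77
 FRE-H         11              13           9           18        0.40       0.64
 FRE-A          3              18          14           22        0.14       0.22
 FRE-M         17              16          11           23        0.33       0.53
FRE-MH         11              14           7           25        0.44       0.70
```

Requiring more measured disorders (FRE-H: at least three; FRE-A: all six)
raises the naive estimate toward the multivariate one, but discards most of
the data; the meta-regression (FRE-M) extrapolates with a much wider
interval.

Other entry points: `ap.fit_model2(data)` for IPD datasets,
`res.conditional_probability(given=["panic"], target="gad")` for comorbidity
conditionals, `res.per_study_predictions()` for posterior-predictive checks,
`ap.preset_config("sim1")` / `ap.generate_meta_analysis` /
`ap.evaluate(...)` for simulation studies, and the `anyprev`
CLI (`fit`, `estimate`, `table2`, `simulate`, `evaluate`).

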