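# Methods

## The problem

Epidemiological meta-analyses often need the prevalence of a *superordinate
category* — "any anxiety disorder", "any cardiac disorder" — defined as
having at least one of a fixed panel of D constituent disorders. Primary
studies rarely measure the whole panel, so their reported "any disorder"
estimates operationalize different categories: a study measuring only
generalized anxiety disorder reports the prevalence of *that* category, not
of "any of six anxiety disorders". Pooling such estimates directly biases the
category prevalence downward; regressing on the number of measured disorders
extrapolates under an equal-prevalence assumption that is rarely justified.

`anyprev` instead models the constituent disorders jointly and *derives* the
category prevalence from the joint posterior.

## The model

Index studies (clusters) by `s` and disorders by `d = 1..D`. Let
`mu_{s,d}` be the probit-transformed prevalence of disorder `d` in study `s`.

**Between studies.** Study effects are exchangeable draws from a correlated
random-effects distribution:

    mu_{s,*} ~ MVN(theta, Sigma_B),
    Sigma_B[d,d'] = tau_d * omega_B[d,d'] * tau_d',

where `theta_d` is the probit-scale mean prevalence, `tau_d >= 0` the
between-study SD of disorder `d` (heterogeneity), and `omega_B` a correlation
matrix. Two samples reported by the same parent article (e.g. a pregnant and
a postpartum cohort) share one `mu_{s,*}` through a common cluster label,
which keeps their dependence from spuriously tightening the pooled estimate.

**Within a study, aggregate counts.** When only the diagnosed count
`n_{s,d}` out of `N_s` participants is available:

    n_{s,d} ~ Binomial(N_s, Phi(mu_{s,d}))

independently across the measured disorders given `mu`. Unmeasured disorders
simply contribute no factor — their `mu_{s,d}` remains informed by `theta`,
`tau` and `omega_B` (within-model imputation). The reported "any disorder"
count is deliberately never used as data: its meaning differs across studies.

**Within a study, individual participant data (IPD).** When per-participant
binary diagnoses `y_{s,d,i}` are available, they are modelled as
dichotomizations of a latent multivariate-normal trait:

    y_{s,d,i} = 1{ ytilde_{s,d,i} > 0 },
    ytilde_{s,*,i} ~ MVN(mu_{s,*}, omega_C),

with unit variances, so `omega_C` is the matrix of tetrachoric (latent)
comorbidity correlations. For IPD samples this likelihood *replaces* the
binomial. Latent coordinates of unmeasured disorders are marginalized out.

**Priors** (defaults; all exposed in `Priors`):

| parameter | prior | default rationale |
|---|---|---|
| `theta_d` | `N(-1.88, 0.30^2)` | population prevalences of roughly 0.7%–10% probable within 2 SD — mildly informative for rare disorders |
| `tau_d`   | half-normal, scale 0.25 | values above 0.5 unlikely; at a 3% mean prevalence, `tau = 0.5` already spans study prevalences of 0.2%–18.9% |
| `Chol(omega_B)`, `Chol(omega_C)` | LKJ(2) | weakly favours moderate correlations, guarantees positive-definiteness |

**Model 1 vs Model 2.** Without IPD, `omega_C` is not identified from
aggregate counts; Model 1 (`fit_model1` / `PrevalenceModel(..., omega_C=...)`)
takes it as known and carries it through unchanged. Model 2 (`fit_model2`)
places the LKJ prior on `omega_C` and estimates it from the IPD, propagating
its uncertainty into every downstream quantity.

## Category-level quantities

All category quantities are posterior functionals evaluated by simulation.
For a participant drawn from a random *new* study, the latent trait is
marginally `MVN(theta, Sigma_B + omega_C)`. Per posterior draw `m`,

* `category_prevalence(k)` estimates `P(at least k diagnoses)` by Monte Carlo
  over `n_inner` participants, *each from its own fresh study effect*; the
  summary is the median and 95% highest-density interval (HDI) of the
  per-draw values. The default `n_inner = 1000` makes the per-draw
  Monte-Carlo noise (about 1.2 percentage points at a 18% prevalence) small
  relative to posterior spread; raise it when quoting tight intervals.
* The **prediction interval** repeats the computation with one shared new
  study per posterior draw, so between-study heterogeneity widens it: it
  describes the category prevalence expected in a single future study, not
  uncertainty about the population mean.
* `conditional_probability(given, target)` computes comorbidity conditionals
  such as P(GAD | panic disorder) as a ratio of orthant probabilities of
  `MVN(theta, Sigma_B + omega_C)`; sets of up to four disorders use numerical
  orthant integration, larger ones Monte Carlo with an orthant fallback
  whenever the conditioning event goes unobserved (never a silent NaN).
* `per_study_predictions` simulates `N_s` participants per posterior draw
  from each sample's own cluster effect — the posterior-predictive check
  that each observed prevalence (and each observed "any measured disorder"
  prevalence, which the model never saw as data) falls inside its 95% band.

The HDI of a sample is the shortest contiguous window containing 95% of the
sorted values.

## Posterior computation

No probabilistic-programming backend is used; the package carries its own
sampler, specified entirely by the posterior above:

* **Kernel**: multinomial No-U-Turn HMC with dual-averaging step-size
  adaptation (target acceptance 0.8) and a diagonal mass matrix estimated
  from a warmup window (a dense matrix is available via
  `SamplerConfig(dense_mass=True)`).
* **Parameterizations**: `tau = exp(lambda)`; correlation matrices through
  the tanh/canonical-partial-correlation Cholesky construction with the
  LKJ(2) density plus transform Jacobian (derivatives by complex-step
  differentiation, exact to machine precision). Study effects are
  non-centered (`mu_c = theta + diag(tau) L_B z_c`) for aggregate-only
  clusters — the right geometry when counts are weakly informative — and
  centered (`mu_c` sampled directly) for clusters with IPD, whose likelihood
  pins `mu_c` tightly.
* **Model 2 augmentation**: latent traits are resampled between NUTS
  transitions by truncated-normal Gibbs sweeps (two per transition),
  a Metropolis-within-Gibbs scheme. The latent correlation `omega_C` mixes
  slowest under this augmentation — its draws are strongly autocorrelated in
  data-rich blocks — so `omega_C` summaries deserve longer chains than
  `theta`/`tau` summaries; the convergence report makes this visible.
* **Diagnostics**: split R-hat and bulk effective sample size per reported
  parameter; a fit is flagged (warning plus `converged=False`) unless every
  non-constant parameter has R-hat <= 1.05 and ESS >= 200. Divergent
  transitions are counted and reported. Chains derive their seeds
  deterministically from the configured seed.
* **Degenerate inputs**: a one-disorder panel is rejected (the model is
  multivariate by construction); a disorder observed in no sample is allowed
  but warned about, its posterior reproducing the prior; zero-size samples
  contribute no likelihood, which the prior-reproduction tests exploit.

Numerical guards reject states with overflowing `tau` or numerically
singular correlation submatrices (log-density `-inf`), regions of negligible
posterior mass visited only by the step-size search.

## The case-study fixture

The bundled dataset covers 20 samples from 18 articles (10,033 peripartum
participants) reporting prevalences for up to six anxiety and related
disorders; 7 samples (1,506 participants) also contributed IPD to the
original analysis. The source table prints percentages, so integer counts
are reconstructed as `round(pct * N / 100)` — exact to the printed precision.
Zero-percent cells become zero counts (legal binomial data; any continuity
correction is an estimator concern, applied only inside the logit-effects
computation). The raw IPD are not redistributable; the fixture carries only
an `ipd_available` flag, so the package fits Model 1 to the case study and
the IPD model is exercised on synthetic data. Consequently published
IPD-model case-study numbers serve as qualitative anchors only; the
acceptance suite checks that the aggregate-only fit with an exchangeable
`omega_C` (rho = 0.3) lands materially above naive pooling and near the
full-panel analyses, which it does.

## Frequentist comparators

The estimators the Bayesian model is compared against are implemented from
first principles in `anyprev.freq`:

* logit effects `yi = log(p/(1-p))`, `vi = 1/(N p) + 1/(N (1-p))` from the
  any-disorder counts, with the standard only-zero-cells correction (add 0.5
  events, 1 to N) for boundary proportions — chosen because it reproduces
  the reference results at printed precision and matches common tooling
  defaults;
* REML estimation of the between-study variance by direct numerical
  maximization of the profiled restricted log-likelihood (bounded scalar
  optimization, tolerance 1e-10, variance floored at zero), inverse-variance
  weights, Wald-z 95% intervals, no small-sample adjustments;
* meta-regression on the number of measured disorders with prediction at the
  full panel (`x = D`), Wald p-value for the slope;
* the half-panel filter retains samples measuring at least `ceil(D/2)`
  disorders.

Cluster dependence is deliberately ignored here: that is how these
comparators are used in practice and exactly what the multivariate model
improves on. An independent cross-check against a general-purpose REML
implementation (metafor, driven through Rscript) agrees to 4+ decimals.

## Synthetic-data generator

`generate_meta_analysis` draws meta-analyses from the same statistical
structure the model assumes: 20 studies with `N = 100 + Exp(rate 0.005)`
(mean 300, rounded); study effects from `MVN(probit(p), Sigma_B)`;
participant diagnoses thresholded from `MVN(mu_s, omega_C)`; a measurement
process that includes disorder `d` with probability `incl_prob_d` (redrawn
if a study would measure nothing — redrawing avoids biasing any particular
disorder); the first two studies exempt from the measurement process so
every disorder is represented; the first seven studies exporting IPD for
their measured columns. The three presets give the canonical conditions:
`sim1` (prevalences 1.5/2.0/2.5/3.5/4.0/6.0%, tau 0.50/0.25/0.45/0.10/0.40/
0.35, inclusion 50/50/70/50/70/40%) and `sim2`/`sim3` (prevalences
1/2/3/5/7/9%, tau 0.1 and 0.4, same inclusion probabilities). The
correlation matrices of the original simulations were posterior medians from
a case-study fit and were never published; the presets default to
exchangeable matrices with rho = 0.3 for both `omega_B` and `omega_C` — a
realistic moderate-comorbidity substitute — and accept any user-supplied
matrices.

The "true" category prevalence of a configuration is defined by brute force:
the median over many replicates of the proportion of participants — each
from a separate fresh study — with at least k of all D disorders (defaults
10,000 participants x 10,000 replicates; the evaluation harness uses 10,000
x 2,000, which is stable to well under 0.1 percentage points).

What the generator deliberately does not emulate: the case study's
preponderance of single-disorder studies (an idiosyncrasy of that
literature), heterogeneity of `omega_C` across studies, covariate effects on
`theta`, and reporting or selection bias. Passing recovery tests therefore
demonstrate correctness of the estimators *under the assumed generative
process*, not robustness to violations of it.

## Evaluation harness

`evaluate` runs FRE / FRE-H / FRE-M / FRE-MH / BMV-K / BMV-IPD over
replicated simulated meta-analyses and reports median estimate, median bias,
coverage with its binomial Monte-Carlo error `sqrt(c(1-c)/reps)`, mean
interval width, and slope-test power at two-sided alpha = 0.05. Coverage is
judged against the brute-force truth, never an analytic shortcut. BMV-K
takes the generating `omega_C` as its known matrix by default (the "omega_C
known" assumption), with any substitute injectable. Method failures on a
replicate (e.g. a constant-moderator design for the meta-regression) are
recorded and skipped, not fatal.

## Problem sizes used by the test suite

The default test run scales the expensive experiments down, as its own
design choice, to sizes where the assertions retain power: parameter
recovery uses a three-disorder, 12-study configuration (25 replicates,
2 chains x 450 iterations) for the aggregate model and a two-disorder,
8-study configuration (6 replicates) plus a single 4,000-participant
tetrachoric-recovery study for the IPD model, with binomial 3-sigma bounds
on coverage counts; the coverage contrast uses 100 frequentist replicates;
the case-study fit uses 2 chains x 1100 iterations. The acceptance script
(`scripts/acceptance.py`) runs the comparator table at full size — it is
deterministic — and the coverage experiment at 100 replicates with a
10,000 x 2,000 brute-force truth.

## Known limitations

* `omega_C` is homogeneous across studies by assumption.
* No covariate (meta-regression) term in `theta`; no bias modelling.
* The data-augmentation sampler's `omega_C` mixing is slow in data-rich
  blocks; a parameter-expanded augmentation would improve it.
* Aggregate counts of different disorders are conditionally independent
  given `mu` — the within-study sampling correlation the IPD likelihood
  captures is ignored for aggregate-only samples (as in the model this
  package implements).
* The case-study IPD are unavailable, so Model 2 is validated on synthetic
  data only.
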