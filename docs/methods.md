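# Methods

## Model

`apomap` fits a joint shared-component spatio-temporal model for K related
binomial outcomes observed on N areal units over J periods, all counted
against one live-birth denominator per area-period:

```
Y_ijk ~ Binomial(n_ij, pi_ijk)
logit(pi_ijk) = alpha_k + X_i beta_s + X_ij beta_st + mu_ijk
mu_ijk = gamma_s[k] u_s[i] + u_sk[i,k] + gamma_t[k] u_t[j] + u_tk[j,k] + nu_ij
```

The premise is borrowing strength: adverse pregnancy outcomes share much
of their etiology (access to and quality of obstetric care, malaria
exposure, maternal nutrition), so a latent spatial field `u_s` and
temporal trend `u_t` common to all outcomes are estimated jointly, with a
per-outcome positive loading (`gamma_s[k]`, `gamma_t[k]`) expressing how
strongly each outcome participates in the shared geography/trend.
Outcome-specific fields (`u_sk`, `u_tk`) absorb departures, and `nu_ij`
is residual space-time interaction.

### Priors

* Spatial blocks (`u_s`, each `u_sk`): intrinsic CAR — improper GMRF with
  density `∝ tau^{rank/2} exp(-tau/2 Σ_{a~b} (u_a - u_b)^2)` over the
  adjacency graph, `rank = N - #components`.  Isolated areas (possible
  with island geographies) get an exchangeable Normal(0, 1/tau) with the
  block's precision, adding one rank unit each.
* Temporal blocks (`u_t`, each `u_tk`): RW1 — the same penalty on squared
  first differences, rank J-1.
* Interaction `nu`: exchangeable Normal (Knorr-Held Type I) by default;
  Type II (independent RW1 per area) via `ModelConfig(interaction="rw1")`.
  Type I is the minimal reading of "unstructured heterogeneity"; Type II
  is the natural alternative when area-specific trends are suspected.
* Fixed effects `alpha`, `beta`: Normal(0, 10^2).
* Precisions: Gamma(0.5, 0.0005) — vague, WinBUGS-era convention.  Shape
  and rate are configurable (`HyperPriors`).
* Weights: LogNormal(0, 0.68^2) on each `gamma`, keeping weights mostly
  within [0.2, 5].

All hyperpriors are explicit and configurable; none is load-bearing for
the package's tests beyond ordinary vagueness.

### Identifiability

The decomposition is redundant: field levels trade against `alpha`,
component means against each other, and a common factor in `gamma` against
the scale of the shared field.  The constrained parameterization is:

* every `u` field sums to zero (per connected component for spatial
  blocks); `nu` sums to zero (globally for Type I, per area for Type II);
* `Σ_k log gamma_s[k] = Σ_k log gamma_t[k] = 0` (product one).

`apply_constraints` projects any state onto this parameterization,
compensating through `alpha` (and, for the weight rescaling, through the
shared fields) so that on a connected graph the likelihood is unchanged to
floating-point accuracy.  Shared-component analyses are sometimes written
with an *additive* sum-to-zero on the spatial weights alongside a
multiplicative one on the temporal weights; an additive constraint on
multiplicative positive loadings forces negative weights and contradicts
the shared-component construction, so product-one is the default for
both, and the additive variant is retained behind
`ModelConfig(literal_spatial_constraint=True)` (weights then get a
Normal(0,1) prior and may be negative) for comparison.

On a disconnected graph the between-component means cannot be absorbed
into a common intercept (there is no unscaled common spatial term); the
per-component centring is then part of the model definition rather than a
pure reparameterization.  The same applies to per-area centring of a
Type II interaction.  All shipped configurations use connected lattices.

### Coefficient sharing

One pooled coefficient vector per covariate block is the default (the
reporting convention of national analyses: a single estimate with one
uncertainty interval per covariate); `ModelConfig(share_coefficients=
False)` switches to outcome-specific coefficients.

## Sampler

Adaptive Metropolis-within-Gibbs, one sweep =

1. conjugate Gamma draws for every precision: shape + rank/2, rate +
   quadform/2, with the intrinsic ranks above;
2. random-walk Metropolis for `alpha` (vectorized across outcomes —
   outcome slices of the likelihood are disjoint, so parallel acceptance
   is exact), for each pooled `beta` (sequential scalars), and for
   `log gamma` (parallel across outcomes);
3. chromatic single-site random-walk Metropolis for each field: a proper
   colouring of the adjacency (or period-path) graph is computed once and
   all same-colour sites are proposed/accepted in parallel, which is valid
   because same-colour sites are conditionally independent given the rest
   (for the Type I interaction all N*J sites are independent and update in
   one shot);
4. re-projection onto the constrained parameterization.

Proposal scales adapt per block toward 0.44 acceptance (Robbins-Monro on
the log scale) during burn-in only, so the post-burn-in kernel is fixed
and the chain valid.  Initialization: `alpha` at the pooled empirical
logit per outcome, fields at zero, weights at one, precisions at one.
Likelihood surfaces are cached per chain and refreshed every 1,000 sweeps
to stop floating-point drift.

Chain protocol defaults follow the motivating analysis: two chains of
80,000 iterations with a 4,000-iteration burn-in.  Thinning (default 10)
is this package's addition, bounding memory for long runs; set `thin=1` to
disable.  Convergence is flagged at R-hat < 1.1 (classic Gelman–Rubin,
between/within-variance form — deliberately not the rank-normalized
split variant) together with the MC-error/SD < 5% rule computed by batch
means with floor(sqrt(n)) batches.  Trace-plot export covers every scalar
parameter.

## Covariate screening

Per (covariate, outcome) pair a bivariate Poisson regression
`log E[Y] = log n + b0 + b1 x` is fitted by IRLS (statsmodels GLM); the
two-sided Wald p-value and residual deviance are recorded, with a
frequentist Wald interval.  Covariates significant at p < 0.05 for at
least one outcome survive step 1; step 2 drops, within any pair with
|r| > 0.7 (configurable; a common epidemiological convention), the member
with the larger best p-value (ties: larger deviance, then name).  The
intervals reported at this stage are frequentist Wald intervals — this is
a maximum-likelihood screen, not a Bayesian one.  No multiple-testing
correction is applied, as is usual for association-strength screens in
mapping pipelines.

## Synthetic data

`generate_dataset` simulates panels with exactly the generative structure
the model assumes, emulating the motivating application's scale: a 29x10
rook-contiguity lattice standing in for ~290 sub-counties, 4 annual
periods (2016-2019), 4 outcomes, and 500-5,000 live births per
area-period.  Default true baselines (-3.05, -3.75, -3.96, -4.97 on the
logit scale) correspond to the national-scale rates of the four outcomes
(~4.5 and 2.3 per 100; ~18.7 and 6.9 per 1,000 live births).  Spatial
fields are exact intrinsic-CAR draws (eigenbasis of the component
Laplacian, variances 1/(tau*eigenvalue), sum-to-zero by construction);
temporal trends are centred Gaussian random walks.  Covariates are one
spatially smooth (standardized ICAR draw) and one white-noise variable per
block, so the screening stage has both signal and noise to separate; the
default true effects load on the smooth variables only.  Precisions
default to (tau_us, tau_usk, tau_ut, tau_utk, tau_nu) = (4, 10, 25, 50,
100): a strong shared geography, weaker specific fields, modest trends,
small interaction.

What the generator does *not* emulate: reporting-completeness artefacts
of a real facility system (strikes, late entry), denominator
misclassification, or outcome-definition drift.  A generic uniform
missingness fraction is available (`missing_fraction`), default 0 —
passing tests on these panels demonstrates correctness of the machinery
under the model's own assumptions, not robustness to real-data pathology.

## Validation and reporting

Model adequacy follows the refit-and-predict design: 20% of observed
(area, period, outcome) cells are masked (uniformly; optionally stratified
by outcome), the model is refitted on the rest, and posterior-predictive
binomial draws at the held-out cells are compared with the observations.
Interval coverage and rate-scale MAE are this package's choice of
comparison metrics; no single canonical metric exists for this check.

The reporting layer computes outcome-by-period totals with margins and
completeness notes, signed percent changes (error on a zero baseline),
rates per 100 or 1,000 live births — crude rates always labelled as such,
distinct from model-based posterior-median rates — per-area absolute rate
differences with decline/increase partitions and rankings, and the
posterior summary of the shared spatial field keyed by area id for joining
to map geometries.  Percents and rates are presented to one decimal,
round-half-even.

## Problem sizes used in the tests

Tests exercise the full pipeline at desk scale: 4x4 to 8x8 lattices, with
the parameter-recovery study at the 6x6 / 4-period / 4-outcome /
~2,000-births-per-cell configuration, ten replicates of 2 chains x 20,000
iterations, and the holdout study at 8x8 (1,024 cells, 205 held out).
At these sizes the credible intervals cover the true baselines, pooled
effects and temporal weights in well over 80% of replicate-parameter
pairs.  One identifiability observation: with only J=4 periods and modest
trend variance, the *temporal* weights `gamma_t` are weakly identified —
their wide credible intervals cover truth, but their posterior medians do
not reliably reproduce the true ordering.  The *spatial* weights
`gamma_s`, informed by N=36+ areas, rank correctly in most replicates;
the residual inversions concentrate in the weights of the two rarest
outcomes (stillbirth and neonatal death), whose thin binomial counts
leave the widest weight posteriors.  Rank-concordance checks therefore
use the spatial weights, and their pass rate should be read as a
statement about information, not sampler correctness: shared-component
loadings are only as well identified as the latent field they scale is
informative and the outcome they belong to is common.

## Known limitations

* Single-site Metropolis mixes slowly for strongly coupled fields;
  the chromatic scheme vectorizes it but does not change its statistics.
  Very large graphs would warrant block or marginal updates.
* The weight/field scaling direction (gamma vs u) relies on the
  post-sweep re-projection; with proper priors on `alpha` and `gamma` the
  compensated moves are not exactly prior-invariant (standard practice,
  but worth knowing).
* Holdout prediction requires the held-out cells' denominators; cells
  with zero live births are excluded with a warning.
* No spatially varying coefficients, BYM2 reparameterization, or
  non-binomial likelihoods.
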