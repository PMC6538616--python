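# Methods

## The model

`pikemodel` estimates the Proportion of Illegally Killed Elephants (PIKE)
from ranger-collected carcass encounters.  Each record *i* is one site-year:
`n_total` carcasses found, `n_illegal` of them judged illegal kills.  The
model is a hierarchical binomial-logit regression

    n_illegal_i ~ Binomial(p_i, n_total_i)
    logit(p_i)  = b0 + b1*Precip_i + b2*IMR_i + b3*CPI_c[i]
                  + a_site[i] + a_year[i] + a_country[i]

with normally distributed random intercepts whose site- and year-level means
are themselves linear in level covariates:

    a_site,s    ~ N(b4*PovDens_s + b5*LawEnf_s + b6*ln(Area)_s, sigma_site)
    a_year,y    ~ N(b7*Seizures_y + b8*IvoryPrice_y,            sigma_year)
    a_country,c ~ N(0,                                          sigma_country)

Every covariate is centred and scaled to mean 0, sd 1 before fitting (sample
sd, n−1); precipitation and site area are natural-log transformed first
because both are strongly right-skewed in real monitoring data.  The
site-level and year-level covariates are standardised over their native
units — one value per site, one per year — rather than over replicated
record rows, so that unbalanced reporting cannot distort their scale (a
`level_weighting="records"` switch provides the alternative).

Shrinkage ("Bayesian lasso"): `b1..b8 ~ Laplace(0, 1/lambda)` with a diffuse
Gamma(r=1, delta=1) hyperprior on `lambda^2`, so the penalty strength is
estimated from the data.  The intercept `b0` is not penalised; it gets a
diffuse Normal(0, 10) prior, since shrinking an intercept toward zero has no
subject-matter justification.  The three level standard deviations carry
Gamma(1, 1) priors by default, with a Uniform(0, 20) alternative for prior
sensitivity checks; a `fixed_scale_normal` coefficient-prior mode replaces
the Laplace priors with fixed-scale normals.

PIKE converts to an annual poaching mortality rate through
`m_p = PIKE * m_n / (1 - PIKE)` under an assumed constant natural mortality
`m_n` (default 0.03; 0.02 and 0.04 as sensitivity values).  The conversion
is uncapped and undefined at PIKE = 1; observed pooled PIKE of exactly 1
propagates as missing rather than being truncated.

## The sampler

No probabilistic-programming backend is used; the sampler is an adaptive
Metropolis-within-Gibbs scheme written directly against the target density,
operating on a non-centred parameterisation (intercept = mean + sigma * z,
z ~ N(0,1)):

* a jointly adapted 9-dimensional random-walk block for the coefficients
  (empirical-covariance proposal, Haario-style, plus componentwise refreshes
  of `b0..b3`);
* vectorised independent random-walk updates of the z's per level — given
  everything else the site deviations are conditionally independent across
  sites (each record belongs to exactly one site), so all 53 update in one
  vectorised step, and likewise years and countries;
* log-scale random walks for the sigmas and lambda;
* likelihood-invariant *translation* moves (shift a coefficient, compensate
  in the z's that can absorb it) and *rescale* moves (sigma -> sigma e^u,
  z -> z e^-u) that break the coefficient/intercept and sigma/z couplings —
  without these the hierarchical posterior mixes an order of magnitude more
  slowly.

Proposal scales adapt by Robbins–Monro only during burn-in and are frozen
afterwards, so the retained chains are valid Markov chains with the
posterior invariant.  Defaults follow common practice for this model class:
3 chains of 100,000 iterations, 50,000 burn-in, thinning 50, hence 3,000
retained draws.  Convergence is flagged with arviz's rank-normalised split
R-hat (< 1.01) and bulk effective sample size (> 400) on the scalar
parameters; a failing fit completes but is marked and warned about.

Sampler correctness is tested three ways: the log-likelihood and log-prior
agree with independently coded density sums to 1e-10; an intercept-only
posterior matches numerical quadrature of likelihood x prior to
Kolmogorov–Smirnov distance < 0.02 at 3,000 draws; and 90% credible
intervals cover the generating coefficients at >= 75% empirical rate across
20 generate-and-refit replicates.

## The synthetic-data generator

The generator draws from exactly the generative process above: default
dimensions 53 sites in 29 countries over 16 years from 2002 (sites allocated
to countries, and countries to four regions, as evenly as possible);
covariates are standard normals drawn directly on the standardised scale at
all four resolutions (optionally equicorrelated below the collinearity
screen's 0.5 threshold); `n_total` is negative binomial with mean
`carcass_rate` (default 30) and dispersion 5 — overdispersed carcass counts
are realistic and stress the binomial model; Poisson is the dispersion->inf
limit.  A missingness fraction of 0.28 is deleted at random, mirroring the
unbalanced reporting of a real 16-year monitoring programme in which roughly
72% of possible site-years carry records.  The default sparse truth
(intercept −0.5; cpi −0.4, pov_dens +0.4, law_enf −0.4, price +0.6; the
other four coefficients exactly zero; sigmas 0.5/0.3/0.3) gives each level
of the hierarchy signal while leaving genuinely null covariates for the
lasso to shrink.

What the generator does *not* emulate: spatially explicit carcass placement
or residual spatial autocorrelation, detection-probability differences
between carcass causes, reporting gaps that correlate with poaching
pressure, and real covariate distributions (log-normal prices, bounded CPI
scores).  Missingness is completely at random.  Passing tests therefore
demonstrate that the machinery recovers the model's own process at realistic
dimensions — not that the model is correctly specified for real monitoring
data.

## Analysis products

* **Annual rates** (continental and per region): per posterior draw,
  site-year PIKE -> rates -> median across the sites observed that year;
  then the median and equal-tailed 90% interval across draws.  Medians
  across sites are deliberately taken over *observed* site-years only;
  predicting unobserved site-years would require fresh random effects and
  change the estimand.  Observed counterparts pool all carcasses per year
  first and are flagged as biased toward well-sampled sites.
* **Temporal validation**: fit on years up to a cutoff, predict later years.
  Unseen year intercepts are drawn per draw from N(mu_year, sigma_year)
  using the test years' annual covariates — the only generative-consistent
  treatment.  The score is the squared *weighted Pearson correlation*
  between posterior-median predicted and observed PIKE with weights
  `n_total` (a weighted-regression R² variant exists behind the
  `DescrStatsW` cross-check in tests); its 90% CI comes from scoring each
  draw separately.
* **Residual diagnostics**: residual = posterior-median PIKE − observed
  PIKE (records with no carcasses excluded).  The correlogram bins pairwise
  residual correlations by great-circle distance (equal-count bins) and by
  year lag over between-site pairs; it is a screening tool, not a formal
  spline correlogram with bootstrap envelope.
* **Interventions**: each interventable covariate in turn is overwritten
  everywhere with its most elephant-friendly observed value — found by brute
  scan for the observed value minimising the posterior-mean linear-predictor
  contribution, so the direction follows the fitted sign rather than a
  hard-coded min/max.  Precipitation is excluded and held at its mean in
  every scenario and the baseline (it proxies natural-mortality variation,
  not a conservation lever).  Random-intercept deviations keep their
  posterior draws; only fixed-covariate contributions change.  The pooled
  summary is, per draw, the median of the annual medians within the year
  range, summarised across draws.

## Numerical choices and edge cases

* Binomial records with `n_total = 0` contribute exactly zero likelihood,
  stay in the data model, and are excluded from observed-PIKE denominators
  and residuals.
* Zero-variance covariate columns are a standardisation error, not a silent
  drop; missing covariate cells are rejected at read time (no imputation).
* Year-level lags (0/1/2 for seizures and price) are applied from the raw
  year table before standardisation; a lag that runs off the start of the
  series raises with the missing years listed.
* The gamma hyperprior density on `lambda^2` uses the standard negative
  exponent `exp(-delta * lambda^2)`; sigma and lambda proposals are made on
  the log scale with the Jacobian included.
* Equal-tailed (5%, 95%) quantiles are used wherever a 90% interval is
  reported.
* Seeds are mandatory everywhere randomness enters (fits, generation,
  prediction with unseen levels); no hidden global RNG state.

## Problem sizes used in tests and the acceptance script

Test fits use the generator at full default dimensions (53 x 16) for
recovery and correlation checks but shorter chains than the defaults
(typically 3 chains x 4,000 iterations, burn-in 2,000, thinning 2 — also
3,000 retained draws); hold-out and intervention replicate studies run at
20 x 12 and 10 x 8 with 2 chains.  These sizes are the package's chosen
trade-off between Monte-Carlo error and turnaround; all thresholds
(coverage >= 0.75, KS < 0.02, permutation-null wins >= 80%, ordering >= 95%)
are evaluated at exactly these sizes with fixed seeds.

## Known limitations

* PIKE assumes equal detectability of legal and illegal carcasses and
  constant background mortality; the model inherits both assumptions.
* The sampler is random-walk based: posteriors with far more sites or
  strongly correlated covariates would mix more slowly than a
  gradient-based sampler; R-hat/ESS flags are the guard.
* The intervention analysis is correlative — "best observed value"
  counterfactuals say nothing about causal transportability.
* The weighted R² CI reflects draw-to-draw prediction variability, not
  sampling variability of the observed test set.
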