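import numpy as np
import pytest
import scipy.stats as st

from pikemodel import (McmcSettings, ModelSpec, ParameterPoint,
                       ValidationError, effective_sample_size, fit,
                       log_likelihood, log_prior, rhat)
from pikemodel.data_io import BETA_NAMES
from pikemodel.model import PosteriorSamples
from pikemodel.synthetic import SyntheticConfig, generate_dataset

from conftest import intercept_only_data, quiet_fit


def random_point(design, rng):
    return ParameterPoint(
        beta=rng.normal(0, 1, 9),
        site_effect=rng.normal(0, 1, len(design.site_ids)),
        year_effect=rng.normal(0, 1, len(design.years)),
        country_effect=rng.normal(0, 1, len(design.country_ids)),
        sigma_site=rng.uniform(0.2, 2), sigma_year=rng.uniform(0.2, 2),
        sigma_country=rng.uniform(0.2, 2), lam=rng.uniform(0.5, 3))


# ------------------------------------------------------------- log-densities
def test_log_likelihood_closed_forms():
    data = intercept_only_data(k=1, n=2)
    zero = ParameterPoint(beta=np.zeros(9), site_effect=np.zeros(1),
                          year_effect=np.zeros(1), country_effect=np.zeros(1),
                          sigma_site=1, sigma_year=1, sigma_country=1)
    assert np.isclose(log_likelihood(zero, data), np.log(0.5))
    empty = intercept_only_data(k=0, n=0)
    assert log_likelihood(zero, empty) == 0.0


def test_log_likelihood_matches_brute_force_binomial_sum():
    truth = generate_dataset(SyntheticConfig(n_sites=5, n_countries=3,
                                             n_years=4, carcass_rate=20,
                                             missingness_fraction=0.0), seed=2)
    design = truth.data.design()
    rng = np.random.default_rng(0)
    for _ in range(5):
        point = random_point(design, rng)
        eta = (point.beta[0] + design.X_rec @ point.beta[1:4]
               + point.site_effect[design.site_idx]
               + point.year_effect[design.year_idx]
               + point.country_effect[design.country_idx])
        expected = st.binom.logpmf(design.k, design.n, st.logistic.cdf(eta)).sum()
        assert abs(log_likelihood(point, truth.data) - expected) < 1e-10


def test_log_likelihood_rejects_nonfinite_predictor():
    data = intercept_only_data()
    point = ParameterPoint(beta=np.r_[np.inf, np.zeros(8)],
                           site_effect=np.zeros(1), year_effect=np.zeros(1),
                           country_effect=np.zeros(1), sigma_site=1,
                           sigma_year=1, sigma_country=1)
    with pytest.raises(ValueError, match="non-finite"):
        log_likelihood(point, data)


def test_log_prior_laplace_closed_forms():
    data = intercept_only_data()
    spec = ModelSpec()
    base = ParameterPoint(beta=np.zeros(9), site_effect=np.zeros(1),
                          year_effect=np.zeros(1), country_effect=np.zeros(1),
                          sigma_site=1, sigma_year=1, sigma_country=1, lam=1.0)
    shifted = ParameterPoint(**{**base.__dict__, "beta": np.eye(9)[1]})
    # moving one penalised coefficient from 0 to 1 at lambda=1 costs
    # exactly the Laplace exponent: log f(1) - log f(0) = -1
    assert np.isclose(log_prior(shifted, spec, data)
                      - log_prior(base, spec, data), -1.0)
    # at lambda=2 the Laplace log-density at zero is ln(lambda/2) = 0
    assert np.isclose(st.laplace.logpdf(0.0, scale=1 / 2.0), 0.0)


def test_log_prior_matches_independent_density_sum():
    truth = generate_dataset(SyntheticConfig(n_sites=5, n_countries=3,
                                             n_years=4), seed=2)
    design = truth.data.design()
    rng = np.random.default_rng(1)
    for sd_prior in ("gamma", "uniform"):
        spec = ModelSpec(sd_prior=sd_prior)
        point = random_point(design, rng)
        mu_site = design.X_site @ point.beta[4:7]
        mu_year = design.X_year @ point.beta[7:9]
        expected = (
            st.norm.logpdf(point.beta[0], 0, spec.beta0_prior_sd)
            + st.laplace.logpdf(point.beta[1:], 0, 1 / point.lam).sum()
            + st.gamma.logpdf(point.lam ** 2, a=spec.lambda_r,
                              scale=1 / spec.lambda_delta)
            + st.norm.logpdf(point.site_effect, mu_site, point.sigma_site).sum()
            + st.norm.logpdf(point.year_effect, mu_year, point.sigma_year).sum()
            + st.norm.logpdf(point.country_effect, 0, point.sigma_country).sum())
        if sd_prior == "gamma":
            for s in (point.sigma_site, point.sigma_year, point.sigma_country):
                expected += st.gamma.logpdf(s, a=spec.sd_r,
                                            scale=1 / spec.sd_delta)
        else:
            expected += 3 * st.uniform.logpdf(0.5, 0, spec.sd_uniform_upper)
        assert abs(log_prior(point, spec, truth.data) - expected) < 1e-10


def test_log_prior_invalid_scales_are_minus_infinity():
    data = intercept_only_data()
    bad = ParameterPoint(beta=np.zeros(9), site_effect=np.zeros(1),
                         year_effect=np.zeros(1), country_effect=np.zeros(1),
                         sigma_site=-1, sigma_year=1, sigma_country=1, lam=1)
    assert log_prior(bad, ModelSpec(), data) == -np.inf
    bad2 = ParameterPoint(**{**bad.__dict__, "sigma_site": 1.0, "lam": 0.0})
    assert log_prior(bad2, ModelSpec(), data) == -np.inf


def test_label_invariance_under_site_permutation():
    truth = generate_dataset(SyntheticConfig(n_sites=6, n_countries=3,
                                             n_years=4), seed=5)
    design = truth.data.design()
    rng = np.random.default_rng(3)
    point = random_point(design, rng)
    ll = log_likelihood(point, truth.data)
    lp = log_prior(point, ModelSpec(), truth.data)

    # rename sites in reverse alphabetical order (covariates travel along)
    mapping = {s: f"Z{i}" for i, s in enumerate(reversed(design.site_ids))}
    renamed = truth.data
    records = renamed.records.assign(site_id=renamed.records["site_id"].map(mapping))
    sy = renamed.sy_table.assign(site_id=renamed.sy_table["site_id"].map(mapping))
    site = renamed.site_table.assign(site_id=renamed.site_table["site_id"].map(mapping))
    from pikemodel.data_io import assemble
    data2 = assemble(records[["site_id", "country_id", "region", "year",
                              "n_total", "n_illegal"]],
                     sy, renamed.cy_table, site, renamed.year_table,
                     log_covariates=())
    data2.standardised = True
    design2 = data2.design()
    order = np.argsort([mapping[s] for s in design.site_ids])
    point2 = ParameterPoint(**{**point.__dict__,
                               "site_effect": point.site_effect[order]})
    assert np.isclose(log_likelihood(point2, data2), ll, atol=1e-10)
    assert np.isclose(log_prior(point2, ModelSpec(), data2), lp, atol=1e-10)


# ------------------------------------------------------------------ settings
def test_mcmc_settings_validation():
    with pytest.raises(ValueError):
        McmcSettings(seed=0, n_burnin=100, n_iterations=100)
    with pytest.raises(ValueError):
        McmcSettings(seed=0, thin=0)
    s = McmcSettings(seed=0)
    assert s.draws_per_chain == 1000 and s.total_draws == 3000


def test_fit_contract_errors(small_truth):
    from dataclasses import replace
    data = small_truth.data
    unstd = replace(data, standardised=False)
    with pytest.raises(ValidationError, match="standardised"):
        fit(unstd, ModelSpec(), McmcSettings(seed=0, n_iterations=20,
                                             n_burnin=10, thin=1))
    degen = replace(data, records=data.records.assign(n_total=0, n_illegal=0))
    with pytest.raises(ValidationError, match="n_total"):
        fit(degen, ModelSpec(), McmcSettings(seed=0, n_iterations=20,
                                             n_burnin=10, thin=1))


def test_fit_draw_shapes_and_positivity(small_samples, small_truth):
    s = small_samples
    assert s.n_draws == s.settings.total_draws == 3000
    assert s.beta.shape == (3, 1000, 9)
    assert (s.flat("sigma_site") > 0).all()
    assert (s.flat("lam") > 0).all()
    assert s.z_site.shape[-1] == len(small_truth.data.site_ids)


def test_posterior_save_load_roundtrip(small_samples, tmp_path):
    path = tmp_path / "post.npz"
    small_samples.save(path)
    back = PosteriorSamples.load(path)
    assert np.array_equal(back.beta, small_samples.beta)
    assert back.site_ids == small_samples.site_ids
    assert back.spec == small_samples.spec
    assert back.settings == small_samples.settings


# --------------------------------------------------------------- diagnostics
def test_rhat_identical_chains_is_one():
    # identical chains whose halves are also identical: between-chain
    # variance is zero (the rank-normalised estimator carries a small
    # finite-sample correction, hence the tolerance)
    pattern = np.tile(np.random.default_rng(0).normal(size=100), 2)
    chains = np.stack([pattern, pattern])
    assert abs(rhat(chains) - 1.0) < 0.01


def test_rhat_detects_offset_chains():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 500)
    b = rng.normal(10, 1, 500)
    assert rhat(np.stack([a, b])) > 1.5


def test_rhat_well_mixed_chains_near_one():
    rng = np.random.default_rng(1)
    chains = rng.normal(size=(4, 5000))
    assert rhat(chains) < 1.01


def test_rhat_single_chain_errors():
    with pytest.raises(ValueError):
        rhat(np.random.default_rng(0).normal(size=(1, 100)))


def test_ess_white_noise_near_total():
    rng = np.random.default_rng(2)
    chains = rng.normal(size=(4, 10000))
    ess = effective_sample_size(chains)
    assert abs(ess - 40000) / 40000 < 0.1


def test_ess_ar1_matches_closed_form():
    rng = np.random.default_rng(3)
    phi, n = 0.9, 20000
    chains = np.empty((4, n))
    for c in range(4):
        e = rng.normal(size=n)
        x = np.empty(n)
        x[0] = e[0]
        for t in range(1, n):
            x[t] = phi * x[t - 1] + e[t]
        chains[c] = x
    expected = 4 * n * (1 - phi) / (1 + phi)
    assert abs(effective_sample_size(chains) - expected) / expected < 0.3


def test_ess_constant_chain_is_degenerate():
    assert effective_sample_size(np.ones((2, 100))) == 0.0


def test_diagnostics_table_marks_fixed_parameters(small_truth):
    spec = ModelSpec(lambda_fixed=1.5)
    s = quiet_fit(small_truth.data, spec,
                  McmcSettings(seed=4, n_chains=2, n_iterations=400,
                               n_burnin=200, thin=2))
    assert not s.diagnostics.loc["lam", "sampled"]
    assert np.isnan(s.diagnostics.loc["lam", "rhat"])
    assert s.diagnostics.loc["beta[price]", "sampled"]


# ------------------------------------------------------- posterior behaviour
def test_fixed_lambda_shrinkage_is_monotone():
    """Raising a fixed lasso penalty must not inflate a null coefficient
    (averaged over replicate datasets)."""
    meds = {1.0: [], 8.0: []}
    for seed in (21, 22, 23):
        truth = generate_dataset(SyntheticConfig(
            n_sites=10, n_countries=5, n_years=8, carcass_rate=20,
            missingness_fraction=0.0), seed=seed)
        for lam in meds:
            s = quiet_fit(truth.data, ModelSpec(lambda_fixed=lam),
                          McmcSettings(seed=seed, n_chains=2,
                                       n_iterations=2500, n_burnin=1000,
                                       thin=3), compute_diagnostics=False)
            j = BETA_NAMES.index("imr")      # true coefficient is zero
            meds[lam].append(np.median(np.abs(s.flat("beta")[:, j])))
    assert np.mean(meds[8.0]) <= np.mean(meds[1.0]) + 0.01


def test_gamma_and_uniform_sd_priors_agree_on_identified_data(full_truth):
    """Swapping the gamma sd-priors for uniform ones should barely move the
    coefficient posteriors when the data are informative."""
    settings = McmcSettings(seed=6, n_chains=2, n_iterations=3000,
                            n_burnin=1500, thin=3)
    s_gamma = quiet_fit(full_truth.data, ModelSpec(sd_prior="gamma"),
                        settings, compute_diagnostics=False)
    s_unif = quiet_fit(full_truth.data, ModelSpec(sd_prior="uniform"),
                       settings, compute_diagnostics=False)
    med_g = np.median(s_gamma.flat("beta"), axis=0)
    med_u = np.median(s_unif.flat("beta"), axis=0)
    sd_g = s_gamma.flat("beta").std(axis=0)
    assert np.all(np.abs(med_g - med_u) < sd_g)
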