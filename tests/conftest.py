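"""Shared fixtures: small synthetic datasets and fitted posteriors.

Fits are session-scoped so several test modules can share one MCMC run;
chain lengths are reduced relative to the defaults to keep the suite quick
while leaving enough effective draws for the checks that use them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from pikemodel import McmcSettings, ModelSpec, fit, generate_dataset, preset
from pikemodel.data_io import StandardisationRecord, assemble
from pikemodel.errors import ConvergenceWarning
from pikemodel.model import PosteriorSamples

#: reduced-length chains used throughout the suite; chosen so that
#: 3 x (4000 - 2000) / 2 = 3000 retained draws, matching the draw count the
#: full-length default settings produce
FAST_MCMC = dict(n_chains=3, n_iterations=4000, n_burnin=2000, thin=2)


def quiet_fit(data, spec, settings, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return fit(data, spec, settings, **kw)


@pytest.fixture(scope="session")
def small_truth():
    return generate_dataset(preset("small"), seed=11)


@pytest.fixture(scope="session")
def small_samples(small_truth):
    return quiet_fit(small_truth.data, ModelSpec(),
                     McmcSettings(seed=2, **FAST_MCMC))


@pytest.fixture(scope="session")
def full_truth():
    return generate_dataset(preset("full_scale"), seed=5)


@pytest.fixture(scope="session")
def full_samples(full_truth):
    return quiet_fit(full_truth.data, ModelSpec(),
                     McmcSettings(seed=1, n_chains=3, n_iterations=6000,
                                  n_burnin=3000, thin=3))


def make_natural_data():
    """A tiny dataset on natural covariate scales (positive precip/area),
    exercising the log-transform path."""
    carcasses = pd.DataFrame({
        "site_id": ["S1", "S1", "S1", "S2", "S2"],
        "country_id": ["C1", "C1", "C1", "C2", "C2"],
        "region": ["Eastern", "Eastern", "Eastern", "Western", "Western"],
        "year": [2001, 2002, 2003, 2001, 2003],
        "n_total": [10, 12, 0, 8, 9],
        "n_illegal": [4, 6, 0, 2, 9],
    })
    sy = pd.DataFrame({
        "site_id": ["S1"] * 3 + ["S2"] * 3,
        "year": [2001, 2002, 2003] * 2,
        "imr": [30.0, 28.0, 26.0, 55.0, 50.0, 45.0],
        "precip": [400.0, 500.0, 450.0, 900.0, 950.0, 1000.0],
    })
    cy = pd.DataFrame({
        "country_id": ["C1"] * 3 + ["C2"] * 3,
        "year": [2001, 2002, 2003] * 2,
        "cpi": [30.0, 32.0, 35.0, 55.0, 54.0, 52.0],
    })
    site = pd.DataFrame({
        "site_id": ["S1", "S2"],
        "pov_dens": [12.0, 3.0],
        "area": [1500.0, 22000.0],
        "law_enf": [0.4, 0.7],
    })
    year = pd.DataFrame({
        "year": [2000, 2001, 2002, 2003],
        "seizures": [500.0, 800.0, 2400.0, 1200.0],
        "price": [25.0, 40.0, 90.0, 60.0],
    })
    return assemble(carcasses, sy, cy, site, year)


def intercept_only_data(k: int = 15, n: int = 50):
    """One record, all covariates zero: the posterior reduces to the
    intercept given k of n illegal carcasses."""
    carc = pd.DataFrame({
        "site_id": ["S1"], "country_id": ["C1"], "region": ["Eastern"],
        "year": [2002], "n_total": [n], "n_illegal": [k],
    })
    sy = pd.DataFrame({"site_id": ["S1"], "year": [2002],
                       "imr": [0.0], "precip": [0.0]})
    cy = pd.DataFrame({"country_id": ["C1"], "year": [2002], "cpi": [0.0]})
    site = pd.DataFrame({"site_id": ["S1"], "pov_dens": [0.0],
                         "law_enf": [0.0], "area": [0.0]})
    year = pd.DataFrame({"year": [2002], "seizures": [0.0], "price": [0.0]})
    data = assemble(carc, sy, cy, site, year, log_covariates=())
    data.standardised = True
    data.standardisation = StandardisationRecord.identity()
    return data


def constant_samples(data, beta=None, sigma=0.5, n_draws=40) -> PosteriorSamples:
    """A degenerate posterior whose every draw is the same parameter point
    (all z deviations zero); handy for closed-form product checks."""
    design = data.design()
    S, Y, C = len(design.site_ids), len(design.years), len(design.country_ids)
    beta = np.zeros(9) if beta is None else np.asarray(beta, float)
    shape = (1, n_draws)
    return PosteriorSamples(
        beta=np.broadcast_to(beta, shape + (9,)).copy(),
        sigma_site=np.full(shape, sigma), sigma_year=np.full(shape, sigma),
        sigma_country=np.full(shape, sigma), lam=np.ones(shape),
        z_site=np.zeros(shape + (S,)), z_year=np.zeros(shape + (Y,)),
        z_country=np.zeros(shape + (C,)),
        site_ids=design.site_ids, years=design.years,
        country_ids=design.country_ids,
        X_site=design.X_site, X_year=design.X_year,
        spec=ModelSpec(), settings=McmcSettings(seed=0, n_chains=1,
                                                n_iterations=2 * n_draws,
                                                n_burnin=n_draws, thin=1),
    )
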