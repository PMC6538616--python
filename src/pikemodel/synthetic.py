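"""Synthetic carcass-monitoring datasets drawn from the model's own
generative process, with known truth for recovery and calibration tests.

The generator mirrors the structure of the ranger-based monitoring data the
model is built for: ~53 sites nested in ~29 countries over 16 years, binomial
counts of illegally killed carcasses whose logit-probability combines eight
covariates with normally distributed site/year/country intercepts, site and
year intercept means themselves linear in level covariates.  Covariates are
drawn directly on the standardised scale (the model never sees anything
else), and a configurable fraction of site-years is deleted to emulate the
unbalanced reporting of real monitoring programmes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import REGIONS, StandardisationRecord, ModelData, assemble

#: default sparse truth: intercept below 0.5 PIKE, poverty density up,
#: law enforcement and national integrity down, ivory price up; the
#: remaining coefficients exactly zero.
DEFAULT_TRUE_BETA = (-0.5, 0.0, 0.0, -0.4, 0.4, -0.4, 0.0, 0.0, 0.6)


@dataclass(frozen=True)
class SyntheticConfig:
    n_sites: int = 53
    n_countries: int = 29
    n_years: int = 16
    start_year: int = 2002
    true_beta: tuple = DEFAULT_TRUE_BETA
    sigma_site: float = 0.5
    sigma_year: float = 0.3
    sigma_country: float = 0.3
    carcass_rate: float = 30.0        # mean carcasses per observed site-year
    dispersion: float = 5.0           # negative-binomial size; inf => Poisson
    missingness_fraction: float = 0.28  # ~607 of 848 site-years observed
    covariate_correlation: float = 0.0  # equicorrelation within a resolution
    seed: int = 0

    def __post_init__(self):
        if not (self.n_sites >= self.n_countries >= 1):
            raise ValueError("need n_sites >= n_countries >= 1")
        if len(self.true_beta) != 9:
            raise ValueError("true_beta must have 9 entries (beta0..beta8)")
        if min(self.sigma_site, self.sigma_year, self.sigma_country) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.carcass_rate <= 0:
            raise ValueError("carcass_rate must be positive")
        if not 0 <= self.missingness_fraction < 1:
            raise ValueError("missingness_fraction must be in [0, 1)")


@dataclass
class CovariateTables:
    """The four covariate tables at their native resolutions."""

    sy: pd.DataFrame
    cy: pd.DataFrame
    site: pd.DataFrame
    year: pd.DataFrame


@dataclass
class SyntheticTruth:
    """A generated dataset paired with the parameters that produced it."""

    config: SyntheticConfig
    data: ModelData
    site_effects: np.ndarray      # realised intercepts, one per site
    year_effects: np.ndarray
    country_effects: np.ndarray
    mu_site: np.ndarray
    mu_year: np.ndarray
    p: np.ndarray                 # true PIKE per retained record

    @property
    def true_beta(self) -> np.ndarray:
        return np.asarray(self.config.true_beta, dtype=float)


def _allocate(n_items: int, n_groups: int) -> np.ndarray:
    """Deterministic as-even-as-possible allocation; remainder to the first
    groups.  Returns the group index of each item."""
    base, rem = divmod(n_items, n_groups)
    counts = np.full(n_groups, base)
    counts[:rem] += 1
    return np.repeat(np.arange(n_groups), counts)


def _correlated_normals(rng, n_rows: int, n_cols: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((n_rows, n_cols))
    if n_cols == 1 or rho == 0.0:
        return z
    cov = np.full((n_cols, n_cols), rho)
    np.fill_diagonal(cov, 1.0)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"covariate correlation {rho} is not positive-definite for "
            f"{n_cols} covariates") from exc
    return z @ chol.T


def _labels(config: SyntheticConfig):
    sites = [f"S{i+1:02d}" for i in range(config.n_sites)]
    countries = [f"C{i+1:02d}" for i in range(config.n_countries)]
    years = list(range(config.start_year, config.start_year + config.n_years))
    return sites, countries, years


def generate_covariates(config: SyntheticConfig,
                        seed: int | None = None) -> CovariateTables:
    """Draw covariates at all four resolutions as standard normals on the
    standardised scale, optionally equicorrelated within each resolution."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sites, countries, years = _labels(config)
    rho = config.covariate_correlation

    sy_vals = _correlated_normals(rng, len(sites) * len(years), 2, rho)
    sy = pd.DataFrame({
        "site_id": np.repeat(sites, len(years)),
        "year": np.tile(years, len(sites)),
        "imr": sy_vals[:, 0], "precip": sy_vals[:, 1],
    })
    cy = pd.DataFrame({
        "country_id": np.repeat(countries, len(years)),
        "year": np.tile(years, len(countries)),
        "cpi": rng.standard_normal(len(countries) * len(years)),
    })
    site_vals = _correlated_normals(rng, len(sites), 3, rho)
    site = pd.DataFrame({
        "site_id": sites, "pov_dens": site_vals[:, 0],
        "law_enf": site_vals[:, 1], "area": site_vals[:, 2],
    })
    year_vals = _correlated_normals(rng, len(years), 2, rho)
    year = pd.DataFrame({"year": years, "seizures": year_vals[:, 0],
                         "price": year_vals[:, 1]})
    return CovariateTables(sy=sy, cy=cy, site=site, year=year)


def generate_dataset(config: SyntheticConfig,
                     seed: int | None = None) -> SyntheticTruth:
    """Generate one dataset: covariates, realised random intercepts,
    binomial carcass counts, and random site-year missingness.

    Exactly reproducible from (config, seed); ``seed`` overrides
    ``config.seed`` when given.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sites, countries, years = _labels(config)
    beta = np.asarray(config.true_beta, dtype=float)

    covs = generate_covariates(config, seed=rng.integers(2**31))
    site_country = _allocate(config.n_sites, config.n_countries)
    country_region = _allocate(config.n_countries, len(REGIONS))

    X_site = covs.site[["pov_dens", "law_enf", "area"]].to_numpy()
    X_year = covs.year[["seizures", "price"]].to_numpy()
    mu_site = X_site @ beta[4:7]
    mu_year = X_year @ beta[7:9]
    site_eff = rng.normal(mu_site, config.sigma_site)
    year_eff = rng.normal(mu_year, config.sigma_year)
    country_eff = rng.normal(0.0, config.sigma_country, config.n_countries)

    # full site x year grid on the standardised scale
    grid = covs.sy.copy()
    s_idx = grid["site_id"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    y_idx = grid["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
    c_idx = site_country[s_idx]
    cpi = covs.cy.set_index(["country_id", "year"])["cpi"]
    grid["country_id"] = np.asarray(countries)[c_idx]
    grid["cpi"] = cpi.loc[list(zip(grid["country_id"], grid["year"]))].to_numpy()

    eta = (beta[0] + beta[1] * grid["precip"].to_numpy()
           + beta[2] * grid["imr"].to_numpy() + beta[3] * grid["cpi"].to_numpy()
           + site_eff[s_idx] + year_eff[y_idx] + country_eff[c_idx])
    p = expit(eta)

    if np.isinf(config.dispersion):
        n_total = rng.poisson(config.carcass_rate, len(grid))
    else:
        k = config.dispersion
        n_total = rng.negative_binomial(k, k / (k + config.carcass_rate), len(grid))
    n_illegal = rng.binomial(n_total, p)

    keep = rng.random(len(grid)) >= config.missingness_fraction
    if not keep.any():
        raise ValueError("missingness removed every site-year")

    carcasses = pd.DataFrame({
        "site_id": grid["site_id"],
        "country_id": grid["country_id"],
        "region": np.asarray(REGIONS)[country_region[c_idx]],
        "year": grid["year"],
        "n_total": n_total,
        "n_illegal": n_illegal,
    })[keep].reset_index(drop=True)

    data = assemble(carcasses, covs.sy, covs.cy, covs.site, covs.year,
                    log_covariates=())
    data.standardised = True
    data.standardisation = StandardisationRecord.identity()
    return SyntheticTruth(
        config=config, data=data,
        site_effects=site_eff, year_effects=year_eff,
        country_effects=country_eff, mu_site=mu_site, mu_year=mu_year,
        p=p[keep],
    )


#: named presets: the default mirrors the monitoring programme's scale,
#: the smaller ones keep end-to-end tests fast
PRESETS: dict[str, SyntheticConfig] = {
    "full_scale": SyntheticConfig(),
    "small": SyntheticConfig(n_sites=8, n_countries=4, n_years=6,
                             missingness_fraction=0.1),
    "tiny": SyntheticConfig(n_sites=4, n_countries=2, n_years=4,
                            missingness_fraction=0.0),
}


def preset(name: str) -> SyntheticConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}") from None
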