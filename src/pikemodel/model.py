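"""The hierarchical Bayesian-lasso binomial-logit model of PIKE and its
MCMC machinery.

Model
-----
For record *i* (one site-year), ``n_illegal_i ~ Binomial(p_i, n_total_i)``
with

``logit(p_i) = b0 + b1*Precip_i + b2*IMR_i + b3*CPI_c[i]
               + a_site[i] + a_year[i] + a_country[i]``

where the random intercepts are normal with level-specific means and shared
per-level standard deviations:

* ``a_site,s  ~ N(b4*PovDens_s + b5*LawEnf_s + b6*Area_s, sigma_site)``
* ``a_year,y  ~ N(b7*Seizures_y + b8*Price_y,            sigma_year)``
* ``a_country ~ N(0, sigma_country)``

Shrinkage: ``b1..b8 ~ Laplace(0, 1/lambda)`` with a Gamma(r, delta)
hyperprior on ``lambda**2`` (the lasso penalty estimated from the data); the
intercept b0 gets a diffuse normal prior and is not penalised.  Gamma(1, 1)
(or optionally uniform) priors sit on the three standard deviations.

Sampler
-------
The posterior is explored with an adaptive Metropolis-within-Gibbs scheme on
a non-centred parameterisation (intercept = mean + sigma * z, z ~ N(0,1)):
a jointly adapted random-walk block for the nine coefficients, vectorised
independent random-walk updates for the z's of each level (sites are
conditionally independent given everything else, and likewise years and
countries), log-scale random walks for the sigmas and lambda.  Proposal
scales adapt by Robbins-Monro only during burn-in, so the retained chain is
a valid Markov chain with the posterior as its invariant distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_io import BETA_NAMES, Design, ModelData
from .errors import ConvergenceWarning, ValidationError

_SCALAR_PARAMS = ("sigma_site", "sigma_year", "sigma_country", "lam")


@dataclass(frozen=True)
class ModelSpec:
    """Structural and prior configuration of the hierarchical lasso model."""

    coefficient_prior: str = "laplace_lasso"   # or "fixed_scale_normal"
    lambda_r: float = 1.0          # gamma hyperprior shape on lambda^2
    lambda_delta: float = 1.0      # gamma hyperprior rate on lambda^2
    lambda_fixed: float | None = None
    sd_prior: str = "gamma"        # or "uniform"
    sd_r: float = 1.0
    sd_delta: float = 1.0
    sd_uniform_upper: float = 20.0
    sigma_fixed: Mapping[str, float] | None = None  # {"site": v, ...}
    normal_prior_scale: float = 1.0  # used by fixed_scale_normal
    beta0_prior_sd: float = 10.0
    lag: int = 0
    imr_mode: str = "site_by_year"
    m_n: float = 0.03              # natural mortality for rate conversion

    def __post_init__(self):
        if self.coefficient_prior not in ("laplace_lasso", "fixed_scale_normal"):
            raise ValueError(f"unknown coefficient_prior "
                             f"{self.coefficient_prior!r}")
        if self.sd_prior not in ("gamma", "uniform"):
            raise ValueError(f"unknown sd_prior {self.sd_prior!r}")
        if self.lambda_r <= 0 or self.lambda_delta <= 0:
            raise ValueError("gamma hyperprior needs r > 0 and delta > 0")
        if not 0 < self.m_n < 1:
            raise ValueError("m_n must lie in (0, 1)")
        if self.lag not in (0, 1, 2):
            raise ValueError("lag must be 0, 1 or 2")

    def fixed_sigma(self, level: str) -> float | None:
        if self.sigma_fixed is None:
            return None
        return self.sigma_fixed.get(level)


@dataclass(frozen=True)
class McmcSettings:
    seed: int
    n_chains: int = 3
    n_iterations: int = 100_000
    n_burnin: int = 50_000
    thin: int = 50

    def __post_init__(self):
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be below n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.draws_per_chain


@dataclass
class ParameterPoint:
    """A complete parameter point on the centred scale (realised
    intercepts, not z-scores); used by the density functions."""

    beta: np.ndarray
    site_effect: np.ndarray
    year_effect: np.ndarray
    country_effect: np.ndarray
    sigma_site: float
    sigma_year: float
    sigma_country: float
    lam: float = 1.0


@dataclass
class PosteriorSamples:
    """Retained MCMC draws organised chain x draw (x parameter).

    Random intercepts are stored as standard-normal deviations ``z``;
    realised intercepts are ``mu(beta) + sigma * z`` with the level design
    matrices stored alongside (see :meth:`site_effects`).
    """

    beta: np.ndarray           # (chains, draws, 9)
    sigma_site: np.ndarray     # (chains, draws)
    sigma_year: np.ndarray
    sigma_country: np.ndarray
    lam: np.ndarray
    z_site: np.ndarray         # (chains, draws, S)
    z_year: np.ndarray
    z_country: np.ndarray
    site_ids: tuple
    years: tuple
    country_ids: tuple
    X_site: np.ndarray
    X_year: np.ndarray
    spec: ModelSpec
    settings: McmcSettings
    data_digest: str = ""
    accept_rates: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None
    converged: bool | None = None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        """Total retained draws pooled over chains."""
        return self.beta.shape[0] * self.beta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled over chains: (total_draws, ...)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def site_effects(self) -> np.ndarray:
        """Realised site intercepts (chains, draws, S) = mu_site + sigma*z."""
        mu = np.einsum("cdk,sk->cds", self.beta[..., 4:7], self.X_site)
        return mu + self.sigma_site[..., None] * self.z_site

    def year_effects(self) -> np.ndarray:
        mu = np.einsum("cdk,yk->cdy", self.beta[..., 7:9], self.X_year)
        return mu + self.sigma_year[..., None] * self.z_year

    def country_effects(self) -> np.ndarray:
        return self.sigma_country[..., None] * self.z_country

    def to_inference_data(self, include_intercepts: bool = False):
        """Package the draws as an :class:`arviz.InferenceData`."""
        import arviz as az

        post = {f"beta[{n}]": self.beta[..., i]
                for i, n in enumerate(BETA_NAMES)}
        for p in _SCALAR_PARAMS:
            post[p] = getattr(self, p)
        if include_intercepts:
            post["site_effect"] = self.site_effects()
            post["year_effect"] = self.year_effects()
            post["country_effect"] = self.country_effects()
        return az.from_dict(posterior=post)

    def save(self, path) -> None:
        arrays = {k: getattr(self, k) for k in
                  ("beta", "sigma_site", "sigma_year", "sigma_country", "lam",
                   "z_site", "z_year", "z_country", "X_site", "X_year")}
        meta = json.dumps({
            "site_ids": list(self.site_ids), "years": list(self.years),
            "country_ids": list(self.country_ids),
            "spec": asdict(self.spec), "settings": asdict(self.settings),
            "data_digest": self.data_digest,
        })
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @staticmethod
    def load(path) -> "PosteriorSamples":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            arrays = {k: z[k] for k in z.files if k != "_meta"}
        spec_kw = meta["spec"]
        if spec_kw.get("sigma_fixed") is not None:
            spec_kw["sigma_fixed"] = dict(spec_kw["sigma_fixed"])
        return PosteriorSamples(
            site_ids=tuple(meta["site_ids"]), years=tuple(meta["years"]),
            country_ids=tuple(meta["country_ids"]),
            spec=ModelSpec(**spec_kw), settings=McmcSettings(**meta["settings"]),
            data_digest=meta["data_digest"], **arrays)


# ---------------------------------------------------------------------------
# densities

def _binom_logpmf(k, n, eta):
    """Binomial log-pmf at success probability expit(eta), including the
    binomial coefficient; exactly zero for n = 0."""
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + k * eta - n * np.logaddexp(0.0, eta))


def linear_predictor(point: ParameterPoint, design: Design) -> np.ndarray:
    eta = (point.beta[0] + design.X_rec @ point.beta[1:4]
           + point.site_effect[design.site_idx]
           + point.year_effect[design.year_idx]
           + point.country_effect[design.country_idx])
    return eta


def log_likelihood(point: ParameterPoint, data: ModelData | Design,
                   imr_mode: str = "site_by_year") -> float:
    """Binomial log-likelihood of a complete parameter point.

    Records with ``n_total = 0`` contribute exactly zero.  Raises on a
    non-finite linear predictor.
    """
    design = data if isinstance(data, Design) else data.design(imr_mode)
    eta = linear_predictor(point, design)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return float(np.sum(_binom_logpmf(design.k, design.n, eta)))


def _norm_logpdf(x, mean, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _gamma_logpdf(x, r, delta):
    return r * np.log(delta) - gammaln(r) + (r - 1) * np.log(x) - delta * x


def log_prior(point: ParameterPoint, spec: ModelSpec,
              data: ModelData | Design, imr_mode: str | None = None) -> float:
    """Joint log-prior density of a complete parameter point.

    Sum of: Laplace(0, 1/lambda) on b1..b8 (or fixed-scale normals), the
    gamma hyperprior on lambda^2, the diffuse normal on b0, gamma or uniform
    densities on the three sigmas, and normal densities of the realised
    intercepts around their hierarchical means.  Non-positive sigma or
    lambda yields -inf.
    """
    design = data if isinstance(data, Design) else data.design(
        imr_mode or spec.imr_mode)
    sig = (point.sigma_site, point.sigma_year, point.sigma_country)
    if min(sig) <= 0 or (spec.coefficient_prior == "laplace_lasso"
                         and point.lam <= 0):
        return -np.inf

    beta = np.asarray(point.beta, dtype=float)
    lp = _norm_logpdf(beta[0], 0.0, spec.beta0_prior_sd)
    if spec.coefficient_prior == "laplace_lasso":
        lam = point.lam
        lp += np.sum(np.log(lam / 2.0) - lam * np.abs(beta[1:]))
        if spec.lambda_fixed is None:
            lp += _gamma_logpdf(lam ** 2, spec.lambda_r, spec.lambda_delta)
    else:
        lp += np.sum(_norm_logpdf(beta[1:], 0.0, spec.normal_prior_scale))

    for level, s in zip(("site", "year", "country"), sig):
        if spec.fixed_sigma(level) is not None:
            continue
        if spec.sd_prior == "gamma":
            lp += _gamma_logpdf(s, spec.sd_r, spec.sd_delta)
        else:
            if s >= spec.sd_uniform_upper:
                return -np.inf
            lp += -np.log(spec.sd_uniform_upper)

    mu_site = design.X_site @ beta[4:7]
    mu_year = design.X_year @ beta[7:9]
    lp += np.sum(_norm_logpdf(point.site_effect, mu_site, point.sigma_site))
    lp += np.sum(_norm_logpdf(point.year_effect, mu_year, point.sigma_year))
    lp += np.sum(_norm_logpdf(point.country_effect, 0.0, point.sigma_country))
    return float(lp)


# ---------------------------------------------------------------------------
# sampler

def _ll_vec(k, n, eta):
    # binomial log-pmf without the eta-independent combinatorial constant
    return k * eta - n * np.logaddexp(0.0, eta)


class _ChainState:
    """One chain of the adaptive Metropolis-within-Gibbs sampler."""

    def __init__(self, design: Design, spec: ModelSpec, rng: np.random.Generator):
        self.d = design
        self.spec = spec
        self.rng = rng
        S, Y, C = len(design.site_ids), len(design.years), len(design.country_ids)

        self.beta = rng.normal(0.0, 0.3, 9)
        self.z_s = rng.normal(0.0, 0.3, S)
        self.z_y = rng.normal(0.0, 0.3, Y)
        self.z_c = rng.normal(0.0, 0.3, C)
        self.sig = {}
        for level in ("site", "year", "country"):
            fx = spec.fixed_sigma(level)
            self.sig[level] = float(fx) if fx is not None else float(
                rng.uniform(0.3, 1.2))
        if spec.coefficient_prior != "laplace_lasso":
            self.lam = 1.0
        elif spec.lambda_fixed is not None:
            self.lam = float(spec.lambda_fixed)
        else:
            self.lam = float(rng.uniform(0.6, 1.6))

        # adaptation state
        self.ls_beta = np.log(0.1)
        self.ls_z = {lvl: np.full(n, np.log(0.5))
                     for lvl, n in (("site", S), ("year", Y), ("country", C))}
        self.ls_sig = {lvl: np.log(0.3) for lvl in ("site", "year", "country")}
        self.ls_tr = {k: np.log(0.3) for k in
                      ("intercept_country", "intercept_site",
                       "intercept_year", "site", "year")}
        self.ls_b1 = np.full(4, np.log(0.2))
        self.ls_resc = {lvl: np.log(0.3) for lvl in ("site", "year", "country")}
        self.ls_lam = np.log(0.5)
        self.chol = np.eye(9)
        self._bsum = np.zeros(9)
        self._bsumsq = np.zeros((9, 9))
        self._bcount = 0

        self._refresh_eta()

    # -- linear predictor bookkeeping ------------------------------------
    def _mu(self, beta):
        return self.d.X_site @ beta[4:7], self.d.X_year @ beta[7:9]

    def _eta_for(self, beta, z_s=None, z_y=None, z_c=None):
        z_s = self.z_s if z_s is None else z_s
        z_y = self.z_y if z_y is None else z_y
        z_c = self.z_c if z_c is None else z_c
        mu_s, mu_y = self._mu(beta)
        d = self.d
        return (beta[0] + d.X_rec @ beta[1:4]
                + (mu_s + self.sig["site"] * z_s)[d.site_idx]
                + (mu_y + self.sig["year"] * z_y)[d.year_idx]
                + (self.sig["country"] * z_c)[d.country_idx])

    def _refresh_eta(self):
        self.eta = self._eta_for(self.beta)
        self.ll = _ll_vec(self.d.k, self.d.n, self.eta)
        self.ll_sum = self.ll.sum()

    # -- priors (constants that cancel are dropped) ----------------------
    def _beta_logprior(self, beta):
        lp = -0.5 * (beta[0] / self.spec.beta0_prior_sd) ** 2
        if self.spec.coefficient_prior == "laplace_lasso":
            lp -= self.lam * np.abs(beta[1:]).sum()
        else:
            lp -= 0.5 * np.sum((beta[1:] / self.spec.normal_prior_scale) ** 2)
        return lp

    def _sigma_logprior(self, s):
        # includes the log-scale sampling Jacobian log(s)
        if self.spec.sd_prior == "gamma":
            return (self.spec.sd_r - 1) * np.log(s) - self.spec.sd_delta * s + np.log(s)
        if s >= self.spec.sd_uniform_upper:
            return -np.inf
        return np.log(s)

    def _lambda_logtarget(self, lam):
        # Gamma(r, delta) prior on lam^2 mapped to u = log(lam), plus the
        # Laplace normalising terms of b1..b8
        spec = self.spec
        return ((spec.lambda_r - 1) * 2 * np.log(lam) - spec.lambda_delta * lam ** 2
                + 2 * np.log(lam)  # Jacobian d(lam^2)/d(log lam) = 2 lam^2
                + 8 * np.log(lam) - lam * np.abs(self.beta[1:]).sum())

    # -- updates ----------------------------------------------------------
    def update_beta(self):
        prop = self.beta + np.exp(self.ls_beta) * (
            self.chol @ self.rng.standard_normal(9))
        eta_p = self._eta_for(prop)
        ll_p = _ll_vec(self.d.k, self.d.n, eta_p)
        delta = (ll_p.sum() - self.ll_sum
                 + self._beta_logprior(prop) - self._beta_logprior(self.beta))
        accept = np.log(self.rng.random()) < delta
        if accept:
            self.beta = prop
            self.eta, self.ll, self.ll_sum = eta_p, ll_p, ll_p.sum()
        return float(accept)

    def update_beta_singles(self):
        """Componentwise random-walk refreshes of b0..b3 (the intercept and
        record-level coefficients), which the joint block moves slowly; the
        linear predictor updates incrementally."""
        acc = np.zeros(4)
        for j in range(4):
            delta = np.exp(self.ls_b1[j]) * self.rng.standard_normal()
            eta_p = self.eta + (delta if j == 0 else
                                self.d.X_rec[:, j - 1] * delta)
            ll_p = _ll_vec(self.d.k, self.d.n, eta_p)
            beta_p = self.beta.copy()
            beta_p[j] += delta
            d = (ll_p.sum() - self.ll_sum
                 + self._beta_logprior(beta_p) - self._beta_logprior(self.beta))
            if np.log(self.rng.random()) < d:
                self.beta = beta_p
                self.eta, self.ll, self.ll_sum = eta_p, ll_p, ll_p.sum()
                acc[j] = 1.0
        return acc

    def _update_z(self, level, z, idx, sigma):
        step = np.exp(self.ls_z[level]) * self.rng.standard_normal(len(z))
        eta_p = self.eta + (sigma * step)[idx]
        ll_p = _ll_vec(self.d.k, self.d.n, eta_p)
        dll = np.bincount(idx, weights=ll_p - self.ll, minlength=len(z))
        dpr = -0.5 * ((z + step) ** 2 - z ** 2)
        acc = np.log(self.rng.random(len(z))) < dll + dpr
        if acc.any():
            z[acc] += step[acc]
            acc_rec = acc[idx]
            # each record belongs to exactly one level unit, so per-unit
            # acceptances splice record-wise
            self.eta = np.where(acc_rec, eta_p, self.eta)
            self.ll = np.where(acc_rec, ll_p, self.ll)
            self.ll_sum = self.ll.sum()
        return acc.astype(float)

    def _update_sigma(self, level, z, idx):
        if self.spec.fixed_sigma(level) is not None:
            return None
        s = self.sig[level]
        s_p = s * np.exp(np.exp(self.ls_sig[level]) * self.rng.standard_normal())
        eta_p = self.eta + ((s_p - s) * z)[idx]
        ll_p = _ll_vec(self.d.k, self.d.n, eta_p)
        delta = (ll_p.sum() - self.ll_sum
                 + self._sigma_logprior(s_p) - self._sigma_logprior(s))
        accept = np.log(self.rng.random()) < delta
        if accept:
            self.sig[level] = float(s_p)
            self.eta, self.ll, self.ll_sum = eta_p, ll_p, ll_p.sum()
        return float(accept)

    def _translate(self, which: str):
        """Likelihood-invariant shear move between coefficients and the
        intercept deviations that can absorb them.

        Shifting the intercept and subtracting the same amount from the
        country deviations (or shifting the level-mean coefficients and
        compensating the corresponding z's) leaves the linear predictor
        unchanged, so only the priors enter the acceptance ratio.  These
        moves decouple the coefficients from the random-intercept block and
        are essential for mixing in this hierarchical posterior.
        """
        rng, spec = self.rng, self.spec
        beta_p = self.beta.copy()
        if which.startswith("intercept"):
            delta = np.exp(self.ls_tr[which]) * rng.standard_normal()
            beta_p[0] += delta
            lvl = which.split("_")[1]
            z_old = {"country": self.z_c, "site": self.z_s,
                     "year": self.z_y}[lvl]
            z_new = z_old - delta / self.sig[lvl]
        elif which == "site":
            delta = np.exp(self.ls_tr["site"]) * rng.standard_normal(3)
            beta_p[4:7] += delta
            z_new = self.z_s - (self.d.X_site @ delta) / self.sig["site"]
            z_old = self.z_s
        else:  # "year"
            delta = np.exp(self.ls_tr["year"]) * rng.standard_normal(2)
            beta_p[7:9] += delta
            z_new = self.z_y - (self.d.X_year @ delta) / self.sig["year"]
            z_old = self.z_y
        dpr = (self._beta_logprior(beta_p) - self._beta_logprior(self.beta)
               - 0.5 * (np.sum(z_new ** 2) - np.sum(z_old ** 2)))
        accept = np.log(rng.random()) < dpr
        if accept:
            self.beta = beta_p
            if which == "intercept_country":
                self.z_c = z_new
            elif which in ("intercept_site", "site"):
                self.z_s = z_new
            else:  # "intercept_year" or "year"
                self.z_y = z_new
        return float(accept)

    def _rescale_sigma(self, level, z):
        """Likelihood-invariant scale move: multiply sigma by e^u and divide
        the level's z by e^u, keeping the realised intercepts sigma*z fixed.

        Decouples the level standard deviation from its deviations (the
        remaining funnel after non-centring).  With a symmetric proposal on
        u the acceptance ratio is the prior change plus the Jacobian
        u*(1 - n_z).
        """
        if self.spec.fixed_sigma(level) is not None:
            return None
        u = np.exp(self.ls_resc[level]) * self.rng.standard_normal()
        s = self.sig[level]
        s_p = s * np.exp(u)
        z_p = z * np.exp(-u)
        delta = (self._sigma_logprior(s_p) - self._sigma_logprior(s)
                 - len(z) * u - 0.5 * (np.sum(z_p ** 2) - np.sum(z ** 2)))
        accept = np.log(self.rng.random()) < delta
        if accept:
            self.sig[level] = float(s_p)
            z *= np.exp(-u)
        return float(accept)

    def update_lambda(self):
        if (self.spec.coefficient_prior != "laplace_lasso"
                or self.spec.lambda_fixed is not None):
            return None
        lam_p = self.lam * np.exp(np.exp(self.ls_lam) * self.rng.standard_normal())
        delta = self._lambda_logtarget(lam_p) - self._lambda_logtarget(self.lam)
        accept = np.log(self.rng.random()) < delta
        if accept:
            self.lam = float(lam_p)
        return float(accept)

    def sweep(self, t: int, adapting: bool):
        d = self.d
        acc_b = self.update_beta()
        acc_b1 = self.update_beta_singles()
        acc_zs = self._update_z("site", self.z_s, d.site_idx, self.sig["site"])
        acc_zy = self._update_z("year", self.z_y, d.year_idx, self.sig["year"])
        acc_zc = self._update_z("country", self.z_c, d.country_idx,
                                self.sig["country"])
        acc_sig = {lvl: self._update_sigma(lvl, z, idx) for lvl, z, idx in
                   (("site", self.z_s, d.site_idx),
                    ("year", self.z_y, d.year_idx),
                    ("country", self.z_c, d.country_idx))}
        acc_resc = {lvl: self._rescale_sigma(lvl, z) for lvl, z in
                    (("site", self.z_s), ("year", self.z_y),
                     ("country", self.z_c))}
        acc_lam = self.update_lambda()
        acc_tr = {k: self._translate(k) for k in self.ls_tr}

        if adapting:
            gam = (t + 10.0) ** -0.6
            self.ls_beta += gam * (acc_b - 0.25)
            self.ls_b1 += gam * (acc_b1 - 0.44)
            for k, acc in acc_tr.items():
                self.ls_tr[k] += gam * (acc - 0.35)
            for lvl, acc in (("site", acc_zs), ("year", acc_zy),
                             ("country", acc_zc)):
                self.ls_z[lvl] += gam * (acc - 0.44)
            for lvl, acc in acc_sig.items():
                if acc is not None:
                    self.ls_sig[lvl] += gam * (acc - 0.44)
            for lvl, acc in acc_resc.items():
                if acc is not None:
                    self.ls_resc[lvl] += gam * (acc - 0.44)
            if acc_lam is not None:
                self.ls_lam += gam * (acc_lam - 0.44)
            # running covariance of beta for the joint proposal
            self._bsum += self.beta
            self._bsumsq += np.outer(self.beta, self.beta)
            self._bcount += 1
            if self._bcount >= 200 and t % 100 == 0:
                m = self._bsum / self._bcount
                cov = self._bsumsq / self._bcount - np.outer(m, m)
                cov = cov * (2.38 ** 2 / 9) + 1e-9 * np.eye(9)
                try:
                    self.chol = np.linalg.cholesky(cov)
                    self.ls_beta = 0.0
                except np.linalg.LinAlgError:
                    pass
        return acc_b

    def snapshot(self):
        return (self.beta.copy(), self.sig["site"], self.sig["year"],
                self.sig["country"], self.lam, self.z_s.copy(),
                self.z_y.copy(), self.z_c.copy())


def fit(data: ModelData, spec: ModelSpec, settings: McmcSettings,
        compute_diagnostics: bool = True,
        rhat_threshold: float = 1.01, ess_threshold: float = 400.0) -> PosteriorSamples:
    """Fit the hierarchical lasso model by MCMC.

    Requires standardised data.  Runs ``settings.n_chains`` independent
    chains from overdispersed starts; retains every ``thin``-th draw after
    burn-in.  Convergence (split R-hat and ESS on the scalar parameters) is
    assessed with arviz; a failing fit completes but carries
    ``converged=False`` and emits a :class:`ConvergenceWarning`.
    """
    if not data.standardised:
        raise ValidationError("fit requires standardised data; call "
                              "data_io.standardize first")
    design = data.design(spec.imr_mode)
    if np.all(design.n == 0):
        raise ValidationError("degenerate data: every record has n_total = 0")

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    n_keep = settings.draws_per_chain
    S, Y, C = len(design.site_ids), len(design.years), len(design.country_ids)
    out = {
        "beta": np.empty((settings.n_chains, n_keep, 9)),
        "sigma_site": np.empty((settings.n_chains, n_keep)),
        "sigma_year": np.empty((settings.n_chains, n_keep)),
        "sigma_country": np.empty((settings.n_chains, n_keep)),
        "lam": np.empty((settings.n_chains, n_keep)),
        "z_site": np.empty((settings.n_chains, n_keep, S)),
        "z_year": np.empty((settings.n_chains, n_keep, Y)),
        "z_country": np.empty((settings.n_chains, n_keep, C)),
    }
    accept = []
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        chain = _ChainState(design, spec, rng)
        kept = 0
        n_acc = 0.0
        for t in range(settings.n_iterations):
            n_acc += chain.sweep(t, adapting=t < settings.n_burnin)
            post = t - settings.n_burnin + 1
            if post > 0 and post % settings.thin == 0 and kept < n_keep:
                (out["beta"][c, kept], out["sigma_site"][c, kept],
                 out["sigma_year"][c, kept], out["sigma_country"][c, kept],
                 out["lam"][c, kept], out["z_site"][c, kept],
                 out["z_year"][c, kept], out["z_country"][c, kept]) = chain.snapshot()
                kept += 1
        accept.append(n_acc / settings.n_iterations)

    samples = PosteriorSamples(
        site_ids=design.site_ids, years=design.years,
        country_ids=design.country_ids, X_site=design.X_site,
        X_year=design.X_year, spec=spec, settings=settings,
        data_digest=data.digest(),
        accept_rates={"beta_block": accept}, **out)

    if compute_diagnostics and settings.n_chains >= 2 and n_keep >= 4:
        samples.diagnostics = diagnostics_table(samples)
        free = samples.diagnostics["sampled"]
        ok = samples.diagnostics[free]
        samples.converged = bool((ok["rhat"] < rhat_threshold).all()
                                 and (ok["ess"] > ess_threshold).all())
        if not samples.converged:
            warnings.warn(
                "MCMC convergence thresholds not met "
                f"(max R-hat {ok['rhat'].max():.3f}, "
                f"min ESS {ok['ess'].min():.0f}); treat estimates with care",
                ConvergenceWarning)
    return samples


# ---------------------------------------------------------------------------
# convergence diagnostics (arviz wrappers)

def _as_chain_array(obj, name: str | None) -> np.ndarray:
    if isinstance(obj, PosteriorSamples):
        if name is None:
            raise ValueError("need a parameter name for PosteriorSamples input")
        if name.startswith("beta["):
            i = BETA_NAMES.index(name[5:-1])
            return obj.beta[..., i]
        return getattr(obj, name)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    return arr


def rhat(obj, name: str | None = None):
    """Rank-normalised split-chain Gelman-Rubin statistic.

    Accepts a (chains, draws) array or a :class:`PosteriorSamples` (then
    returns a Series over all scalar parameters when ``name`` is None).
    Requires at least two chains of at least four draws.
    """
    import arviz as az

    if isinstance(obj, PosteriorSamples) and name is None:
        return diagnostics_table(obj)["rhat"]
    arr = _as_chain_array(obj, name)
    if arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("R-hat needs >= 2 chains with >= 4 draws each")
    return float(az.rhat(az.convert_to_dataset(arr))["x"].values)


def effective_sample_size(obj, name: str | None = None):
    """Autocorrelation-adjusted effective sample size (arviz "bulk" ESS).

    A constant (zero-variance) chain is reported as 0.
    """
    import arviz as az

    if isinstance(obj, PosteriorSamples) and name is None:
        return diagnostics_table(obj)["ess"]
    arr = _as_chain_array(obj, name)
    if arr.shape[0] < 1 or arr.shape[1] < 4:
        raise ValueError("ESS needs chains of at least 4 draws")
    if np.ptp(arr) == 0:
        return 0.0
    return float(az.ess(az.convert_to_dataset(arr))["x"].values)


def diagnostics_table(samples: PosteriorSamples) -> pd.DataFrame:
    """R-hat and ESS per scalar parameter (betas, sigmas, lambda).

    Parameters held fixed by the spec are flagged ``sampled=False`` and get
    NaN diagnostics.
    """
    spec = samples.spec
    rows = []
    for i, n in enumerate(BETA_NAMES):
        rows.append((f"beta[{n}]", samples.beta[..., i], True))
    for level in ("site", "year", "country"):
        rows.append((f"sigma_{level}", getattr(samples, f"sigma_{level}"),
                     spec.fixed_sigma(level) is None))
    rows.append(("lam", samples.lam,
                 spec.coefficient_prior == "laplace_lasso"
                 and spec.lambda_fixed is None))
    recs = []
    for name, arr, sampled in rows:
        if sampled and np.ptp(arr) > 0:
            recs.append((name, rhat(arr), effective_sample_size(arr), sampled))
        else:
            recs.append((name, np.nan, np.nan, False))
    df = pd.DataFrame(recs, columns=["parameter", "rhat", "ess", "sampled"])
    return df.set_index("parameter")
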