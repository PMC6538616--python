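"""Posterior products: PIKE predictions, the PIKE-to-poaching-rate
conversion, and annual continental/regional rate summaries.

The conversion assumes a constant natural mortality rate ``m_n`` (default
0.03): if a proportion PIKE of all carcasses found died illegally, the
annual poaching mortality of the living population is
``m_p = PIKE * m_n / (1 - PIKE)``, a strictly increasing and uncapped map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import ModelData
from .errors import ValidationError
from .model import PosteriorSamples


def predict_pike(samples: PosteriorSamples, data: ModelData,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-draw, per-record PIKE: (total_draws, n_records) in (0, 1).

    In-sample site/year/country levels reuse their fitted intercept
    deviations; levels unseen at fit time get fresh standard-normal
    deviations per draw (their means still follow the level covariates), so
    an ``rng`` is required whenever such levels occur.
    """
    design = data.design(samples.spec.imr_mode)
    beta = samples.flat("beta")              # (D, 9)
    D = beta.shape[0]

    def level_z(flat_name, fit_ids, data_ids):
        z_fit = samples.flat(flat_name)
        pos = {l: i for i, l in enumerate(fit_ids)}
        unseen = [l for l in data_ids if l not in pos]
        z = np.empty((D, len(data_ids)))
        for j, l in enumerate(data_ids):
            if l in pos:
                z[:, j] = z_fit[:, pos[l]]
        if unseen:
            if rng is None:
                raise ValidationError(
                    f"levels {unseen} were not in the fitted data; pass an "
                    "rng to draw fresh intercepts")
            cols = [j for j, l in enumerate(data_ids) if l not in pos]
            z[:, cols] = rng.standard_normal((D, len(cols)))
        return z

    z_s = level_z("z_site", samples.site_ids, design.site_ids)
    z_y = level_z("z_year", samples.years, design.years)
    z_c = level_z("z_country", samples.country_ids, design.country_ids)

    sig_s = samples.flat("sigma_site")[:, None]
    sig_y = samples.flat("sigma_year")[:, None]
    sig_c = samples.flat("sigma_country")[:, None]
    site_eff = beta[:, 4:7] @ design.X_site.T + sig_s * z_s
    year_eff = beta[:, 7:9] @ design.X_year.T + sig_y * z_y
    country_eff = sig_c * z_c

    eta = (beta[:, [0]] + beta[:, 1:4] @ design.X_rec.T
           + site_eff[:, design.site_idx]
           + year_eff[:, design.year_idx]
           + country_eff[:, design.country_idx])
    return expit(eta)


def pike_to_rate(pike, m_n: float = 0.03):
    """Convert PIKE to an annual poaching mortality rate.

    ``m_p = pike * m_n / (1 - pike)``; undefined at pike = 1 (raises).
    """
    if not 0 < m_n < 1:
        raise ValueError("m_n must lie in (0, 1)")
    p = np.asarray(pike, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("PIKE must lie in [0, 1); the conversion is "
                         "undefined at 1")
    out = p * m_n / (1.0 - p)
    return float(out) if np.isscalar(pike) else out


def rate_to_pike(rate, m_n: float = 0.03):
    """Inverse of :func:`pike_to_rate`: PIKE = m_p / (m_p + m_n)."""
    if not 0 < m_n < 1:
        raise ValueError("m_n must lie in (0, 1)")
    r = np.asarray(rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    out = r / (r + m_n)
    return float(out) if np.isscalar(rate) else out


def _annual_summary(rates: np.ndarray, years: np.ndarray, year_per_record,
                    scope: str, m_n: float) -> pd.DataFrame:
    """Per draw: median across the records of each year; then median and
    5%/95% quantiles across draws."""
    rows = []
    for y in years:
        cols = np.flatnonzero(year_per_record == y)
        per_draw = np.median(rates[:, cols], axis=1)
        lo, med, hi = np.quantile(per_draw, [0.05, 0.5, 0.95])
        rows.append((scope, int(y), med, lo, hi, m_n, len(cols)))
    return pd.DataFrame(rows, columns=["scope", "year", "median", "ci_low",
                                       "ci_high", "m_n", "n_sites"])


def continental_rate_estimated(samples: PosteriorSamples, data: ModelData,
                               m_n: float = 0.03,
                               pike: np.ndarray | None = None,
                               rng: np.random.Generator | None = None,
                               scope: str = "continental") -> pd.DataFrame:
    """Model-based annual poaching rates: per draw, site-by-year PIKE is
    converted to rates and the median across the sites observed in each year
    is taken; the annual median and equal-tailed 90% interval are then read
    across draws.
    """
    if pike is None:
        pike = predict_pike(samples, data, rng=rng)
    rates = pike_to_rate(pike, m_n)
    year_per_record = data.records["year"].to_numpy()
    return _annual_summary(rates, data.years, year_per_record, scope, m_n)


def continental_rate_observed(data: ModelData, m_n: float = 0.03) -> pd.DataFrame:
    """Observed annual rates: carcasses summed over all sites per year,
    PIKE_obs = sum(n_illegal)/sum(n_total), then the rate conversion.

    Years with no carcasses, or with PIKE_obs = 1 (conversion undefined),
    are reported with NaN rate.  Caveat: sites finding more carcasses
    dominate these pooled values, biasing them toward well-sampled sites.
    """
    g = data.records.groupby("year")[["n_illegal", "n_total"]].sum()
    tot = g["n_total"].to_numpy(float)
    ill = g["n_illegal"].to_numpy(float)
    pike = np.where(tot > 0, ill / np.maximum(tot, 1.0), np.nan)
    ok = np.isfinite(pike) & (pike < 1)
    rate = np.full_like(pike, np.nan)
    rate[ok] = pike[ok] * m_n / (1.0 - pike[ok])
    return pd.DataFrame({"year": g.index.to_numpy(int), "pike_obs": pike,
                         "rate": rate, "m_n": m_n})


def regional_rates(samples: PosteriorSamples, data: ModelData, region: str,
                   m_n: float = 0.03,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """As :func:`continental_rate_estimated`, restricted to one region."""
    mask = data.records["region"] == region
    if not mask.any():
        raise ValidationError(f"no records in region {region!r}")
    sub = ModelData(records=data.records[mask].reset_index(drop=True),
                    sy_table=data.sy_table, cy_table=data.cy_table,
                    site_table=data.site_table, year_table=data.year_table,
                    standardised=data.standardised,
                    standardisation=data.standardisation, lag=data.lag,
                    log_covariates=data.log_covariates)
    return continental_rate_estimated(samples, sub, m_n=m_n, rng=rng,
                                      scope=f"region:{region}")
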