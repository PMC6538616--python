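"""Counterfactual conservation-target analysis.

Each covariate in turn is overwritten everywhere with its most
elephant-friendly observed value (the observed extremum that minimises that
covariate's posterior-mean contribution to the linear predictor), poaching
rates are re-predicted from the posterior draws, and the pooled annual
medians are compared with a no-intervention baseline.  Precipitation is not
an interventable covariate: it proxies variation in natural mortality, so it
is held at its average in every counterfactual and in the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_io import (ALL_COVARIATES, COUNTRY_YEAR_COVS, SITE_COVS,
                      SITE_YEAR_COVS, YEAR_COVS, ModelData, assemble,
                      _CARCASS_COLS)
from .errors import ValidationError
from .model import PosteriorSamples
from .products import pike_to_rate, predict_pike

#: covariates that may be intervened on (precipitation is excluded; it is
#: averaged out instead)
INTERVENABLE = tuple(c for c in ALL_COVARIATES if c != "precip")


@dataclass(frozen=True)
class InterventionScenario:
    covariate_name: str
    target_value: float          # on the covariate's natural scale
    provenance: str = ""

    def __post_init__(self):
        if self.covariate_name not in INTERVENABLE:
            raise ValueError(
                f"{self.covariate_name!r} is not an interventable covariate "
                f"(choose from {INTERVENABLE})")
        if not np.isfinite(self.target_value):
            raise ValueError("target_value must be finite")


def _covariate_frame(data: ModelData, name: str) -> tuple[pd.DataFrame, str]:
    """The native table holding ``name`` and a label template for rows."""
    if name in SITE_YEAR_COVS:
        return data.sy_table, "site {site_id}, year {year}"
    if name in COUNTRY_YEAR_COVS:
        return data.cy_table, "country {country_id}, year {year}"
    if name in SITE_COVS:
        return data.site_table, "site {site_id}"
    if name in YEAR_COVS:
        return data.year_table, "year {year}"
    raise ValidationError(f"unknown covariate {name!r}")


def best_observed_values(data: ModelData,
                         samples: PosteriorSamples) -> list[InterventionScenario]:
    """The most elephant-friendly observed value of each interventable
    covariate: a brute scan over observed values for the one minimising the
    posterior-mean linear-predictor contribution (minimum for positively
    associated covariates, maximum for negatively associated ones).

    Values are reported on the data's stored (natural) scale together with
    the site/country/year where they were observed.
    """
    from .data_io import BETA_NAMES

    beta_mean = samples.flat("beta").mean(axis=0)
    record = data.standardisation
    scenarios = []
    for name in INTERVENABLE:
        table, label = _covariate_frame(data, name)
        values = table[name].to_numpy(float)
        if data.standardised:
            std = values
            natural = record.inverse(name, values) if record is not None else values
        else:
            std = record.transform(name, values) if record is not None else values
            natural = values
        contrib = beta_mean[BETA_NAMES.index(name)] * std
        i = int(np.argmin(contrib))
        row = table.iloc[i].to_dict()
        if "year" in row:
            row["year"] = int(row["year"])
        scenarios.append(InterventionScenario(
            covariate_name=name, target_value=float(np.asarray(natural)[i]),
            provenance=label.format(**row)))
    return scenarios


def _overwrite(data: ModelData, name: str | None, value: float | None,
               average_precip: bool = True) -> ModelData:
    """Standardised copy of the data with one covariate column overwritten
    everywhere (at its native resolution) and precipitation averaged."""
    sy, cy, site, year = (data.sy_table.copy(), data.cy_table.copy(),
                          data.site_table.copy(), data.year_table.copy())
    tables = {"sy": sy, "cy": cy, "site": site, "year": year}
    if average_precip:
        sy["precip"] = sy["precip"].mean()
    if name is not None:
        std_value = value
        if data.standardised and data.standardisation is not None:
            # scenarios carry natural-scale values; map onto the fitted scale
            std_value = float(data.standardisation.transform(name, value))
        for tab in tables.values():
            if name in tab.columns:
                tab[name] = std_value
    out = assemble(data.records[list(_CARCASS_COLS)], sy, cy, site, year,
                   log_covariates=data.log_covariates)
    out.standardised = data.standardised
    out.standardisation = data.standardisation
    out.lag = data.lag
    return out


@dataclass
class InterventionResult:
    scenario: InterventionScenario | None     # None = baseline
    annual: pd.DataFrame                      # year, median, ci_low, ci_high
    pooled_median: float
    pooled_ci_low: float
    pooled_ci_high: float

    @property
    def name(self) -> str:
        return "baseline" if self.scenario is None else self.scenario.covariate_name


def simulate_intervention(samples: PosteriorSamples, data: ModelData,
                          scenario: InterventionScenario | None,
                          year_range: tuple[int, int] | None = None,
                          m_n: float = 0.03) -> InterventionResult:
    """Re-predict poaching rates with one covariate overwritten everywhere.

    Random-intercept deviations keep their posterior draws; only the
    fixed-covariate contributions (including the hierarchical level means)
    change.  Precipitation is held at its across-sites-and-years average,
    both here and in the baseline (``scenario=None``).

    Per draw, site-by-year PIKE is converted to rates and annual medians
    across sites taken; the pooled summary is the distribution, across
    draws, of each draw's median annual value within ``year_range``.
    """
    mod = _overwrite(data,
                     None if scenario is None else scenario.covariate_name,
                     None if scenario is None else scenario.target_value)
    years = mod.years
    if year_range is not None:
        lo, hi = year_range
        keep = (mod.records["year"] >= lo) & (mod.records["year"] <= hi)
        if not keep.any():
            raise ValidationError(f"no records in year range {year_range}")
        mod = replace(mod, records=mod.records[keep].reset_index(drop=True))
        years = mod.years

    pike = predict_pike(samples, mod)
    rates = pike_to_rate(pike, m_n)
    year_per_record = mod.records["year"].to_numpy()
    annual_per_draw = np.column_stack([
        np.median(rates[:, year_per_record == y], axis=1) for y in years])
    rows = []
    for j, y in enumerate(years):
        lo_, med, hi_ = np.quantile(annual_per_draw[:, j], [0.05, 0.5, 0.95])
        rows.append((int(y), med, lo_, hi_))
    annual = pd.DataFrame(rows, columns=["year", "median", "ci_low", "ci_high"])
    pooled = np.median(annual_per_draw, axis=1)
    plo, pmed, phi = np.quantile(pooled, [0.05, 0.5, 0.95])
    return InterventionResult(scenario=scenario, annual=annual,
                              pooled_median=float(pmed),
                              pooled_ci_low=float(plo),
                              pooled_ci_high=float(phi))


def run_all_interventions(samples: PosteriorSamples, data: ModelData,
                          year_range: tuple[int, int] | None = None,
                          m_n: float = 0.03) -> pd.DataFrame:
    """Baseline plus every best-observed-value scenario, as one table."""
    results = [simulate_intervention(samples, data, None, year_range, m_n)]
    for sc in best_observed_values(data, samples):
        results.append(simulate_intervention(samples, data, sc, year_range, m_n))
    rows = []
    for res in results:
        rows.append({
            "scenario": res.name,
            "target_value": (np.nan if res.scenario is None
                             else res.scenario.target_value),
            "provenance": ("" if res.scenario is None
                           else res.scenario.provenance),
            "pooled_median": res.pooled_median,
            "ci_low": res.pooled_ci_low, "ci_high": res.pooled_ci_high,
            "baseline": res.scenario is None,
        })
    return pd.DataFrame(rows)
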