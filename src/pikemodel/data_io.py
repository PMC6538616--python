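"""Reading, validation, standardisation and temporal partitioning of
carcass-encounter and covariate tables.

The data model mirrors ranger-based carcass monitoring: each record is one
site-year with the total number of elephant carcasses found (``n_total``) and
the number identified as illegally killed (``n_illegal``).  Covariates live at
four resolutions:

* site-by-year: infant mortality rate (``imr``), annual precipitation
  (``precip``, natural-log transformed before standardisation),
* country-by-year: corruption perceptions index (``cpi``),
* site-level: poverty density (``pov_dens``), law-enforcement adequacy
  (``law_enf``), site area (``area``, natural-log transformed),
* year-level: large-scale ivory seizure weight (``seizures``) and mammoth
  ivory price (``price``).

All covariates are centred and scaled to mean 0, sd 1 before modelling; the
(mean, sd) pairs are retained so new values (e.g. intervention scenarios) can
be mapped onto the fitted scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import SchemaError, ValidationError

REGIONS = ("Central", "Eastern", "Western", "Southern")

SITE_YEAR_COVS = ("imr", "precip")
COUNTRY_YEAR_COVS = ("cpi",)
SITE_COVS = ("pov_dens", "law_enf", "area")
YEAR_COVS = ("seizures", "price")
ALL_COVARIATES = SITE_YEAR_COVS + COUNTRY_YEAR_COVS + SITE_COVS + YEAR_COVS

#: covariates natural-log transformed before standardisation (left-skewed)
LOG_COVARIATES = ("precip", "area")

#: coefficient order of the linear predictor: intercept, then the three
#: record-level terms, the three site-level terms and the two year-level terms
BETA_NAMES = (
    "beta0", "precip", "imr", "cpi",
    "pov_dens", "law_enf", "area",
    "seizures", "price",
)

_CARCASS_COLS = ("site_id", "country_id", "region", "year", "n_total", "n_illegal")
_FILE_SCHEMAS = {
    "carcasses": (_CARCASS_COLS, {}),
    "site_year": (("site_id", "year", "imr", "precip"), {}),
    "country_year": (("country_id", "year", "cpi"), {}),
    "site": (("site_id", "pov_dens", "area_km2", "law_enf"), {"area_km2": "area"}),
    "year": (("year", "seizures_kg", "price_usd_kg"),
             {"seizures_kg": "seizures", "price_usd_kg": "price"}),
}
_FILE_NAMES = {
    "carcasses": "carcasses.csv",
    "site_year": "covariates_site_year.csv",
    "country_year": "covariates_country_year.csv",
    "site": "covariates_site.csv",
    "year": "covariates_year.csv",
}


@dataclass(frozen=True)
class StandardisationRecord:
    """Per-covariate (mean, sd) computed at fit time, plus which covariates
    were natural-log transformed before centring.

    ``transform`` maps a natural-scale value onto the standardised scale the
    model was fitted on; ``inverse`` maps back.
    """

    stats: Mapping[str, tuple[float, float]]
    log_covariates: tuple[str, ...] = LOG_COVARIATES

    def transform(self, name: str, value):
        mean, sd = self.stats[name]
        x = np.asarray(value, dtype=float)
        if name in self.log_covariates:
            x = np.log(x)
        return (x - mean) / sd

    def inverse(self, name: str, value):
        mean, sd = self.stats[name]
        x = np.asarray(value, dtype=float) * sd + mean
        if name in self.log_covariates:
            x = np.exp(x)
        return x

    @staticmethod
    def identity(log_covariates: tuple[str, ...] = ()) -> "StandardisationRecord":
        return StandardisationRecord(
            {c: (0.0, 1.0) for c in ALL_COVARIATES}, log_covariates
        )


@dataclass
class Design:
    """Numeric arrays the sampler and predictors consume.

    Rows follow ``ModelData.records`` order; level matrices follow the sorted
    unique levels that actually occur in the records.
    """

    k: np.ndarray            # n_illegal per record
    n: np.ndarray            # n_total per record
    X_rec: np.ndarray        # (n_records, 3): precip, imr, cpi
    site_idx: np.ndarray
    year_idx: np.ndarray
    country_idx: np.ndarray
    X_site: np.ndarray       # (S, 3): pov_dens, law_enf, area
    X_year: np.ndarray       # (Y, 2): seizures, price
    site_ids: tuple
    years: tuple
    country_ids: tuple
    regions: tuple           # region per site, aligned with site_ids

    @property
    def n_records(self) -> int:
        return len(self.k)


@dataclass
class ModelData:
    """A validated bundle of carcass records and aligned covariate tables."""

    records: pd.DataFrame
    sy_table: pd.DataFrame
    cy_table: pd.DataFrame
    site_table: pd.DataFrame
    year_table: pd.DataFrame
    standardised: bool = False
    standardisation: StandardisationRecord | None = None
    lag: int = 0
    log_covariates: tuple[str, ...] = LOG_COVARIATES

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.records["year"].unique())

    @property
    def site_ids(self) -> list:
        return sorted(self.records["site_id"].unique())

    @property
    def country_ids(self) -> list:
        return sorted(self.records["country_id"].unique())

    def observed_pike(self) -> pd.Series:
        """Raw n_illegal/n_total per record; NaN where no carcasses were found."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.records["n_illegal"] / self.records["n_total"]
        return p

    def design(self, imr_mode: str = "site_by_year") -> Design:
        rec = self.records
        site_ids = self.site_ids
        years = [int(y) for y in self.years]
        country_ids = self.country_ids
        s_map = {s: i for i, s in enumerate(site_ids)}
        y_map = {y: i for i, y in enumerate(years)}
        c_map = {c: i for i, c in enumerate(country_ids)}

        imr = rec["imr"].to_numpy(float)
        if imr_mode == "site_level_only":
            # collapse the temporal axis: each site keeps its time-mean IMR
            site_means = rec.groupby("site_id")["imr"].transform("mean")
            imr = site_means.to_numpy(float)
        elif imr_mode != "site_by_year":
            raise ValueError(f"unknown imr_mode: {imr_mode!r}")

        X_rec = np.column_stack([rec["precip"].to_numpy(float), imr,
                                 rec["cpi"].to_numpy(float)])

        site_tab = self.site_table.set_index("site_id").loc[site_ids]
        X_site = site_tab[["pov_dens", "law_enf", "area"]].to_numpy(float)
        year_tab = self.year_table.set_index("year")
        missing = [y for y in years if y not in year_tab.index]
        if missing:
            raise ValidationError(f"year-level covariates missing for years {missing}")
        X_year = year_tab.loc[years, ["seizures", "price"]].to_numpy(float)

        regions = tuple(
            rec.drop_duplicates("site_id").set_index("site_id").loc[site_ids, "region"]
        )
        return Design(
            k=rec["n_illegal"].to_numpy(float),
            n=rec["n_total"].to_numpy(float),
            X_rec=X_rec,
            site_idx=rec["site_id"].map(s_map).to_numpy(np.intp),
            year_idx=rec["year"].map(y_map).to_numpy(np.intp),
            country_idx=rec["country_id"].map(c_map).to_numpy(np.intp),
            X_site=X_site,
            X_year=X_year,
            site_ids=tuple(site_ids),
            years=tuple(years),
            country_ids=tuple(country_ids),
            regions=regions,
        )

    def digest(self) -> str:
        h = hashlib.md5()
        for df in (self.records, self.sy_table, self.cy_table,
                   self.site_table, self.year_table):
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing column(s) {missing}")


def _read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols, rename = _FILE_SCHEMAS[kind]
    _require_columns(df, cols, kind)
    return df.rename(columns=rename)


def assemble(carcasses: pd.DataFrame, sy: pd.DataFrame, cy: pd.DataFrame,
             site: pd.DataFrame, year: pd.DataFrame,
             log_covariates: tuple[str, ...] = LOG_COVARIATES) -> ModelData:
    """Validate the five tables and merge covariates onto the records.

    Raises :class:`SchemaError` for layout problems and
    :class:`ValidationError` for invariant violations (counts, duplicate
    keys, unknown regions, inconsistent site->country mapping, missing
    covariate coverage).
    """
    carcasses = carcasses.copy()
    carcasses["year"] = carcasses["year"].astype(int)

    bad = carcasses[(carcasses["n_illegal"] < 0) | (carcasses["n_total"] < 0)
                    | (carcasses["n_illegal"] > carcasses["n_total"])]
    if len(bad):
        r = bad.iloc[0]
        raise ValidationError(
            f"record site={r['site_id']} year={r['year']}: "
            f"n_illegal={r['n_illegal']} exceeds n_total={r['n_total']} "
            "(or a count is negative)"
        )
    unknown = set(carcasses["region"]) - set(REGIONS)
    if unknown:
        raise ValidationError(f"unknown region label(s): {sorted(unknown)}")
    dup = carcasses.duplicated(["site_id", "year"])
    if dup.any():
        r = carcasses[dup].iloc[0]
        raise ValidationError(
            f"duplicate (site_id, year) = ({r['site_id']}, {r['year']})")
    site_map = carcasses.groupby("site_id")[["country_id", "region"]].nunique()
    inconsistent = site_map[(site_map > 1).any(axis=1)]
    if len(inconsistent):
        raise ValidationError(
            f"site(s) mapped to multiple countries/regions: "
            f"{list(inconsistent.index)}")

    merged = carcasses.merge(sy, on=["site_id", "year"], how="left")
    merged = merged.merge(cy, on=["country_id", "year"], how="left")
    merged = merged.merge(site, on="site_id", how="left")
    merged = merged.merge(year, on="year", how="left")
    cov_missing = merged[list(ALL_COVARIATES)].isna()
    if cov_missing.any().any():
        row = merged[cov_missing.any(axis=1)].iloc[0]
        names = [c for c in ALL_COVARIATES if pd.isna(row[c])]
        raise ValidationError(
            f"missing covariate value(s) {names} for record "
            f"site={row['site_id']} year={row['year']}; resolve missingness "
            "upstream (the reader does not impute)")

    return ModelData(records=merged, sy_table=sy.copy(), cy_table=cy.copy(),
                     site_table=site.copy(), year_table=year.copy(),
                     log_covariates=tuple(log_covariates))


def read_dataset(carcass_path, site_year_path, country_year_path,
                 site_path, year_path,
                 log_covariates: tuple[str, ...] = LOG_COVARIATES) -> ModelData:
    """Read the five-CSV layout and return a validated :class:`ModelData`."""
    return assemble(
        _read_table(carcass_path, "carcasses"),
        _read_table(site_year_path, "site_year"),
        _read_table(country_year_path, "country_year"),
        _read_table(site_path, "site"),
        _read_table(year_path, "year"),
        log_covariates=log_covariates,
    )


def read_directory(directory,
                   log_covariates: tuple[str, ...] = LOG_COVARIATES) -> ModelData:
    d = Path(directory)
    return read_dataset(*(d / _FILE_NAMES[k] for k in
                          ("carcasses", "site_year", "country_year", "site", "year")),
                        log_covariates=log_covariates)


def write_dataset(data: ModelData, directory) -> None:
    """Write the five-CSV layout that :func:`read_directory` reads back."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    data.records[list(_CARCASS_COLS)].to_csv(d / _FILE_NAMES["carcasses"], index=False)
    data.sy_table.to_csv(d / _FILE_NAMES["site_year"], index=False)
    data.cy_table.to_csv(d / _FILE_NAMES["country_year"], index=False)
    data.site_table.rename(columns={"area": "area_km2"}).to_csv(
        d / _FILE_NAMES["site"], index=False)
    data.year_table.rename(columns={"seizures": "seizures_kg",
                                    "price": "price_usd_kg"}).to_csv(
        d / _FILE_NAMES["year"], index=False)


def _standardise_columns(df: pd.DataFrame, cols: Iterable[str],
                         logs: Iterable[str], stats: dict) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        x = df[c].to_numpy(float)
        if c in logs:
            if np.any(x <= 0):
                raise ValidationError(
                    f"covariate {c!r} has non-positive values; cannot apply "
                    "the natural-log transform")
            x = np.log(x)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValidationError(f"covariate {c!r} has zero variance; "
                                  "cannot standardise")
        df[c] = (x - mean) / sd
        stats[c] = (mean, sd)
    return df


def standardize(data: ModelData,
                level_weighting: str = "native") -> tuple[ModelData, StandardisationRecord]:
    """Centre and scale every covariate to mean 0, sd 1 (sample sd, n-1).

    ``precip`` and ``area`` are natural-log transformed first (when listed in
    ``data.log_covariates`` and the data are still on the natural scale).
    Site- and year-level covariates are standardised over their native units
    (one value per site / per year) under the default ``level_weighting=
    "native"``; ``"records"`` instead weights by record occurrences.

    Returns the standardised bundle and the :class:`StandardisationRecord`
    mapping natural-scale values onto the fitted scale.  Applying
    ``standardize`` to already-standardised data is a no-op up to floating
    point (the log transform is not re-applied).
    """
    if level_weighting not in ("native", "records"):
        raise ValueError(f"unknown level_weighting: {level_weighting!r}")
    logs = () if data.standardised else tuple(data.log_covariates)
    stats: dict[str, tuple[float, float]] = {}

    if level_weighting == "native":
        sy = _standardise_columns(data.sy_table, SITE_YEAR_COVS, logs, stats)
        cy = _standardise_columns(data.cy_table, COUNTRY_YEAR_COVS, logs, stats)
        site = _standardise_columns(data.site_table, SITE_COVS, logs, stats)
        year = _standardise_columns(data.year_table, YEAR_COVS, logs, stats)
    else:
        # statistics from the replicated record rows, then applied to tables
        rec_stats: dict[str, tuple[float, float]] = {}
        _standardise_columns(data.records, ALL_COVARIATES, logs, rec_stats)

        def apply(df, cols):
            df = df.copy()
            for c in cols:
                x = df[c].to_numpy(float)
                if c in logs:
                    x = np.log(x)
                m, s = rec_stats[c]
                df[c] = (x - m) / s
            return df

        sy = apply(data.sy_table, SITE_YEAR_COVS)
        cy = apply(data.cy_table, COUNTRY_YEAR_COVS)
        site = apply(data.site_table, SITE_COVS)
        year = apply(data.year_table, YEAR_COVS)
        stats = rec_stats

    if data.standardised and data.standardisation is not None:
        # compose with the earlier transform so the record still maps the
        # original natural scale onto the final fitted scale
        prev = data.standardisation
        composed = {
            c: (prev.stats[c][0] + stats[c][0] * prev.stats[c][1],
                prev.stats[c][1] * stats[c][1])
            for c in ALL_COVARIATES
        }
        record = StandardisationRecord(composed, prev.log_covariates)
    else:
        record = StandardisationRecord(dict(stats), logs)

    out = assemble(data.records[list(_CARCASS_COLS)], sy, cy, site, year,
                   log_covariates=data.log_covariates)
    out.standardised = True
    out.standardisation = record
    out.lag = data.lag
    return out, record


def collinearity_screen(data: ModelData,
                        threshold: float = 0.5) -> tuple[pd.DataFrame, bool]:
    """Pairwise Spearman rho-squared among the eight covariates.

    Computed on the record-level design (level covariates broadcast onto
    records).  Returns the symmetric rho-squared matrix with unit diagonal and
    a flag that is true iff every off-diagonal entry is below ``threshold``.
    """
    X = data.records[list(ALL_COVARIATES)].to_numpy(float)
    if len(X) < 3:
        raise ValidationError("collinearity screen needs at least 3 records")
    rho = spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    rho2 = rho ** 2
    np.fill_diagonal(rho2, 1.0)
    mat = pd.DataFrame(rho2, index=list(ALL_COVARIATES), columns=list(ALL_COVARIATES))
    off = rho2[~np.eye(len(ALL_COVARIATES), dtype=bool)]
    return mat, bool(np.all(off < threshold))


def apply_lag(data: ModelData, lag: int) -> ModelData:
    """Shift the year-level covariates: seizures/price for year *y* take
    their values from year *y - lag*.  Other covariates are unchanged.

    Lags must be applied to unlagged, unstandardised data (the raw year table
    is the lookup source).  A lagged year missing from the year table raises
    a :class:`ValidationError` listing the missing years.
    """
    if lag not in (0, 1, 2):
        raise ValueError("lag must be 0, 1 or 2")
    if data.lag != 0:
        raise ValidationError("data are already lagged; re-lag from the "
                              "original dataset")
    if data.standardised:
        raise ValidationError("apply lags before standardisation")
    if lag == 0:
        out = replace(data)
        return out

    year_tab = data.year_table.set_index("year")
    years = [int(y) for y in data.years]
    missing = [y for y in years if (y - lag) not in year_tab.index]
    if missing:
        raise ValidationError(
            f"lag {lag} needs year-level covariates for "
            f"{sorted(y - lag for y in missing)} (missing for target years "
            f"{sorted(missing)})")
    new_year = pd.DataFrame({
        "year": years,
        "seizures": [year_tab.loc[y - lag, "seizures"] for y in years],
        "price": [year_tab.loc[y - lag, "price"] for y in years],
    })
    out = assemble(data.records[list(_CARCASS_COLS)], data.sy_table,
                   data.cy_table, data.site_table, new_year,
                   log_covariates=data.log_covariates)
    out.standardised = data.standardised
    out.standardisation = data.standardisation
    out.lag = lag
    return out


def split_temporal(data: ModelData,
                   last_training_year: int) -> tuple[ModelData, ModelData]:
    """Partition records into train (year <= cutoff) and test (year > cutoff).

    The partition is exhaustive and disjoint; an empty side raises.
    Covariate tables are shared by both halves so test-year covariates remain
    available for prediction.
    """
    mask = data.records["year"] <= last_training_year

    def subset(m) -> ModelData:
        sub = replace(data, records=data.records[m].reset_index(drop=True))
        return sub

    train, test = subset(mask), subset(~mask)
    if train.n_records == 0 or test.n_records == 0:
        raise ValidationError(
            f"cutoff {last_training_year} leaves an empty partition "
            f"(train={train.n_records}, test={test.n_records})")
    return train, test
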