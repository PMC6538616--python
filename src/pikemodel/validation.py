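"""Temporal hold-out validation, the carcass-count-weighted R-squared
score, and residual autocorrelation diagnostics.

Predictive power is scored on a temporal block split: the model is fitted to
the early years and its PIKE predictions for the held-out late years are
compared against the observed proportions, weighting each record by its
total carcass count (records built on more carcasses are more informative
about the underlying proportion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ModelData, split_temporal
from .errors import ValidationError
from .model import McmcSettings, ModelSpec, PosteriorSamples, fit
from .products import predict_pike


def weighted_r2(predicted, observed, weights) -> float:
    """Squared weighted Pearson correlation between two series.

    Weights are normalised to sum to one; with equal weights this reduces to
    the ordinary squared Pearson correlation.  Invariant to affine
    transforms of either series and to positive rescaling of the weights.
    Raises when either series has zero weighted variance.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("predicted, observed and weights must have equal length")
    if np.any(w < 0) or np.sum(w > 0) < 2:
        raise ValueError("need non-negative weights with at least two positive")
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    if vx == 0 or vy == 0:
        raise ValidationError("zero weighted variance; weighted R^2 undefined")
    return float(cov ** 2 / (vx * vy))


@dataclass
class ValidationReport:
    r2_weighted: float
    r2_ci_low: float
    r2_ci_high: float
    cutoff_year: int
    n_train: int
    n_test: int
    table: pd.DataFrame            # per-record predicted vs observed PIKE
    samples: PosteriorSamples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "r2_weighted": self.r2_weighted, "r2_ci_low": self.r2_ci_low,
            "r2_ci_high": self.r2_ci_high, "cutoff_year": self.cutoff_year,
            "n_train": self.n_train, "n_test": self.n_test,
        }])


def temporal_validation(data: ModelData, spec: ModelSpec,
                        settings: McmcSettings, cutoff_year: int,
                        prediction_seed: int | None = None) -> ValidationReport:
    """Fit on records up to ``cutoff_year``, predict the later records.

    Year intercepts for unseen test years are drawn per posterior draw from
    their hierarchical distribution given the test years' annual covariates.
    The headline score is the weighted R^2 of the posterior-median
    predictions against observed PIKE (weights ``n_total``); its 90% CI
    comes from scoring each draw's predictions separately.
    """
    train, test = split_temporal(data, cutoff_year)
    samples = fit(train, spec, settings)
    rng = np.random.default_rng(
        settings.seed + 1 if prediction_seed is None else prediction_seed)
    pike = predict_pike(samples, test, rng=rng)      # (D, n_test)

    rec = test.records
    mask = rec["n_total"].to_numpy() > 0
    if mask.sum() < 2:
        raise ValidationError("fewer than two test records with carcasses")
    obs = (rec["n_illegal"] / rec["n_total"]).to_numpy()[mask]
    w = rec["n_total"].to_numpy(float)[mask]
    pred_med = np.median(pike, axis=0)[mask]
    r2 = weighted_r2(pred_med, obs, w)

    per_draw = np.empty(pike.shape[0])
    for d in range(pike.shape[0]):
        try:
            per_draw[d] = weighted_r2(pike[d][mask], obs, w)
        except ValidationError:
            per_draw[d] = np.nan
    lo, hi = np.nanquantile(per_draw, [0.05, 0.95])

    table = pd.DataFrame({
        "site_id": rec["site_id"].to_numpy()[mask],
        "year": rec["year"].to_numpy()[mask],
        "observed_pike": obs, "predicted_pike": pred_med, "n_total": w,
    })
    return ValidationReport(r2_weighted=r2, r2_ci_low=float(lo),
                            r2_ci_high=float(hi), cutoff_year=cutoff_year,
                            n_train=train.n_records, n_test=test.n_records,
                            table=table, samples=samples)


def residuals(samples: PosteriorSamples, data: ModelData,
              pike: np.ndarray | None = None,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Posterior-median estimated PIKE minus observed PIKE per record.

    Records with ``n_total = 0`` have no observed proportion and are
    excluded.
    """
    if pike is None:
        pike = predict_pike(samples, data, rng=rng)
    est = np.median(pike, axis=0)
    rec = data.records
    mask = rec["n_total"].to_numpy() > 0
    obs = (rec["n_illegal"] / rec["n_total"]).to_numpy()[mask]
    return pd.DataFrame({
        "site_id": rec["site_id"].to_numpy()[mask],
        "year": rec["year"].to_numpy()[mask],
        "residual": est[mask] - obs,
    })


def _haversine_km(lat1, lon1, lat2, lon2) -> float:
    r = 6371.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp, dl = p2 - p1, np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))


def correlogram(residual_table: pd.DataFrame, site_coordinates: pd.DataFrame,
                n_bins: int = 5, max_lag: int | None = None,
                min_shared_years: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binned residual correlation versus distance and versus time lag.

    Spatial part: for every site pair sharing at least ``min_shared_years``
    years, the Pearson correlation of their residual series; pairs are
    grouped into ``n_bins`` equal-count great-circle-distance bins and the
    mean correlation per bin reported.  Temporal part: for each year lag,
    the correlation over all between-site residual pairs separated by that
    lag.  A model without structure left in its residuals shows bin values
    scattered around zero.
    """
    sites = sorted(residual_table["site_id"].unique())
    if len(sites) < 2:
        raise ValidationError("spatial correlogram needs at least 2 sites")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    coords = site_coordinates.set_index("site_id")
    wide = residual_table.pivot(index="year", columns="site_id",
                                values="residual")

    dists, corrs = [], []
    for i, s1 in enumerate(sites):
        for s2 in sites[i + 1:]:
            pair = wide[[s1, s2]].dropna()
            if len(pair) < min_shared_years:
                continue
            c = np.corrcoef(pair[s1], pair[s2])[0, 1]
            if not np.isfinite(c):
                continue
            dists.append(_haversine_km(coords.loc[s1, "lat"], coords.loc[s1, "lon"],
                                       coords.loc[s2, "lat"], coords.loc[s2, "lon"]))
            corrs.append(c)
    dists, corrs = np.asarray(dists), np.asarray(corrs)
    n_bins_eff = min(n_bins, max(1, len(dists)))
    edges = np.quantile(dists, np.linspace(0, 1, n_bins_eff + 1))
    edges[-1] += 1e-9
    rows = []
    for b in range(n_bins_eff):
        sel = (dists >= edges[b]) & (dists < edges[b + 1])
        rows.append((0.5 * (edges[b] + edges[b + 1]),
                     float(np.mean(corrs[sel])) if sel.any() else np.nan,
                     int(sel.sum())))
    spatial = pd.DataFrame(rows, columns=["distance_km", "mean_correlation",
                                          "n_pairs"])

    years = wide.index.to_numpy()
    if max_lag is None:
        max_lag = min(5, len(years) - 1)
    trows = []
    for lag in range(max_lag + 1):
        xs, ys = [], []
        for y in years:
            if y + lag not in wide.index:
                continue
            a = wide.loc[y].to_numpy()
            b = wide.loc[y + lag].to_numpy()
            for i in range(len(sites)):
                for j in range(len(sites)):
                    if i == j:
                        continue
                    if np.isfinite(a[i]) and np.isfinite(b[j]):
                        xs.append(a[i])
                        ys.append(b[j])
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            c = float(np.corrcoef(xs, ys)[0, 1])
        else:
            c = np.nan
        trows.append((lag, c, len(xs)))
    temporal = pd.DataFrame(trows, columns=["lag", "mean_correlation",
                                            "n_pairs"])
    return spatial, temporal
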