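import numpy as np
import pandas as pd
import pytest

from pikemodel import (ModelData, SchemaError, ValidationError, apply_lag,
                       collinearity_screen, read_directory, split_temporal,
                       standardize, write_dataset)
from pikemodel.data_io import (ALL_COVARIATES, SITE_COVS, SITE_YEAR_COVS,
                               YEAR_COVS, assemble)

from conftest import make_natural_data


# ---------------------------------------------------------------------- read
def test_read_write_round_trip(tmp_path):
    data = make_natural_data()
    write_dataset(data, tmp_path)
    back = read_directory(tmp_path)
    pd.testing.assert_frame_equal(
        back.records[data.records.columns], data.records, check_dtype=False)
    for attr in ("sy_table", "cy_table", "site_table", "year_table"):
        pd.testing.assert_frame_equal(getattr(back, attr), getattr(data, attr),
                                      check_dtype=False)


def test_count_invariant_violation_names_record():
    data = make_natural_data()
    carc = data.records[["site_id", "country_id", "region", "year",
                         "n_total", "n_illegal"]].copy()
    carc.loc[0, ["n_total", "n_illegal"]] = [3, 5]
    with pytest.raises(ValidationError, match="S1"):
        assemble(carc, data.sy_table, data.cy_table, data.site_table,
                 data.year_table)


@pytest.mark.parametrize("mutate,err,match", [
    (lambda c: c.assign(region="Northern"), ValidationError, "region"),
    (lambda c: pd.concat([c, c.iloc[[0]]]), ValidationError, "duplicate"),
    (lambda c: c.assign(country_id=["C1", "C2", "C1", "C2", "C2"]),
     ValidationError, "multiple"),
])
def test_carcass_table_validation(mutate, err, match):
    data = make_natural_data()
    carc = mutate(data.records[["site_id", "country_id", "region", "year",
                                "n_total", "n_illegal"]].copy())
    with pytest.raises(err, match=match):
        assemble(carc, data.sy_table, data.cy_table, data.site_table,
                 data.year_table)


def test_missing_column_is_schema_error(tmp_path):
    data = make_natural_data()
    write_dataset(data, tmp_path)
    df = pd.read_csv(tmp_path / "carcasses.csv").drop(columns=["n_total"])
    df.to_csv(tmp_path / "carcasses.csv", index=False)
    with pytest.raises(SchemaError, match="n_total"):
        read_directory(tmp_path)


def test_missing_covariate_cell_rejected():
    data = make_natural_data()
    sy = data.sy_table.copy()
    sy.loc[0, "imr"] = np.nan
    with pytest.raises(ValidationError, match="imr"):
        assemble(data.records[["site_id", "country_id", "region", "year",
                               "n_total", "n_illegal"]],
                 sy, data.cy_table, data.site_table, data.year_table)


def test_zero_carcass_records_are_retained():
    data = make_natural_data()
    assert ((data.records["n_total"] == 0).sum()) == 1
    assert data.n_records == 5


# --------------------------------------------------------------- standardise
def test_standardize_closed_form_sample_sd():
    # a three-value column [1,2,3] has sample sd 1 -> standardises to -1,0,1
    data = make_natural_data()
    sy = data.sy_table.copy()
    sy["imr"] = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    data2 = assemble(data.records[["site_id", "country_id", "region", "year",
                                   "n_total", "n_illegal"]],
                     sy, data.cy_table, data.site_table, data.year_table)
    std, _ = standardize(data2)
    s1 = std.sy_table.loc[std.sy_table["site_id"] == "S1", "imr"].to_numpy()
    expected = (np.array([1, 2, 3]) - 2.0) / np.std([1, 2, 3, 1, 2, 3], ddof=1)
    assert np.allclose(s1, expected)


def test_standardize_moments_and_log_transform():
    data = make_natural_data()
    std, record = standardize(data)
    for tab, cols in ((std.sy_table, SITE_YEAR_COVS),
                      (std.site_table, SITE_COVS),
                      (std.year_table, YEAR_COVS)):
        for c in cols:
            x = tab[c].to_numpy(float)
            assert abs(x.mean()) < 1e-9
            assert abs(x.std(ddof=1) - 1) < 1e-9
    # area was logged first: standardised values equal standardising ln(area)
    ln_area = np.log(data.site_table["area"].to_numpy())
    expect = (ln_area - ln_area.mean()) / ln_area.std(ddof=1)
    assert np.allclose(std.site_table["area"], expect)
    # the record maps natural values onto the fitted scale
    assert np.isclose(record.transform("area", data.site_table["area"][0]),
                      expect[0])


def test_standardize_zero_variance_errors():
    data = make_natural_data()
    site = data.site_table.copy()
    site["pov_dens"] = 5.0
    data2 = assemble(data.records[["site_id", "country_id", "region", "year",
                                   "n_total", "n_illegal"]],
                     data.sy_table, data.cy_table, site, data.year_table)
    with pytest.raises(ValidationError, match="pov_dens"):
        standardize(data2)


def test_standardize_is_idempotent():
    std1, rec1 = standardize(make_natural_data())
    std2, rec2 = standardize(std1)
    for attr in ("sy_table", "cy_table", "site_table", "year_table"):
        a = getattr(std1, attr)[list(getattr(std1, attr).columns)]
        b = getattr(std2, attr)
        pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-12)
    # composed record still maps the original natural scale
    for c in ALL_COVARIATES:
        assert np.allclose(rec1.stats[c], rec2.stats[c], atol=1e-9)


# -------------------------------------------------------------- collinearity
def test_collinearity_identical_and_monotone_columns():
    data = make_natural_data()
    sy = data.sy_table.copy()
    sy["precip"] = sy["imr"] ** 3          # strictly monotone transform
    cy = data.cy_table.copy()
    cy["cpi"] = [30.0, 28.0, 26.0, 55.0, 50.0, 45.0]  # imr replicated
    data2 = assemble(data.records[["site_id", "country_id", "region", "year",
                                   "n_total", "n_illegal"]],
                     sy, cy, data.site_table, data.year_table)
    mat, ok = collinearity_screen(data2)
    assert np.isclose(mat.loc["imr", "precip"], 1.0)   # rank invariance
    assert not ok


def test_collinearity_independent_covariates_pass(full_truth):
    mat, ok = collinearity_screen(full_truth.data)
    off = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
    assert ok
    assert off.max() < 0.1
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 1.0)


def test_collinearity_needs_three_records():
    data = make_natural_data()
    small = ModelData(records=data.records.iloc[:2], sy_table=data.sy_table,
                      cy_table=data.cy_table, site_table=data.site_table,
                      year_table=data.year_table)
    with pytest.raises(ValidationError):
        collinearity_screen(small)


# ----------------------------------------------------------------------- lag
def test_apply_lag_identity_and_shift():
    data = make_natural_data()
    lag0 = apply_lag(data, 0)
    pd.testing.assert_frame_equal(lag0.year_table, data.year_table)

    lag1 = apply_lag(data, 1)
    yt = lag1.year_table.set_index("year")
    raw = data.year_table.set_index("year")
    for y in (2001, 2002, 2003):
        assert yt.loc[y, "price"] == raw.loc[y - 1, "price"]
        assert yt.loc[y, "seizures"] == raw.loc[y - 1, "seizures"]
    # non-year covariates untouched
    pd.testing.assert_frame_equal(lag1.sy_table, data.sy_table)
    assert lag1.lag == 1


def test_apply_lag_missing_years_error():
    data = make_natural_data()
    with pytest.raises(ValidationError, match="1999"):
        apply_lag(data, 2)   # needs 1999 for target year 2001


# --------------------------------------------------------------------- split
def test_split_temporal_partitions_every_cutoff():
    data = make_natural_data()
    years = data.years
    for cutoff in range(int(years.min()), int(years.max())):
        train, test = split_temporal(data, cutoff)
        assert train.n_records + test.n_records == data.n_records
        assert (train.records["year"] <= cutoff).all()
        assert (test.records["year"] > cutoff).all()


def test_split_temporal_example_years():
    data = make_natural_data()
    train, test = split_temporal(data, 2002)
    assert set(train.records["year"]) == {2001, 2002}
    assert set(test.records["year"]) == {2003}


def test_split_temporal_empty_partition_errors():
    data = make_natural_data()
    with pytest.raises(ValidationError):
        split_temporal(data, 2003)
    with pytest.raises(ValidationError):
        split_temporal(data, 1990)
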