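"""Reading, validating and reshaping survey-mean tables."""

import logging

import numpy as np
import pandas as pd
import pytest

from sitar.growth_tables import (
    GrowthDataError,
    GrowthTable,
    assign_midyear_ages,
    build_cohort_table,
    match_period_to_cohort,
    merge_triennia,
    read_growth_table,
    survey_metadata,
    write_growth_table,
)


def make_csv(tmp_path, rows, columns=("country", "year", "sex", "measurement", "age_group", "value")):
    path = tmp_path / "table.csv"
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
    return path


def korea_rows(years=(1965, 1975, 1984, 1997, 2005), ages=range(1, 21)):
    return [
        ("Korea", y, "male", "height", a, 70.0 + 5.2 * a + 0.05 * (y - 1965))
        for y in years
        for a in ages
    ]


class TestReadGrowthTable:
    def test_five_surveys_twenty_ages(self, tmp_path):
        table = read_growth_table(make_csv(tmp_path, korea_rows()))
        assert table.n_obs == 100
        assert len(table.surveys) == 5
        assert table.mode == "period"
        # sorted by survey then age
        assert table.data.groupby("survey")["age"].apply(
            lambda a: bool(np.all(np.diff(a) > 0))
        ).all()

    def test_header_only_file_gives_empty_table(self, tmp_path):
        table = read_growth_table(make_csv(tmp_path, []))
        assert table.n_obs == 0
        with pytest.raises(GrowthDataError, match="empty"):
            table.check_fittable()

    def test_non_numeric_age_cites_row(self, tmp_path):
        rows = korea_rows(years=(1965,), ages=range(1, 6))
        rows[2] = ("Korea", 1965, "male", "height", "abc", 85.0)
        with pytest.raises(GrowthDataError, match="row 2"):
            read_growth_table(make_csv(tmp_path, rows))

    def test_missing_column_named(self, tmp_path):
        rows = [("Korea", 1965, "male", 1, 75.0)]
        path = make_csv(tmp_path, rows, columns=("country", "year", "sex", "age_group", "value"))
        with pytest.raises(GrowthDataError, match="measurement"):
            read_growth_table(path)

    def test_duplicate_survey_age_rejected(self, tmp_path):
        rows = korea_rows(years=(1965,), ages=[1, 2, 2, 3])
        with pytest.raises(GrowthDataError, match="duplicate"):
            read_growth_table(make_csv(tmp_path, rows))

    def test_sex_filter_selects_stratum(self, tmp_path):
        rows = korea_rows() + [
            ("Korea", y, "female", "height", a, 70.0 + 4.8 * a)
            for y in (1965,)
            for a in range(1, 21)
        ]
        table = read_growth_table(make_csv(tmp_path, rows), sex="female")
        assert set(table.data["sex"]) == {"female"}
        with pytest.raises(GrowthDataError, match="one sex"):
            read_growth_table(make_csv(tmp_path, rows))

    def test_round_trip_through_writer(self, tmp_path):
        table = read_growth_table(make_csv(tmp_path, korea_rows()))
        out = tmp_path / "again.csv"
        write_growth_table(table, out)
        again = read_growth_table(out)
        pd.testing.assert_frame_equal(table.data, again.data)


class TestMidyearAges:
    def test_half_year_added_once(self, tmp_path):
        table = read_growth_table(make_csv(tmp_path, korea_rows()))
        shifted = assign_midyear_ages(table)
        assert shifted.data["age"].min() == 1.5
        assert shifted.data["age"].max() == 20.5
        pd.testing.assert_series_equal(
            shifted.data["value"], table.data["value"], check_names=False
        )

    def test_double_application_guard(self, tmp_path):
        table = assign_midyear_ages(read_growth_table(make_csv(tmp_path, korea_rows())))
        with pytest.raises(GrowthDataError, match="already fractional"):
            assign_midyear_ages(table)


def annual_table(years, ages=range(1, 20), trend=0.0, n=None):
    rows = []
    for y in years:
        for a in ages:
            rows.append(
                {
                    "survey": f"Japan {y}",
                    "country": "Japan",
                    "year": y,
                    "sex": "male",
                    "measurement": "height",
                    "age": float(a),
                    "value": 70.0 + 5.2 * a + trend * (y - years[0]),
                    "n": np.nan if n is None else float(n),
                }
            )
    return GrowthTable(data=pd.DataFrame(rows), mode="period")


class TestMergeTriennia:
    def test_mean_of_three_years_labelled_by_center(self):
        table = annual_table([1949, 1950, 1951], trend=1.0)
        merged = merge_triennia(table, [1950])
        assert merged.surveys == ["Japan 1950"]
        # values 0, +1, +2 around the base -> mean offset +1
        base = annual_table([1949]).data["value"].to_numpy()
        np.testing.assert_allclose(merged.data["value"].to_numpy(), base + 1.0)

    def test_identical_years_unchanged_and_within_bounds(self):
        table = annual_table([1959, 1960, 1961], trend=0.0)
        merged = merge_triennia(table, [1960])
        np.testing.assert_allclose(
            merged.data["value"].to_numpy(),
            annual_table([1959]).data["value"].to_numpy(),
        )

    def test_weighted_when_counts_present(self):
        frames = []
        for y, n, v in [(1969, 100.0, 110.0), (1970, 300.0, 112.0), (1971, 100.0, 114.0)]:
            t = annual_table([y], ages=[10], n=n)
            t.data.loc[:, "value"] = v
            frames.append(t.data)
        table = GrowthTable(data=pd.concat(frames, ignore_index=True), mode="period")
        merged = merge_triennia(table, [1970])
        expected = (100 * 110 + 300 * 112 + 100 * 114) / 500
        assert merged.data["value"].iloc[0] == pytest.approx(expected)

    def test_missing_year_named(self):
        table = annual_table([1959, 1960])
        with pytest.raises(GrowthDataError, match="1961"):
            merge_triennia(table, [1960])


class TestCohortConstruction:
    def test_period_year_maps_to_birth_11_years_earlier(self):
        assert match_period_to_cohort(1950) == 1939
        assert match_period_to_cohort(2010) == 1999
        assert match_period_to_cohort(11) == 0

    def test_cohort_collects_measurement_year_birth_plus_age(self):
        annual = annual_table(range(1940, 1960))
        cohort = build_cohort_table(annual, [1939])
        got = cohort.for_survey("Japan 1939")
        # age a comes from measurement year 1939 + a
        for a in got["age"]:
            src = annual.data.query("year == @a + 1939 and age == @a")
            assert src["value"].iloc[0] == got.loc[got["age"] == a, "value"].iloc[0]
        assert cohort.mode == "cohort"

    def test_complete_span_gives_full_curve(self):
        annual = annual_table(range(1941, 1960))  # years 1941..1959 = ages 1..19 of 1940
        cohort = build_cohort_table(annual, [1940])
        assert len(cohort.for_survey("Japan 1940")) == 19

    def test_partial_edges_kept(self):
        annual = annual_table(range(1949, 1960))
        cohort = build_cohort_table(annual, [1945])
        ages = cohort.for_survey("Japan 1945")["age"].to_numpy()
        # only measurement years 1949-1959 exist: ages 4..14
        np.testing.assert_array_equal(ages, np.arange(4, 15, dtype=float))

    def test_unpopulated_cohort_excluded_with_warning(self, caplog):
        annual = annual_table(range(1949, 1960))
        with caplog.at_level(logging.WARNING, logger="sitar"):
            cohort = build_cohort_table(annual, [1990])
        assert cohort.n_obs == 0
        assert "1990" in caplog.text

    def test_trend_free_period_and_cohort_curves_coincide(self):
        annual = annual_table(range(1949, 1971), trend=0.0)
        cohort = build_cohort_table(annual, [1950])
        period = annual.for_survey("Japan 1960")
        got = cohort.for_survey("Japan 1950")
        shared = sorted(set(period["age"]) & set(got["age"]))
        for a in shared:
            assert (
                period.loc[period["age"] == a, "value"].iloc[0]
                == got.loc[got["age"] == a, "value"].iloc[0]
            )


def test_survey_metadata_one_row_per_survey(tmp_path):
    table = read_growth_table(make_csv(tmp_path, korea_rows()))
    meta = survey_metadata(table)
    assert list(meta.columns) == ["survey", "country", "year"]
    assert len(meta) == 5
    assert set(meta["year"]) == {1965, 1975, 1984, 1997, 2005}
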