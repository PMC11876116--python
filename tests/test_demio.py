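"""Table IO contracts, prevalence-to-count conversion and aggregation."""

import numpy as np
import pandas as pd
import pytest

from prevproj import demio
from prevproj.surfaces import PrevalenceSurface


def write_csv(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def two_age_surface():
    return PrevalenceSurface(
        "male",
        np.array([60.0, 70.0]),
        np.array([2015.0, 2016.0]),
        np.array([[0.1, 0.1], [0.2, 0.2]]),
    )


@pytest.fixture
def two_age_population():
    rows = []
    for year in (2015.0, 2016.0):
        rows += [
            {"sex": "male", "age": 60.0, "year": year, "count": 1000.0},
            {"sex": "male", "age": 70.0, "year": year, "count": 500.0},
        ]
    return pd.DataFrame(rows)


class TestReadRateTable:
    def test_well_formed_table_preserves_records(self, tmp_path):
        path = write_csv(
            tmp_path,
            "inc.csv",
            "sex,age_group,year,rate\n"
            "male,18-34,2015,0.001\nmale,35-49,2015,0.002\n"
            "female,18-34,2015,0.001\nfemale,80+,2015,0.01\n",
        )
        df = demio.read_rate_table(path, "incidence_estimates")
        assert len(df) == 4

    def test_negative_value_names_row(self, tmp_path):
        path = write_csv(
            tmp_path, "mort.csv", "sex,age,year,rate\nmale,60,2015,0.01\nmale,61,2015,-0.1\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            demio.read_rate_table(path, "mortality")

    def test_per1000_rescaling(self, tmp_path):
        path = write_csv(tmp_path, "mort.csv", "sex,age,year,rate\nmale,60,2015,5.0\n")
        df = demio.read_rate_table(path, "mortality", rate_scale="per1000")
        assert df["rate"].iloc[0] == pytest.approx(0.005)

    def test_missing_column_diagnostic(self, tmp_path):
        path = write_csv(tmp_path, "pop.csv", "sex,age,count\nmale,60,100\n")
        with pytest.raises(ValueError, match="year"):
            demio.read_rate_table(path, "population")

    def test_duplicate_key_diagnostic(self, tmp_path):
        path = write_csv(
            tmp_path, "pop.csv", "sex,age,year,count\nmale,60,2015,100\nmale,60,2015,90\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            demio.read_rate_table(path, "population")

    def test_unparseable_age_group_diagnostic(self, tmp_path):
        path = write_csv(
            tmp_path, "inc.csv", "sex,age_group,year,rate\nmale,old,2015,0.01\nfemale,18-34,2015,0.01\n"
        )
        with pytest.raises(ValueError, match="old"):
            demio.read_rate_table(path, "incidence_estimates")

    def test_unit_safety_identical_downstream(self, tmp_path):
        per1 = write_csv(tmp_path, "a.csv", "sex,age,year,rate\nmale,60,2015,0.004\n")
        per1000 = write_csv(tmp_path, "b.csv", "sex,age,year,rate\nmale,60,2015,4.0\n")
        a = demio.read_rate_table(per1, "mortality")
        b = demio.read_rate_table(per1000, "mortality", rate_scale="per1000")
        pd.testing.assert_frame_equal(a, b)


class TestSurfaceRoundTrip:
    def test_write_then_read_reproduces_values(self, truth, grid, tmp_path):
        surf = truth.mortality_surface("female", grid.ages, grid.years)
        table = demio.surface_to_table(surf, "rate")
        path = tmp_path / "mortality.csv"
        demio.write_table(table, path)
        back = demio.surface_from_table(demio.read_rate_table(path, "mortality"), "female")
        np.testing.assert_array_equal(back.values, surf.values)


class TestCounts:
    def test_zero_and_unit_prevalence_bounds(self, two_age_population):
        ages = np.array([60.0, 70.0])
        years = np.array([2015.0, 2016.0])
        zero = PrevalenceSurface("male", ages, years, np.zeros((2, 2)))
        one = PrevalenceSurface("male", ages, years, np.ones((2, 2)))
        _, total0 = demio.counts_from_prevalence(zero, two_age_population, 2015.0)
        df1, total1 = demio.counts_from_prevalence(one, two_age_population, 2015.0)
        assert total0 == 0.0
        assert total1 == pytest.approx(1500.0)
        np.testing.assert_array_equal(df1["count"], df1["population"])

    def test_hand_arithmetic(self, two_age_surface, two_age_population):
        df, total = demio.counts_from_prevalence(two_age_surface, two_age_population, 2015.0)
        np.testing.assert_allclose(df["count"], [100.0, 100.0])
        assert total == pytest.approx(200.0)

    def test_overall_prevalence_weighted(self, two_age_surface, two_age_population):
        assert demio.overall_prevalence(two_age_surface, two_age_population, 2015.0) == pytest.approx(
            200.0 / 1500.0
        )

    def test_missing_year_raises(self, two_age_surface, two_age_population):
        with pytest.raises(KeyError):
            demio.counts_from_prevalence(two_age_surface, two_age_population, 2030.0)

    def test_ages_above_top_node_pool_there(self, two_age_surface):
        pop = pd.DataFrame(
            [
                {"sex": "male", "age": 60.0, "year": 2015.0, "count": 100.0},
                {"sex": "male", "age": 70.0, "year": 2015.0, "count": 100.0},
                {"sex": "male", "age": 95.0, "year": 2015.0, "count": 50.0},  # above top node
                {"sex": "male", "age": 17.0, "year": 2015.0, "count": 999.0},  # below adult range
            ]
        )
        df, total = demio.counts_from_prevalence(two_age_surface, pop, 2015.0)
        assert df["population"].tolist() == [100.0, 150.0]
        assert total == pytest.approx(0.1 * 100 + 0.2 * 150)


class TestConstantPrevalenceProjection:
    def test_constant_population_gives_identical_totals(self, two_age_population):
        res = demio.constant_prevalence_projection(
            "constant_prevalence",
            {"male": np.array([0.1, 0.2])},
            np.array([60.0, 70.0]),
            np.array([2015.0, 2016.0]),
            two_age_population,
        )
        t15 = res.total_row("male", 2015.0)
        t16 = res.total_row("male", 2016.0)
        assert t15["cases"] == pytest.approx(t16["cases"])

    def test_population_shift_toward_high_prevalence_raises_crude_rate(self):
        pop = pd.DataFrame(
            [
                {"sex": "male", "age": 60.0, "year": 2015.0, "count": 1000.0},
                {"sex": "male", "age": 70.0, "year": 2015.0, "count": 500.0},
                {"sex": "male", "age": 60.0, "year": 2016.0, "count": 500.0},
                {"sex": "male", "age": 70.0, "year": 2016.0, "count": 1000.0},
            ]
        )
        res = demio.constant_prevalence_projection(
            "constant_prevalence",
            {"male": np.array([0.1, 0.2])},
            np.array([60.0, 70.0]),
            np.array([2015.0, 2016.0]),
            pop,
        )
        assert res.total_row("male", 2016.0)["prevalence"] > res.total_row("male", 2015.0)["prevalence"]

    def test_flat_profile_gives_constant_crude_prevalence(self):
        pop = pd.DataFrame(
            [
                {"sex": "male", "age": 60.0, "year": 2015.0, "count": 1000.0},
                {"sex": "male", "age": 70.0, "year": 2015.0, "count": 500.0},
                {"sex": "male", "age": 60.0, "year": 2016.0, "count": 100.0},
                {"sex": "male", "age": 70.0, "year": 2016.0, "count": 900.0},
            ]
        )
        res = demio.constant_prevalence_projection(
            "constant_prevalence",
            {"male": np.full(2, 0.07)},
            np.array([60.0, 70.0]),
            np.array([2015.0, 2016.0]),
            pop,
        )
        for year in (2015.0, 2016.0):
            assert res.total_row("male", year)["prevalence"] == pytest.approx(0.07)


class TestAggregationConsistency:
    def test_totals_equal_weighted_aggregates(self, scenario_results):
        res = scenario_results["trend_until_2030"]
        for _, row in res.totals.iterrows():
            if row["sex"] == "total":
                continue
            sub = res.counts[(res.counts["sex"] == row["sex"]) & (res.counts["year"] == row["year"])]
            assert row["cases"] == pytest.approx(sub["count"].sum(), rel=1e-12)
            assert row["prevalence"] * row["population"] == pytest.approx(row["cases"], rel=1e-12)
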