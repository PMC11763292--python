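"""Catch indices: MTL, FiB, the region decomposition, gridding and effort."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophicweb import (
    IndexSeries,
    TrophicLevelTable,
    biomass_by_year,
    effort_indices,
    fishing_in_balance,
    grid_quadrants,
    index_series,
    mean_trophic_level,
    rmtl_decompose,
)
from trophicweb.indices import quadrant_area, quadrant_cell


def records(rows):
    base = {
        "month": 1,
        "fleet": "VIC",
        "lat": -26.0,
        "lon": -47.0,
        "depth_m": 50.0,
        "days_at_sea": 5,
        "fishing_days": 3,
        "hauls": 4,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestMeanTrophicLevel:
    def test_single_species_identity(self):
        tl = TrophicLevelTable(entries={"SV": 2.77})
        recs = records([{"year": 2000, "species_code": "SV", "catch_t": 10.0}])
        mtl, cov = mean_trophic_level(recs, tl)
        assert mtl == pytest.approx(2.77)
        assert cov == 1.0

    def test_equal_catches_average(self):
        tl = TrophicLevelTable(entries={"A": 2.0, "B": 4.0})
        recs = records(
            [
                {"year": 2000, "species_code": "A", "catch_t": 5.0},
                {"year": 2000, "species_code": "B", "catch_t": 5.0},
            ]
        )
        assert mean_trophic_level(recs, tl)[0] == pytest.approx(3.0)

    def test_hand_weighted_mean(self):
        tl = TrophicLevelTable(entries={"SV": 2.77, "CA": 3.38})
        recs = records(
            [
                {"year": 2000, "species_code": "SV", "catch_t": 100.0},
                {"year": 2000, "species_code": "CA", "catch_t": 50.0},
            ]
        )
        # (100·2.77 + 50·3.38)/150 = 446/150
        assert mean_trophic_level(recs, tl)[0] == pytest.approx(446.0 / 150.0)

    def test_unknown_species_excluded_with_coverage(self):
        tl = TrophicLevelTable(entries={"SV": 2.77})
        recs = records(
            [
                {"year": 2000, "species_code": "SV", "catch_t": 75.0},
                {"year": 2000, "species_code": "???", "catch_t": 25.0},
            ]
        )
        mtl, cov = mean_trophic_level(recs, tl)
        assert mtl == pytest.approx(2.77)
        assert cov == pytest.approx(0.75)

    def test_no_usable_catch_signalled(self):
        tl = TrophicLevelTable(entries={"SV": 2.77})
        recs = records([{"year": 2000, "species_code": "??", "catch_t": 5.0}])
        with pytest.raises(ValueError):
            mean_trophic_level(recs, tl)

    @given(st.floats(0.1, 1e4))
    @settings(deadline=None)
    def test_invariant_under_uniform_rescaling(self, scale):
        tl = TrophicLevelTable(entries={"A": 2.0, "B": 3.4, "C": 4.1})
        recs = records(
            [
                {"year": 2000, "species_code": "A", "catch_t": 10.0},
                {"year": 2000, "species_code": "B", "catch_t": 20.0},
                {"year": 2000, "species_code": "C", "catch_t": 5.0},
            ]
        )
        scaled = recs.assign(catch_t=recs["catch_t"] * scale)
        assert mean_trophic_level(scaled, tl)[0] == pytest.approx(
            mean_trophic_level(recs, tl)[0], rel=1e-12
        )


class TestFishingInBalance:
    def test_equilibrium_is_zero(self):
        assert fishing_in_balance(np.array([50.0]), np.array([3.0]), 50.0, 3.0)[
            0
        ] == pytest.approx(0.0, abs=1e-15)

    def test_exact_cancellation(self):
        # tenfold catch against one full trophic level lost, TE = 0.1
        fib = fishing_in_balance(np.array([100.0]), np.array([2.0]), 10.0, 3.0, 0.1)
        assert fib[0] == pytest.approx(0.0, abs=1e-12)

    def test_doubled_catch(self):
        fib = fishing_in_balance(np.array([20.0]), np.array([3.0]), 10.0, 3.0, 0.1)
        assert fib[0] == pytest.approx(math.log10(2.0), abs=1e-12)

    def test_nonpositive_catch_rejected(self):
        with pytest.raises(ValueError):
            fishing_in_balance(np.array([0.0]), np.array([3.0]), 10.0, 3.0)

    @given(
        st.floats(0.01, 0.99),
        st.floats(1.0, 1e5),
        st.floats(1.0, 1e5),
        st.floats(2.0, 4.5),
        st.floats(2.0, 4.5),
    )
    @settings(deadline=None)
    def test_closed_form_equivalence(self, te, yk, y0, mtlk, mtl0):
        """Eq-form and reduced closed form agree for any TE in (0,1)."""
        fib = fishing_in_balance(np.array([yk]), np.array([mtlk]), y0, mtl0, te)[0]
        closed = math.log10(yk / y0) + (mtlk - mtl0) * math.log10(1.0 / te)
        assert fib == pytest.approx(closed, abs=1e-12)


class TestRmtlDecompose:
    def make_series(self, years, y, mtl, ref=None):
        table = pd.DataFrame({"year": years, "Y": y, "MTL": mtl})
        ref = ref or years[0]
        r = table.set_index("year").loc[ref]
        table["FiB"] = fishing_in_balance(
            table["Y"].to_numpy(), table["MTL"].to_numpy(), r["Y"], r["MTL"], 0.1
        )
        table["coverage"] = 1.0
        return IndexSeries(table=table, reference_year=ref, te=0.1)

    def test_no_expansion_is_identity(self):
        s = self.make_series([2000, 2001], [100.0, 110.0], [3.0, 3.05])
        part = rmtl_decompose(s, [2001])
        r1 = part.region(1)
        assert (r1["Y_hat"].to_numpy() == np.array([100.0, 110.0])).all()
        assert (r1["MTL_hat"].to_numpy() == np.array([3.0, 3.05])).all()

    def test_region1_catch_direct_evaluation(self):
        # Ŷ¹ = 100·10^(3.0−3.1) for the first post-expansion year
        s = self.make_series([2000, 2001], [100.0, 150.0], [3.0, 3.1])
        part = rmtl_decompose(s, [2000])
        y1 = part.region(1)["Y_hat"].iloc[1]
        assert y1 == pytest.approx(100.0 * 10 ** (3.0 - 3.1), rel=1e-12)

    def test_region1_mtl_and_mass_weighted_identity(self):
        s = self.make_series([2000, 2001], [100.0, 200.0], [3.0, 3.0])
        part = rmtl_decompose(s, [2000])
        tab = part.table[part.table["year"] == 2001]
        m1 = tab[tab["region"] == 1]["MTL_hat"].iloc[0]
        assert m1 == pytest.approx(3.0 - math.log10(2.0), rel=1e-12)
        # conservation: Σ Ŷ = Y and Σ MTL̂·Ŷ = MTL·Y
        assert tab["Y_hat"].sum() == pytest.approx(200.0, rel=1e-12)
        assert (tab["MTL_hat"] * tab["Y_hat"]).sum() == pytest.approx(
            3.0 * 200.0, rel=1e-9
        )

    def test_negative_residual_floored_and_flagged(self):
        # catch collapses while MTL drops: balance predicts more region-1
        # catch than was landed
        s = self.make_series([2000, 2001], [100.0, 50.0], [3.0, 2.5])
        part = rmtl_decompose(s, [2000])
        tab = part.table[part.table["year"] == 2001]
        assert (tab["Y_hat"] >= 0).all()
        assert "assumption violated" in set(tab["flag"])

    def test_synthetic_two_region_recovery(self):
        from trophicweb import generate_two_region_series

        series, truth = generate_two_region_series(region2_mtl=2.8, seed=1)
        s = IndexSeries(
            table=series.assign(FiB=0.0, coverage=1.0), reference_year=2000, te=0.1
        )
        part = rmtl_decompose(s, [2007])
        r2 = part.region(2).set_index("year")
        for year in range(2008, 2017):
            assert r2.loc[year, "MTL_hat"] == pytest.approx(2.8, rel=1e-6)
            assert r2.loc[year, "Y_hat"] == pytest.approx(
                truth.set_index("year").loc[year, "Y2"], rel=1e-6
            )


class TestQuadrants:
    def test_cell_floor_arithmetic(self):
        assert quadrant_cell(-26.2, -48.7) == (-53, -98)

    def test_two_records_one_cell(self):
        recs = records(
            [
                {"year": 2000, "species_code": "SV", "catch_t": 5.0, "lat": -26.2, "lon": -48.7},
                {"year": 2000, "species_code": "SV", "catch_t": 7.0, "lat": -26.4, "lon": -48.6},
            ]
        )
        grid = grid_quadrants(recs)
        assert grid.n_quadrants() == 1
        assert grid.cells["catch_t"].iloc[0] == pytest.approx(12.0)

    def test_cell_area_spherical_formula(self):
        # cell with centre at 26.25° S (lat_idx -53 spans -26.5..-26.0)
        idx = -53
        expected = (111.32 * 0.5) * (111.32 * math.cos(math.radians(-26.25)) * 0.5)
        assert quadrant_area(idx) == pytest.approx(expected, rel=1e-12)

    def test_missing_coordinates_excluded(self):
        recs = records(
            [
                {"year": 2000, "species_code": "SV", "catch_t": 5.0, "lat": None},
                {"year": 2000, "species_code": "SV", "catch_t": 7.0},
            ]
        )
        grid = grid_quadrants(recs)
        assert grid.n_excluded == 1


class TestBiomassByYear:
    def test_single_quadrant_density(self):
        recs = records(
            [{"year": 2000, "species_code": "SV", "catch_t": 50.0, "lat": -26.2, "lon": -48.7}]
        )
        out = biomass_by_year(recs)
        area = quadrant_area(-53)
        assert out["density_t_km2"].iloc[0] == pytest.approx(50.0 / area)

    def test_density_linear_in_catch(self):
        recs = records(
            [
                {"year": 2000, "species_code": "SV", "catch_t": 50.0, "lat": -26.2, "lon": -48.7},
                {"year": 2000, "species_code": "SV", "catch_t": 30.0, "lat": -25.1, "lon": -47.2},
            ]
        )
        d1 = biomass_by_year(recs)["density_t_km2"].iloc[0]
        d2 = biomass_by_year(recs.assign(catch_t=recs["catch_t"] * 2))[
            "density_t_km2"
        ].iloc[0]
        assert d2 == pytest.approx(2 * d1)

    def test_three_quadrant_hand_sum(self):
        rows = [
            {"year": 2000, "species_code": "SV", "catch_t": 10.0, "lat": -26.2, "lon": -48.7},
            {"year": 2000, "species_code": "SV", "catch_t": 20.0, "lat": -25.1, "lon": -47.2},
            {"year": 2000, "species_code": "SV", "catch_t": 30.0, "lat": -24.3, "lon": -46.1},
        ]
        recs = records(rows)
        out = biomass_by_year(recs)
        total_area = sum(
            quadrant_area(math.floor(r["lat"] / 0.5)) for r in rows
        )
        assert out["biomass_t"].iloc[0] == pytest.approx(60.0)
        assert out["density_t_km2"].iloc[0] == pytest.approx(60.0 / total_area)


class TestEffortIndices:
    def test_reference_year_is_one(self):
        recs = records(
            [
                {"year": 2000, "species_code": "SV", "catch_t": 1.0},
                {"year": 2001, "species_code": "SV", "catch_t": 1.0},
            ]
        )
        out = effort_indices(recs, reference_year=2000).set_index("year")
        assert out.loc[2000, ["days_at_sea_idx", "fishing_days_idx", "hauls_idx"]].tolist() == [
            1.0,
            1.0,
            1.0,
        ]

    def test_half_effort_gives_half_index(self):
        recs = records(
            [
                {"year": 2000, "species_code": "SV", "catch_t": 1.0, "days_at_sea": 10},
                {"year": 2001, "species_code": "SV", "catch_t": 1.0, "days_at_sea": 5},
            ]
        )
        out = effort_indices(recs, reference_year=2000).set_index("year")
        assert out.loc[2001, "days_at_sea_idx"] == pytest.approx(0.5)

    def test_mixed_fleet_hand_ratios(self):
        rows = [
            {"year": 2000, "fleet": "VIC", "species_code": "SV", "catch_t": 1, "days_at_sea": 10, "fishing_days": 6, "hauls": 8},
            {"year": 2000, "fleet": "VRB", "species_code": "SV", "catch_t": 1, "days_at_sea": 20, "fishing_days": 12, "hauls": 4},
            {"year": 2001, "fleet": "VIC", "species_code": "SV", "catch_t": 1, "days_at_sea": 15, "fishing_days": 3, "hauls": 16},
            {"year": 2001, "fleet": "VRB", "species_code": "SV", "catch_t": 1, "days_at_sea": 10, "fishing_days": 18, "hauls": 2},
        ]
        recs = records(rows)
        out = effort_indices(recs, reference_year=2000).set_index(["fleet", "year"])
        assert out.loc[("VIC", 2001), "days_at_sea_idx"] == pytest.approx(1.5)
        assert out.loc[("VIC", 2001), "fishing_days_idx"] == pytest.approx(0.5)
        assert out.loc[("VRB", 2001), "hauls_idx"] == pytest.approx(0.5)


def test_index_series_reference_defaults_to_first_year():
    tl = TrophicLevelTable(entries={"SV": 2.77})
    recs = records(
        [
            {"year": 2003, "species_code": "SV", "catch_t": 10.0},
            {"year": 2004, "species_code": "SV", "catch_t": 20.0},
        ]
    )
    series = index_series(recs, tl)
    assert series.reference_year == 2003
    assert series.table.set_index("year").loc[2003, "FiB"] == 0.0
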