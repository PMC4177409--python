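"""Summary statistics, map export and the end-to-end pipeline."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msfd9.integration import CellAssessment
from msfd9.reporting import (
    class_totals,
    exceedance_frequency,
    format_summary_table,
    render_maps,
    round_half_up,
    run_assessment,
    spatial_coverage,
    summarize,
    write_geojson,
    write_summary_csv,
)
from msfd9.spatial_grid import clip_to_subregion, make_fishnet
from msfd9.synthetic_data import CategoryPlan, Scenario, gen_dataset


def _grid(polygon, cell=0.45):
    return clip_to_subregion(make_fishnet(polygon.bounds, cell), polygon)


def _scenario(fractions, n_stations=12, seed=0, years=(2010,), n_per=3):
    plans = tuple(
        CategoryPlan(code, target_exceedance_fraction=f,
                     n_per_station=n_per, years=years)
        for code, f in fractions.items()
    )
    return Scenario(polygon="elongated_basin", n_stations=n_stations,
                    plans=plans, seed=seed)


class TestRounding:
    def test_half_up(self):
        assert round_half_up(82.35) == 82.4
        assert round_half_up(0.05) == 0.1
        assert round_half_up(2.44999) == 2.4


class TestSpatialCoverage:
    def test_zero_and_full(self):
        assert spatial_coverage(0, 77) == 0.0
        assert spatial_coverage(51, 51) == 100.0

    def test_42_of_51_rounds_to_82_4(self):
        # 4200/51 = 82.3529... by rational arithmetic
        assert spatial_coverage(42, 51) == 82.4

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            spatial_coverage(1, 0)
        with pytest.raises(ValueError):
            spatial_coverage(52, 51)


class TestExceedanceFrequency:
    def test_one_in_sixteen(self):
        codes = [1] * 15 + [2]
        assert exceedance_frequency(codes) == (1, 6.3)

    def test_no_exceedances(self):
        assert exceedance_frequency([1, 1, 1]) == (0, 0.0)

    @given(st.lists(st.sampled_from([1, 2]), min_size=1, max_size=300))
    def test_matches_brute_force(self, codes):
        n, pct = exceedance_frequency(codes)
        assert n == codes.count(2)
        assert pct == round_half_up(100 * codes.count(2) / len(codes))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            exceedance_frequency([])


class TestPipelineAndSummary:
    def test_all_within_scenario(self, catalog, basin_polygon):
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.0}), catalog)
        res = run_assessment(ms, catalog, _grid(basin_polygon), "SYN")
        row = next(r for r in res.summary if r.category_code == "Hg 3.3.1")
        assert row.pct_data_within == 100.0
        assert row.pct_data_outside == 0.0
        assert row.pct_stations_within == 100.0
        assert row.pct_cells_within == 100.0

    def test_all_exceeding_scenario(self, catalog, basin_polygon):
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 1.0}), catalog)
        res = run_assessment(ms, catalog, _grid(basin_polygon), "SYN")
        row = next(r for r in res.summary if r.category_code == "Hg 3.3.1")
        assert row.pct_data_within == 0.0
        assert row.pct_cells_outside == 100.0

    def test_hand_checkable_tie_cell(self, catalog, basin_polygon):
        """Two stations in one cell, one exceeding: stations split 50/50,
        the cell goes red by the precautionary tie rule."""
        from msfd9.catalog_and_io import Measurement

        grid = _grid(basin_polygon)
        lon, lat = 14.0, 43.0
        ms = [
            Measurement("A", lon, lat, 2010, "x", "t", "Hg 3.3.1", 0.1,
                        "mg/kg w.w."),
            Measurement("B", lon + 0.01, lat, 2010, "x", "t", "Hg 3.3.1",
                        0.9, "mg/kg w.w."),
        ]
        res = run_assessment(ms, catalog, grid, "SYN")
        row = next(r for r in res.summary if r.category_code == "Hg 3.3.1")
        assert row.pct_stations_within == 50.0
        assert row.pct_cells_within == 0.0

    def test_no_data_categories_marked(self, catalog, basin_polygon):
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.0}), catalog)
        res = run_assessment(ms, catalog, _grid(basin_polygon), "SYN")
        row = next(r for r in res.summary if r.category_code == "Cd 3.2.5")
        assert row.no_data
        assert row.spatial_coverage_pct is None

    def test_single_year_mode_filters(self, catalog, basin_polygon):
        ms, _ = gen_dataset(
            _scenario({"Hg 3.3.1": 0.0}, years=(2008, 2009)), catalog
        )
        res = run_assessment(
            ms, catalog, _grid(basin_polygon), "SYN",
            mode="single_year", year=2008,
        )
        row = next(r for r in res.summary if r.category_code == "Hg 3.3.1")
        assert row.n_data == len(ms) // 2

    def test_station_year_votes_in_whole_period(self, catalog, basin_polygon):
        """A station sampled in three years contributes three cell votes."""
        ms, _ = gen_dataset(
            _scenario({"Hg 3.3.1": 0.0}, n_stations=1,
                      years=(2008, 2009, 2010), n_per=1),
            catalog,
        )
        res = run_assessment(ms, catalog, _grid(basin_polygon), "SYN")
        (cell,) = res.cell_assessments["Hg 3.3.1"].values()
        assert cell.n_stations_code1 == 3

    def test_complement_identity_random_summaries(self, catalog, basin_polygon):
        """within% + outside% stays in [99.9, 100.1] at every level."""
        grid = _grid(basin_polygon)
        rng = np.random.default_rng(0)
        for i in range(25):
            f = float(rng.uniform(0, 1))
            ms, _ = gen_dataset(
                _scenario({"Hg 3.3.1": f}, n_stations=6, seed=i), catalog
            )
            res = run_assessment(ms, catalog, grid, "SYN")
            for r in res.summary:
                if r.no_data:
                    continue
                for a, b in [
                    (r.pct_data_within, r.pct_data_outside),
                    (r.pct_stations_within, r.pct_stations_outside),
                    (r.pct_cells_within, r.pct_cells_outside),
                ]:
                    assert 99.9 <= a + b <= 100.1

    def test_class_totals_sum_to_grand_total(self, catalog, basin_polygon):
        ms, _ = gen_dataset(
            _scenario({"Hg 3.3.1": 0.0, "Benzo(a)pyrene 6.1.6": 0.0,
                       "Dioxins 5.3": 0.0}),
            catalog,
        )
        res = run_assessment(ms, catalog, _grid(basin_polygon), "SYN")
        totals = class_totals(res.summary, catalog)
        assert totals["total"] == len(ms)
        assert totals["metals"] + totals["pahs"] + totals["hocs"] == totals["total"]


class TestMaps:
    def test_colors_match_codes(self, catalog, basin_polygon):
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.3}), catalog)
        grid = _grid(basin_polygon)
        res = run_assessment(ms, catalog, grid, "SYN")
        geo = render_maps(res.cell_assessments["Hg 3.3.1"], grid)
        for f in geo["features"]:
            p = f["properties"]
            assert p["color"] == {1: "green", 2: "red"}[p["code"]]

    def test_all_green_when_compliant(self, catalog, basin_polygon):
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.0}), catalog)
        grid = _grid(basin_polygon)
        res = run_assessment(ms, catalog, grid, "SYN")
        geo = render_maps(res.cell_assessments["Hg 3.3.1"], grid)
        assert {f["properties"]["color"] for f in geo["features"]} == {"green"}

    def test_round_trip_preserves_codes(self, tmp_path, catalog, basin_polygon):
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.5}), catalog)
        grid = _grid(basin_polygon)
        res = run_assessment(ms, catalog, grid, "SYN")
        geo = render_maps(res.cell_assessments["Hg 3.3.1"], grid)
        p = tmp_path / "map.geojson"
        write_geojson(geo, p)
        back = json.loads(p.read_text(encoding="utf-8"))
        codes = {
            (f["properties"]["row"], f["properties"]["col"]):
            f["properties"]["code"]
            for f in back["features"]
        }
        assert codes == {
            cid: a.code
            for cid, a in res.cell_assessments["Hg 3.3.1"].items()
        }

    def test_png_render_writes_image(self, tmp_path, catalog, basin_polygon):
        from msfd9.reporting import render_png

        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.5}, n_stations=5), catalog)
        grid = _grid(basin_polygon)
        res = run_assessment(ms, catalog, grid, "SYN")
        p = tmp_path / "map.png"
        render_png(res.cell_assessments["Hg 3.3.1"], grid, p)
        assert p.stat().st_size > 0

    def test_dangling_cell_is_hard_error(self, catalog, basin_polygon):
        grid = _grid(basin_polygon)
        bogus = {
            (999, 999): CellAssessment((999, 999), "Hg 3.3.1", 1, 1, 0)
        }
        with pytest.raises(ValueError, match="outside the grid"):
            render_maps(bogus, grid)

    def test_consistency_with_summary(self, catalog, basin_polygon):
        """pct_cells_within recomputed from the map equals the summary."""
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.4, }), catalog)
        grid = _grid(basin_polygon)
        res = run_assessment(ms, catalog, grid, "SYN")
        geo = render_maps(res.cell_assessments["Hg 3.3.1"], grid)
        greens = sum(
            1 for f in geo["features"] if f["properties"]["color"] == "green"
        )
        n = len(geo["features"])
        row = next(r for r in res.summary if r.category_code == "Hg 3.3.1")
        assert row.pct_cells_within == round_half_up(100 * greens / n)


class TestExports:
    def test_summary_csv_marks_no_data(self, tmp_path, catalog, basin_polygon):
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.0}), catalog)
        res = run_assessment(ms, catalog, _grid(basin_polygon), "SYN")
        p = tmp_path / "summary.csv"
        write_summary_csv(res.summary, p)
        lines = p.read_text(encoding="utf-8").splitlines()
        assert len(lines) == 1 + len(res.summary)
        no_data_line = next(l for l in lines if l.startswith("SYN,Cd 3.2.5"))
        assert ",-," in no_data_line

    def test_table_has_verbatim_row_labels(self, catalog, basin_polygon):
        ms, _ = gen_dataset(_scenario({"Hg 3.3.1": 0.0}), catalog)
        res = run_assessment(ms, catalog, _grid(basin_polygon), "SYN")
        table = format_summary_table(res.summary)
        for label in [
            "% of spatial coverage",
            "% of data within the limits",
            "% of station within the limits",
            "% of cells within the limits",
        ]:
            assert label in table
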