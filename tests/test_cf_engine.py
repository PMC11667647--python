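import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from biocf import cf_engine, spatial_overlay
from biocf.cf_engine import (
    MissingRegionError,
    UncharacterizableError,
    aggregate_cf_area_weighted,
    aggregate_cf_flow_weighted,
    apply_proxy_nearest,
    apply_proxy_touching_average,
    compare_proxy_methods,
    fill_missing_region_cfs,
    marginality_check,
)
from conftest import brute_force_area_cfs, brute_force_flow_cfs


def native_table(rows):
    """rows: (ecoregion, lut, cf, realm, biome, status)"""
    return pd.DataFrame(
        rows,
        columns=["ecoregion_id", "land_use_type", "cf_pdf_per_km2", "realm", "biome", "status"],
    ).assign(proxy_source="")


def two_polygon_world(cfs=(1e-15, 3e-15), production=(25.0, 75.0)):
    polygons = pd.DataFrame(
        {
            "polygon_id": ["A|e1", "A|e2"],
            "region_id": ["A", "A"],
            "ecoregion_id": ["e1", "e2"],
            "area_km2": [50.0, 50.0],
        }
    )
    P = pd.DataFrame(
        {
            "polygon_id": ["A|e1", "A|e2"],
            "region_id": ["A", "A"],
            "ecoregion_id": ["e1", "e2"],
            "crop_id": ["wheat", "wheat"],
            "production_km2": list(production),
        }
    )
    native = native_table(
        [
            ("e1", "Annual", cfs[0], "Palearctic", "b1", "observed"),
            ("e2", "Annual", cfs[1], "Palearctic", "b1", "observed"),
        ]
    )
    return P, native, polygons


class TestFlowWeighted:
    def test_production_weighted_mean_oracle(self):
        """CFs {1e-15, 3e-15} with production {25, 75} km² → 2.5e-15."""
        P, native, polygons = two_polygon_world()
        out = aggregate_cf_flow_weighted(P, native, polygons)
        assert out["cf_pdf_per_km2"].iloc[0] == pytest.approx(2.5e-15, rel=1e-12)
        assert (out["method"] == "flow_weighted").all()
        assert out["coverage"].iloc[0] == 1.0

    def test_all_production_in_one_polygon_gives_native_cf(self):
        P, native, polygons = two_polygon_world(production=(0.0, 80.0))
        out = aggregate_cf_flow_weighted(P, native, polygons)
        assert out["cf_pdf_per_km2"].iloc[0] == pytest.approx(3e-15, rel=1e-12)

    def test_equal_production_gives_arithmetic_mean(self):
        P, native, polygons = two_polygon_world(production=(40.0, 40.0))
        out = aggregate_cf_flow_weighted(P, native, polygons)
        assert out["cf_pdf_per_km2"].iloc[0] == pytest.approx(2e-15, rel=1e-12)

    def test_missing_cf_polygon_excluded_and_renormalized(self):
        P, native, polygons = two_polygon_world()
        native.loc[native["ecoregion_id"] == "e1", ["cf_pdf_per_km2", "status"]] = [np.nan, "missing"]
        out = aggregate_cf_flow_weighted(P, native, polygons)
        assert out["cf_pdf_per_km2"].iloc[0] == pytest.approx(3e-15, rel=1e-12)
        assert out["coverage"].iloc[0] == pytest.approx(0.75)

    def test_positive_production_with_no_characterizable_polygon_errors(self):
        P, native, polygons = two_polygon_world()
        native["status"] = "missing"
        native["cf_pdf_per_km2"] = np.nan
        with pytest.raises(UncharacterizableError, match="wheat"):
            aggregate_cf_flow_weighted(P, native, polygons)

    def test_zero_production_pair_falls_back_to_area_weighting(self):
        P, native, polygons = two_polygon_world(production=(0.0, 0.0))
        out = aggregate_cf_flow_weighted(P, native, polygons)
        assert out["coverage"].iloc[0] == 0.0
        assert out["provenance"].iloc[0] == "zero_production_fallback"
        # equal areas → plain mean of the two native CFs
        assert out["cf_pdf_per_km2"].iloc[0] == pytest.approx(2e-15, rel=1e-12)


class TestAreaWeighted:
    def test_land_share_weighted_mean_oracle(self):
        """Shares {0.215, 0.785} with CFs {4e-15, 1e-15} → 1.645e-15."""
        shares = pd.DataFrame(
            {"region_id": ["A", "A"], "ecoregion_id": ["e1", "e2"], "land_share": [0.215, 0.785]}
        )
        native = native_table(
            [
                ("e1", "Annual", 4e-15, "r", "b", "observed"),
                ("e2", "Annual", 1e-15, "r", "b", "observed"),
            ]
        )
        out = aggregate_cf_area_weighted(shares, native, crops=["wheat"])
        assert out["cf_pdf_per_km2"].iloc[0] == pytest.approx(1.645e-15, rel=1e-12)

    def test_uniform_cf_field_is_share_independent(self):
        shares = pd.DataFrame(
            {"region_id": ["A", "A"], "ecoregion_id": ["e1", "e2"], "land_share": [0.9, 0.1]}
        )
        native = native_table(
            [
                ("e1", "Annual", 7e-15, "r", "b", "observed"),
                ("e2", "Annual", 7e-15, "r", "b", "observed"),
            ]
        )
        out = aggregate_cf_area_weighted(shares, native, crops=["wheat"])
        assert out["cf_pdf_per_km2"].iloc[0] == pytest.approx(7e-15, rel=1e-15)

    def test_same_land_use_type_crops_share_identical_cf(self, small_world, lut):
        polygons = spatial_overlay.polygons_from_cells(small_world.cells)
        shares = spatial_overlay.compute_land_shares(polygons)
        out = aggregate_cf_area_weighted(
            shares, small_world.native_cfs, crops=["wheat", "sugar"]
        )
        wide = out.pivot(index="region_id", columns="crop_id", values="cf_pdf_per_km2")
        pd.testing.assert_series_equal(
            wide["wheat"], wide["sugar"], check_names=False
        )


class TestProxyNearest:
    def fixture(self):
        """Gap in e1; nearer candidate in the wrong biome, farther in the right one."""
        native = native_table(
            [
                ("e1", "Annual", np.nan, "Palearctic", "desert", "missing"),
                ("e2", "Annual", 5e-15, "Palearctic", "forest", "observed"),  # near, wrong biome
                ("e3", "Annual", 2e-15, "Palearctic", "desert", "observed"),  # far, right biome
            ]
        )
        centroids = pd.DataFrame(
            {"ecoregion_id": ["e1", "e2", "e3"], "x": [0.0, 1.0, 50.0], "y": [0.0, 0.0, 0.0]}
        )
        polygons = pd.DataFrame(
            {
                "polygon_id": ["A|e1", "A|e2", "A|e3"],
                "region_id": ["A"] * 3,
                "ecoregion_id": ["e1", "e2", "e3"],
                "area_km2": [10.0] * 3,
            }
        )
        P = pd.DataFrame(
            {
                "polygon_id": ["A|e1"],
                "region_id": ["A"],
                "ecoregion_id": ["e1"],
                "crop_id": ["wheat"],
                "production_km2": [5.0],
            }
        )
        return native, P, polygons, centroids

    def test_same_realm_same_biome_beats_nearer_different_biome(self):
        native, P, polygons, centroids = self.fixture()
        out, log = apply_proxy_nearest(native, P, polygons, centroids)
        row = out[out["ecoregion_id"] == "e1"].iloc[0]
        assert row["status"] == "proxied"
        assert row["proxy_source"] == "e3"
        assert row["cf_pdf_per_km2"] == 2e-15
        assert log.applied["rule"].iloc[0] == "nearest_same_realm_biome"

    def test_gap_without_crops_stays_missing(self):
        native, P, polygons, centroids = self.fixture()
        P = P.assign(production_km2=[0.0])
        out, log = apply_proxy_nearest(native, P, polygons, centroids)
        assert out[out["ecoregion_id"] == "e1"]["status"].iloc[0] == "missing"
        assert log.applied.empty and not log.unresolved

    def test_no_candidate_leaves_unresolved_diagnostic(self):
        native, P, polygons, centroids = self.fixture()
        native.loc[native["ecoregion_id"] == "e3", "biome"] = "forest"
        out, log = apply_proxy_nearest(native, P, polygons, centroids)
        assert out[out["ecoregion_id"] == "e1"]["status"].iloc[0] == "missing"
        assert ("e1", "Annual") in log.unresolved

    def test_proxied_entry_shares_realm_and_biome_with_source(self, small_world):
        polygons = spatial_overlay.polygons_from_cells(small_world.cells)
        P = spatial_overlay.allocate_production(small_world.production, polygons).crop_areas
        out, _ = apply_proxy_nearest(small_world.native_cfs, P, polygons, small_world.centroids)
        labels = small_world.native_cfs.drop_duplicates("ecoregion_id").set_index("ecoregion_id")
        for row in out[out["status"] == "proxied"].itertuples():
            src = labels.loc[row.proxy_source]
            assert (src["realm"], src["biome"]) == (row.realm, row.biome)


class TestProxyTouchingAverage:
    def fixture(self):
        native = native_table(
            [
                ("e1", "Annual", np.nan, "r", "b", "missing"),
                ("e2", "Annual", 2.0, "r", "b", "observed"),
                ("e3", "Annual", 4.0, "r", "b", "observed"),
                ("e4", "Annual", 99.0, "r", "b", "observed"),  # not touching
            ]
        )
        adjacency = pd.DataFrame(
            {"ecoregion_a": ["e1", "e1", "e3"], "ecoregion_b": ["e2", "e3", "e4"]}
        )
        P = pd.DataFrame(
            {
                "region_id": ["A"],
                "ecoregion_id": ["e1"],
                "crop_id": ["wheat"],
                "production_km2": [1.0],
            }
        )
        return native, P, adjacency

    def test_mean_of_touching_neighbours(self):
        native, P, adjacency = self.fixture()
        out, _ = apply_proxy_touching_average(native, P, adjacency)
        assert out[out["ecoregion_id"] == "e1"]["cf_pdf_per_km2"].iloc[0] == 3.0

    def test_single_neighbour_copies_its_cf(self):
        native, P, adjacency = self.fixture()
        adjacency = adjacency.iloc[:1]
        out, _ = apply_proxy_touching_average(native, P, adjacency)
        assert out[out["ecoregion_id"] == "e1"]["cf_pdf_per_km2"].iloc[0] == 2.0

    def test_no_observed_neighbour_is_unresolved(self):
        native, P, adjacency = self.fixture()
        native.loc[native["ecoregion_id"].isin(["e2", "e3"]), "status"] = "missing"
        out, log = apply_proxy_touching_average(native, P, adjacency)
        assert ("e1", "Annual") in log.unresolved

    def test_comparison_harness_reports_small_differences(self, small_world):
        polygons = spatial_overlay.polygons_from_cells(small_world.cells)
        P = spatial_overlay.allocate_production(small_world.production, polygons).crop_areas
        table = compare_proxy_methods(
            small_world.native_cfs,
            P,
            polygons,
            small_world.centroids,
            small_world.adjacency,
        )
        assert {"region_id", "crop_id", "relative_difference"} <= set(table.columns)
        assert len(table) > 0
        assert table["relative_difference"].abs().max() < 1.0  # same order of magnitude


class TestFillMissingRegions:
    def aggregated(self):
        return pd.DataFrame(
            {
                "region_id": ["A", "B"],
                "crop_id": ["wheat", "wheat"],
                "land_use_type": ["Annual", "Annual"],
                "cf_pdf_per_km2": [1e-15, 3e-15],
                "method": ["area_weighted", "area_weighted"],
                "coverage": [1.0, 1.0],
                "provenance": ["native", "native"],
            }
        )

    def context(self):
        polygons = pd.DataFrame(
            {
                "polygon_id": ["A|e1", "B|e2"],
                "region_id": ["A", "B"],
                "ecoregion_id": ["e1", "e2"],
                "area_km2": [30.0, 70.0],
            }
        )
        native = native_table(
            [
                ("e1", "Annual", 1e-15, "r", "b", "observed"),
                ("e2", "Annual", 3e-15, "r", "b", "observed"),
            ]
        )
        return polygons, native

    def test_alias_takes_priority_over_continent(self):
        polygons, native = self.context()
        out = fill_missing_region_cfs(
            self.aggregated(),
            continent_map={"A": "K", "B": "K", "T": "K"},
            alias_map={"T": "B"},
            native_cfs=native,
            polygons=polygons,
        )
        row = out[out["region_id"] == "T"].iloc[0]
        assert row["provenance"] == "alias"
        assert row["cf_pdf_per_km2"] == 3e-15

    def test_unaliased_gap_gets_continental_cf_recomputed_from_polygons(self):
        polygons, native = self.context()
        out = fill_missing_region_cfs(
            self.aggregated(),
            continent_map={"A": "K", "B": "K", "G": "K"},
            native_cfs=native,
            polygons=polygons,
        )
        row = out[out["region_id"] == "G"].iloc[0]
        assert row["provenance"] == "continent"
        # pooled land shares 0.3/0.7 over the two member polygons
        assert row["cf_pdf_per_km2"] == pytest.approx(0.3 * 1e-15 + 0.7 * 3e-15, rel=1e-12)

    def test_fully_covered_table_is_returned_unchanged(self):
        out = fill_missing_region_cfs(self.aggregated(), continent_map={"A": "K", "B": "K"})
        pd.testing.assert_frame_equal(out, self.aggregated())

    def test_gap_with_no_route_errors(self):
        with pytest.raises(MissingRegionError):
            fill_missing_region_cfs(
                self.aggregated(), continent_map={"A": "K", "B": "K", "G": "X"}
            )


class TestMarginality:
    def world(self, proxied_share):
        total = 100.0
        polygons = pd.DataFrame(
            {
                "polygon_id": ["A|e1", "A|e2"],
                "region_id": ["A", "A"],
                "ecoregion_id": ["e1", "e2"],
                "area_km2": [50.0, 50.0],
            }
        )
        P = pd.DataFrame(
            {
                "polygon_id": ["A|e1", "A|e2"],
                "region_id": ["A", "A"],
                "ecoregion_id": ["e1", "e2"],
                "crop_id": ["wheat", "wheat"],
                "production_km2": [total * (1 - proxied_share), total * proxied_share],
            }
        )
        native = native_table(
            [
                ("e1", "Annual", 1e-15, "r", "b", "observed"),
                ("e2", "Annual", 1e-15, "r", "b", "proxied"),
            ]
        )
        return P, native, polygons

    @pytest.mark.parametrize(
        "share,flagged", [(0.02, False), (0.03, False), (0.05, True), (0.0301, True)]
    )
    def test_flag_fires_strictly_above_three_percent(self, share, flagged):
        P, native, polygons = self.world(share)
        out = marginality_check(P, native, polygons)
        assert bool(out["flagged"].iloc[0]) is flagged
        assert out["proxied_fraction"].iloc[0] == pytest.approx(share)

    def test_no_proxies_means_zero_fractions(self):
        P, native, polygons = self.world(0.5)
        native["status"] = "observed"
        out = marginality_check(P, native, polygons)
        assert (out["proxied_fraction"] == 0).all()
        assert not out["flagged"].any()


class TestAggregationProperties:
    def test_convexity_both_methods(self, small_world, lut):
        polygons = spatial_overlay.polygons_from_cells(small_world.cells)
        P = spatial_overlay.allocate_production(small_world.production, polygons).crop_areas
        shares = spatial_overlay.compute_land_shares(polygons)
        native, _ = apply_proxy_nearest(
            small_world.native_cfs, P, polygons, small_world.centroids
        )
        char = native[native["status"].isin(["observed", "proxied"])]
        lo = char["cf_pdf_per_km2"].min()
        hi = char["cf_pdf_per_km2"].max()
        for table in (
            aggregate_cf_flow_weighted(P, native, polygons),
            aggregate_cf_area_weighted(shares, native, crops=sorted(P["crop_id"].unique())),
        ):
            assert (table["cf_pdf_per_km2"] >= lo - 1e-30).all()
            assert (table["cf_pdf_per_km2"] <= hi + 1e-30).all()

    def test_oracle_equivalence_on_small_world(self, small_world, lut):
        polygons = spatial_overlay.polygons_from_cells(small_world.cells)
        P = spatial_overlay.allocate_production(small_world.production, polygons).crop_areas
        shares = spatial_overlay.compute_land_shares(polygons)
        native, _ = apply_proxy_nearest(
            small_world.native_cfs, P, polygons, small_world.centroids
        )
        flow = aggregate_cf_flow_weighted(P, native, polygons)
        expected = brute_force_flow_cfs(P, native, polygons, lut)
        for (region, crop), cf in expected.items():
            got = flow.query("region_id == @region and crop_id == @crop")["cf_pdf_per_km2"].iloc[0]
            assert got == pytest.approx(cf, rel=1e-12)
        area = aggregate_cf_area_weighted(shares, native, crops=sorted(P["crop_id"].unique()))
        expected_area = brute_force_area_cfs(shares, native, lut, sorted(P["crop_id"].unique()))
        for (region, crop), cf in expected_area.items():
            got = area.query("region_id == @region and crop_id == @crop")["cf_pdf_per_km2"].iloc[0]
            assert got == pytest.approx(cf, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p1=st.floats(0.1, 100.0),
        p2=st.floats(0.1, 100.0),
        transfer=st.floats(0.0, 1.0),
        c1=st.floats(1e-16, 1e-13),
        c2=st.floats(1e-16, 1e-13),
    )
    def test_monotonicity_under_mass_transfer(self, p1, p2, transfer, c1, c2):
        """Moving production toward the higher-CF polygon never lowers the CF."""
        lo_cf, hi_cf = sorted([c1, c2])
        moved = transfer * p1
        before = aggregate_cf_flow_weighted(
            *two_polygon_world(cfs=(lo_cf, hi_cf), production=(p1, p2))
        )["cf_pdf_per_km2"].iloc[0]
        after = aggregate_cf_flow_weighted(
            *two_polygon_world(cfs=(lo_cf, hi_cf), production=(p1 - moved, p2 + moved))
        )["cf_pdf_per_km2"].iloc[0]
        assert after >= before * (1 - 1e-12)

    def test_flow_equals_area_when_production_proportional_to_area(self):
        polygons = pd.DataFrame(
            {
                "polygon_id": ["A|e1", "A|e2", "A|e3"],
                "region_id": ["A"] * 3,
                "ecoregion_id": ["e1", "e2", "e3"],
                "area_km2": [10.0, 30.0, 60.0],
            }
        )
        P = polygons.assign(crop_id="wheat", production_km2=polygons["area_km2"] * 0.2)
        native = native_table(
            [
                ("e1", "Annual", 1e-15, "r", "b", "observed"),
                ("e2", "Annual", 5e-15, "r", "b", "observed"),
                ("e3", "Annual", 2e-15, "r", "b", "observed"),
            ]
        )
        shares = spatial_overlay.compute_land_shares(polygons)
        flow = aggregate_cf_flow_weighted(P, native, polygons)["cf_pdf_per_km2"].iloc[0]
        area = aggregate_cf_area_weighted(shares, native, crops=["wheat"])["cf_pdf_per_km2"].iloc[0]
        assert flow == pytest.approx(area, rel=1e-12)
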