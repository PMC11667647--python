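"""Overlay of political and ecoregion layers; production allocation; land shares.

National characterization factors are built over the polygons obtained by
intersecting a political boundary layer with the terrestrial-ecoregion
layer, so that each resulting polygon is homogeneous in both region and
ecoregion. Gridded crop production is then allocated into those polygons
by cell centroid (whole-cell allocation: the source raster's granularity
does not support sub-cell splitting), and each region's ecoregion land
shares — the weights of the baseline CF aggregation — are the polygon
area fractions.

Two input routes are supported:

* real vector layers as ``{feature_id: shapely geometry}`` mappings,
  intersected geometrically (areas must be computed in an equal-area
  frame; record the projection in the output metadata);
* synthetic labelled cells, where (region, ecoregion) labels already
  define the partition and no geometry is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import Point
from shapely.validation import explain_validity

logger = logging.getLogger(__name__)


class InvalidGeometryError(ValueError):
    """A layer feature is invalid and could not be repaired."""


class EmptyRegionError(ValueError):
    """A region has zero total polygon area."""


def _polygon_id(region_id: str, ecoregion_id: str) -> str:
    return f"{region_id}|{ecoregion_id}"


def _repair(feature_id: str, geom):
    """Zero-width buffer repair; unrepairable features are hard errors."""
    if geom.is_empty:
        raise InvalidGeometryError(f"feature {feature_id!r} has empty geometry")
    if geom.is_valid:
        return geom
    fixed = geom.buffer(0)
    if not fixed.is_valid or fixed.is_empty:
        raise InvalidGeometryError(
            f"feature {feature_id!r} invalid and unrepairable: {explain_validity(geom)}"
        )
    logger.info("repaired invalid geometry for feature %r", feature_id)
    return fixed


def overlay_layers(
    political_layer: dict[str, "object"],
    ecoregion_layer: dict[str, "object"],
    *,
    coverage_rtol: float = 1e-3,
) -> tuple[pd.DataFrame, dict[str, "object"]]:
    """Intersect the two layers into (region, ecoregion) polygons.

    Returns the polygon table (polygon_id, region_id, ecoregion_id,
    area_km2) and the polygon geometries. Output polygons partition each
    region; if a region's polygon areas do not sum to its area within
    ``coverage_rtol`` (incomplete ecoregion coverage), a warning is
    logged. Regions intersecting no ecoregion get an empty-intersection
    warning and no rows.
    """
    political = {k: _repair(k, g) for k, g in political_layer.items()}
    ecoregions = {k: _repair(k, g) for k, g in ecoregion_layer.items()}

    rows = []
    geoms: dict[str, object] = {}
    for region_id, rg in political.items():
        hits = 0
        for eco_id, eg in ecoregions.items():
            inter = rg.intersection(eg)
            if inter.is_empty or inter.area <= 0:
                continue
            pid = _polygon_id(region_id, eco_id)
            rows.append(
                {
                    "polygon_id": pid,
                    "region_id": region_id,
                    "ecoregion_id": eco_id,
                    "area_km2": float(inter.area),
                }
            )
            geoms[pid] = inter
            hits += 1
        if hits == 0:
            logger.warning("region %r intersects no ecoregion feature", region_id)
            continue
        covered = sum(r["area_km2"] for r in rows if r["region_id"] == region_id)
        if abs(covered - rg.area) > coverage_rtol * rg.area:
            logger.warning(
                "region %r polygon areas cover %.6g of region area %.6g",
                region_id,
                covered,
                rg.area,
            )
    return pd.DataFrame(rows, columns=["polygon_id", "region_id", "ecoregion_id", "area_km2"]), geoms


def polygons_from_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Label-aggregation overlay: polygons are the (region, ecoregion) groups."""
    grouped = (
        cells.groupby(["region_id", "ecoregion_id"], as_index=False)["area_km2"].sum()
    )
    grouped.insert(
        0,
        "polygon_id",
        [_polygon_id(r, e) for r, e in zip(grouped["region_id"], grouped["ecoregion_id"])],
    )
    return grouped


@dataclass
class AllocationResult:
    """Outcome of allocating gridded production into overlay polygons."""

    crop_areas: pd.DataFrame  # polygon_id, region_id, ecoregion_id, crop_id, production_km2
    unassigned: pd.DataFrame  # cells outside every polygon, with their lost mass
    boundary_ties: list[str] = field(default_factory=list)

    @property
    def unassigned_mass(self) -> float:
        if self.unassigned.empty:
            return 0.0
        return float(self.unassigned["production_km2"].sum())


def allocate_production(
    gridded_production: pd.DataFrame,
    polygons: pd.DataFrame,
    geometries: dict[str, "object"] | None = None,
) -> AllocationResult:
    """Allocate per-cell crop production into overlay polygons.

    Whole-cell allocation by centroid: a cell's entire production goes to
    the polygon covering its centroid. A centroid on a shared boundary is
    assigned to the lexicographically smallest polygon_id and the tie is
    logged. Cells outside every polygon are reported with their mass as a
    diagnostic, never dropped silently. Production inside polygons is
    conserved exactly (values are moved, never rescaled).

    Without ``geometries``, the production table must carry ``region_id``
    and ``ecoregion_id`` labels and assignment is a direct label lookup.
    """
    prod = gridded_production.copy()
    if geometries is None:
        if not {"region_id", "ecoregion_id"} <= set(prod.columns):
            raise ValueError("label allocation needs region_id/ecoregion_id on production rows")
        key = polygons.set_index(["region_id", "ecoregion_id"])["polygon_id"]
        prod["polygon_id"] = pd.MultiIndex.from_frame(
            prod[["region_id", "ecoregion_id"]]
        ).map(key)
        ties: list[str] = []
    else:
        if not {"centroid_x", "centroid_y"} <= set(prod.columns):
            raise ValueError("geometric allocation needs centroid_x/centroid_y columns")
        ties = []
        assignment = {}
        centroids = prod[["cell_id", "centroid_x", "centroid_y"]].drop_duplicates("cell_id")
        ordered = sorted(geometries.items())
        for cell_id, cx, cy in centroids.itertuples(index=False):
            pt = Point(cx, cy)
            hits = [pid for pid, geom in ordered if geom.covers(pt)]
            if not hits:
                assignment[cell_id] = None
            else:
                if len(hits) > 1:
                    ties.append(cell_id)
                    logger.info(
                        "cell %r centroid on shared boundary of %s; assigned to %r",
                        cell_id,
                        hits,
                        hits[0],
                    )
                assignment[cell_id] = hits[0]
        prod["polygon_id"] = prod["cell_id"].map(assignment)

    unassigned = prod[prod["polygon_id"].isna()].drop(columns="polygon_id")
    assigned = prod[prod["polygon_id"].notna()]
    if not unassigned.empty:
        logger.warning(
            "%d production rows outside all polygons (mass %.6g km²)",
            len(unassigned),
            float(unassigned["production_km2"].sum()),
        )
    # fsum per group: polygon totals are the correctly rounded sums of
    # their cells' values, so conservation is exact group by group
    crop_areas = (
        assigned.groupby(["polygon_id", "crop_id"], as_index=False)["production_km2"]
        .agg(lambda s: math.fsum(s))
    )
    crop_areas = crop_areas.merge(
        polygons[["polygon_id", "region_id", "ecoregion_id"]], on="polygon_id"
    )[["polygon_id", "region_id", "ecoregion_id", "crop_id", "production_km2"]]
    if (crop_areas["production_km2"] < 0).any():
        raise ValueError("negative production areas")
    return AllocationResult(crop_areas=crop_areas, unassigned=unassigned, boundary_ties=ties)


def compute_land_shares(polygons: pd.DataFrame) -> pd.DataFrame:
    """Ecoregion land share per region: polygon area / region area.

    Shares form a probability vector per region. A region whose polygons
    have zero total area cannot be weighted and raises
    :class:`EmptyRegionError`.
    """
    totals = polygons.groupby("region_id")["area_km2"].sum()
    empty = totals[totals <= 0]
    if not empty.empty:
        raise EmptyRegionError(f"regions with zero total area: {list(empty.index)}")
    shares = polygons.merge(totals.rename("region_area"), on="region_id")
    shares["land_share"] = shares["area_km2"] / shares["region_area"]
    return shares[["region_id", "ecoregion_id", "land_share"]]
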