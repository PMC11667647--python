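"""Aggregation of native ecoregion characterization factors to regions.

A native land-occupation characterization factor (CF, PDF/km²) is
defined per ecoregion and cropland land-use type ("Annual" or
"Permanent"). Country-scale impact models need one CF per (region,
crop); two estimators are implemented:

* **flow-weighted** (the crop-specific method): the CF of crop j in
  region x is the production-weighted mean over the region's overlay
  polygons,

      LC_jx = Σ_i  P_ijx / (Σ_i P_ijx)  ·  C_ix,

  with P_ijx the physical production area of crop j in polygon i and
  C_ix the native CF of polygon i's ecoregion for the crop's land-use
  type;
* **area-weighted** (the baseline): the ecoregion land-share weighted
  mean per (region, land-use type), broadcast to every crop of that
  type — the weighting used by regionalized impact databases when no
  crop location data are available.

Both are convex combinations of native CFs, so every aggregate lies
within the [min, max] of its contributors, and both coincide when
production is proportional to polygon area.

Missing native CFs are handled by explicit rules: an ecoregion with
crop production but no CF borrows the CF of the nearest ecoregion of
the same realm and biome (validated against the alternative of averaging
all touching neighbours); ecoregions with neither CF nor crops are
treated as zeros and excluded, the weights being renormalized over the
characterizable polygons (the renormalization is recorded in output
metadata); regions with no aggregate at all fall back to an alias
region or to their continent's CF, recomputed with the same estimator
over the continent's polygons. A marginality diagnostic flags any
(region, crop) with more than 3% of its crop area in proxied
ecoregions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import land_use_lookup
from .spatial_overlay import compute_land_shares

logger = logging.getLogger(__name__)

#: Proxied crop-area fraction above which the marginality diagnostic fires.
MARGINALITY_THRESHOLD = 0.03

CHARACTERIZABLE = ("observed", "proxied")

#: Metadata attached to aggregated tables: the estimator renormalizes
#: weights over characterizable polygons when gaps are excluded.
NORMALIZATION_NOTE = "weights renormalized over characterizable polygons"


class UncharacterizableError(ValueError):
    """A (region, crop) has positive production but no characterizable CF."""


class MissingRegionError(ValueError):
    """A region cannot be filled by alias or continental fallback."""


@dataclass
class ProxyLog:
    """Record of gap treatments: applied proxies and unresolved gaps."""

    applied: pd.DataFrame = field(default_factory=pd.DataFrame)
    unresolved: list[tuple[str, str]] = field(default_factory=list)  # (ecoregion, land-use type)


def _ensure_ecoregion(P: pd.DataFrame, polygons: pd.DataFrame) -> pd.DataFrame:
    if "ecoregion_id" in P.columns and "region_id" in P.columns:
        return P
    return P.merge(polygons[["polygon_id", "region_id", "ecoregion_id"]], on="polygon_id")


def _gap_trigger(P: pd.DataFrame, polygons: pd.DataFrame, lut: dict[str, str]) -> pd.Series:
    """Crop area per (ecoregion, land_use_type) — the proxy trigger mass."""
    P = _ensure_ecoregion(P, polygons)
    P = P.assign(land_use_type=P["crop_id"].map(lut))
    return P.groupby(["ecoregion_id", "land_use_type"])["production_km2"].sum()


def apply_proxy_nearest(
    native_cfs: pd.DataFrame,
    P: pd.DataFrame,
    polygons: pd.DataFrame,
    centroids: pd.DataFrame,
    land_use_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ProxyLog]:
    """Fill CF gaps from the nearest same-realm, same-biome ecoregion.

    Only gaps in ecoregions that actually carry crop production of the
    affected land-use type are filled; gap ecoregions without crops are
    left missing (they are excluded from aggregation anyway). "Nearest"
    is the Euclidean distance between ecoregion centroids; ties go to
    the smaller ecoregion_id and are logged. A gap with no observed
    candidate in its realm and biome stays missing and is reported in
    the log's ``unresolved`` list.
    """
    lut = land_use_lookup(land_use_map)
    trigger = _gap_trigger(P, polygons, lut)
    pos = centroids.set_index("ecoregion_id")[["x", "y"]]

    out = native_cfs.copy()
    log_rows = []
    unresolved = []
    observed = out[out["status"] == "observed"]
    for idx, row in out[out["status"] == "missing"].iterrows():
        eco, lu = row["ecoregion_id"], row["land_use_type"]
        if trigger.get((eco, lu), 0.0) <= 0.0:
            continue
        cands = observed[
            (observed["land_use_type"] == lu)
            & (observed["realm"] == row["realm"])
            & (observed["biome"] == row["biome"])
            & (observed["ecoregion_id"] != eco)
        ]
        cands = cands[cands["ecoregion_id"].isin(pos.index)]
        if cands.empty or eco not in pos.index:
            unresolved.append((eco, lu))
            logger.warning("no same-realm same-biome proxy candidate for %s/%s", eco, lu)
            continue
        here = pos.loc[eco].to_numpy(dtype=float)
        there = pos.loc[cands["ecoregion_id"]].to_numpy(dtype=float)
        dist = np.hypot(*(there - here).T)
        ranked = cands.assign(_d=dist).sort_values(["_d", "ecoregion_id"])
        if len(ranked) > 1 and np.isclose(ranked["_d"].iloc[0], ranked["_d"].iloc[1]):
            logger.info(
                "proxy distance tie for %s/%s broken by ecoregion_id order", eco, lu
            )
        best = ranked.iloc[0]
        out.loc[idx, "cf_pdf_per_km2"] = best["cf_pdf_per_km2"]
        out.loc[idx, "status"] = "proxied"
        out.loc[idx, "proxy_source"] = best["ecoregion_id"]
        log_rows.append(
            {
                "ecoregion_id": eco,
                "land_use_type": lu,
                "proxy_source": best["ecoregion_id"],
                "rule": "nearest_same_realm_biome",
                "distance": float(best["_d"]),
            }
        )
    return out, ProxyLog(applied=pd.DataFrame(log_rows), unresolved=unresolved)


def apply_proxy_touching_average(
    native_cfs: pd.DataFrame,
    P: pd.DataFrame,
    adjacency: pd.DataFrame,
    polygons: pd.DataFrame | None = None,
    land_use_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ProxyLog]:
    """Fill CF gaps with the unweighted mean of touching neighbours' CFs.

    The validation alternative to the nearest-neighbour rule: same
    trigger (crop production present in the gap ecoregion), but the
    proxy value is the arithmetic mean of the observed CFs of all
    ecoregions sharing a border with the gap. ``adjacency`` is an
    undirected edge list with columns ecoregion_a, ecoregion_b.
    """
    lut = land_use_lookup(land_use_map)
    trigger = _gap_trigger(P, polygons if polygons is not None else P, lut)

    neighbours: dict[str, set[str]] = {}
    for a, b in adjacency[["ecoregion_a", "ecoregion_b"]].itertuples(index=False):
        neighbours.setdefault(a, set()).add(b)
        neighbours.setdefault(b, set()).add(a)

    out = native_cfs.copy()
    observed = out[out["status"] == "observed"]
    log_rows = []
    unresolved = []
    for idx, row in out[out["status"] == "missing"].iterrows():
        eco, lu = row["ecoregion_id"], row["land_use_type"]
        if trigger.get((eco, lu), 0.0) <= 0.0:
            continue
        touch = neighbours.get(eco, set())
        cands = observed[
            (observed["land_use_type"] == lu) & observed["ecoregion_id"].isin(touch)
        ]
        if cands.empty:
            unresolved.append((eco, lu))
            logger.warning("no touching neighbour with observed CF for %s/%s", eco, lu)
            continue
        value = float(cands["cf_pdf_per_km2"].mean())
        out.loc[idx, "cf_pdf_per_km2"] = value
        out.loc[idx, "status"] = "proxied"
        out.loc[idx, "proxy_source"] = ",".join(sorted(cands["ecoregion_id"]))
        log_rows.append(
            {
                "ecoregion_id": eco,
                "land_use_type": lu,
                "proxy_source": out.loc[idx, "proxy_source"],
                "rule": "touching_average",
                "distance": np.nan,
            }
        )
    return out, ProxyLog(applied=pd.DataFrame(log_rows), unresolved=unresolved)


def _native_join(
    P: pd.DataFrame,
    native_cfs: pd.DataFrame,
    polygons: pd.DataFrame,
    lut: dict[str, str],
) -> pd.DataFrame:
    P = _ensure_ecoregion(P, polygons).copy()
    P["land_use_type"] = P["crop_id"].map(lut)
    unknown = P.loc[P["land_use_type"].isna(), "crop_id"].unique()
    if len(unknown):
        raise KeyError(f"crops with no land-use type: {sorted(unknown)}")
    return P.merge(
        native_cfs[["ecoregion_id", "land_use_type", "cf_pdf_per_km2", "status"]],
        on=["ecoregion_id", "land_use_type"],
        how="left",
    )


def aggregate_cf_flow_weighted(
    P: pd.DataFrame,
    native_cfs: pd.DataFrame,
    polygons: pd.DataFrame,
    land_use_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Elementary-flow weighted aggregation: LC_jx = Σ_i w_ijx · C_ix.

    Weights w_ijx are the polygon production shares of crop j in region
    x. Polygons whose ecoregion CF is missing contribute neither to the
    numerator nor to the normalizer (exclusion + renormalization over
    characterizable polygons); ``coverage`` reports the characterized
    production fraction. A (region, crop) with positive production but
    zero characterizable production raises
    :class:`UncharacterizableError`. Zero-production pairs fall back to
    the area-weighted estimate (dense output), carrying coverage 0 and
    provenance "zero_production_fallback".
    """
    lut = land_use_lookup(land_use_map)
    joined = _native_join(P, native_cfs, polygons, lut)
    crops = sorted(joined["crop_id"].unique())
    regions = sorted(polygons["region_id"].unique())

    fallback_cache: dict[str, pd.DataFrame] = {}

    def area_fallback(region: str, crop: str) -> float:
        # computed lazily: only zero-production pairs need the baseline
        if "table" not in fallback_cache:
            fallback_cache["table"] = aggregate_cf_area_weighted(
                compute_land_shares(polygons), native_cfs, land_use_map, crops=crops
            ).set_index(["region_id", "crop_id"])
        return float(fallback_cache["table"].loc[(region, crop), "cf_pdf_per_km2"])

    char = joined["status"].isin(CHARACTERIZABLE) & joined["cf_pdf_per_km2"].notna()
    rows = []
    grouped = joined.groupby(["region_id", "crop_id"])
    sums = grouped["production_km2"].sum()
    for region in regions:
        for crop in crops:
            total = float(sums.get((region, crop), 0.0))
            if total > 0:
                sub = joined[
                    (joined["region_id"] == region) & (joined["crop_id"] == crop) & char
                ]
                char_total = float(sub["production_km2"].sum())
                if char_total <= 0:
                    raise UncharacterizableError(
                        f"region {region!r}, crop {crop!r}: positive production "
                        "but no characterizable polygon"
                    )
                cf = float((sub["production_km2"] * sub["cf_pdf_per_km2"]).sum() / char_total)
                coverage = char_total / total
                provenance = "native"
            else:
                cf = area_fallback(region, crop)
                coverage = 0.0
                provenance = "zero_production_fallback"
            rows.append(
                {
                    "region_id": region,
                    "crop_id": crop,
                    "land_use_type": lut[crop],
                    "cf_pdf_per_km2": cf,
                    "method": "flow_weighted",
                    "coverage": coverage,
                    "provenance": provenance,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["normalization"] = NORMALIZATION_NOTE
    return out


def aggregate_cf_area_weighted(
    shares: pd.DataFrame,
    native_cfs: pd.DataFrame,
    land_use_map: pd.DataFrame | None = None,
    *,
    crops: list[str] | None = None,
) -> pd.DataFrame:
    """Land-share weighted aggregation, broadcast per land-use type.

    The regional CF for a land-use type is Σ_e share_e · C_e over the
    region's characterizable ecoregions (shares renormalized over them),
    applied identically to every crop of that type. ``coverage`` here is
    the characterized land-share fraction.
    """
    lut = land_use_lookup(land_use_map)
    if crops is None:
        crops = list(lut)
    rows = []
    for region, sub in shares.groupby("region_id", sort=True):
        for lu in sorted({lut[c] for c in crops}):
            cf_rows = sub.merge(
                native_cfs[native_cfs["land_use_type"] == lu],
                on="ecoregion_id",
                how="left",
            )
            char = cf_rows[
                cf_rows["status"].isin(CHARACTERIZABLE) & cf_rows["cf_pdf_per_km2"].notna()
            ]
            w = float(char["land_share"].sum())
            if w <= 0:
                raise UncharacterizableError(
                    f"region {region!r}: no characterizable ecoregion for {lu} cropland"
                )
            cf = float((char["land_share"] * char["cf_pdf_per_km2"]).sum() / w)
            for crop in crops:
                if lut[crop] != lu:
                    continue
                rows.append(
                    {
                        "region_id": region,
                        "crop_id": crop,
                        "land_use_type": lu,
                        "cf_pdf_per_km2": cf,
                        "method": "area_weighted",
                        "coverage": w,
                        "provenance": "native",
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["normalization"] = NORMALIZATION_NOTE
    return out


def fill_missing_region_cfs(
    aggregated: pd.DataFrame,
    continent_map: dict[str, str],
    alias_map: dict[str, str] | None = None,
    *,
    P: pd.DataFrame | None = None,
    native_cfs: pd.DataFrame | None = None,
    polygons: pd.DataFrame | None = None,
    land_use_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Alias-then-continent fallback for regions with no aggregated CF.

    A gap region listed in ``alias_map`` copies the alias region's CFs
    (provenance "alias"). Otherwise its continent's CF is recomputed
    from the member regions' polygons with the same estimator that built
    ``aggregated`` — not by averaging national CFs — and applied
    (provenance "continent"). A region with neither route raises
    :class:`MissingRegionError`. A fully covered table is returned
    unchanged.
    """
    alias_map = alias_map or {}
    have = set(aggregated["region_id"].unique())
    gaps = [r for r in continent_map if r not in have]
    if not gaps:
        return aggregated
    method = aggregated["method"].iloc[0]

    continent_cache: dict[str, pd.DataFrame] = {}

    def continent_cf(continent: str) -> pd.DataFrame:
        if continent in continent_cache:
            return continent_cache[continent]
        if polygons is None or native_cfs is None:
            raise MissingRegionError(
                "continental recomputation requires polygons and native CFs"
            )
        members = [r for r, k in continent_map.items() if k == continent and r in set(polygons["region_id"])]
        if not members:
            raise MissingRegionError(f"continent {continent!r} has no member polygons")
        pooled_polys = polygons[polygons["region_id"].isin(members)].copy()
        pooled_polys["region_id"] = continent
        if method == "flow_weighted":
            if P is None:
                raise MissingRegionError("flow-weighted continental fill requires P")
            pooled_P = _ensure_ecoregion(P, polygons)
            pooled_P = pooled_P[pooled_P["region_id"].isin(members)].copy()
            pooled_P["region_id"] = continent
            table = aggregate_cf_flow_weighted(pooled_P, native_cfs, pooled_polys, land_use_map)
        else:
            pooled_shares = compute_land_shares(pooled_polys)
            table = aggregate_cf_area_weighted(
                pooled_shares, native_cfs, land_use_map,
                crops=sorted(aggregated["crop_id"].unique()),
            )
        continent_cache[continent] = table
        return table

    frames = [aggregated]
    for region in gaps:
        if region in alias_map:
            src = alias_map[region]
            block = aggregated[aggregated["region_id"] == src]
            if block.empty:
                raise MissingRegionError(f"alias source {src!r} for {region!r} has no CFs")
            block = block.assign(region_id=region, provenance="alias")
        else:
            table = continent_cf(continent_map[region])
            block = table.assign(region_id=region, provenance="continent")
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["normalization"] = NORMALIZATION_NOTE
    return out


def marginality_check(
    P: pd.DataFrame,
    native_cfs: pd.DataFrame,
    polygons: pd.DataFrame,
    land_use_map: pd.DataFrame | None = None,
    *,
    threshold: float = MARGINALITY_THRESHOLD,
) -> pd.DataFrame:
    """Fraction of each (region, crop)'s area in proxied ecoregions.

    Flags pairs strictly above the threshold (default 3% of the crop's
    area in the region) where the proxy assumption stops being a
    marginal correction.
    """
    lut = land_use_lookup(land_use_map)
    joined = _native_join(P, native_cfs, polygons, lut)
    joined["proxied_km2"] = joined["production_km2"].where(joined["status"] == "proxied", 0.0)
    agg = joined.groupby(["region_id", "crop_id"], as_index=False).agg(
        production_km2=("production_km2", "sum"),
        proxied_km2=("proxied_km2", "sum"),
    )
    agg["proxied_fraction"] = np.where(
        agg["production_km2"] > 0, agg["proxied_km2"] / agg["production_km2"], 0.0
    )
    agg["flagged"] = agg["proxied_fraction"] > threshold
    return agg[["region_id", "crop_id", "proxied_fraction", "flagged"]]


def compare_proxy_methods(
    native_cfs: pd.DataFrame,
    P: pd.DataFrame,
    polygons: pd.DataFrame,
    centroids: pd.DataFrame,
    adjacency: pd.DataFrame,
    land_use_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Relative difference of aggregated CFs under the two proxy rules.

    Runs the full flow-weighted aggregation once with nearest-neighbour
    proxies and once with touching-neighbour averages, and reports the
    per-(region, crop) relative CF difference — the validation check
    that the choice of proxy rule has negligible effect.
    """
    near, _ = apply_proxy_nearest(native_cfs, P, polygons, centroids, land_use_map)
    touch, _ = apply_proxy_touching_average(native_cfs, P, adjacency, polygons, land_use_map)
    a = aggregate_cf_flow_weighted(P, near, polygons, land_use_map)
    b = aggregate_cf_flow_weighted(P, touch, polygons, land_use_map)
    merged = a.merge(
        b, on=["region_id", "crop_id"], suffixes=("_nearest", "_touching")
    )
    denom = merged["cf_pdf_per_km2_nearest"].where(merged["cf_pdf_per_km2_nearest"] != 0, np.nan)
    merged["relative_difference"] = (
        merged["cf_pdf_per_km2_touching"] - merged["cf_pdf_per_km2_nearest"]
    ) / denom
    return merged[
        ["region_id", "crop_id", "cf_pdf_per_km2_nearest", "cf_pdf_per_km2_touching", "relative_difference"]
    ]
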