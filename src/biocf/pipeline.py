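"""End-to-end orchestration: world → overlay → CFs → accounts → comparison.

One call runs the whole analysis on a synthetic world: aggregate the
native CFs with both estimators (flow-weighted and land-share weighted),
characterize the MRIO pressure accounts with each, and compare. This is
the surface the CLI, the acceptance script and the end-to-end tests
share.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cf_engine, spatial_overlay
from .accounts import compare_methods
from .mrio_engine import ImpactAccounts, biodiversity_accounts, build_characterization_matrix
from .synthetic_world import SyntheticWorld, WorldSpec, generate_world


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one pipeline run."""

    world: SyntheticWorld
    polygons: pd.DataFrame
    crop_areas: pd.DataFrame
    land_shares: pd.DataFrame
    native_cfs: pd.DataFrame  # post proxy treatment
    cf_flow: pd.DataFrame
    cf_area: pd.DataFrame
    accounts_flow: ImpactAccounts
    accounts_area: ImpactAccounts
    comparison: pd.DataFrame
    marginality: pd.DataFrame
    proxy_log: cf_engine.ProxyLog


def run_pipeline(
    spec_or_world: WorldSpec | SyntheticWorld,
    *,
    proxy: str = "nearest",
) -> PipelineResult:
    """Run the full analysis on a (generated) synthetic world.

    ``proxy`` selects the missing-CF rule: "nearest" (same realm and
    biome, nearest centroid) or "touching" (mean of touching
    neighbours).
    """
    world = (
        spec_or_world
        if isinstance(spec_or_world, SyntheticWorld)
        else generate_world(spec_or_world)
    )

    polygons = spatial_overlay.polygons_from_cells(world.cells)
    allocation = spatial_overlay.allocate_production(world.production, polygons)
    P = allocation.crop_areas
    shares = spatial_overlay.compute_land_shares(polygons)

    if proxy == "nearest":
        native, proxy_log = cf_engine.apply_proxy_nearest(
            world.native_cfs, P, polygons, world.centroids
        )
    elif proxy == "touching":
        native, proxy_log = cf_engine.apply_proxy_touching_average(
            world.native_cfs, P, world.adjacency, polygons
        )
    else:
        raise ValueError(f"unknown proxy rule {proxy!r}")

    cf_flow = cf_engine.aggregate_cf_flow_weighted(P, native, polygons)
    cf_area = cf_engine.aggregate_cf_area_weighted(
        shares, native, crops=sorted(P["crop_id"].unique())
    )
    marginality = cf_engine.marginality_check(P, native, polygons)

    C_flow = build_characterization_matrix(cf_flow, world.mrio.S)
    C_area = build_characterization_matrix(cf_area, world.mrio.S)
    acc_flow = biodiversity_accounts(world.mrio, C_flow, method="flow_weighted")
    acc_area = biodiversity_accounts(world.mrio, C_area, method="area_weighted")

    return PipelineResult(
        world=world,
        polygons=polygons,
        crop_areas=P,
        land_shares=shares,
        native_cfs=native,
        cf_flow=cf_flow,
        cf_area=cf_area,
        accounts_flow=acc_flow,
        accounts_area=acc_area,
        comparison=compare_methods(acc_flow, acc_area),
        marginality=marginality,
        proxy_log=proxy_log,
    )
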