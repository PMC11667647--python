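import math

import pandas as pd
import pytest

from biocf.concordance import land_use_lookup
from biocf.synthetic_world import WorldSpec, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A 3-region world with gaps and mid concentration, shared read-only."""
    spec = WorldSpec(
        n_regions=3,
        ecoregions_per_region=4,
        grid_cells_per_ecoregion=5,
        crops=("wheat", "sugar", "vegetable, fruit, nuts"),
        concentration=0.6,
        cf_gap_fraction=0.2,
        seed=11,
    )
    return generate_world(spec)


@pytest.fixture(scope="session")
def lut():
    return land_use_lookup()


def brute_force_flow_cfs(P, native_cfs, polygons, lut):
    """Independent plain-loop recomputation of flow-weighted CFs.

    Excludes polygons with missing CFs from numerator and normalizer,
    mirroring the treat-as-zero rule. Returns {(region, crop): cf} for
    pairs with positive characterizable production.
    """
    poly = {p.polygon_id: (p.region_id, p.ecoregion_id) for p in polygons.itertuples()}
    cf = {}
    for row in native_cfs.itertuples():
        if row.status in ("observed", "proxied") and not math.isnan(row.cf_pdf_per_km2):
            cf[(row.ecoregion_id, row.land_use_type)] = row.cf_pdf_per_km2
    num, den = {}, {}
    for row in P.itertuples():
        region, eco = poly[row.polygon_id]
        key = (region, row.crop_id)
        c = cf.get((eco, lut[row.crop_id]))
        if c is None:
            continue
        num[key] = num.get(key, 0.0) + row.production_km2 * c
        den[key] = den.get(key, 0.0) + row.production_km2
    return {k: num[k] / den[k] for k in num if den[k] > 0}


def brute_force_area_cfs(shares, native_cfs, lut, crops):
    """Independent plain-loop recomputation of land-share weighted CFs."""
    cf = {}
    for row in native_cfs.itertuples():
        if row.status in ("observed", "proxied") and not math.isnan(row.cf_pdf_per_km2):
            cf[(row.ecoregion_id, row.land_use_type)] = row.cf_pdf_per_km2
    out = {}
    for region in shares["region_id"].unique():
        sub = shares[shares["region_id"] == region]
        for crop in crops:
            lu = lut[crop]
            num = den = 0.0
            for row in sub.itertuples():
                c = cf.get((row.ecoregion_id, lu))
                if c is None:
                    continue
                num += row.land_share * c
                den += row.land_share
            if den > 0:
                out[(region, crop)] = num / den
    return out
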