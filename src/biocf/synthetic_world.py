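"""Seeded synthetic worlds for offline testing of the footprint pipeline.

A world consists of four linked layers:

1. a planar spatial grid of cells, each belonging to exactly one
   political region and one ecoregion (ecoregion areas deliberately
   unequal, via log-uniform cell areas);
2. native-scale characterization factors (CFs, PDF/km²) per ecoregion
   and cropland land-use type, with realm/biome labels and an optional
   fraction of entries deleted to exercise the missing-data proxy rules;
3. per-cell crop production areas whose spatial concentration in
   high-CF ecoregions is controlled by a single knob — the pattern, seen
   in northern temperate countries, of cropland crowding into the small,
   species-rich share of the territory;
4. a balanced toy MRIO whose crop stressor extensions reproduce the
   generated production totals exactly.

Geometry is abstract and planar: region r occupies the x-band
[10r, 10(r+1)], ecoregion e within it the y-band [10e, 10(e+1)], so
every (region, ecoregion) block is a 10×10 square. Cell areas are drawn
independently of this layout (they are bookkeeping quantities, not
planar extents). Ecoregions touch when their blocks share an edge.

All four generators are deterministic for a fixed ``WorldSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import DEFAULT_LAND_USE_TYPES, land_use_lookup
from .mrio_engine import MRIOSystem, spectral_radius

REALMS = ["Palearctic", "Nearctic", "Neotropic", "Afrotropic"]
BIOMES = [
    "Temperate broadleaf and mixed forests",
    "Deserts and xeric shrublands",
    "Tropical moist broadleaf forests",
    "Boreal forests/taiga",
]

BLOCK = 10.0  # planar side length of one (region, ecoregion) block

#: Median native CF, PDF/km². Land-occupation endpoint factors for
#: cropland are of order 1e-14 PDF/m² in the most sensitive regions,
#: i.e. 1e-8 PDF/km²; the generator centres one order of magnitude below.
CF_MEDIAN = 1e-9
CF_SIGMA = 1.0  # lognormal sigma of native CFs across ecoregions

CROPLAND_FRACTION = 0.3  # share of region area under crops
MAX_CELL_LOAD = 0.9  # cap on (crop area)/(cell area) per cell
TILT_STRENGTH = 4.0  # softmax temperature scale at concentration = 1


class BalancingError(RuntimeError):
    """MRIO row balancing failed within the bounded rescaling attempts."""


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic world.

    ``concentration`` in [0, 1] correlates production density with
    ecoregion CF magnitude: 0 means density proportional to cell area
    only, 1 makes density a strictly increasing function of the
    ecoregion's CF. ``cf_gap_fraction`` deletes that fraction of native
    CF entries (per land-use type) among ecoregions that are not their
    region's sole ecoregion, so every region stays characterizable.
    ``production_noise`` is the lognormal sd of a per-cell allocation
    jitter; the default 0 keeps the allocation exactly deterministic in
    the stated limits.
    """

    n_regions: int = 3
    ecoregions_per_region: int = 4
    grid_cells_per_ecoregion: int = 10
    crops: tuple[str, ...] = tuple(DEFAULT_LAND_USE_TYPES)
    sectors_per_region: int = 0  # 0 → len(crops) + 1
    concentration: float = 0.5
    cf_gap_fraction: float = 0.0
    production_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_regions", "ecoregions_per_region", "grid_cells_per_ecoregion"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("concentration", "cf_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.production_noise < 0:
            raise ValueError("production_noise must be >= 0")
        if not self.crops:
            raise ValueError("at least one crop required")
        n_sec = self.sectors_per_region or len(self.crops) + 1
        if n_sec < len(self.crops) + 1:
            raise ValueError("sectors_per_region must be >= number of crops + 1")
        object.__setattr__(self, "sectors_per_region", n_sec)

    @property
    def region_ids(self) -> list[str]:
        return [f"R{r}" for r in range(self.n_regions)]

    def ecoregion_ids(self, region: str) -> list[str]:
        return [f"{region}-E{e}" for e in range(self.ecoregions_per_region)]


# fixed stream offsets keep the four generators independent under one seed
_STREAMS = {"grid": 11, "cfs": 23, "production": 37, "mrio": 53}


def _stream_rng(spec: WorldSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, _STREAMS[stream]]))


def generate_spatial_grid(spec: WorldSpec) -> pd.DataFrame:
    """Grid cells with region/ecoregion labels, areas and planar centroids.

    Every (region, ecoregion) pair receives exactly
    ``spec.grid_cells_per_ecoregion`` cells; cell areas are log-uniform
    over [10, 1000] km² so ecoregion areas come out unequal. Centroids
    are scattered uniformly inside the ecoregion's block.
    """
    rng = _stream_rng(spec, "grid")
    rows = []
    for r, region in enumerate(spec.region_ids):
        for e, eco in enumerate(spec.ecoregion_ids(region)):
            x0, y0 = r * BLOCK, e * BLOCK
            n = spec.grid_cells_per_ecoregion
            areas = np.exp(rng.uniform(np.log(10.0), np.log(1000.0), size=n))
            cx = x0 + rng.uniform(0.5, BLOCK - 0.5, size=n)
            cy = y0 + rng.uniform(0.5, BLOCK - 0.5, size=n)
            for k in range(n):
                rows.append(
                    {
                        "cell_id": f"{eco}-C{k}",
                        "region_id": region,
                        "ecoregion_id": eco,
                        "area_km2": float(areas[k]),
                        "centroid_x": float(cx[k]),
                        "centroid_y": float(cy[k]),
                    }
                )
    return pd.DataFrame(rows)


def ecoregion_centroids(spec: WorldSpec) -> pd.DataFrame:
    """Deterministic block-centre centroid per ecoregion."""
    rows = []
    for r, region in enumerate(spec.region_ids):
        for e, eco in enumerate(spec.ecoregion_ids(region)):
            rows.append(
                {
                    "ecoregion_id": eco,
                    "x": (r + 0.5) * BLOCK,
                    "y": (e + 0.5) * BLOCK,
                }
            )
    return pd.DataFrame(rows)


def ecoregion_adjacency(spec: WorldSpec) -> pd.DataFrame:
    """Touching-neighbour edges from the block layout (shared block edges)."""
    edges = []
    for r in range(spec.n_regions):
        for e in range(spec.ecoregions_per_region):
            eco = f"R{r}-E{e}"
            if e + 1 < spec.ecoregions_per_region:
                edges.append((eco, f"R{r}-E{e + 1}"))
            if r + 1 < spec.n_regions:
                edges.append((eco, f"R{r + 1}-E{e}"))
    return pd.DataFrame(edges, columns=["ecoregion_a", "ecoregion_b"])


def generate_native_cfs(spec: WorldSpec, ecoregion_ids: list[str] | None = None) -> pd.DataFrame:
    """Native CF table per (ecoregion, land-use type) with labelled gaps.

    CFs are lognormal around :data:`CF_MEDIAN` with a shared per-ecoregion
    sensitivity (so Annual and Permanent factors of one ecoregion are
    correlated), strictly positive and finite. Realm labels cycle by
    region, biome labels by ecoregion position, giving same-realm,
    same-biome candidates for the nearest-neighbour proxy rule. A
    fraction ``cf_gap_fraction`` of entries per land-use type is deleted
    (status "missing", CF NaN), drawn only from ecoregions that are not
    their region's sole ecoregion.
    """
    if ecoregion_ids is None:
        ecoregion_ids = [e for reg in spec.region_ids for e in spec.ecoregion_ids(reg)]
    if not ecoregion_ids:
        raise ValueError("ecoregion list must be nonempty")
    rng = _stream_rng(spec, "cfs")
    rows = []
    for eco in ecoregion_ids:
        region, e_part = eco.rsplit("-E", 1)
        r_idx = int(region[1:])
        e_idx = int(e_part)
        base = CF_MEDIAN * np.exp(rng.normal(0.0, CF_SIGMA))
        for lut in ("Annual", "Permanent"):
            wobble = np.exp(rng.normal(0.0, 0.3))
            rows.append(
                {
                    "ecoregion_id": eco,
                    "land_use_type": lut,
                    "cf_pdf_per_km2": float(base * wobble),
                    "realm": REALMS[r_idx % len(REALMS)],
                    # period-2 biome cycle: any region with 3+ ecoregions
                    # contains same-realm same-biome proxy candidates
                    "biome": BIOMES[e_idx % 2],
                    "status": "observed",
                    "proxy_source": "",
                }
            )
    table = pd.DataFrame(rows)

    if spec.cf_gap_fraction > 0:
        sole = spec.ecoregions_per_region == 1
        eligible = [] if sole else list(ecoregion_ids)
        n_gaps = int(round(spec.cf_gap_fraction * len(eligible)))
        for lut in ("Annual", "Permanent"):
            if n_gaps == 0:
                break
            chosen = rng.choice(eligible, size=n_gaps, replace=False)
            mask = table["ecoregion_id"].isin(chosen) & (table["land_use_type"] == lut)
            table.loc[mask, "cf_pdf_per_km2"] = np.nan
            table.loc[mask, "status"] = "missing"
    return table


def generate_crop_production(
    spec: WorldSpec,
    cells: pd.DataFrame,
    native_cfs: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cell crop production areas, km², tilted toward high-CF ecoregions.

    Per region, a fixed cropland share of total area is split across
    crops (seeded Dirichlet) and allocated to cells with weight
    area × exp(strength · concentration · z), where z in [0, 1] is the
    rank-normalized native CF of the cell's ecoregion for the crop's
    land-use type. At concentration 0 the allocation is proportional to
    cell area alone; at 1 production density increases strictly with the
    ecoregion CF. Gapped CFs fall back to the observed median for the
    tilt only. Totals are rescaled per region if any cell would exceed
    :data:`MAX_CELL_LOAD` of its area, preserving all share structure.
    """
    rng = _stream_rng(spec, "production")
    lut = land_use_lookup()
    crop_lut = {c: lut.get(c, "Annual") for c in spec.crops}

    # tilt basis: fill gaps with the observed median so missing CFs do
    # not distort the allocation machinery (pivot, not pivot_table:
    # ecoregions missing both land-use types must stay in the index)
    cf_wide = native_cfs.pivot(
        index="ecoregion_id", columns="land_use_type", values="cf_pdf_per_km2"
    ).reindex(cells["ecoregion_id"].unique())
    cf_wide = cf_wide.apply(lambda col: col.fillna(col.median()))
    cf_wide = cf_wide.fillna(CF_MEDIAN)

    out_frames = []
    for region, reg_cells in cells.groupby("region_id", sort=True):
        reg_cells = reg_cells.sort_values("cell_id").reset_index(drop=True)
        region_area = reg_cells["area_km2"].sum()
        crop_shares = rng.dirichlet(np.ones(len(spec.crops)))
        totals = CROPLAND_FRACTION * region_area * crop_shares

        noise = (
            np.exp(rng.normal(0.0, spec.production_noise, size=(len(reg_cells), len(spec.crops))))
            if spec.production_noise > 0
            else np.ones((len(reg_cells), len(spec.crops)))
        )

        alloc = np.zeros((len(reg_cells), len(spec.crops)))
        for j, crop in enumerate(spec.crops):
            cf_col = cf_wide[crop_lut[crop]]
            eco_cf = reg_cells["ecoregion_id"].map(cf_col)
            # rank-normalize within the region: strictly monotone in CF
            ranks = eco_cf.rank(method="dense") - 1.0
            z = ranks / max(float(ranks.max()), 1.0)
            weight = reg_cells["area_km2"].to_numpy() * np.exp(
                TILT_STRENGTH * spec.concentration * z.to_numpy()
            ) * noise[:, j]
            alloc[:, j] = totals[j] * weight / weight.sum()

        load = alloc.sum(axis=1) / reg_cells["area_km2"].to_numpy()
        worst = load.max()
        if worst > MAX_CELL_LOAD:
            alloc *= MAX_CELL_LOAD / worst

        frame = pd.DataFrame(alloc, columns=list(spec.crops))
        frame.insert(0, "cell_id", reg_cells["cell_id"])
        out_frames.append(
            frame.melt(id_vars="cell_id", var_name="crop_id", value_name="production_km2")
        )
    out = pd.concat(out_frames, ignore_index=True)
    return out.merge(cells[["cell_id", "region_id", "ecoregion_id"]], on="cell_id")


def regional_crop_totals(production: pd.DataFrame) -> pd.DataFrame:
    """Sum per-cell production to (region, crop) totals in km²."""
    return (
        production.groupby(["region_id", "crop_id"], as_index=False)["production_km2"]
        .sum()
        .rename(columns={"production_km2": "area_km2"})
    )


def generate_mrio(spec: WorldSpec, crop_totals: pd.DataFrame, *, max_rescale: int = 40) -> MRIOSystem:
    """Balanced toy MRIO whose crop stressors reproduce ``crop_totals``.

    Each region has one sector per crop plus an aggregate rest-of-economy
    sector. Crop-sector prices are powers of two, so the stressor
    intensities S (km² per unit output) satisfy S·diag(x) = crop areas in
    exact floating point. Inter-industry coefficients are random with
    column sums < 0.6 (hence spectral radius < 1); rows whose implied
    final demand would go negative are damped, bounded by
    ``max_rescale`` halvings, after which :class:`BalancingError` is
    raised. Final demand is split across consuming regions by a seeded
    Dirichlet with an exact-sum closure on the last column.
    """
    rng = _stream_rng(spec, "mrio")
    crops = list(spec.crops)
    sectors = crops + [f"other{k}" for k in range(spec.sectors_per_region - len(crops))]
    regions = spec.region_ids
    index = pd.MultiIndex.from_product([regions, sectors], names=["region", "sector"])
    n = len(index)

    areas = crop_totals.set_index(["region_id", "crop_id"])["area_km2"]
    total_crop_area = float(areas.sum())
    x = pd.Series(0.0, index=index)
    intensity = pd.Series(0.0, index=index)
    for region in regions:
        for crop in crops:
            a = float(areas.get((region, crop), 0.0))
            price = float(2.0 ** rng.integers(0, 3))  # money per km², power of two
            x.loc[(region, crop)] = a * price if a > 0 else float(rng.uniform(0.5, 2.0))
            intensity.loc[(region, crop)] = 1.0 / price if a > 0 else 0.0
        for sec in sectors[len(crops):]:
            x.loc[(region, sec)] = float(rng.uniform(2.0, 5.0)) * max(total_crop_area, 1.0)

    A = rng.uniform(0.0, 1.0, size=(n, n))
    col_targets = rng.uniform(0.2, 0.6, size=n)
    A *= col_targets / A.sum(axis=0)

    xv = x.to_numpy()
    for _ in range(max_rescale):
        y_tot = xv - A @ xv
        short = y_tot < 0.02 * xv
        if not short.any():
            break
        A[short, :] *= 0.5
    else:
        raise BalancingError("could not achieve positive final demand for every sector")

    rho = spectral_radius(A)
    assert rho < 1.0, f"constructive bound violated: spectral radius {rho}"

    Z = pd.DataFrame(A * xv[None, :], index=index, columns=index)
    y_tot = xv - Z.to_numpy().sum(axis=1)

    shares = rng.dirichlet(np.ones(len(regions)), size=n)
    y_arr = shares * y_tot[:, None]
    # exact-sum closure: the last consuming region absorbs rounding
    y_arr[:, -1] = y_tot - y_arr[:, :-1].sum(axis=1)
    y = pd.DataFrame(y_arr, index=index, columns=regions)

    stress_index = pd.MultiIndex.from_product([regions, crops], names=["region", "crop"])
    S = pd.DataFrame(0.0, index=stress_index, columns=index)
    col_pos = {key: j for j, key in enumerate(index)}
    arr = S.to_numpy()
    for i, (region, crop) in enumerate(stress_index):
        arr[i, col_pos[(region, crop)]] = intensity.loc[(region, crop)]
    S = pd.DataFrame(arr, index=stress_index, columns=index)

    mrio = MRIOSystem(Z=Z, x=x, y=y, S=S)
    mrio.validate(rtol=1e-10)
    return mrio


@dataclass
class SyntheticWorld:
    """All generated layers of one world, plus derived helper tables."""

    spec: WorldSpec
    cells: pd.DataFrame
    native_cfs: pd.DataFrame
    production: pd.DataFrame
    mrio: MRIOSystem
    centroids: pd.DataFrame = field(default_factory=pd.DataFrame)
    adjacency: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_world(spec: WorldSpec) -> SyntheticWorld:
    """Run all four generators in order for one seeded world."""
    cells = generate_spatial_grid(spec)
    native = generate_native_cfs(spec)
    production = generate_crop_production(spec, cells, native)
    mrio = generate_mrio(spec, regional_crop_totals(production))
    return SyntheticWorld(
        spec=spec,
        cells=cells,
        native_cfs=native,
        production=production,
        mrio=mrio,
        centroids=ecoregion_centroids(spec),
        adjacency=ecoregion_adjacency(spec),
    )


def save_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write the world as plain CSVs plus a spec echo in world.json."""
    outdir = Path(outdir)
    (outdir / "mrio").mkdir(parents=True, exist_ok=True)
    world.cells.to_csv(outdir / "cells.csv", index=False)
    world.native_cfs.to_csv(outdir / "native_cfs.csv", index=False)
    world.production.to_csv(outdir / "production.csv", index=False)
    world.centroids.to_csv(outdir / "centroids.csv", index=False)
    world.adjacency.to_csv(outdir / "adjacency.csv", index=False)
    m = world.mrio
    m.Z.to_csv(outdir / "mrio" / "Z.csv")
    m.y.to_csv(outdir / "mrio" / "y.csv")
    m.x.rename("x").to_csv(outdir / "mrio" / "x.csv")
    m.S.to_csv(outdir / "mrio" / "S.csv")
    payload = asdict(world.spec)
    payload["crops"] = list(payload["crops"])
    (outdir / "world.json").write_text(json.dumps(payload, indent=2))


def load_world(indir: str | Path) -> SyntheticWorld:
    """Round-trip loader for :func:`save_world` output."""
    indir = Path(indir)
    payload = json.loads((indir / "world.json").read_text())
    payload["crops"] = tuple(payload["crops"])
    spec = WorldSpec(**payload)
    Z = pd.read_csv(indir / "mrio" / "Z.csv", index_col=[0, 1], header=[0, 1])
    y = pd.read_csv(indir / "mrio" / "y.csv", index_col=[0, 1])
    x = pd.read_csv(indir / "mrio" / "x.csv", index_col=[0, 1])["x"]
    S = pd.read_csv(indir / "mrio" / "S.csv", index_col=[0, 1], header=[0, 1])
    return SyntheticWorld(
        spec=spec,
        cells=pd.read_csv(indir / "cells.csv"),
        native_cfs=pd.read_csv(indir / "native_cfs.csv").fillna({"proxy_source": ""}),
        production=pd.read_csv(indir / "production.csv"),
        mrio=MRIOSystem(Z=Z, x=x, y=y, S=S),
        centroids=pd.read_csv(indir / "centroids.csv"),
        adjacency=pd.read_csv(indir / "adjacency.csv"),
    )
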