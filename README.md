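# biocf

Crop-specific national biodiversity characterization factors and
EE-MRIO biodiversity footprint accounts.

## What this is for

Land occupation by agriculture drives species loss, and the damage per
km² varies enormously between ecoregions. Regionalized life-cycle
impact assessment supplies that sensitivity as ecoregion-scale
characterization factors (CFs, in PDF/km² — potentially disappeared
fraction of species per km² of cropland occupied, per year). But
country-scale tools, in particular environmentally extended
multi-regional input–output (EE-MRIO) models, need one CF per country
and crop, and the standard way to get one — weighting ecoregion CFs by
ecoregion *land shares* — ignores where crops are actually grown.

`biocf` is for industrial-ecology and LCA practitioners who want to
quantify what that choice does to biodiversity footprints. It builds
national crop CFs by weighting native ecoregion CFs with gridded crop
*production* areas (elementary flows),

    LC_jx = Σ_i ( P_ijx / Σ_i P_ijx ) · C_ix

(P_ijx = production area of crop *j* in polygon *i* of region *x*;
C_ix = native CF of the polygon's ecoregion), contrasts them with the
land-share weighted baseline, and pushes both through a Leontief model:

    E = S L y            pressure footprint (km², by consuming region)
    F = S diag(x)        pressures at the point of production
    D_cba = C ⊙ S L y    consumption-based impacts (PDF·yr)
    D_pba = C ⊙ F        production-based impacts (PDF·yr)

It ships with a seeded synthetic-world generator (grid, native CFs with
gaps, tunably concentrated crop production, balanced toy MRIO) so the
whole chain — including the missing-data proxy rules and conservation
identities — is testable without the multi-gigabyte external databases.

## Worked example

```python
from biocf import WorldSpec, run_pipeline

spec = WorldSpec(
    n_regions=3, ecoregions_per_region=4, grid_cells_per_ecoregion=10,
    crops=("wheat", "sugar", "vegetable, fruit, nuts"),
    concentration=0.8,      # production tilted toward high-CF ecoregions
    cf_gap_fraction=0.15,   # 15% of native CFs deleted, proxy rules engaged
    seed=42,
)
r = run_pipeline(spec)

glob = r.comparison.query("region_id == 'GLOBAL' and perspective == 'pba'").iloc[0]
print(f"global PBA, flow-weighted CFs: {glob['impact_flow']:.3e} PDF·yr")
print(f"global PBA, area-weighted CFs: {glob['impact_area']:.3e} PDF·yr")
print(f"percent change:                {glob['pct_change']:+.1f}%")
```

prints

```
global PBA, flow-weighted CFs: 3.072e-05 PDF·yr
global PBA, area-weighted CFs: 1.504e-05 PDF·yr
percent change:                +104.2%
```

Read: on this world, production-based biodiversity impacts are
3.07×10⁻⁵ PDF·yr when crops are characterized by where they are
actually grown, versus 1.50×10⁻⁵ PDF·yr under land-share weighting —
the baseline underestimates impacts by half because cropland is
concentrated (knob at 0.8) in the species-sensitive ecoregions. With
`concentration=0` the two numbers coincide. Per-region rows of
`r.comparison` decompose the change (here +43.7%, +28.8% and +151.4%
for the three regions), `r.marginality` flags (region, crop) pairs with
more than 3% of their area under proxied CFs, and `r.accounts_flow.cba`
holds the consumption-based account by consuming region.

The same stages are scriptable from a shell:

```sh
biocf --output-dir out generate --config world.yaml --seed 42
biocf --output-dir out overlay
biocf --output-dir out build-cfs --method both --proxy nearest
biocf --output-dir out footprint --perspective both
biocf --output-dir out compare
```

## Layout

| module | role |
| --- | --- |
| `biocf.synthetic_world` | seeded world generator: grid, native CFs, production, balanced MRIO |
| `biocf.spatial_overlay` | political × ecoregion overlay, production allocation, land shares |
| `biocf.concordance` | source→target crop mapping, Annual/Permanent land-use typing |
| `biocf.cf_engine` | both CF aggregation estimators and all missing-data rules |
| `biocf.mrio_engine` | Leontief calculus, characterization matrix, impact accounts |
| `biocf.accounts` | method comparison, crop shares, rankings, CF distributions |
| `biocf.pipeline` | end-to-end orchestration |
| `biocf.cli` | `biocf` command-line interface |

See `docs/methods.md` for the model, the missing-data rules, the
generator's assumptions and known limitations.
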