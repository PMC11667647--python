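"""Comparison and reporting over characterized impact accounts.

Joins impact accounts built from the two CF aggregation methods into
percent-change tables, computes crop contribution shares and region
rankings, and summarizes CF distributions across regions. Percent
changes are always computed on PDF·yr impact totals; CF-level
distribution summaries are a separate surface so the two kinds of
contrast are never conflated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mrio_engine import ImpactAccounts

GLOBAL = "GLOBAL"
ALL_CROPS = "all"


def _totals(acc: ImpactAccounts, perspective: str) -> pd.DataFrame:
    """Impact per (region, crop): producing region for PBA, consuming for CBA."""
    if perspective == "pba":
        t = acc.pba.groupby(["producing_region", "crop_id"], as_index=False)["impact_pdf_yr"].sum()
        return t.rename(columns={"producing_region": "region_id"})
    t = acc.cba.groupby(["consuming_region", "crop_id"], as_index=False)["impact_pdf_yr"].sum()
    return t.rename(columns={"consuming_region": "region_id"})


def _pct_change(flow: pd.Series, area: pd.Series) -> tuple[pd.Series, pd.Series]:
    defined = area != 0
    pct = pd.Series(np.nan, index=flow.index)
    pct[defined] = 100.0 * (flow[defined] - area[defined]) / area[defined]
    return pct, defined


def compare_methods(D_flow: ImpactAccounts, D_area: ImpactAccounts) -> pd.DataFrame:
    """Per-(region, crop) and global contrast of the two CF methods.

    Both accounts must come from identical MRIO inputs, differing only
    in the characterization matrix. Rows where the baseline impact is
    zero keep the flow value and carry ``pct_defined = False`` rather
    than being dropped. Includes per-region "all"-crop rows and one
    GLOBAL summary row per perspective.
    """
    frames = []
    for persp in ("pba", "cba"):
        f = _totals(D_flow, persp).rename(columns={"impact_pdf_yr": "impact_flow"})
        a = _totals(D_area, persp).rename(columns={"impact_pdf_yr": "impact_area"})
        merged = f.merge(a, on=["region_id", "crop_id"], how="outer")
        if merged[["impact_flow", "impact_area"]].isna().any().any():
            raise ValueError(f"mismatched (region, crop) keys between accounts ({persp})")

        region_rows = merged.groupby("region_id", as_index=False)[["impact_flow", "impact_area"]].sum()
        region_rows["crop_id"] = ALL_CROPS
        glob = pd.DataFrame(
            {
                "region_id": [GLOBAL],
                "crop_id": [ALL_CROPS],
                "impact_flow": [merged["impact_flow"].sum()],
                "impact_area": [merged["impact_area"].sum()],
            }
        )
        block = pd.concat([merged, region_rows, glob], ignore_index=True)
        block.insert(0, "perspective", persp)
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out["pct_change"], out["pct_defined"] = _pct_change(out["impact_flow"], out["impact_area"])
    return out


def crop_contribution_shares(
    acc: ImpactAccounts,
    *,
    perspective: str = "pba",
    region_grouping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Share of each crop in a region group's total impact.

    ``region_grouping`` maps regions to groups (default: each region its
    own group). Shares are nonnegative and sum to 1 per group; a group
    with zero total impact emits zero-share rows flagged
    ``zero_total = True``.
    """
    t = _totals(acc, perspective)
    t["group"] = (
        t["region_id"].map(region_grouping) if region_grouping else t["region_id"]
    )
    g = t.groupby(["group", "crop_id"], as_index=False)["impact_pdf_yr"].sum()
    totals = g.groupby("group")["impact_pdf_yr"].transform("sum")
    g["zero_total"] = totals == 0
    g["share"] = np.where(g["zero_total"], 0.0, g["impact_pdf_yr"] / totals.where(totals != 0, 1.0))
    return g[["group", "crop_id", "impact_pdf_yr", "share", "zero_total"]]


def rank_regions(
    acc: ImpactAccounts,
    perspective: str,
    other: ImpactAccounts | None = None,
) -> pd.DataFrame:
    """Regions ordered by descending total impact; ties broken by id.

    With a second account the table adds its ranks and a
    ``rank_change = other_rank − rank`` column (positive = the region
    climbed when moving from ``other`` to ``acc``).
    """
    def ranked(a: ImpactAccounts) -> pd.DataFrame:
        t = _totals(a, perspective).groupby("region_id", as_index=False)["impact_pdf_yr"].sum()
        t = t.sort_values(["impact_pdf_yr", "region_id"], ascending=[False, True]).reset_index(drop=True)
        t["rank"] = np.arange(1, len(t) + 1)
        return t

    out = ranked(acc)
    if other is not None:
        prev = ranked(other)[["region_id", "rank"]].rename(columns={"rank": "other_rank"})
        out = out.merge(prev, on="region_id", how="left")
        out["rank_change"] = out["other_rank"] - out["rank"]
    return out


def cf_distribution_summary(*aggregated_tables: pd.DataFrame) -> pd.DataFrame:
    """Quartile summary of aggregated CFs per (crop, method) across regions.

    The cross-region spread of national CFs per crop, reported as
    min / q25 / median / q75 / max — the distribution contrast between
    aggregation methods, kept separate from impact percent changes.
    """
    table = pd.concat(aggregated_tables, ignore_index=True)
    return (
        table.groupby(["crop_id", "method"])["cf_pdf_per_km2"]
        .agg(
            min="min",
            q25=lambda s: s.quantile(0.25),
            median="median",
            q75=lambda s: s.quantile(0.75),
            max="max",
        )
        .reset_index()
    )
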