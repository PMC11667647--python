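"""Crop concordances and land-use typing.

Gridded crop inventories and MRIO stressor accounts rarely share a crop
classification: the gridded side resolves several dozen individual crops,
while the MRIO side carries a handful of aggregate crop stressor
categories. This module maps values keyed by source crops onto target
crops through an explicit weighted bipartite table, and assigns each
target crop the land-use type ("Annual" or "Permanent") that selects
which native characterization-factor surface applies to it.

The concordance table has columns ``source_crop``, ``target_crop``,
``weight``; weights are nonnegative and sum to one per source crop, so a
weight-complete mapping conserves total mass exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

ANNUAL = "Annual"
PERMANENT = "Permanent"

#: The eight aggregate crop stressor categories used on the MRIO side,
#: and the cropland land-use type that characterizes each.
DEFAULT_LAND_USE_TYPES: dict[str, str] = {
    "paddy rice": ANNUAL,
    "wheat": ANNUAL,
    "cereal grains nec": ANNUAL,
    "sugar": ANNUAL,
    "oil seeds": ANNUAL,
    "plant-based fibers": ANNUAL,
    "crops nec": ANNUAL,
    "vegetable, fruit, nuts": PERMANENT,
}

# Source-side (MapSPAM-style) crop codes mapped onto the eight target
# categories. The target names are authoritative; the source assignment
# is a packaged default that users should replace with their own audited
# table (every row is marked user_verified = "no").
_DEFAULT_SOURCE_MAP: dict[str, str] = {
    "whea": "wheat",
    "rice": "paddy rice",
    "maiz": "cereal grains nec",
    "barl": "cereal grains nec",
    "pmil": "cereal grains nec",
    "smil": "cereal grains nec",
    "sorg": "cereal grains nec",
    "ocer": "cereal grains nec",
    "pota": "vegetable, fruit, nuts",
    "swpo": "vegetable, fruit, nuts",
    "yams": "vegetable, fruit, nuts",
    "cass": "vegetable, fruit, nuts",
    "orts": "vegetable, fruit, nuts",
    "bean": "vegetable, fruit, nuts",
    "chic": "vegetable, fruit, nuts",
    "cowp": "vegetable, fruit, nuts",
    "pige": "vegetable, fruit, nuts",
    "lent": "vegetable, fruit, nuts",
    "opul": "vegetable, fruit, nuts",
    "soyb": "oil seeds",
    "grou": "oil seeds",
    "cnut": "oil seeds",
    "oilp": "oil seeds",
    "sunf": "oil seeds",
    "rape": "oil seeds",
    "sesa": "oil seeds",
    "ooil": "oil seeds",
    "sugc": "sugar",
    "sugb": "sugar",
    "cott": "plant-based fibers",
    "ofib": "plant-based fibers",
    "acof": "crops nec",
    "rcof": "crops nec",
    "coco": "crops nec",
    "teas": "crops nec",
    "toba": "crops nec",
    "bana": "vegetable, fruit, nuts",
    "plnt": "vegetable, fruit, nuts",
    "citr": "vegetable, fruit, nuts",
    "trof": "vegetable, fruit, nuts",
    "temf": "vegetable, fruit, nuts",
    "vege": "vegetable, fruit, nuts",
    "rest": "crops nec",
    "teaw": "crops nec",
    "toma": "vegetable, fruit, nuts",
    "onio": "vegetable, fruit, nuts",
}


class ConcordanceError(ValueError):
    """Raised when a mapping cannot be applied to the given table."""


class UnknownCropError(KeyError):
    """Raised when a crop has no land-use type assignment."""


def default_concordance() -> pd.DataFrame:
    """Packaged many-to-one source→target concordance.

    Returns a weighted bipartite table with all weights equal to 1 and a
    ``user_verified`` column set to ``"no"`` on every row: the target
    categories are fixed, but the source-side assignment is a convenience
    default, not an audited mapping.
    """
    rows = [
        {"source_crop": s, "target_crop": t, "weight": 1.0, "user_verified": "no"}
        for s, t in _DEFAULT_SOURCE_MAP.items()
    ]
    return pd.DataFrame(rows)


def default_land_use_map() -> pd.DataFrame:
    """Land-use type per target crop as a two-column table."""
    return pd.DataFrame(
        {
            "target_crop": list(DEFAULT_LAND_USE_TYPES),
            "land_use_type": list(DEFAULT_LAND_USE_TYPES.values()),
        }
    )


@dataclass
class ValidationReport:
    """Outcome of checking a concordance against source/target universes."""

    unmapped_sources: list[str] = field(default_factory=list)
    unknown_targets: list[str] = field(default_factory=list)
    weight_violations: list[tuple[str, float]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (self.unmapped_sources or self.unknown_targets or self.weight_violations)


def validate_concordance(
    concordance: pd.DataFrame,
    source_list: list[str],
    target_list: list[str],
    *,
    weight_tol: float = 1e-9,
) -> ValidationReport:
    """Check completeness and weight sums of a concordance.

    The report lists sources from ``source_list`` with no mapping row,
    mapped targets absent from ``target_list``, and source crops whose
    weights do not sum to 1 within ``weight_tol``. The concordance passes
    iff all three lists are empty.
    """
    report = ValidationReport()
    mapped_sources = set(concordance["source_crop"])
    report.unmapped_sources = sorted(set(source_list) - mapped_sources)
    report.unknown_targets = sorted(set(concordance["target_crop"]) - set(target_list))
    sums = concordance.groupby("source_crop")["weight"].sum()
    bad = sums[(sums - 1.0).abs() > weight_tol]
    report.weight_violations = [(str(k), float(v)) for k, v in bad.items()]
    if (concordance["weight"] < 0).any():
        neg = concordance.loc[concordance["weight"] < 0, "source_crop"]
        report.weight_violations.extend((str(s), float("nan")) for s in neg)
    return report


def map_crops(
    table: pd.DataFrame,
    concordance: pd.DataFrame,
    *,
    crop_col: str = "crop_id",
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Re-key a value table from source crops to target crops.

    Each target value is the weight-sum of the source values mapping to
    it; all non-crop, non-value columns are treated as grouping keys, so
    a table keyed by (polygon, source crop) comes back keyed by
    (polygon, target crop). Mass is conserved exactly for
    weight-complete concordances.

    Raises :class:`ConcordanceError` if a source crop with nonzero value
    has no mapping row.
    """
    if value_cols is None:
        value_cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c]) and c != crop_col]
    if table.empty:
        return table.copy()

    merged = table.merge(
        concordance[["source_crop", "target_crop", "weight"]],
        left_on=crop_col,
        right_on="source_crop",
        how="left",
    )
    unmapped = merged["target_crop"].isna()
    if unmapped.any():
        offending = merged.loc[unmapped & (merged[value_cols].abs().sum(axis=1) > 0), crop_col]
        if not offending.empty:
            raise ConcordanceError(
                f"source crops with nonzero values have no concordance entry: {sorted(set(offending))}"
            )
        merged = merged[~unmapped]
    for col in value_cols:
        merged[col] = merged[col] * merged["weight"]
    group_cols = [c for c in table.columns if c != crop_col and c not in value_cols]
    # fsum per group: weight-1 mappings conserve each target total exactly
    out = (
        merged.groupby(group_cols + ["target_crop"], as_index=False)[value_cols]
        .agg(lambda s: math.fsum(s))
        .rename(columns={"target_crop": crop_col})
    )
    return out[group_cols + [crop_col] + value_cols]


def assign_land_use_type(target_crop: str, land_use_map: pd.DataFrame | None = None) -> str:
    """Land-use type ("Annual"/"Permanent") for a target crop.

    Unknown crops — including excluded categories such as pasture — raise
    :class:`UnknownCropError`.
    """
    if land_use_map is None:
        mapping = DEFAULT_LAND_USE_TYPES
    else:
        mapping = dict(zip(land_use_map["target_crop"], land_use_map["land_use_type"]))
    try:
        return mapping[target_crop]
    except KeyError:
        raise UnknownCropError(
            f"no land-use type for crop {target_crop!r}; pasture and other "
            "non-crop categories are excluded from characterization"
        ) from None


def land_use_lookup(land_use_map: pd.DataFrame | None = None) -> dict[str, str]:
    """Plain dict view of a land-use map (default map if None)."""
    if land_use_map is None:
        return dict(DEFAULT_LAND_USE_TYPES)
    return dict(zip(land_use_map["target_crop"], land_use_map["land_use_type"]))
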