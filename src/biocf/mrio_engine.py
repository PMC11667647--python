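"""Leontief calculus and biodiversity characterization for an EE-MRIO system.

An environmentally extended multi-regional input-output (EE-MRIO) system
links final demand ``y`` to gross output ``x`` through the technical
coefficient matrix ``A`` and its Leontief inverse ``L = (I - A)^-1``.
Land-occupation stressors enter through the intensity matrix ``S`` (km²
of crop stressor per unit output), giving

* consumption-based pressure accounts ``E = S L y`` (one column per
  consuming region), and
* production-based accounts ``F = S diag(x)`` (pressure at the point of
  production).

Characterized biodiversity impacts apply a characterization matrix ``C``
(PDF/km², same shape as ``S``, a column for each region/sector and rows
for each region/crop stressor) elementwise:

    D_cba = C ⊙ (S L y),     D_pba = C ⊙ F

with results in PDF·yr for a year of land occupation. Direct pressures
of final demand are excluded: the accounts cover production serving
final demand only.

On a balanced system (``x = Z·1 + y·1``) the two perspectives agree
globally, since ``x = L (y·1)`` implies ``Σ D_pba = Σ D_cba``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

M2_PER_KM2 = 1e6


class NonProductiveEconomyError(ValueError):
    """Spectral radius of A is >= 1: the economy cannot meet any demand."""


class UnitMismatchError(ValueError):
    """Characterization unit does not match the stressor account unit."""


@dataclass
class MRIOSystem:
    """A multi-regional IO system with land-use stressor extensions.

    Attributes
    ----------
    Z : inter-industry flow matrix (money), index and columns are
        (region, sector) MultiIndexes.
    x : gross output vector (money), same index.
    y : final demand, one column per consuming region (money).
    S : stressor intensities, rows are (region, crop) land stressors,
        columns match Z (km² per unit output).
    """

    Z: pd.DataFrame
    x: pd.Series
    y: pd.DataFrame
    S: pd.DataFrame

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.Z.index.get_level_values(0)))

    @property
    def sectors(self) -> list[str]:
        return list(dict.fromkeys(self.Z.index.get_level_values(1)))

    def validate(self, rtol: float = 1e-8) -> None:
        """Check conformability, nonnegativity of x, and row balance."""
        n = len(self.x)
        if self.Z.shape != (n, n):
            raise ValueError(f"Z is {self.Z.shape}, expected ({n}, {n})")
        if self.y.shape[0] != n or self.S.shape[1] != n:
            raise ValueError("y rows and S columns must match x")
        if (self.x < 0).any():
            raise ValueError("negative gross output")
        supply = self.Z.sum(axis=1) + self.y.sum(axis=1)
        scale = np.maximum(self.x.to_numpy(), 1.0)
        resid = np.abs(self.x.to_numpy() - supply.to_numpy()) / scale
        if (resid > rtol).any():
            worst = float(resid.max())
            raise ValueError(f"row balance violated: max relative residual {worst:.3e}")


def technical_coefficients(Z: pd.DataFrame, x: pd.Series) -> pd.DataFrame:
    """A[i, j] = Z[i, j] / x[j]; zero-output columns become all-zero.

    A zero-output sector with nonzero intra-column flows is logged as an
    imbalance; the column is still zeroed by convention.
    """
    if (x < 0).any():
        raise ValueError("negative gross output")
    xv = x.to_numpy(dtype=float)
    zero = xv == 0
    if zero.any():
        bad = Z.loc[:, zero].to_numpy()
        if np.abs(bad).sum() > 0:
            logger.warning(
                "zero-output sectors with nonzero input flows; columns zeroed: %s",
                list(Z.columns[zero & (np.abs(Z.to_numpy()).sum(axis=0) > 0)]),
            )
    denom = np.where(zero, 1.0, xv)
    A = Z.div(pd.Series(denom, index=Z.columns), axis=1)
    A.loc[:, zero] = 0.0
    return A


def spectral_radius(A: pd.DataFrame | np.ndarray) -> float:
    vals = np.linalg.eigvals(np.asarray(A, dtype=float))
    return float(np.abs(vals).max())


def leontief_inverse(A: pd.DataFrame) -> pd.DataFrame:
    """L = (I - A)^-1 via a dense linear solve of (I - A) X = I.

    Raises :class:`NonProductiveEconomyError` if the spectral radius of
    ``A`` is >= 1 (Neumann series diverges; the economy is not
    productive).
    """
    M = np.asarray(A, dtype=float)
    rho = spectral_radius(M)
    if rho >= 1.0:
        raise NonProductiveEconomyError(f"spectral radius {rho:.6f} >= 1")
    n = M.shape[0]
    L = np.linalg.solve(np.eye(n) - M, np.eye(n))
    return pd.DataFrame(L, index=A.index, columns=A.columns)


def footprint(S: pd.DataFrame, L: pd.DataFrame, y: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Consumption-based pressure account E = S L y.

    ``y`` may be a single final-demand vector or one column per consuming
    region; the result has one column per demand column, rows = stressors,
    units km².
    """
    if isinstance(y, pd.Series):
        y = y.to_frame("total")
    if S.shape[1] != L.shape[0] or L.shape[1] != y.shape[0]:
        raise ValueError(
            f"non-conformable shapes: S {S.shape}, L {L.shape}, y {y.shape}"
        )
    E = S.to_numpy() @ L.to_numpy() @ y.to_numpy()
    return pd.DataFrame(E, index=S.index, columns=y.columns)


def production_account(S: pd.DataFrame, x: pd.Series) -> pd.DataFrame:
    """Production-based pressure account F = S diag(x), km² per (region, sector)."""
    return S.mul(x, axis=1)


def build_characterization_matrix(
    aggregated_cfs: pd.DataFrame,
    S: pd.DataFrame,
    *,
    cf_col: str = "cf_pdf_per_km2",
    cf_unit: str = "PDF/km2",
) -> pd.DataFrame:
    """Materialize C at S's full (region, sector) resolution.

    ``aggregated_cfs`` carries one CF per (region, crop). The output has
    the shape of ``S``: row (region r, crop c) holds CF(r, c) in the
    column of region r's sector c and zero elsewhere, realizing a dense
    characterization with a column for each region/crop pair.

    ``cf_unit`` may be "PDF/km2" (internal unit) or "PDF/m2", which is
    converted by the exact 1e6 m²/km² factor.
    """
    if cf_unit == "PDF/km2":
        factor = 1.0
    elif cf_unit == "PDF/m2":
        factor = M2_PER_KM2
    else:
        raise UnitMismatchError(f"unknown CF unit {cf_unit!r}")
    lookup = {
        (r, c): v * factor
        for r, c, v in aggregated_cfs[["region_id", "crop_id", cf_col]].itertuples(index=False)
    }
    arr = np.zeros(S.shape)
    col_pos = {key: j for j, key in enumerate(S.columns)}
    for i, (region, crop) in enumerate(S.index):
        j = col_pos.get((region, crop))
        if j is not None:
            arr[i, j] = lookup.get((region, crop), 0.0)
    if (arr < 0).any():
        raise ValueError("negative characterization factors")
    return pd.DataFrame(arr, index=S.index, columns=S.columns)


def characterize(
    C: pd.DataFrame,
    account: pd.DataFrame,
    *,
    account_unit: str = "km2",
) -> pd.DataFrame:
    """Elementwise characterization D = C ⊙ account (PDF·yr).

    ``account`` must share S's (stressor × column) shape — typically F.
    A pressure account in m² must be converted before characterization;
    passing ``account_unit="m2"`` raises to force the explicit 1e6
    conversion rather than silently mixing units.
    """
    if account_unit != "km2":
        raise UnitMismatchError(
            f"account unit {account_unit!r}: convert pressures to km² before characterizing"
        )
    if C.shape != account.shape:
        raise ValueError(f"C {C.shape} does not match account {account.shape}")
    return C * account.to_numpy()


@dataclass
class ImpactAccounts:
    """Characterized biodiversity impacts from both accounting perspectives.

    ``pba`` rows: (producing_region, crop, impact_pdf_yr);
    ``cba`` rows: (producing_region, crop, consuming_region, impact_pdf_yr).
    """

    pba: pd.DataFrame
    cba: pd.DataFrame
    method: str = ""

    def global_total(self, perspective: str) -> float:
        table = self.pba if perspective == "pba" else self.cba
        return float(table["impact_pdf_yr"].sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-form ImpactAccount table with a ``perspective`` column."""
        pba = self.pba.assign(perspective="pba", consuming_region="")
        cba = self.cba.assign(perspective="cba")
        cols = ["perspective", "producing_region", "crop_id", "consuming_region", "impact_pdf_yr", "method"]
        out = pd.concat([pba, cba], ignore_index=True)
        out["method"] = self.method
        return out[cols]


def biodiversity_accounts(
    mrio: MRIOSystem,
    C: pd.DataFrame,
    *,
    method: str = "",
) -> ImpactAccounts:
    """Full characterization pipeline: D_pba = C ⊙ F and D_cba = C ⊙ SLy.

    The consumption-based account is decomposed by consuming region: for
    demand column y_c the characterized impact of stressor s is
    Σ_j C[s, j] S[s, j] (L y_c)[j], i.e. (C ⊙ S) L y_c. Both perspectives
    are returned in long form, the CBA split by (producing stressor,
    consuming region).
    """
    mrio.validate()
    A = technical_coefficients(mrio.Z, mrio.x)
    L = leontief_inverse(A)
    S_char = C * mrio.S.to_numpy()  # PDF per unit output

    F_char = production_account(S_char, mrio.x)
    pba = (
        F_char.sum(axis=1)
        .rename("impact_pdf_yr")
        .rename_axis(["producing_region", "crop_id"])
        .reset_index()
    )

    D_cba = footprint(S_char, L, mrio.y)
    cba = (
        D_cba.rename_axis(["producing_region", "crop_id"])
        .reset_index()
        .melt(
            id_vars=["producing_region", "crop_id"],
            var_name="consuming_region",
            value_name="impact_pdf_yr",
        )
    )
    neg_tol = -1e-15 * max(1.0, float(np.abs(D_cba.to_numpy()).max()))
    if (cba["impact_pdf_yr"] < neg_tol).any() or (pba["impact_pdf_yr"] < neg_tol).any():
        raise ValueError("negative characterized impacts from nonnegative inputs")
    cba["impact_pdf_yr"] = cba["impact_pdf_yr"].clip(lower=0.0)
    pba["impact_pdf_yr"] = pba["impact_pdf_yr"].clip(lower=0.0)
    return ImpactAccounts(pba=pba, cba=cba, method=method)
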