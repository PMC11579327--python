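"""Inventory revision, agronomic unit conversions and descriptive stats.

Inventory rates are short tons of NOx per day on an NO₂-equivalent mass
basis (the US inventory convention). Converting to a nitrogen flux per
cropland area therefore multiplies by days per year, kilograms per short
ton, and the mass fraction of N in NO₂ (14.007/46.0055 ≈ 0.3045), then
divides by the cropland area in hectares:

    kg N ha⁻¹ yr⁻¹ = tons/d × 365 × 907.185 × 0.3045 / area_ha

The fertilizer fraction expresses the same annualized N flux as a
percentage of the N applied to the region's fields in a year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SOIL, EmissionInventory
from .errors import InvalidInputError

KG_PER_SHORT_TON = 907.185
N_MASS_FRACTION = 14.007 / 46.0055  # N share of NO₂-equivalent mass

#: Imperial Valley agricultural area (ha), from satellite land-surface
#: classification of cropped land.
IMPERIAL_CROPLAND_HA = 270_500.0
#: Imperial County 2022 purchases of nitrogen fertilizer, minerals and
#: compost (short tons N per year).
IMPERIAL_FERTILIZER_N = 57_630.0


@dataclass(frozen=True)
class ConversionContext:
    """Region constants for flux unit conversions."""

    cropland_area: float = IMPERIAL_CROPLAND_HA  # ha
    days_per_year: float = 365.0
    kg_per_short_ton: float = KG_PER_SHORT_TON
    n_mass_fraction: float = N_MASS_FRACTION
    fertilizer_n: float = IMPERIAL_FERTILIZER_N  # short tons N / yr

    def __post_init__(self) -> None:
        for name in (
            "cropland_area",
            "days_per_year",
            "kg_per_short_ton",
            "n_mass_fraction",
            "fertilizer_n",
        ):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")


def tons_per_day_to_kgN_per_ha_yr(rate: float, ctx: ConversionContext) -> float:
    """Annualized N mass flux per cropland area from a tons/day rate."""
    if rate < 0:
        raise InvalidInputError("rate must be >= 0")
    return (
        rate
        * ctx.days_per_year
        * ctx.kg_per_short_ton
        * ctx.n_mass_fraction
        / ctx.cropland_area
    )


def kgN_per_ha_yr_to_tons_per_day(flux: float, ctx: ConversionContext) -> float:
    """Inverse of :func:`tons_per_day_to_kgN_per_ha_yr`."""
    if flux < 0:
        raise InvalidInputError("flux must be >= 0")
    return (
        flux
        * ctx.cropland_area
        / (ctx.days_per_year * ctx.kg_per_short_ton * ctx.n_mass_fraction)
    )


def fertilizer_fraction(rate: float, ctx: ConversionContext) -> float:
    """Annualized soil NOx-N emission as a percentage of applied N.

    Both the emission and the fertilizer figure are in short tons, so
    only the N mass fraction and the day→year factor enter.
    """
    if rate < 0:
        raise InvalidInputError("rate must be >= 0")
    return 100.0 * rate * ctx.days_per_year * ctx.n_mass_fraction / ctx.fertilizer_n


def revise_inventory(
    inventory: EmissionInventory, e_soil: float, soil_source: str = SOIL
) -> pd.DataFrame:
    """Replace the inventory's soil rate with a field-based estimate.

    Non-soil rates are conserved exactly; the total and percentage
    shares are recomputed from the revised components (shares sum to
    100 %). Returns a table with columns source, rate, share_percent.
    """
    if e_soil < 0:
        raise InvalidInputError("e_soil must be >= 0")
    revised = inventory.replacing(soil_source, e_soil)
    total = revised.component_sum
    rows = [
        {"source": src, "rate": rate, "share_percent": 100.0 * rate / total}
        for src, rate in revised.rates.items()
    ]
    rows.append({"source": "total", "rate": total, "share_percent": 100.0})
    return pd.DataFrame(rows)


def pearson_no2_no3(samples: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation between paired δ¹⁵N-NO₂ and δ¹⁵N-tNO₃.

    Pairs with missing tNO₃ are dropped; returns (r, n_pairs). A fair
    correlation is expected — both species descend from the same NOx —
    but tNO₃ integrates days of transport across basins, which is why it
    is reported descriptively and not used for apportionment.
    """
    for col in ("delta_no2", "delta_tno3"):
        if col not in samples.columns:
            raise InvalidInputError(f"sample table lacks column {col!r}")
    sub = samples[["delta_no2", "delta_tno3"]].dropna().astype(float)
    n = len(sub)
    if n < 3:
        raise InvalidInputError(f"need >= 3 complete pairs, have {n}")
    r, _ = stats.pearsonr(sub["delta_no2"], sub["delta_tno3"])
    return float(r), n
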