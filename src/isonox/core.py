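"""Domain types and δ¹⁵N arithmetic shared by every pipeline stage.

The δ¹⁵N notation expresses a sample's ¹⁵N/¹⁴N isotope ratio relative to
atmospheric N₂ in per mil (‰):

    δ¹⁵N = (R_sample / R_standard − 1) × 10³

Flux-weighted linear mixing of source signatures underlies both the a
priori inventory signature and the mass-balance inversion downstream:
an air parcel fed by sources with emission rates Fᵢ and signatures δᵢ
carries δ = Σ Fᵢδᵢ / Σ Fᵢ.

Emission rates follow the US inventory convention: short tons of NOx per
day on an NO₂-equivalent mass basis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError

#: Canonical source classes of a CEPAM/NEI-style NOx inventory.
KNOWN_SOURCES = ("mobile", "biomass_burning", "stationary", "biogenic_soil")

#: Conventional name of the biogenic soil source.
SOIL = "biogenic_soil"

#: Pooled analytic standard deviation of the ¹⁵N reference material (‰).
DEFAULT_ANALYTIC_SD = 0.11


@dataclass(frozen=True)
class IsotopeRatio:
    """A raw ¹⁵N/¹⁴N ratio pair (sample, atmospheric-N₂ standard)."""

    r_sample: float
    r_standard: float

    def __post_init__(self) -> None:
        if not (self.r_sample > 0 and self.r_standard > 0):
            raise InvalidInputError(
                f"isotope ratios must be strictly positive, got "
                f"r_sample={self.r_sample}, r_standard={self.r_standard}"
            )


@dataclass
class IsotopeSample:
    """One site-period observation of δ¹⁵N-NO₂ (all δ values in ‰).

    ``delta_tno3`` (total particulate nitrate) and ``delta_nox`` (the
    fractionation-corrected NOx value) may be missing (None/NaN).
    """

    site: str
    period_start: date
    period_end: date
    delta_no2: float
    delta_tno3: float | None = None
    delta_nox: float | None = None
    analytic_sd: float = DEFAULT_ANALYTIC_SD

    def __post_init__(self) -> None:
        if self.period_end < self.period_start:
            raise InvalidInputError(
                f"{self.site}: period_end {self.period_end} precedes "
                f"period_start {self.period_start}"
            )
        if not math.isfinite(self.delta_no2):
            raise InvalidInputError(f"{self.site}: delta_no2 must be finite")
        for name in ("delta_tno3", "delta_nox"):
            v = getattr(self, name)
            if v is not None and math.isnan(v):
                setattr(self, name, None)
            elif v is not None and not math.isfinite(v):
                raise InvalidInputError(f"{self.site}: {name} must be finite or missing")
        if self.analytic_sd < 0:
            raise InvalidInputError("analytic_sd must be >= 0")


@dataclass(frozen=True)
class SourceSignature:
    """A NOx emission source's literature δ¹⁵N-NOx mean and spread (‰)."""

    source: str
    mean_delta: float
    sd_delta: float
    range_low: float | None = None
    range_high: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sd_delta < 0:
            raise InvalidInputError(f"{self.source}: sd_delta must be >= 0")
        if self.range_low is not None and self.range_high is not None:
            if not (self.range_low <= self.mean_delta <= self.range_high):
                raise InvalidInputError(
                    f"{self.source}: mean_delta {self.mean_delta} outside "
                    f"[{self.range_low}, {self.range_high}]"
                )


@dataclass(frozen=True)
class EmissionInventory:
    """Per-source NOx emission rates for one region.

    Rates are short tons NOx day⁻¹ (NO₂-equivalent mass basis).
    ``reported_total`` carries the total as printed by the inventory
    provider; printed totals occasionally disagree with the component sum
    at the last decimal, and when present the printed total is what the
    total emission E_inv and the source proportions αᵢ are computed
    against (matching how the inventory is cited downstream).
    """

    region: str
    rates: Mapping[str, float]
    year: int = 0
    reported_total: float | None = None

    def __post_init__(self) -> None:
        if not self.rates:
            raise InvalidInputError(f"{self.region}: inventory has no sources")
        for src, rate in self.rates.items():
            if rate < 0 or not math.isfinite(rate):
                raise InvalidInputError(f"{self.region}/{src}: rate {rate} invalid")
        if not any(r > 0 for r in self.rates.values()):
            raise InvalidInputError(f"{self.region}: all rates are zero")
        object.__setattr__(self, "rates", dict(self.rates))

    @property
    def component_sum(self) -> float:
        return float(sum(self.rates.values()))

    @property
    def total(self) -> float:
        """Total emission E_inv: the printed total when given, else the sum."""
        return self.component_sum if self.reported_total is None else float(self.reported_total)

    def replacing(self, source: str, rate: float) -> "EmissionInventory":
        """A copy with one source's rate replaced (printed total dropped,
        since it no longer describes the revised mix)."""
        rates = dict(self.rates)
        rates[source] = rate
        return EmissionInventory(self.region, rates, self.year, reported_total=None)


@dataclass(frozen=True)
class ApportionmentResult:
    """Soil source strength solved from the mixing-model inversion.

    ``e_soil`` is the reported (possibly zero-truncated) estimate;
    ``e_soil_raw`` keeps the untruncated value. σ is never truncated.
    """

    period: str
    e_soil: float
    sigma_e_soil: float
    apriori_delta: float
    delta_obs: float
    truncated: bool = False
    e_soil_raw: float | None = None

    def __post_init__(self) -> None:
        if self.truncated and self.e_soil < 0:
            raise InvalidInputError("truncated result must report e_soil >= 0")
        if self.sigma_e_soil < 0:
            raise InvalidInputError("sigma_e_soil must be >= 0")


# --------------------------------------------------------------------------
# δ arithmetic


def delta_from_ratio(ratio: IsotopeRatio) -> float:
    """δ¹⁵N in ‰ from a raw ratio pair: (R_sample/R_standard − 1) × 10³."""
    return (ratio.r_sample / ratio.r_standard - 1.0) * 1e3


def ratio_from_delta(delta: float) -> float:
    """R_sample/R_standard implied by a δ value in ‰ (inverse of
    :func:`delta_from_ratio`); δ ≤ −1000‰ would imply a non-positive ratio."""
    if delta <= -1000.0:
        raise InvalidInputError(f"delta {delta}‰ implies a non-positive isotope ratio")
    return 1.0 + delta / 1e3


def mix_delta(fluxes: Sequence[float], deltas: Sequence[float]) -> float:
    """Flux-weighted mean δ of a mixture: Σ Fᵢδᵢ / Σ Fᵢ.

    The result is always bounded by the component deltas.
    """
    f = np.asarray(fluxes, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if f.shape != d.shape or f.ndim != 1:
        raise InvalidInputError("fluxes and deltas must be equal-length 1-d vectors")
    if np.any(f < 0):
        raise InvalidInputError("fluxes must be >= 0")
    total = f.sum()
    if not total > 0:
        raise InvalidInputError("total flux must be > 0")
    return float(f @ d / total)


def inventory_fractions(inventory: EmissionInventory) -> dict[str, float]:
    """Source proportions αᵢ = rateᵢ / E_inv.

    For a self-consistent inventory the fractions sum to 1. When the
    inventory carries a printed total that disagrees with the component
    sum at the last decimal, the printed total is the divisor and the sum
    of fractions reflects that discrepancy.
    """
    total = inventory.total
    if not total > 0:
        raise InvalidInputError(f"{inventory.region}: inventory total must be > 0")
    return {src: rate / total for src, rate in inventory.rates.items()}


def apriori_signature(
    inventory: EmissionInventory,
    signatures: Mapping[str, SourceSignature] | Sequence[SourceSignature],
    override: float | None = None,
) -> float:
    """Flux-weighted mean δ¹⁵N-NOx implied by an inventory's source mix.

    This is the Σ αᵢδᵢ term of the mass-balance inversion. ``override``
    supplies an externally stated a priori signature directly; it takes
    precedence, with a warning when it disagrees with the computed value
    by more than 0.1‰ (signature compilations evolve, so a cited a priori
    need not be recomputable from the packaged signature library).
    """
    sig_map = _as_signature_map(signatures)
    missing = [
        src for src, rate in inventory.rates.items() if rate > 0 and src not in sig_map
    ]
    if missing:
        raise ConfigurationError(
            f"{inventory.region}: no δ¹⁵N signature for active source(s) {missing}"
        )
    rates, deltas = zip(
        *((rate, sig_map[src].mean_delta) for src, rate in inventory.rates.items())
    )
    # Weight against the printed total (via α's) rather than the raw sum so
    # the computed value matches how the inventory is cited.
    computed = float(np.dot(rates, deltas) / inventory.total)
    if override is None:
        return computed
    if abs(override - computed) > 0.1:
        warnings.warn(
            f"{inventory.region}: a priori override {override:+.2f}‰ differs from "
            f"inventory-computed {computed:+.2f}‰ by more than 0.1‰",
            stacklevel=2,
        )
    return float(override)


def _as_signature_map(
    signatures: Mapping[str, SourceSignature] | Sequence[SourceSignature],
) -> dict[str, SourceSignature]:
    if isinstance(signatures, Mapping):
        return dict(signatures)
    return {s.source: s for s in signatures}
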