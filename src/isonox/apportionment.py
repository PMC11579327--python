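"""Inversion of the isotope mass-balance mixing model for soil NOx.

The observed ambient δ¹⁵N-NOx (δ_obs) is modelled as the flux-weighted
mixture of the inventory's source signatures. Holding every non-soil
source at its inventory rate and asking what soil emission strength E_s
explains the observation gives

    E_s = (δ_obs − Σᵢ αᵢδᵢ) · E_inv / (δ_s − δ_obs)

with αᵢ the inventory source proportions (the sum runs over all sources
including soil), δᵢ the literature source signatures, δ_s the soil
signature and E_inv the inventory total. Because the a priori sum keeps
the inventory's own soil term, on exactly mixed data this estimator
returns the soil flux *in excess of* the inventory soil rate: the offset
identity E_s = E_true − α_s·E_inv. :func:`consistent_soil_inversion`
solves the same mass balance without that convention and recovers the
total soil flux exactly; it serves as the estimator-validation oracle.

Negative estimates (observed air isotopically heavier than the a priori
mixture) are truncated to zero under the default policy, on the argument
that a negative soil emission is unphysical and the uncertainty band of
such months comfortably spans zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ApportionmentResult
from .errors import InvalidInputError, SingularityError

#: Half-width (‰) of the guard band around δ_obs = δ_s inside which the
#: inversion is treated as singular rather than returning a huge value.
DEFAULT_GUARD_BAND = 0.5


@dataclass(frozen=True)
class ApportionmentPolicy:
    """Aggregation and truncation choices for a campaign-level estimate.

    ``mean_of_monthly`` averages per-period estimates (truncating
    negatives first when enabled); ``invert_mean_delta`` inverts the
    campaign-mean δ_obs in one shot. The two differ because the
    inversion is nonlinear in δ_obs; both are legitimate summaries and
    reports show them side by side.
    """

    aggregate_mode: str = "mean_of_monthly"
    truncate_negative: bool = True
    apriori_override: float | None = None
    guard_band: float = DEFAULT_GUARD_BAND

    def __post_init__(self) -> None:
        if self.aggregate_mode not in ("mean_of_monthly", "invert_mean_delta"):
            raise InvalidInputError(
                f"unknown aggregate_mode {self.aggregate_mode!r}"
            )


def soil_source_strength(
    delta_obs: float,
    apriori: float,
    e_inv: float,
    delta_soil: float,
    guard_band: float = DEFAULT_GUARD_BAND,
) -> float:
    """Untruncated soil source strength from the printed mass-balance
    inversion (short tons day⁻¹; may be negative).

    Raises :class:`SingularityError` when δ_obs falls within
    ``guard_band`` ‰ of δ_s — there the estimate diverges and the
    observation carries no information beyond "essentially pure soil".
    """
    if not e_inv > 0:
        raise InvalidInputError(f"inventory total must be > 0, got {e_inv}")
    denom = delta_soil - delta_obs
    if abs(denom) < guard_band:
        raise SingularityError(
            f"δ_obs={delta_obs}‰ within {guard_band}‰ of the soil end-member "
            f"δ_s={delta_soil}‰: inversion is singular"
        )
    return (delta_obs - apriori) * e_inv / denom


def consistent_soil_inversion(
    delta_obs: float,
    nonsoil_rates: Sequence[float],
    nonsoil_deltas: Sequence[float],
    delta_soil: float,
    guard_band: float = DEFAULT_GUARD_BAND,
) -> float:
    """Exact mass-balance solution for the *total* soil flux E such that
    mixing the non-soil sources with E at δ_s reproduces δ_obs:

        E = (Σ rᵢδᵢ − δ_obs·Σ rᵢ) / (δ_obs − δ_s)

    Requires δ_obs strictly between δ_s and the non-soil mixture mean
    (otherwise no non-negative soil flux can explain the observation).
    """
    r = np.asarray(nonsoil_rates, dtype=float)
    d = np.asarray(nonsoil_deltas, dtype=float)
    if r.shape != d.shape or r.ndim != 1:
        raise InvalidInputError("rates and deltas must be equal-length vectors")
    total = r.sum()
    if not total > 0:
        raise InvalidInputError("total non-soil flux must be > 0")
    denom = delta_obs - delta_soil
    if abs(denom) < guard_band:
        raise SingularityError(
            f"δ_obs={delta_obs}‰ within {guard_band}‰ of δ_s={delta_soil}‰"
        )
    e = float((r @ d - delta_obs * total) / denom)
    if e < 0:
        nonsoil_mean = float(r @ d / total)
        raise InvalidInputError(
            f"δ_obs={delta_obs}‰ not between δ_s={delta_soil}‰ and the "
            f"non-soil mixture mean {nonsoil_mean:.3f}‰: no non-negative "
            "soil flux solves the mass balance"
        )
    return e


def apportion_series(
    samples: pd.DataFrame,
    apriori: float,
    e_inv: float,
    delta_soil: float,
    policy: ApportionmentPolicy | None = None,
    sigma_fn=None,
) -> tuple[list[ApportionmentResult], ApportionmentResult]:
    """Per-period soil estimates plus a campaign aggregate.

    ``samples`` needs a ``delta_nox`` column (fractionation-corrected)
    and optionally a ``period`` label column. Missing δ values are
    dropped with the divisor reduced accordingly. ``sigma_fn``, when
    given, maps δ_obs → σ_Es and fills the uncertainty column;
    truncation never touches σ.
    """
    policy = policy or ApportionmentPolicy()
    if policy.apriori_override is not None:
        apriori = policy.apriori_override
    if "delta_nox" not in samples.columns:
        raise InvalidInputError("sample table lacks a delta_nox column")
    sub = samples[samples["delta_nox"].notna()]
    if sub.empty:
        raise InvalidInputError("no non-missing δ¹⁵N-NOx samples to apportion")
    labels = (
        sub["period"].astype(str).tolist()
        if "period" in sub.columns
        else [str(p) for p in sub["period_start"]]
        if "period_start" in sub.columns
        else [str(i) for i in sub.index]
    )

    def one(delta_obs: float, label: str) -> ApportionmentResult:
        raw = soil_source_strength(
            delta_obs, apriori, e_inv, delta_soil, policy.guard_band
        )
        sigma = float(sigma_fn(delta_obs)) if sigma_fn is not None else 0.0
        truncated = policy.truncate_negative and raw < 0
        return ApportionmentResult(
            period=label,
            e_soil=0.0 if truncated else raw,
            sigma_e_soil=sigma,
            apriori_delta=apriori,
            delta_obs=float(delta_obs),
            truncated=truncated,
            e_soil_raw=raw,
        )

    per_period = [
        one(d, lab) for d, lab in zip(sub["delta_nox"].astype(float), labels)
    ]

    if policy.aggregate_mode == "mean_of_monthly":
        vals = np.array([r.e_soil for r in per_period])
        agg_e = float(vals.mean())
        agg_sigma = (
            float(np.sqrt(np.mean([r.sigma_e_soil**2 for r in per_period])))
            if sigma_fn is not None
            else 0.0
        )
        aggregate = ApportionmentResult(
            period="aggregate",
            e_soil=agg_e,
            sigma_e_soil=agg_sigma,
            apriori_delta=apriori,
            delta_obs=float(sub["delta_nox"].mean()),
            truncated=any(r.truncated for r in per_period),
            e_soil_raw=float(np.mean([r.e_soil_raw for r in per_period])),
        )
    else:  # invert_mean_delta
        mean_delta = float(sub["delta_nox"].mean())
        aggregate = one(mean_delta, "aggregate")
    return per_period, aggregate


def results_frame(results: Iterable[ApportionmentResult]) -> pd.DataFrame:
    """Tabular view of apportionment results."""
    return pd.DataFrame(
        {
            "period": r.period,
            "delta_obs": r.delta_obs,
            "apriori_delta": r.apriori_delta,
            "e_soil": r.e_soil,
            "e_soil_raw": r.e_soil_raw,
            "sigma_e_soil": r.sigma_e_soil,
            "truncated": r.truncated,
        }
        for r in results
    )
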