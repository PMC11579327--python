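"""Conversion of observed δ¹⁵N-NO₂ to emitted δ¹⁵N-NOx.

Between emission and sampling, NOx cycles between NO and NO₂; isotopic
exchange and kinetic effects enrich NO₂ in ¹⁵N relative to the total NOx
pool, so the sampled δ¹⁵N-NO₂ overestimates the emitted δ¹⁵N-NOx. Two
correction modes are provided:

``table``
    A per-sample additive correction Δ = δ¹⁵N-NOx − δ¹⁵N-NO₂. This is
    the authoritative mode for reproducing a campaign in which the
    corrected values are published alongside the raw ones:
    :func:`implied_corrections` recovers Δ from such paired columns.

``parametric``
    The standard single-factor form of the δ¹⁵N-NO₂ literature,

        δ¹⁵N-NOx = δ¹⁵N-NO₂ − (1 − f)·ε_eff,

    with f the NO₂/NOx mixing-ratio fraction and ε_eff an effective
    NO⇌NO₂ equilibrium fractionation (‰). ε_eff may be given directly or
    derived from temperature via a pluggable parameterization whose
    coefficients are configuration, not code. The parametric mode is a
    convenience for synthetic scenarios and sensitivity work; it is not
    a validated photochemical model (no Leighton-cycle or diurnal
    effects), and no reproduction target depends on its constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

#: Default polynomial coefficients (in powers of 1000/T[K]) for the
#: temperature dependence of the effective NO⇌NO₂ exchange fractionation.
#: These are configuration: override via FractionationSpec.epsilon_coeffs
#: or by passing epsilon_eff directly. The default gives ε_eff ≈ 28‰ near
#: 298 K, the order of magnitude of published equilibrium exchange values.
DEFAULT_EPSILON_COEFFS = (0.0, 8.33)


def epsilon_from_temperature(
    t_kelvin: float, coeffs: Sequence[float] = DEFAULT_EPSILON_COEFFS
) -> float:
    """ε_eff(T) in ‰ as a polynomial in x = 1000/T: Σ cₖ xᵏ."""
    if t_kelvin <= 0:
        raise InvalidInputError(f"temperature {t_kelvin} K must be positive")
    x = 1000.0 / t_kelvin
    return float(sum(c * x**k for k, c in enumerate(coeffs)))


@dataclass(frozen=True)
class FractionationSpec:
    """How to map sampled δ¹⁵N-NO₂ to emitted δ¹⁵N-NOx.

    Exactly one mode is configured; there is no silent default because a
    zero correction is a scientific claim, not an absence of choice.
    """

    mode: str  # "table" | "parametric"
    delta: float | Sequence[float] | None = None  # table mode: Δ in ‰
    f: float | None = None  # parametric: NO₂/NOx fraction in (0, 1]
    epsilon_eff: float | None = None  # parametric: ε in ‰
    t_kelvin: float | None = None  # parametric alternative to epsilon_eff
    epsilon_coeffs: tuple[float, ...] = DEFAULT_EPSILON_COEFFS

    def __post_init__(self) -> None:
        if self.mode == "table":
            if self.delta is None:
                raise ConfigurationError("table mode requires a Δ correction")
            arr = np.atleast_1d(np.asarray(self.delta, dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError("table-mode Δ must be finite")
        elif self.mode == "parametric":
            if self.f is None or not (0.0 < self.f <= 1.0):
                raise InvalidInputError(
                    f"parametric mode requires NO₂/NOx fraction f in (0, 1], got {self.f}"
                )
            if self.epsilon_eff is None and self.t_kelvin is None:
                raise ConfigurationError(
                    "parametric mode requires epsilon_eff or t_kelvin"
                )
        else:
            raise ConfigurationError(f"unknown fractionation mode {self.mode!r}")

    @property
    def effective_epsilon(self) -> float:
        if self.mode != "parametric":
            raise ConfigurationError("effective_epsilon is a parametric-mode property")
        if self.epsilon_eff is not None:
            return float(self.epsilon_eff)
        return epsilon_from_temperature(self.t_kelvin, self.epsilon_coeffs)


def correct_no2_to_nox(delta_no2, spec: FractionationSpec):
    """Emitted δ¹⁵N-NOx from sampled δ¹⁵N-NO₂ (scalar or array, ‰).

    Table mode adds the per-sample Δ; parametric mode subtracts
    (1 − f)·ε_eff, which for ε_eff > 0 never raises δ (the emitted NOx is
    isotopically lighter than, or equal to, the NO₂ sampled from it).
    """
    d = np.asarray(delta_no2, dtype=float)
    if spec.mode == "table":
        corr = np.asarray(spec.delta, dtype=float)
        if corr.ndim > 0 and corr.shape != d.shape:
            raise InvalidInputError(
                f"per-sample Δ has shape {corr.shape}, samples have {d.shape}"
            )
        out = d + corr
    else:
        out = d - (1.0 - spec.f) * spec.effective_epsilon
    return float(out) if np.ndim(delta_no2) == 0 else out


def invert_nox_to_no2(delta_nox, spec: FractionationSpec):
    """Inverse map δ¹⁵N-NOx → δ¹⁵N-NO₂ (used by the forward simulator)."""
    d = np.asarray(delta_nox, dtype=float)
    if spec.mode == "table":
        out = d - np.asarray(spec.delta, dtype=float)
    else:
        out = d + (1.0 - spec.f) * spec.effective_epsilon
    return float(out) if np.ndim(delta_nox) == 0 else out


def implied_corrections(samples: pd.DataFrame) -> pd.Series:
    """Per-sample Δ = δ¹⁵N-NOx − δ¹⁵N-NO₂ from a paired sample table.

    Recovers the corrections a campaign actually applied when both the
    raw and corrected columns are published.
    """
    for col in ("delta_no2", "delta_nox"):
        if col not in samples.columns:
            raise InvalidInputError(f"sample table lacks required column {col!r}")
    both = samples[["delta_no2", "delta_nox"]].astype(float)
    if both.isna().any(axis=None):
        raise InvalidInputError(
            "implied corrections need both delta_no2 and delta_nox on every row"
        )
    return (both["delta_nox"] - both["delta_no2"]).rename("delta_correction")
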