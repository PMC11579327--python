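"""Campaign-level reproduction pipeline over the packaged fixtures.

One entry point, :func:`reproduction_bundle`, recomputes every headline
quantity of the packaged SSAB study from its fixtures: sample-table
column means, per-month and annual soil source strengths per site (both
aggregation conventions side by side), the basin-wide sum, revised
inventory shares, agronomic unit conversions, and the descriptive
NO₂–tNO₃ correlation. The CLI ``report`` subcommand and the analysis
drivers are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apportionment import ApportionmentPolicy, apportion_series, results_frame
from .budget import (
    ConversionContext,
    fertilizer_fraction,
    pearson_no2_no3,
    revise_inventory,
    tons_per_day_to_kgN_per_ha_yr,
)
from .core import SOIL, EmissionInventory, SourceSignature
from .io import (
    load_fixture_inventories,
    load_fixture_samples,
    load_fixture_signatures,
    load_study_config,
)
from .uncertainty import inputs_from_inventory, sigma_soil_source

DELTA_COLUMNS = ("delta_no2", "delta_nox", "delta_tno3")


def display_round(x: float) -> float:
    """Report rounding convention: 1 decimal, 2 decimals below |1|."""
    return round(x, 2 if abs(x) < 1 else 1)


def table_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-site means of the δ columns, missing values excluded with the
    divisor reduced accordingly (full precision; round at display)."""
    return samples.groupby("site")[list(DELTA_COLUMNS)].mean()


@dataclass(frozen=True)
class SiteApportionment:
    site: str
    region: str
    apriori: float
    e_inv: float
    per_month: pd.DataFrame
    annual_mean_of_monthly: float
    annual_invert_mean_delta: float
    annual: float  # the site's configured convention
    sigma_annual: float


def apportion_site(
    site: str,
    samples: pd.DataFrame,
    inventory: EmissionInventory,
    signatures: dict[str, SourceSignature],
    apriori_override: float | None,
    delta_soil: float,
    aggregate_mode: str,
) -> SiteApportionment:
    """Per-month and annual soil estimates for one site, with analytic σ."""
    sub = samples[samples["site"] == site].copy()
    sub["period"] = [
        f"{p:%b %Y}" for p in pd.to_datetime(sub["period_start"])
    ]
    e_inv = inventory.total

    def sigma_fn(delta_obs: float) -> float:
        return sigma_soil_source(
            inputs_from_inventory(
                inventory,
                signatures,
                delta_obs,
                apriori_override=apriori_override,
            )
        )

    results = {}
    for mode in ("mean_of_monthly", "invert_mean_delta"):
        policy = ApportionmentPolicy(
            aggregate_mode=mode, apriori_override=apriori_override
        )
        per, agg = apportion_series(
            sub,
            apriori=apriori_override if apriori_override is not None else 0.0,
            e_inv=e_inv,
            delta_soil=delta_soil,
            policy=policy,
            sigma_fn=sigma_fn,
        )
        results[mode] = (per, agg)
    per_month, agg_default = results[aggregate_mode]
    return SiteApportionment(
        site=site,
        region=inventory.region,
        apriori=agg_default.apriori_delta,
        e_inv=e_inv,
        per_month=results_frame(per_month),
        annual_mean_of_monthly=results["mean_of_monthly"][1].e_soil,
        annual_invert_mean_delta=results["invert_mean_delta"][1].e_soil,
        annual=agg_default.e_soil,
        sigma_annual=agg_default.sigma_e_soil,
    )


def reproduction_bundle(
    samples: pd.DataFrame | None = None,
    signatures: dict[str, SourceSignature] | None = None,
    inventories: dict[str, EmissionInventory] | None = None,
    study: dict | None = None,
) -> dict:
    """Recompute the campaign's headline results from (fixture) inputs."""
    samples = load_fixture_samples() if samples is None else samples
    signatures = load_fixture_signatures() if signatures is None else signatures
    inventories = load_fixture_inventories() if inventories is None else inventories
    study = load_study_config() if study is None else study

    means = table_means(samples)
    delta_soil = float(study["delta_soil"])

    sites: dict[str, SiteApportionment] = {}
    for site, cfg in study["sites"].items():
        sites[site] = apportion_site(
            site,
            samples,
            inventories[cfg["region"]],
            signatures,
            apriori_override=cfg.get("apriori_override"),
            delta_soil=delta_soil,
            aggregate_mode=cfg.get("aggregate_mode", "mean_of_monthly"),
        )

    basin_soil = float(sum(s.annual for s in sites.values()))
    basin_sigma = float(np.sqrt(sum(s.sigma_annual**2 for s in sites.values())))

    revisions = {
        s.region: revise_inventory(inventories[s.region], s.annual)
        for s in sites.values()
    }
    if "ssab" in inventories:
        revisions["ssab"] = revise_inventory(inventories["ssab"], basin_soil)

    ctx = ConversionContext(**study.get("conversion", {}))
    imperial_site = next(s for s in sites.values() if s.region == "imperial")
    conversions = {
        "kgN_per_ha_yr": tons_per_day_to_kgN_per_ha_yr(imperial_site.annual, ctx),
        "fertilizer_percent": fertilizer_fraction(imperial_site.annual, ctx),
    }

    r, n_pairs = pearson_no2_no3(samples)

    return {
        "table_means": means,
        "sites": sites,
        "basin_soil_tons_per_day": basin_soil,
        "basin_sigma": basin_sigma,
        "revisions": revisions,
        "conversions": conversions,
        "pearson_no2_tno3": {"r": r, "n": n_pairs},
        "context": ctx,
    }


def bundle_summary_lines(bundle: dict) -> list[str]:
    """Human-readable summary of a reproduction bundle."""
    lines = ["Sample-table column means (‰):"]
    for site, row in bundle["table_means"].iterrows():
        lines.append(
            f"  {site:<12} δ¹⁵N-NO₂ {display_round(row['delta_no2']):>6}   "
            f"δ¹⁵N-NOx {display_round(row['delta_nox']):>6}   "
            f"δ¹⁵N-tNO₃ {display_round(row['delta_tno3']):>6}"
        )
    lines.append("Annual soil NOx source strength (short tons/d):")
    for site, s in bundle["sites"].items():
        lines.append(
            f"  {site:<12} {display_round(s.annual):>5} ± {s.sigma_annual:.1f}   "
            f"(mean-of-monthly {display_round(s.annual_mean_of_monthly)}, "
            f"invert-mean-δ {display_round(s.annual_invert_mean_delta)}; "
            f"a priori {s.apriori:+.2f}‰, E_inv {s.e_inv})"
        )
    lines.append(
        f"  basin total  {display_round(bundle['basin_soil_tons_per_day']):>5} "
        f"± {bundle['basin_sigma']:.1f}"
    )
    conv = bundle["conversions"]
    lines.append(
        f"Imperial soil flux: {conv['kgN_per_ha_yr']:.1f} kg N ha⁻¹ yr⁻¹; "
        f"{conv['fertilizer_percent']:.1f}% of applied fertilizer N"
    )
    pr = bundle["pearson_no2_tno3"]
    lines.append(f"δ¹⁵N-NO₂ vs δ¹⁵N-tNO₃ Pearson r = {pr['r']:.2f} (n={pr['n']})")
    return lines
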