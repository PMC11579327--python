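#!/usr/bin/env python
"""Validate the analytic error propagation against Monte Carlo.

The first-order Taylor variance of the inversion is exact only where
the estimate is linear in the signatures. Scaling all signature SDs
from 10% to 100% of their literature values shows the regimes: at small
σ the analytic and simulated spreads agree to a few per cent; at the
full literature soil SD (9.6‰) light δ_s draws approach the observed δ
and fatten the tails, so the analytic value undershoots the simulated
spread and should be read as a lower bound there.
"""

from pathlib import Path

import pandas as pd

from isonox.io import load_fixture_inventories, load_fixture_signatures, write_table
from isonox.uncertainty import (
    inputs_from_inventory,
    mc_sigma_soil_source,
    sigma_soil_source,
)
from dataclasses import replace

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240

inventories = load_fixture_inventories()
signatures = load_fixture_signatures()
base = inputs_from_inventory(
    inventories["imperial"], signatures, delta_obs=-13.67,
    apriori_override=-5.04,
)

rows = []
for scale in (0.1, 0.25, 0.5, 1.0):
    scaled = replace(
        base,
        nonsoil_sigmas=tuple(s * scale for s in base.nonsoil_sigmas),
        sigma_soil=base.sigma_soil * scale,
    )
    analytic = sigma_soil_source(scaled)
    mc = mc_sigma_soil_source(scaled, n_draws=400_000, seed=SEED)
    rows.append({
        "sigma_scale": scale,
        "sigma_soil_permil": scaled.sigma_soil,
        "sigma_analytic": analytic,
        "sigma_mc": mc.sigma,
        "mc_se": mc.standard_error,
        "mc_rejected": mc.n_rejected,
        "ratio_mc_over_analytic": mc.sigma / analytic,
    })

df = pd.DataFrame(rows)
write_table(df, OUT / "03_sigma_validation.csv", seed=SEED)
print("Analytic vs Monte-Carlo σ of the Imperial annual estimate "
      "(signature SDs scaled):")
print(df.round(4).to_string(index=False))
print("\nAt ≤25% of the literature SDs the two agree within a few per cent; "
      "at the full σ_s = 9.6‰ the simulated spread exceeds the first-order "
      "value — quote the analytic σ there as a lower bound.")
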