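# Packaged configuration of the Salton Sea Air Basin field campaign.
#
# apriori_override values are the inventory provider's cited a priori
# mean signatures; they are treated as authoritative constants for
# reproducing the published estimates (the packaged signature library
# weighted by the inventory gives slightly lighter values, and the
# pipeline warns about the disagreement when computing instead).
samples: field_samples_ssab.csv
signatures: source_signatures.json
inventory: cepam_inventory_2022.csv
delta_soil: -33.2
sites:
  Calipatria:
    region: imperial
    apriori_override: -5.04
    aggregate_mode: invert_mean_delta
  Thermal:
    region: coachella
    apriori_override: -3.11
    aggregate_mode: mean_of_monthly
conversion:
  cropland_area: 270500.0
  fertilizer_n: 57630.0
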