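[
  {
    "source": "mobile",
    "mean_delta": -2.5,
    "sd_delta": 2.7,
    "range_low": -8.1,
    "range_high": 9.8,
    "provenance": "Literature compilation of on-road vehicle exhaust measured with warm catalytic converters (tailpipe studies; cold/neutral-engine and passive-sampler data excluded)."
  },
  {
    "source": "biomass_burning",
    "mean_delta": 1.0,
    "sd_delta": 4.1,
    "range_low": -7.0,
    "range_high": 12.0,
    "provenance": "Literature compilation of biomass-burning plume measurements."
  },
  {
    "source": "stationary",
    "mean_delta": -16.5,
    "sd_delta": 1.7,
    "range_low": -19.7,
    "range_high": -13.9,
    "provenance": "Literature compilation of non-coal stationary combustion (coal excluded: not burned in the study region)."
  },
  {
    "source": "biogenic_soil",
    "mean_delta": -33.2,
    "sd_delta": 9.6,
    "range_low": -59.8,
    "range_high": -14.2,
    "provenance": "Literature compilation of microbial soil NO emissions (nitrification/denitrification; strongly 15N-depleted via the leaky-pipe kinetic preference for 14N)."
  }
]
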