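region,year,source,rate_tons_per_day
imperial,2022,mobile,12.4
imperial,2022,biomass_burning,0.1
imperial,2022,stationary,1.7
imperial,2022,biogenic_soil,0.9
imperial,2022,reported_total,15.2
coachella,2022,mobile,15.9
coachella,2022,biomass_burning,0.7
coachella,2022,stationary,1.3
coachella,2022,biogenic_soil,0.1
coachella,2022,reported_total,18.0
ssab,2022,mobile,28.3
ssab,2022,biomass_burning,0.8
ssab,2022,stationary,3.0
ssab,2022,biogenic_soil,1.0
ssab,2022,reported_total,33.2
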