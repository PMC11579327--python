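site,period_start,period_end,delta_no2,delta_tno3,delta_nox,analytic_sd
Calipatria,2022-06-01,2022-06-30,-13.2,-0.02,-13.6,0.11
Calipatria,2022-07-01,2022-07-31,-13.4,-2.6,-14.1,0.11
Calipatria,2022-08-01,2022-08-31,-14.4,-9.8,-14.9,0.11
Calipatria,2022-09-01,2022-09-30,-15.6,-3.4,-16.6,0.11
Calipatria,2022-10-01,2022-10-31,-5.3,-1.1,-6.1,0.11
Calipatria,2022-11-01,2022-11-30,-12.4,-2.9,-13.4,0.11
Calipatria,2022-12-01,2022-12-31,-13.3,-2.9,-14.9,0.11
Calipatria,2023-01-01,2023-01-31,-9.6,-0.7,-11.6,0.11
Calipatria,2023-02-01,2023-02-28,-14.8,0.1,-15.5,0.11
Calipatria,2023-04-01,2023-04-30,-16.0,-3.4,-16.0,0.11
Thermal,2022-07-01,2022-07-31,-14.3,-4.5,-16.1,0.11
Thermal,2022-08-01,2022-08-31,-4.6,-4.8,-8.0,0.11
Thermal,2022-09-01,2022-09-30,-5.9,,-8.0,0.11
Thermal,2022-10-01,2022-10-31,-9.7,-8.2,-12.0,0.11
Thermal,2022-11-01,2022-11-30,1.8,2.8,0.2,0.11
Thermal,2022-12-01,2022-12-31,-7.5,3.4,-9.1,0.11
Thermal,2023-01-01,2023-01-31,-1.5,3.9,-3.2,0.11
Thermal,2023-02-01,2023-02-28,-11.3,2.6,-12.0,0.11
Thermal,2023-04-01,2023-04-30,-6.8,1.8,-7.6,0.11
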