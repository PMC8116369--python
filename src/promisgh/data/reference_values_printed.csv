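# Published PROMIS-GH reference values for the Dutch general population
# (2016 internet panel, n = 4370) alongside the US reference population,
# by gender and age band.  T-scores: mean 50 / SD 10 in the US calibration
# population; higher = better health.  US columns are external constants
# kept for side-by-side display only.
subgroup,nl_n,gmh_mean,gmh_sd,gmh2a_mean,gmh2a_sd,gph_mean,gph_sd,gph2a_mean,gph2a_sd,us_gmh_n,us_gmh_mean,us_gmh_sd,us_gph_n,us_gph_mean,us_gph_sd
total,4370,44.7,8.0,44.9,7.6,45.2,9.2,45.2,8.3,5215,50.0,10.0,5228,50.0,10.0
male,2069,45.5,8.0,45.4,7.5,46.1,9.2,45.6,8.5,2206,50.8,10.0,2212,51.2,9.8
female,2301,44.1,8.0,44.4,7.6,44.5,9.1,44.9,8.2,3008,49.4,10.0,3015,49.1,10.1
18-34,891,45.6,8.0,45.8,7.6,47.8,8.0,48.6,7.5,1183,48.5,9.7,1182,51.6,8.4
35-44,753,43.8,8.3,44.0,7.8,45.2,8.2,45.7,7.5,863,48.4,10.4,865,50.1,9.8
45-54,646,43.6,8.1,43.8,7.6,44.6,9.3,44.7,8.2,902,48.2,10.3,910,48.2,10.9
55-64,918,43.6,8.0,43.8,7.6,43.4,9.7,43.3,8.7,873,50.3,10.5,875,48.8,11.3
65-74,893,45.9,7.4,45.8,7.1,45.1,9.5,44.1,8.4,715,53.1,8.8,713,51.0,9.9
75+,269,47.3,7.7,46.8,7.4,44.9,9.8,43.7,8.7,679,53.4,8.4,683,49.9,9.2
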