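# Sociodemographic margins: the 2016 Dutch adult population (Statistics
# Netherlands, n = 13.6 million) and the study panel (n = 4370), as
# published.  Percentages per category; the age banding here (18-39 /
# 40-65 / >65) is the representativeness-check scheme, distinct from the
# reference-table age bands.  "unknown" categories are excluded from
# deviation checks.
variable,category,census_pct,sample_pct
age_band,18-39,34,33
age_band,40-65,44,44
age_band,>65,23,23
gender,male,49,47
gender,female,51,53
education,low,30,29
education,middle,40,41
education,high,30,30
region,north,10,10
region,east,21,21
region,south,22,21
region,west,47,48
region,unknown,,0
ethnicity,native,79,78
ethnicity,western_immigrant,10,12
ethnicity,non_western_immigrant,11,10
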