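# Published anchor-based interpretability thresholds for GMH and GPH
# T-scores: the four integer cut points t1 < t2 < t3 < t4 separating
# poor (< t1), fair, good, very good and excellent (>= t4), for the Dutch
# (NL) and US reference populations.  US rows are external constants.
population,subscale,t1,t2,t3,t4
NL,GMH,38,43,49,56
US,GMH,29,40,48,56
NL,GPH,35,44,51,57
US,GPH,35,42,50,58
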