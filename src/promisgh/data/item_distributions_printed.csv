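# Published item-response distributions for the Dutch general population
# (n = 4370), in display order (post-reversal for Global08/Global10; the
# pain item on its raw 0-10 scale, worst first).  Percentages per displayed
# category followed by the printed mean and SD of the displayed codes.
item_id,display_values,percentages,mean,sd
Global01,1|2|3|4|5,7.0|30.9|41.9|16.2|4.1,2.8,0.9
Global02,1|2|3|4|5,4.3|24.9|44.9|21.4|4.6,3.0,0.9
Global03,1|2|3|4|5,8.1|33.6|38.9|15.8|3.7,2.7,0.9
Global04,1|2|3|4|5,4.4|20.4|42.2|24.8|8.3,3.1,1.0
Global05,1|2|3|4|5,5.8|23.1|45.0|20.9|5.2,3.0,0.9
Global06,1|2|3|4|5,2.8|9.7|18.5|17.6|51.4,4.1,1.2
Global07,10|9|8|7|6|5|4|3|2|1|0,0.4|0.9|4.5|10.4|9.8|8.8|6.3|9.2|11.5|13.6|24.6,3.1,2.7
Global08,1|2|3|4|5,2.7|15.6|35.5|32.3|13.9,3.4,1.0
Global09,1|2|3|4|5,4.4|23.3|45.8|21.3|5.2,3.0,0.9
Global10,1|2|3|4|5,1.7|12.0|29.9|32.8|23.6,3.7,1.0
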