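# SYNTHETIC default GRM item parameters for the PROMIS-GH scored items.
# These are NOT the proprietary US calibration parameters (which are not
# redistributable here); they are a hand-chosen plausible set: global-health
# items are highly discriminating (slopes between 2.5 and 3.5 in logit
# units, as published global-health calibrations tend to be) with
# thresholds spread over the latent range.  Global06 sits lower on the
# metric (most adults manage everyday physical activities), Global07
# reflects the banded 0-10 pain item after recoding to 5 categories, and
# Global10 carries the lowest slope of its scale.  Replace with a
# calibration file of the same layout to score on an official metric.
item_id,a,b1,b2,b3,b4
Global01,3.0,-2.4,-1.0,0.6,1.9
Global02,2.9,-2.5,-1.1,0.4,1.8
Global03,3.4,-2.2,-0.9,0.6,1.9
Global04,3.0,-2.6,-1.2,0.2,1.5
Global05,2.7,-2.4,-1.1,0.5,1.8
Global06,3.1,-2.6,-1.6,-0.6,0.6
Global07,2.6,-2.0,-0.8,0.4,1.5
Global08,2.8,-2.3,-0.9,0.8,2.1
Global09,2.9,-2.5,-1.0,0.5,1.8
Global10,2.5,-2.4,-1.1,0.1,1.2
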