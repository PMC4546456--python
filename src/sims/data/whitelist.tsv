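gene	event_class
EGFR	point/indel
KRAS	point/indel
BRAF	point/indel
PIK3CA	point/indel
ERBB2	point/indel
ALK	fusion/rearrangement
ROS1	fusion/rearrangement
RET	fusion/rearrangement
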