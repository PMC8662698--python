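# Synthetic stand-in valence/arousal -> facial action unit mapping.
# Positive valence recruits the smile units (AU6 cheek raiser, AU12 lip
# corner puller); negative valence the frown units (AU1, AU4, AU15); high
# arousal adds AU5 (upper lid raiser), low arousal AU43 (eyes closed).
# Replace with an empirically derived table for production use.
valence_level	arousal_level	aus
low	low	1:0.50 4:0.60 15:0.50 43:0.60
low	medium_low	1:0.50 4:0.60 15:0.50 43:0.30
low	medium	1:0.50 4:0.60 15:0.50
low	medium_high	1:0.50 4:0.60 15:0.50 5:0.30
low	high	1:0.50 4:0.60 15:0.50 5:0.60
medium_low	low	1:0.25 4:0.30 15:0.25 43:0.60
medium_low	medium_low	1:0.25 4:0.30 15:0.25 43:0.30
medium_low	medium	1:0.25 4:0.30 15:0.25
medium_low	medium_high	1:0.25 4:0.30 15:0.25 5:0.30
medium_low	high	1:0.25 4:0.30 15:0.25 5:0.60
medium	low	43:0.60
medium	medium_low	43:0.30
medium	medium	-
medium	medium_high	5:0.30
medium	high	5:0.60
medium_high	low	6:0.30 12:0.35 43:0.60
medium_high	medium_low	6:0.30 12:0.35 43:0.30
medium_high	medium	6:0.30 12:0.35
medium_high	medium_high	6:0.30 12:0.35 5:0.30
medium_high	high	6:0.30 12:0.35 5:0.60
high	low	6:0.60 12:0.70 43:0.60
high	medium_low	6:0.60 12:0.70 43:0.30
high	medium	6:0.60 12:0.70
high	medium_high	6:0.60 12:0.70 5:0.30
high	high	6:0.60 12:0.70 5:0.60
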