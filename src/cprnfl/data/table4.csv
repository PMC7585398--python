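eye_id,label,delta_g,local,segmentation,alignment,other
62,uncertain,21.2,N/A,1,,clipping
143,uncertain,21.1,N/A,1,,clipping
1,uncertain,11.7,N/A,1,,clipping
101,uncertain,6.6,N/A,1,,
57,uncertain,-12.6,,1,2-minor,
137,uncertain,-17.6,,1,,schisis
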