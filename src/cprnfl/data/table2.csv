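eye_id,label,delta_g,local,segmentation,alignment,other
142,NP,-9.5,,,,1-clipping
144,NP,-8.5,,,,1-clipping
122,NP,-6.3,,1,,
52,NP,-5.4,,1,,
4,NP,-4.5,,1,,
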