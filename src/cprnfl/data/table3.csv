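eye_id,label,delta_g,local,segmentation,alignment,other
6,P,-3.96,2,1,,
132,P,-3.6,1,2,,
81,P,-3.0,1*,,,
114,P,-2.6,1,2,,
40,P,-2.3,1,,,
31,P,-1.8,1,2,,
95,P,-1.8,1,,,
104,P,-1.7,2,1,,
7,P,-1.5,1*,1,,
35,P,-1.4,2,1,,
79,P,-1.3,1,2,,
12,P,-0.9,1,,,
98,P,-0.9,1,,,
131,P,-0.3,1,2,,
94,P,0.6,1,2,,
60,P,3.0,1*,2,,3-clipping
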