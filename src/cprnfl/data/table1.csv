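criterion,fp,fp_pct,fn,fn_pct,accuracy_pct
QR,11,18.0,14,46.7,73
3,7,11.5,15,50.0,76
4,5,8.2,16,53.3,77
5,4,6.6,19,63.3,75
6,3,4.9,22,73.3,72
7,2,3.2,22,73.3,74
8,2,3.2,26,86.7,69
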