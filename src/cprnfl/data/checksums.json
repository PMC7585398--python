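{
 "table1.csv": "b0798610e1d15043539aa98198a65a959c5ea531b64a5062a6beafbf1484a3c0",
 "table2.csv": "eb61d059cd01899cea86f297027ba601840a974f81410a9081e5bb664186832b",
 "table3.csv": "384a3c29b8a339b39223501b6c0e8ad2717161211b22c2716e3cdd9fb0a4b4ab",
 "table4.csv": "d43d23361d7823dc25ae1d7fde4833a31e26accaf0f36c742236bcdc3c52ad5c"
}
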