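id	start	end
1	15989	16168
2	16099	16298
3	16214	16438
4	16364	16533
5	16454	74
6	23	182
7	105	304
8	235	404
9	345	530
10	456	619
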