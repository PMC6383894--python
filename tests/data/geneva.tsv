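snp_id	x1	x2	x3	n2	y
rs6646338	230	314	107	604	399
rs12010339	651	0	0	605	603
rs5935567	231	337	83	605	372
rs5968922	275	296	80	604	392
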