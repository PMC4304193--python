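study	pvalue	n
1	0.94	900
2	0.0015	1942
3	0.97	400
4	0.79	1200
5	0.81	630
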