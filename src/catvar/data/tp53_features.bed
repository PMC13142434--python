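GRCh38:chr17	7668402	7687538	TP53	0	-	gene
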