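# config_hash: e34848e8c1a5
chain	start	end	tier
A	3	7	red
A	16	20	yellow
A	24	28	blue
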