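# config_hash: e34848e8c1a5
site	start	end
5	1	8
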