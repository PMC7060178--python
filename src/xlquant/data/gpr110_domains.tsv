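name	start	end
N-terminus	1	145
SEA	148	256
GAIN	251	580
TM6	765	790
C-terminus	800	910
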