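domain_group	link	ratio_syn_oea	p_syn_oea	ratio_syn_dmso	p_syn_dmso
N-terminus	K29-K38	0.86	0.18	0.76	0.06
N-terminus	K31-K32	1.03	0.43	0.89	0.11
N-terminus	K38-K39	0.96	0.42	0.82	0.10
N-terminus	K39-K40	1.26	0.19	0.94	0.40
SEA	K151-K157	1.09	0.36	0.80	0.11
SEA	K151-K187	1.03	0.42	0.92	0.33
SEA	K151-K254	1.13	0.22	0.81	0.22
SEA	K186-K187	1.22	0.27	1.00	0.49
SEA	K187-K240	1.09	0.16	0.90	0.12
SEA	K235-K240	0.88	0.05	0.88	0.02
SEA	K240-K254	1.02	0.47	0.71	0.22
SEA-GAIN	K151-K442	0.89	0.31	0.54	0.07
GAIN	K398-K427	0.86	0.29	0.80	0.28
GAIN	K398-K438	1.53	0.05	1.90	0.03
GAIN	K398-K442	1.02	0.47	0.78	0.19
GAIN	K427-K432	1.03	0.37	1.08	0.20
GAIN	K427-K438	0.99	0.45	0.90	0.21
GAIN	K427-K442	1.08	0.08	0.90	0.05
GAIN	K432-K438	0.96	0.35	0.93	0.26
GAIN	K438-K442	1.15	0.03	1.02	0.41
TM6-C-terminus	K783-K852	1.71	0.04	1.77	0.01
C-terminus	K852-K860	1.16	0.31	0.83	0.26
C-terminus	K860-K864	1.17	0.20	0.91	0.23
C-terminus	K864-K873	1.33	0.07	1.17	0.12
C-terminus	K875-K878	1.06	0.37	1.18	0.12
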