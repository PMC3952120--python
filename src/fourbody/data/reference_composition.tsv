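class	count	proportion
C	3612988	0.633193
N	969253	0.169866
O	1088410	0.190749
S	28502	0.004995
M	2529	0.000443
X	4299	0.000754
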