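pdb	pk_exp	pk_xscore	dg_exp	dg_model
1ABE	6.52	5.25	-8.887610045	-10.3129
1ADB	8.40	8.01	-11.45029515	-23.3388
1ADD	6.74	5.36	-9.187498728	-13.1243
1AF2	3.10	4.90	-4.225704163	-10.0826
1ANF	5.46	6.03	-7.442691848	-9.59131
1CBX	6.35	5.74	-8.655877882	-11.6284
1DBM	9.44	6.65	-12.86795074	-14.9936
1DHF	7.40	5.27	-10.08716478	-13.1753
1GST	4.68	5.21	-6.379450155	-5.48917
1HPV	9.22	6.28	-12.56806206	-16.0903
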