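quad	count	f	p	s
CCCC	4015872	0.116386	0.160748	-0.140244
CCCM	1592	4.61E-05	0.000450	-0.989223
CCCN	4025206	0.116657	0.172495	-0.169866
CCCO	6202159	0.179748	0.193701	-0.032467
CCCS	293157	0.008496	0.005072	0.224008
CCCX	2796	8.10E-05	0.000765	-0.975047
CCMM	132	3.83E-06	4.73E-07	0.908235
CCMN	3318	9.62E-05	0.000362	-0.575981
CCMO	5325	0.000154	0.000407	-0.420893
CCMS	2293	6.65E-05	1.07E-05	0.795108
CCMX	15	4.35E-07	1.61E-06	-0.567697
CCNN	1797552	0.052096	0.069412	-0.124635
CCNO	8233136	0.238609	0.155892	0.184864
CCNS	124653	0.003613	0.004082	-0.053081
CCNX	2007	5.82E-05	0.000616	-1.024729
CCOO	3366568	0.097568	0.087528	0.047161
CCOS	198630	0.005757	0.004584	0.098905
CCOX	4626	0.000134	0.000691	-0.712426
CCSS	15288	0.000443	6.00E-05	0.868158
CCSX	144	4.17E-06	1.81E-05	-0.637352
CCXX	143	4.14E-06	1.37E-06	0.482159
CMMM	23	6.67E-07	2.21E-10	3.480397
CMMN	144	4.17E-06	2.54E-07	1.216422
CMMO	256	7.42E-06	2.85E-07	1.415945
CMMS	662	1.92E-05	7.46E-09	3.410480
CMMX	1	2.90E-08	1.12E-09	1.411130
CMNN	2474	7.17E-05	9.72E-05	-0.132029
CMNO	6267	0.000182	0.000218	-0.079754
CMNS	2588	7.50E-05	5.72E-06	1.118068
CMNX	26	7.54E-07	8.62E-07	-0.058415
CMOO	8481	0.000246	0.000123	0.302308
CMOS	1010	2.93E-05	6.42E-06	0.659069
CMOX	68	1.97E-06	9.68E-07	0.308765
CMSS	2047	5.93E-05	8.40E-08	2.848813
CMSX	13	3.77E-07	2.53E-08	1.172117
CMXX	6	1.74E-07	1.91E-09	1.958862
CNNN	102035	0.002957	0.012414	-0.623046
CNNO	1995038	0.057819	0.041821	0.140679
CNNS	15892	0.000461	0.001095	-0.376176
CNNX	578	1.68E-05	0.000165	-0.993919
CNOO	2734639	0.079254	0.046962	0.227273
CNOS	95438	0.002766	0.002460	0.050981
CNOX	2168	6.28E-05	0.000371	-0.771173
CNSS	4264	0.000124	3.22E-05	0.584024
CNSX	37	1.07E-06	9.71E-06	-0.957113
CNXX	61	1.77E-06	7.33E-07	0.382553
COOO	524994	0.015215	0.017579	-0.062707
COOS	34429	0.000998	0.001381	-0.141141
COOX	23801	0.000690	0.000208	0.520038
COSS	4380	0.000127	3.62E-05	0.545326
COSX	58	1.68E-06	1.09E-05	-0.812243
COXX	65	1.88E-06	8.23E-07	0.359781
CSSS	285	8.26E-06	3.16E-07	1.417735
CSSX	5	1.45E-07	1.43E-07	0.006247
CSXX	4	1.16E-07	2.15E-08	0.730845
CXXX	9	2.61E-07	1.08E-09	2.381656
MMMM	83	2.41E-06	3.86E-14	7.794725
MMMN	37	1.07E-06	5.92E-11	4.258301
MMMO	29	8.40E-07	6.64E-11	4.102142
MMMS	379	1.10E-05	1.74E-12	6.800300
MMMX	0	0	2.62E-13	--
MMNN	83	2.41E-06	3.40E-08	1.849597
MMNO	102	2.96E-06	7.64E-08	1.587734
MMNS	363	1.05E-05	2.00E-09	3.720958
MMNX	0	0	3.02E-10	--
MMOO	306	8.87E-06	4.29E-08	2.315530
MMOS	104	3.01E-06	2.25E-09	3.127729
MMOX	3	8.69E-08	3.39E-10	2.409325
MMSS	254	7.36E-06	2.94E-11	5.398477
MMSX	2	5.80E-08	8.87E-12	3.815151
MMXX	0	0	6.69E-13	--
MNNN	1030	2.99E-05	8.69E-06	0.535960
MNNO	1128	3.27E-05	2.93E-05	0.047955
MNNS	561	1.63E-05	7.67E-07	1.326526
MNNX	5	1.45E-07	1.16E-07	0.098041
MNOO	3744	0.000109	3.29E-05	0.518626
MNOS	314	9.10E-06	1.72E-06	0.723107
MNOX	29	8.40E-07	2.60E-07	0.510083
MNSS	793	2.30E-05	2.25E-08	3.008398
MNSX	5	1.45E-07	6.80E-09	1.328573
MNXX	9	2.61E-07	5.13E-10	2.706383
MOOO	5430	0.000157	1.23E-05	1.106856
MOOS	156	4.52E-06	9.67E-07	0.669977
MOOX	168	4.87E-06	1.46E-07	1.523669
MOSS	210	6.09E-06	2.53E-08	2.380989
MOSX	4	1.16E-07	7.64E-09	1.181307
MOXX	55	1.59E-06	5.76E-10	3.442148
MSSS	62	1.80E-06	2.21E-10	3.910199
MSSX	2	5.80E-08	1.00E-10	2.763224
MSXX	0	0	1.51E-11	--
MXXX	16	4.64E-07	7.58E-13	5.786451
NNNN	3878	0.000112	0.000833	-0.869698
NNNO	46665	0.001352	0.003740	-0.441730
NNNS	460	1.33E-05	9.79E-05	-0.866046
NNNX	34	9.85E-07	1.48E-05	-1.175817
NNOO	340620	0.009872	0.006299	0.195102
NNOS	5637	0.000163	0.000330	-0.305233
NNOX	302	8.75E-06	4.98E-05	-0.754766
NNSS	311	9.01E-06	4.32E-06	0.319427
NNSX	6	1.74E-07	1.30E-06	-0.874705
NNXX	5	1.45E-07	9.83E-08	0.168652
NOOO	171147	0.004960	0.004716	0.021937
NOOS	10697	0.000310	0.000370	-0.077374
NOOX	3102	8.99E-05	5.59E-05	0.206513
NOSS	922	2.67E-05	9.70E-06	0.440012
NOSX	12	3.48E-07	2.93E-06	-0.925060
NOXX	61	1.77E-06	2.21E-07	0.903627
NSSS	33	9.56E-07	8.47E-08	1.052833
NSSX	0	0	3.83E-08	--
NSXX	0	0	5.78E-09	--
NXXX	3	8.69E-08	2.91E-10	2.475964
OOOO	34212	0.000992	0.001324	-0.125549
OOOS	4240	0.000123	0.000139	-0.052504
OOOX	9553	0.000277	2.09E-05	1.121777
OOSS	300	8.69E-06	5.45E-06	0.203077
OOSX	36	1.04E-06	1.64E-06	-0.197264
OOXX	128	3.71E-06	1.24E-07	1.476181
OSSS	38	1.10E-06	9.51E-08	1.063748
OSSX	3	8.69E-08	4.30E-08	0.305472
OSXX	0	0	6.49E-09	--
OXXX	2	5.80E-08	3.26E-10	2.249518
SSSS	6	1.74E-07	6.23E-10	2.446092
SSSX	0	0	3.76E-10	--
SSXX	0	0	8.50E-11	--
SXXX	0	0	8.55E-12	--
XXXX	0	0	3.22E-13	--
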